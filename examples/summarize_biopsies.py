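"""Non-phylogenetic summaries of a simulated individual's SGA matrix.

Per-biopsy burden (count, Mb, percent of a 3,164 Mb genome), pairwise
genetic divergence in time and space, lesion appearance/regression flux
across NSAID intervals, dropout probability, and tree-shape imbalance of
the true genealogy.
"""

from sgaclock.cohort import CohortConfig, simulate_individual
from sgaclock.summaries import (
    divergence_trends,
    dropout_probability,
    lesion_flux,
    pairwise_divergence,
    sga_burden,
    tree_imbalance,
)

ind = simulate_individual(CohortConfig(n_biopsies=9, lam_off=2.0, lam_on=0.4),
                          seed=5)
m = ind.truth_matrix

burden = sga_burden(m)
print("per-biopsy SGA burden (first rows):")
print(burden.head(4).to_string(index=False, float_format=lambda v: f"{v:.2f}"))

records = pairwise_divergence(m)
print(f"\n{len(records)} biopsy pairs; mean Hamming distance "
      f"{sum(r.hamming for r in records) / len(records):.1f} characters")
print(divergence_trends(records).to_string(index=False))

flux = lesion_flux(m)
print(f"\nnew lesions by interval condition:")
print(flux.groupby("nsaid")["n_new"].sum().to_string())

for est in dropout_probability(m):
    print(f"dropout 1-P {est.nsaid}-NSAID: {est.dropout:.2f} "
          f"({est.dropped}/{est.opportunities} lesion-timepoints)")

imb = tree_imbalance(ind.tree, "yule", n_random=500, seed=1)
print(f"\ntree imbalance: Colless {imb.colless} (Yule p={imb.p_colless:.2f}), "
      f"Sackin {imb.sackin} (p={imb.p_sackin:.2f})")
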