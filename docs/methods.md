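# Methods

## Scope

`sgaclock` is a simulation-and-inference pipeline for clonal evolution
in Barrett's esophagus (BE).  It has three layers: a synthetic-cohort
generator with complete ground truth; an SGA caller turning probe-level
SNP-array signals into binary biopsy × character matrices; and the
evolutionary analyses — a Bayesian two-epoch rate sampler, irreversible
parsimony, and non-phylogenetic summary statistics.  Real array data can
enter at the probe-table stage; every downstream stage is testable
without any external data because the generator produces the same
formats.

## Crypt demography

The BE segment is a population of crypts growing logistically from one
founder crypt: N(t) = K / (1 + (K−1)e^(−rt)) with r = ln 2 / T_r and
T_r the crypt doubling time in days.  The time from initiation to the
N_t crypts present at baseline endoscopy has the closed form
T_init = (1/r)·ln(N_t(K−1)/(K−N_t)).  T_r can be estimated from the
fraction I_b of crypts caught branching in histology under a snapshot
model, T_r = visibility / I_b, with a configurable branching-visibility
window (default 30 days); this is an order-of-magnitude device, not a
measurement.  Defaults — K = 50,000 crypts, N_t = 30,000, I_b = 0.05,
hence T_r = 600 d and T_init ≈ 26.6 y — describe a several-centimetre
segment whose crypt counts are in the tens of thousands and that
initiated decades before surveillance.  A baseline exactly at carrying
capacity has no finite initiation time; `build_demography` nudges it to
K − 0.5 with a warning.

## Genealogy prior and simulation

Biopsies are tips of a serial-sample coalescent with pairwise intensity
1/N(t) per year (times an optional `pop_scale` for generation-time
scaling; default 1).  The reciprocal logistic has a closed-form
antiderivative, so both simulation (by inverting the cumulative hazard
against exponential draws) and the density (survival terms
exp(−k(k−1)/2·∫1/N) plus 1/N per coalescence) avoid numerical
quadrature.  Lineages not coalesced by initiation are forced to coalesce
there — the founder crypt — with nanosecond-scale stagger to keep the
tree binary; the event is logged.  The MRCA attaches to a LUCA node at
the initiation time (overridable), representing the last cell with the
unaltered genome.

With the default demography, coalescence between biopsy lineages within
follow-up is rare (intensity ~1/30,000 per pair-year), so simulated
genealogies are deep and near-star-shaped: most clonal divergence dates
to segment expansion.  This matches the observation that most SGAs are
already present at the first endoscopy.

## SGA events

Events arise on branches as a Poisson process with genome-wide intensity
λ_off during off-NSAID calendar time and λ_on during on-NSAID time
(branches spanning the transition are split).  The transition time is
the midpoint between the two flanking endoscopies.  Each event draws a
chromosome (by length), a log-uniform interval size (default 0.1–100 Mb),
one of seven altered molecular states (weights favouring losses and
copy-neutral LOH), and a parental haplotype.  Events are inherited by
all descendant tips and never revert.  With small probability (default
0.01) an event reuses an earlier event's interval/state/haplotype,
producing homoplasy.  Overlapping events on one lineage are applied
oldest-first with later events overriding in the overlap; at the default
densities overlaps are rare.  Defaults λ_off = 8 and λ_on = 0.6 SGAs
per genome per year are the study conditions the pipeline is exercised
under.

## Array signals

Per-probe expectations follow allelic arithmetic: R = copies/2 (control
diploid R ≡ 1) and BAF = B-copies/copies; e.g. AAB gives R = 1.5 and
BAF ∈ {1/3, 2/3}, copy-neutral LOH gives R = 1 and BAF ∈ {0, 1}.  A
piecewise-linear dye-bias warp moves the heterozygous BAF median to 0.53
(anchors 0 and 1 fixed), then Gaussian noise is added.  The intensity
channel gets `noise_sd` (default 0.15); the BAF channel of genotyping
arrays is cluster-calibrated and much tighter, so its noise defaults to
`noise_sd`/3.  15% of biopsies are simulated as two-clone mixtures: the
tip clone blended allele-wise with its parent clone (pendant-branch
events removed) at fraction 0.3.  Probes are evenly spaced with ~30%
heterozygous and known phase.  Tips are assigned to contiguous cm-level
blocks of the segment in clade order — a plausible stand-in for the
unknown spatial process placing clones along the segment.  Not modelled:
raw two-colour normalization, GC waves, probe-specific biases.

## The caller

Per individual: the 0.2% lowest-intensity control probes are excluded
(ties broken by genomic order); dye bias is corrected using the
control-derived warp (the control is diploid everywhere, so its het-BAF
median estimates the assay bias cleanly); heterozygous probes are those
with control BAF strictly inside (0.33, 0.66); three profiles are built
— log2(R/R_control) at het and at hom probes, and mirrored BAF
(mBAF = |BAF−0.5|·2) at het probes.

Breakpoints come from our own multiscale Haar detector: step-kernel
coefficients at scales 2^3..2^9 probes, normalized by a robust noise
estimate, local maxima pooled across scales, Benjamini–Hochberg selected
at fdr_q = 1e−4, unified fine-to-coarse.  Detections from different
profiles and biopsies within a few probes are consolidated; each cluster
is refined per owning biopsy (so a nearby stronger boundary of another
biopsy cannot capture it), re-grouped, and finally localized by a
maximum-likelihood changepoint stage whose flank means are estimated
outside the candidate bracket.  Candidates with no locally significant
step in any profile are phantoms (coarse-scale echoes) and are dropped.
Detection is limited to events spanning at least ~2× the smallest Haar
scale in their informative track; copy-neutral LOH is visible only at
heterozygous probes and therefore localizes to the het-probe spacing.

Events are the intervals between consecutive breakpoints in the union
over all profiles and biopsies — identical breakpoints define identical
events.  Each event in each biopsy receives one of eight states
(AB, AA, A, 0, AAB, AAA, AAAA, AABB) from threshold boxes on two
statistics of the *biopsy's own* enclosing segment (so events fragmented
by other biopsies' breakpoints keep full statistical support): the
pooled log2 R-ratio, and a noise-debiased allelic split.  Mirroring BAF
folds noise upward (a balanced segment at BAF noise 0.05 has mean mBAF
≈ 0.08, and leaked homozygous probes sit at mBAF ≈ 1), so the split is
estimated by inverting the median of the folded distribution,
median(|N(μ, σ)|) = observed, with σ estimated from the control's het
probes via a truncated-normal correction (het probes are selected by the
same window that truncates their spread).  Default boxes are canonical
noiseless levels ± margins; the double-loss boundary sits at
log2 R = −2.5 so that noisy single-loss fragments cannot cross it.
Thresholds are configuration, not constants — measured values can be
substituted.  Unmatched combinations fall back to AB.  The exact closure
of the het window, the dye-bias mechanism (warp vs shift), and the
haplotype vote rule are not pinned down by any published description; we
document our choices here and keep them configurable.

Tiny interior fragments (< 4 probes) flanked by identical calls are
segmentation speckles and absorbed.  Adjacent events with identical
state vectors across all biopsies are merged.  Where phase is known,
allelic-imbalance calls are haplotype-resolved by majority vote of the
het probes' skew direction against the phase; exact ties keep the
A-form flagged unresolved.  The binary matrix has one column per
(interval, haplotype-form); the two forms of one interval are distinct
characters.  Clone mixtures are flagged when ≥ 2 segments show allelic
splits away from every single-clone level {0, 1/3, 1} (tolerance 0.1) —
e.g. a 50/50 mixture of AB and AA clones plateaus at 0.5.

## Likelihood and ascertainment

The irreversible binary model has P(0→0) = e^(−μt), P(1→0) = 0.  The
genome-wide rate divides by the size of the character universe to give
μ.  Two universes are supported: the observed characters only (the
`tree_log_likelihood` default, matching a finite-characters reading),
and an inflated universe whose excess enters as all-zero columns.  The
sampler defaults to 20× inflation: the generative process is a Poisson
event stream, and the finite-character model saturates (a character
cannot be gained twice), which with the deep genealogies here inflates
rate estimates by roughly half the per-branch per-character intensity
(~8% under the default conditions); in the large-universe limit the
likelihood converges to the Poisson process and the bias vanishes.
Identical matrix columns are collapsed to unique patterns with
multiplicities before pruning.

Rate inference removes characters detected in any biopsy of the first
endoscopy (clonal evolution before surveillance is not the target), and
the likelihood is conditioned on exactly that filtering: each character's
probability is divided by the probability that every baseline biopsy is
0.  Without this conditioning the estimator divides observed events by
branch lengths on which the retained events could never occur, biasing
rates downward by tens of percent under the default conditions.
Branch segments before baseline accrue the first epoch's rate.  An
optional exponential prior on the LUCA stem duration is computed and
reported separately.

## MCMC

Metropolis–Hastings over (genealogy, λ_off, λ_on[, pop_scale]):
multiplier and prior-redraw moves on rates (wide and narrow windows
mixed), uniform node-time slides within parent/child bounds, LUCA-time
slides bounded one year older than the demography's initiation estimate,
and narrow/wide subtree exchanges (disabled at ≤ 4 tips, where time
moves dominate anyway).  Uniform rate priors on [1e−5, 1e4].  Defaults:
2×10^5 iterations, thinning 100, burn-in 10% — sized for per-individual
matrices with a few thousand characters on 12 tips, where a chain takes
on the order of a minute.  Summaries report posterior means, central 95%
support intervals (2.5–97.5% quantiles; HPD intervals are computed too
but the central interval is the default), and ESS from the initial
positive-sequence autocorrelation estimator.

Under the default conditions λ_off is tightly identified (thousands of
retained characters) while λ_on is weakly identified: events are not
directly dated, most branches span both epochs, and with deep
coalescence few characters are confined to the on-NSAID window.  Its
posterior is wide but covers the truth; simulation-based calibration
(five replicates at full chain length) shows ≥ 4/5 coverage for both
rates and the correct rate ordering in ≥ 4/5 replicates.

## Parsimony

With reversals forbidden and an all-zero LUCA root, the minimum number
of 0→1 gains for a character has a unique realization: one gain on the
stem of each maximal clade whose tips all carry it, which is also the
DELTRAN (latest) placement; a character in all tips gains once on the
LUCA→MRCA stem.  Search is exhaustive up to 9 taxa (rooted topologies
enumerated by leaf insertion) and SPR hill-climbing with random restarts
beyond; all co-optimal topologies are returned in sorted-Newick order
and downstream branch statistics use the first.  Branch lengths are
event counts or the Mb sum of placed characters.  Epoch labels follow
descent: for off→on individuals a branch is "off" iff any descendant
tip is an off-NSAID biopsy; mirrored for on→off.

## Summaries

Burden: row sums, Mb sums, and percent of a 3,164 Mb genome.  Pairwise
divergence: Hamming distance and the Mb of the symmetric difference over
genome Mb, stratified three ways (within-time-point against follow-up
time; within ±1 cm against temporal gap; within-time-point against
spatial gap) with least-squares trends where a stratum has ≥ 3 pairs.
Lesion flux: per inter-endoscopy interval, "new" characters (first
observed at the closing time point) and "regressed" ones (previously
observed, absent from all biopsies at the closing time point), binned by
size (log-spaced 0–100 Mb, 6 bins) and compared off- vs on-NSAID by
one-sided rank-sum tests.  Dropout: persistence P = persisting
lesion-timepoints / tracking opportunities per NSAID condition; under
perfect detection 1−P still exceeds zero because co-existing clones are
sampled alternately.  Tree imbalance: Colless and Sackin indices with
Monte-Carlo p-values against Yule (random tip splitting) and PDA
(uniform labeled topologies) nulls, 500 trees by default.

## Numerical and design notes

* Coordinates are 0-based half-open everywhere; trees serialize as
  Newick with branch lengths in years and the LUCA time in a root
  comment, via dendropy.
* Every stochastic routine takes a seed or Generator; identical
  config + seed reproduces every artifact byte-for-byte.
* The caller's breakpoint identity across biopsies is enforced by
  consolidation + joint refinement; truly shared boundaries settle on
  one probe, distinct nearby boundaries stay distinct if their evidence
  separates by more than ~3 probes.
* Degenerate inputs: empty matrices are valid (zero likelihood
  contribution, prior-only inference); a character impossible under the
  rates yields −inf log-likelihood; chromosomes shorter than twice the
  smallest Haar scale yield no breakpoints.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the real study — serial
sampling, crypt-limited coalescence, two-epoch rates, eight-state
signals with dye bias, mixtures and homoplasy — but idealizes the
noise: probe noise is i.i.d. Gaussian, probes are evenly spaced, phase
is known exactly, and there are no GC waves, batch effects, or
germline CNVs beyond the low-intensity exclusion.  Passing the
round-trip and calibration suites therefore demonstrates correctness of
the algorithms under the stated model, not performance on raw clinical
arrays; threshold tables and noise parameters would need re-estimation
against real control data.
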