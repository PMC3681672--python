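"""Non-phylogenetic summary statistics of SGA matrices and tree shape.

Covers per-biopsy SGA burden (count, Mb, percent of a 3,164 Mb genome),
pairwise genetic divergence in time and space, lesion appearance /
regression flux across NSAID intervals, lesion dropout probability, and
Colless/Sackin tree-imbalance tests against Yule and PDA null models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import BiopsyMeta, SgaMatrix
from .trees import SampledTree, TreeNode

GENOME_LENGTH_MB = 3164.0  # GRCh37.p5 length used for percent-of-genome


# --------------------------------------------------------------------------
# burden
# --------------------------------------------------------------------------

def sga_burden(
    matrix: SgaMatrix,
    genome_length_mb: float = GENOME_LENGTH_MB,
    meta: dict[str, BiopsyMeta] | None = None,
) -> pd.DataFrame:
    """Per-biopsy SGA burden: event count, Mb affected, percent of genome.

    Percent = 100 * Mb / genome_length_mb; non-overlap of characters is
    assumed (characters tile distinct intervals within an individual).
    """
    if genome_length_mb <= 0:
        raise ValueError("genome_length_mb must be positive")
    meta = meta if meta is not None else matrix.meta
    sizes_mb = matrix.sizes_bp / 1e6
    rows = []
    for bid, presence in zip(matrix.biopsy_ids, matrix.data):
        mb = float(presence @ sizes_mb)
        rows.append(
            {
                "biopsy_id": bid,
                "sample_time": meta[bid].sample_time if bid in meta else math.nan,
                "n_sga": int(presence.sum()),
                "mb": mb,
                "percent_genome": 100.0 * mb / genome_length_mb,
            }
        )
    return pd.DataFrame(rows)


def burden_by_timepoint(burden: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of burden per endoscopy time point."""
    return (
        burden.groupby("sample_time")[["n_sga", "mb", "percent_genome"]]
        .agg(["mean", "std"])
        .reset_index()
    )


def percent_of_genome(mb: float, genome_length_mb: float = GENOME_LENGTH_MB) -> float:
    return 100.0 * mb / genome_length_mb


# --------------------------------------------------------------------------
# pairwise divergence
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergenceRecord:
    biopsy_a: str
    biopsy_b: str
    hamming: int
    proportion: float  # symmetric-difference Mb / genome Mb
    temporal_gap: float  # |years|
    spatial_gap: float  # |cm|
    sample_time_a: float
    sample_time_b: float


def pairwise_divergence(
    matrix: SgaMatrix,
    meta: dict[str, BiopsyMeta] | None = None,
    genome_length_mb: float = GENOME_LENGTH_MB,
) -> list[DivergenceRecord]:
    """All within-individual biopsy pairs scored on both metrics."""
    meta = meta if meta is not None else matrix.meta
    ids = [b for b in matrix.biopsy_ids if not (b in meta and meta[b].is_control)]
    sizes_mb = matrix.sizes_bp / 1e6
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            xa, xb = matrix.row(a), matrix.row(b)
            diff = xa != xb
            out.append(
                DivergenceRecord(
                    a, b,
                    hamming=int(diff.sum()),
                    proportion=float(diff @ sizes_mb) / genome_length_mb,
                    temporal_gap=abs(meta[a].sample_time - meta[b].sample_time),
                    spatial_gap=abs(meta[a].level - meta[b].level),
                    sample_time_a=meta[a].sample_time,
                    sample_time_b=meta[b].sample_time,
                )
            )
    return out


def divergence_trends(
    records: list[DivergenceRecord],
    level_window_cm: float = 1.0,
    metric: str = "hamming",
) -> pd.DataFrame:
    """Least-squares trend per stratum.

    Strata mirror the three columns of the divergence analysis: pairs
    within a time point against follow-up time; pairs within +/- 1 cm
    against temporal distance; same-time-point pairs against spatial
    distance.  Strata with fewer than 3 pairs omit the slope.
    """
    getv = (lambda r: r.hamming) if metric == "hamming" else (lambda r: r.proportion)
    strata = {
        "within_timepoint_vs_followup": [
            (r.sample_time_a, getv(r)) for r in records if r.temporal_gap == 0
        ],
        "within_level_vs_time": [
            (r.temporal_gap, getv(r)) for r in records if r.spatial_gap <= level_window_cm
        ],
        "within_timepoint_vs_space": [
            (r.spatial_gap, getv(r)) for r in records if r.temporal_gap == 0
        ],
    }
    rows = []
    for name, pts in strata.items():
        row = {"stratum": name, "n_pairs": len(pts)}
        xs = np.array([p[0] for p in pts], dtype=float)
        ys = np.array([p[1] for p in pts], dtype=float)
        if len(pts) >= 3 and np.ptp(xs) > 0:
            fit = stats.linregress(xs, ys)
            row.update(slope=fit.slope, intercept=fit.intercept, pvalue=fit.pvalue)
        else:
            row.update(slope=math.nan, intercept=math.nan, pvalue=math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# lesion flux and dropout
# --------------------------------------------------------------------------

def default_size_bins(max_bp: float = 1e8, n_bins: int = 6) -> np.ndarray:
    """Log-spaced lesion-size bin edges over 0 bp - 100 Mb."""
    return np.concatenate([[0.0], np.logspace(5, math.log10(max_bp), n_bins)])


def _presence_by_timepoint(
    matrix: SgaMatrix, meta: dict[str, BiopsyMeta]
) -> tuple[list[float], np.ndarray]:
    """(sorted time points, presence[tp, char]) with presence = any biopsy."""
    ids = [b for b in matrix.biopsy_ids if not (b in meta and meta[b].is_control)]
    tps = sorted({meta[b].sample_time for b in ids})
    pres = np.zeros((len(tps), matrix.n_characters), dtype=bool)
    for b in ids:
        i = tps.index(meta[b].sample_time)
        pres[i] |= matrix.row(b).astype(bool)
    return tps, pres


def lesion_flux(
    matrix: SgaMatrix,
    meta: dict[str, BiopsyMeta] | None = None,
    size_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """New and regressed lesion counts per inter-endoscopy interval and size bin.

    "New" = character first observed at the closing time point of the
    interval; "regressed" = previously observed character absent from all
    biopsies at the closing time point.  Intervals are labeled with the
    NSAID status at their closing endoscopy.
    """
    meta = meta if meta is not None else matrix.meta
    size_bins = size_bins if size_bins is not None else default_size_bins()
    tps, pres = _presence_by_timepoint(matrix, meta)
    if len(tps) < 2:
        raise ValueError("need at least two time points")
    status_at = {}
    for b in matrix.biopsy_ids:
        if b in meta and not meta[b].is_control:
            status_at[meta[b].sample_time] = meta[b].nsaid_status
    sizes = matrix.sizes_bp
    bin_of = np.clip(np.searchsorted(size_bins, sizes, side="right") - 1, 0,
                     len(size_bins) - 2)
    rows = []
    ever_before = pres[0].copy()
    for i in range(1, len(tps)):
        new = pres[i] & ~ever_before
        regressed = ever_before & ~pres[i]
        for b in range(len(size_bins) - 1):
            rows.append(
                {
                    "interval_end": tps[i],
                    "nsaid": status_at[tps[i]],
                    "size_bin": b,
                    "bin_lo_bp": size_bins[b],
                    "bin_hi_bp": size_bins[b + 1],
                    "n_new": int((new & (bin_of == b)).sum()),
                    "n_regressed": int((regressed & (bin_of == b)).sum()),
                }
            )
        ever_before |= pres[i]
    return pd.DataFrame(rows)


def flux_rank_tests(flux: pd.DataFrame) -> pd.DataFrame:
    """One-sided rank-sum tests per size bin: more new lesions off-NSAIDs."""
    rows = []
    for b, grp in flux.groupby("size_bin"):
        off = grp.loc[grp.nsaid == "off", "n_new"].to_numpy()
        on = grp.loc[grp.nsaid == "on", "n_new"].to_numpy()
        if len(off) and len(on):
            stat = stats.mannwhitneyu(off, on, alternative="greater")
            rows.append({"size_bin": b, "u": stat.statistic, "pvalue": stat.pvalue})
        else:
            rows.append({"size_bin": b, "u": math.nan, "pvalue": math.nan})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DropoutEstimate:
    """Per-condition lesion persistence for one individual."""

    individual_id: str
    nsaid: str  # condition of the closing endoscopy of the intervals
    opportunities: int  # lesion-timepoint tracking opportunities
    dropped: int
    persistence: float  # P
    dropout: float  # 1 - P


def dropout_probability(
    matrix: SgaMatrix, meta: dict[str, BiopsyMeta] | None = None
) -> list[DropoutEstimate]:
    """Lesion dropout probability 1-P per NSAID condition.

    An opportunity is a lesion observed at time point t whose next time
    point t+1 was sampled; it persists if seen in any biopsy at t+1.
    """
    meta = meta if meta is not None else matrix.meta
    some = next(iter(meta.values()))
    tps, pres = _presence_by_timepoint(matrix, meta)
    if len(tps) < 2:
        raise ValueError("need at least two time points")
    status_at = {
        meta[b].sample_time: meta[b].nsaid_status
        for b in matrix.biopsy_ids
        if b in meta and not meta[b].is_control
    }
    counts: dict[str, list[int]] = {"on": [0, 0], "off": [0, 0]}  # [opportunities, drops]
    for i in range(len(tps) - 1):
        cond = status_at[tps[i + 1]]
        tracked = pres[i]
        dropped = tracked & ~pres[i + 1]
        counts[cond][0] += int(tracked.sum())
        counts[cond][1] += int(dropped.sum())
    out = []
    for cond, (opp, drop) in counts.items():
        if opp == 0:
            continue
        p = 1.0 - drop / opp
        out.append(DropoutEstimate(some.individual_id, cond, opp, drop, p, 1.0 - p))
    return out


# --------------------------------------------------------------------------
# tree imbalance
# --------------------------------------------------------------------------

def colless_index(tree: SampledTree) -> int:
    """Sum over internal nodes of |left tips - right tips| (LUCA excluded)."""
    sizes: dict[int, int] = {}
    total = 0
    for node in tree.postorder():
        if node.is_leaf:
            sizes[id(node)] = 1
        elif node is not tree.luca:
            left, right = (sizes[id(c)] for c in node.children)
            sizes[id(node)] = left + right
            total += abs(left - right)
    return total


def sackin_index(tree: SampledTree) -> int:
    """Sum of tip depths (edges from the MRCA)."""
    depth = {id(tree.mrca): 0}
    total = 0
    for node in tree.preorder():
        if node is tree.luca or node is tree.mrca:
            continue
        depth[id(node)] = depth[id(node.parent)] + 1
        if node.is_leaf:
            total += depth[id(node)]
    return total


def _random_topology(n: int, rng: np.random.Generator, model: str) -> SampledTree:
    names = [f"t{i}" for i in range(n)]
    if model == "yule":
        # growth by splitting a uniformly chosen extant tip
        tips = [TreeNode(names[0], 0.0), TreeNode(names[1], 0.0)]
        root = TreeNode(time=-1.0)
        root.add_child(tips[0])
        root.add_child(tips[1])
        for k in range(2, n):
            tip = tips[int(rng.integers(len(tips)))]
            a, b = TreeNode(tip.name, 0.0), TreeNode(names[k], 0.0)
            tip.name = None
            tip.add_child(a)
            tip.add_child(b)
            tips.remove(tip)
            tips.extend([a, b])
        _fix_times(root)
    elif model == "pda":
        # uniform over labeled rooted topologies: insert each new leaf on a
        # uniformly chosen edge (including the stem)
        root = TreeNode(names[0], 0.0)
        for k in range(1, n):
            edges = _all_nodes(root)
            target = edges[int(rng.integers(len(edges)))]
            new_internal = TreeNode()
            new_leaf = TreeNode(names[k], 0.0)
            parent = target.parent
            if parent is None:
                root = new_internal
            else:
                parent.children[parent.children.index(target)] = new_internal
                new_internal.parent = parent
            new_internal.children = []
            new_internal.add_child(target)
            new_internal.add_child(new_leaf)
        _fix_times(root)
    else:
        raise ValueError("null model must be 'yule' or 'pda'")
    luca = TreeNode("LUCA", root.time - 1.0)
    luca.add_child(root)
    return SampledTree(luca)


def _all_nodes(root: TreeNode) -> list[TreeNode]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _fix_times(root: TreeNode) -> None:
    def depth_below(n: TreeNode) -> int:
        return 0 if n.is_leaf else 1 + max(depth_below(c) for c in n.children)

    def setter(n: TreeNode) -> None:
        if n.is_leaf:
            n.time = 0.0
            return
        for c in n.children:
            setter(c)
        n.time = -float(depth_below(n))

    setter(root)


@dataclass(frozen=True)
class ImbalanceTest:
    colless: int
    sackin: int
    null_model: str
    n_random: int
    p_colless: float  # fraction of null trees at least as imbalanced
    p_sackin: float


def tree_imbalance(
    tree: SampledTree, null: str = "yule", n_random: int = 500, seed: int = 0
) -> ImbalanceTest:
    """Colless/Sackin imbalance with Monte-Carlo p-values under a null."""
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    for node in tree.postorder():
        if not node.is_leaf and node is not tree.luca and len(node.children) != 2:
            raise ValueError("imbalance indices require a binary tree")
    n = len(tree.tips())
    rng = np.random.default_rng(seed)
    obs_c, obs_s = colless_index(tree), sackin_index(tree)
    null_c = np.empty(n_random)
    null_s = np.empty(n_random)
    for i in range(n_random):
        t = _random_topology(n, rng, null)
        null_c[i] = colless_index(t)
        null_s[i] = sackin_index(t)
    return ImbalanceTest(
        obs_c, obs_s, null, n_random,
        float(np.mean(null_c >= obs_c)), float(np.mean(null_s >= obs_s)),
    )
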