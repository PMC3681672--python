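"""Bayesian MCMC over genealogies and epoch-specific SGA rates.

The posterior couples

* the irreversible binary-character likelihood of the SGA matrix on a
  dated genealogy with a LUCA stem (per-character rate = genome rate /
  number of characters), conditioned on characters not having been
  detected at baseline (matching the preprocessing that removes
  baseline-detected characters),
* the serial-sample coalescent density under the logistic crypt
  demography, and
* uniform priors on the two genome-wide rates over [1e-5, 1e4] events
  per genome per year, with the LUCA (segment initiation) time bounded
  one year older than the demography's initiation estimate.

Moves: rate multipliers and prior redraws, node-time slides, LUCA-time
slides, narrow/wide subtree exchanges, and an optional population-scale
multiplier.  Topology moves are skipped for <= 4 tips, where topology
space is tiny and node-time moves dominate anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import LogisticDemography
from .likelihood import (
    RATE_LOWER,
    RATE_UPPER,
    EpochModel,
    logistic_coalescent_log_density,
    tree_log_likelihood,
)
from .matrix import BiopsyMeta, SgaMatrix
from .trees import SampledTree, TreeNode


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess_matrix(
    matrix: SgaMatrix, meta: dict[str, BiopsyMeta] | None = None
) -> tuple[SgaMatrix, set[str]]:
    """Drop characters detected in any baseline biopsy.

    Baseline = the earliest sample_time among the individual's
    non-control biopsies.  Returns the filtered matrix (column order
    stable) and the baseline biopsy ids (used to condition the
    likelihood on the same filtering).  Idempotent.
    """
    meta = meta if meta is not None else matrix.meta
    times = {
        b: meta[b].sample_time
        for b in matrix.biopsy_ids
        if b in meta and not meta[b].is_control
    }
    if not times:
        raise ValueError("no biopsy metadata to identify the baseline time point")
    t0 = min(times.values())
    baseline = {b for b, t in times.items() if t == t0}
    rows = [matrix.biopsy_ids.index(b) for b in baseline]
    seen_at_baseline = matrix.data[rows].any(axis=0)
    return matrix.select_characters(~seen_at_baseline), baseline


# --------------------------------------------------------------------------
# state and posterior
# --------------------------------------------------------------------------

@dataclass
class McmcState:
    tree: SampledTree
    lam_off: float
    lam_on: float
    pop_scale: float
    log_likelihood: float = math.nan
    log_coalescent: float = math.nan

    def log_posterior(self) -> float:
        # rate priors are uniform (constant) within support
        return self.log_likelihood + self.log_coalescent


@dataclass
class McmcOptions:
    iterations: int = 200_000
    thin: int = 100
    likelihood_on: bool = True
    sample_pop_scale: bool = False
    ascertainment: str = "baseline"  # "baseline" | "none"
    universe_factor: float = 20.0  # character universe / observed characters
    sample_node_times: bool = True  # False: topology and times held fixed
    rate_window: float = 0.6  # log-scale multiplier half-width
    luca_slack_years: float = 1.0  # LUCA bound beyond the initiation estimate
    store_trees_every: int = 0  # 0 = no tree samples


@dataclass
class McmcRun:
    trace: pd.DataFrame
    acceptance: dict[str, float]
    trees: list[str] = field(default_factory=list)
    final_state: McmcState | None = None


def _posterior_parts(
    state: McmcState,
    matrix: SgaMatrix,
    epochs_pattern: str,
    t_switch: float,
    demography: LogisticDemography,
    baseline: set[str],
    opts: McmcOptions,
) -> tuple[float, float]:
    epochs = EpochModel(
        epochs_pattern, t_switch,
        lam_off=state.lam_off, lam_on=state.lam_on,
    )
    if opts.likelihood_on:
        n_univ = max(
            matrix.n_characters,
            int(round(opts.universe_factor * matrix.n_characters)),
        ) or None
        like = tree_log_likelihood(
            state.tree, matrix, epochs,
            n_character_universe=n_univ,
            ascertainment=opts.ascertainment if matrix.n_characters else "none",
            baseline_ids=baseline,
        ).log_likelihood
    else:
        like = 0.0
    coal = logistic_coalescent_log_density(state.tree, demography, state.pop_scale)
    return like, coal


def run_mcmc(
    matrix: SgaMatrix,
    meta: dict[str, BiopsyMeta],
    pattern: str,
    t_switch: float,
    demography: LogisticDemography,
    seed: int | np.random.Generator,
    opts: McmcOptions | None = None,
    initial_tree: SampledTree | None = None,
) -> McmcRun:
    """Metropolis-Hastings sampler over (tree, lam_off, lam_on[, scale]).

    ``matrix`` should already be baseline-filtered (see
    :func:`preprocess_matrix`); baseline biopsies stay in the tree as
    all-zero taxa.  Reproducible given the seed.
    """
    opts = opts or McmcOptions()
    if opts.iterations < 1:
        raise ValueError("iterations must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    times = {b: meta[b].sample_time for b in matrix.biopsy_ids}
    t0 = min(times.values())
    baseline = {b for b, t in times.items() if t == t0}
    luca_floor = -(demography.T_init + opts.luca_slack_years)

    if initial_tree is None:
        from .cohort import simulate_genealogy

        by_time: dict[float, list[str]] = {}
        for b, t in times.items():
            by_time.setdefault(float(t), []).append(b)
        initial_tree = simulate_genealogy(
            demography, sorted(by_time.items()), rng, pop_scale=1.0
        )
    state = McmcState(initial_tree.copy(), lam_off=1.0, lam_on=1.0, pop_scale=1.0)
    state.log_likelihood, state.log_coalescent = _posterior_parts(
        state, matrix, pattern, t_switch, demography, baseline, opts
    )

    internal_nodes = lambda tree: tree.internal_nodes()  # noqa: E731
    n_tips = len(matrix.biopsy_ids)
    topology_moves = n_tips > 4

    moves = ["rate_scale", "rate_prior"]
    weights = [4.0, 1.0]
    if opts.sample_node_times:
        moves += ["node_slide", "luca_slide"]
        weights += [4.0, 1.0]
        if topology_moves:
            moves += ["narrow_exchange", "wide_exchange"]
            weights += [2.0, 1.0]
    if opts.sample_pop_scale:
        moves.append("scale_pop")
        weights.append(1.0)
    weights = np.array(weights) / sum(weights)
    attempts = {m: 0 for m in moves}
    accepts = {m: 0 for m in moves}

    records = []
    trees: list[str] = []

    def try_accept(move: str, proposal: McmcState, log_hastings: float) -> None:
        nonlocal state
        attempts[move] += 1
        try:
            proposal.log_likelihood, proposal.log_coalescent = _posterior_parts(
                proposal, matrix, pattern, t_switch, demography, baseline, opts
            )
        except ValueError:
            return
        log_ratio = proposal.log_posterior() - state.log_posterior() + log_hastings
        if math.isnan(log_ratio):
            return
        if log_ratio >= 0 or rng.uniform() < math.exp(max(log_ratio, -745.0)):
            state = proposal
            accepts[move] += 1

    for it in range(opts.iterations):
        move = moves[int(rng.choice(len(moves), p=weights))]
        if move == "rate_scale":
            which = "lam_off" if rng.uniform() < 0.5 else "lam_on"
            # mix wide and narrow multipliers: wide steps cross the prior's
            # orders of magnitude, narrow ones resolve a tight posterior
            window = opts.rate_window if rng.uniform() < 0.5 else opts.rate_window / 6.0
            m = math.exp(rng.uniform(-window, window))
            new = getattr(state, which) * m
            if RATE_LOWER <= new <= RATE_UPPER:
                prop = McmcState(state.tree, state.lam_off, state.lam_on, state.pop_scale)
                setattr(prop, which, new)
                try_accept(move, prop, math.log(m))
        elif move == "rate_prior":
            which = "lam_off" if rng.uniform() < 0.5 else "lam_on"
            prop = McmcState(state.tree, state.lam_off, state.lam_on, state.pop_scale)
            setattr(prop, which, rng.uniform(RATE_LOWER, RATE_UPPER))
            try_accept(move, prop, 0.0)
        elif move == "node_slide":
            tree = state.tree.copy()
            nodes = internal_nodes(tree)
            node = nodes[int(rng.integers(len(nodes)))]
            lo = node.parent.time
            hi = min(c.time for c in node.children)
            node.time = rng.uniform(lo, hi)
            try_accept(move, McmcState(tree, state.lam_off, state.lam_on, state.pop_scale), 0.0)
        elif move == "luca_slide":
            tree = state.tree.copy()
            hi = tree.mrca.time
            if luca_floor < hi:
                tree.luca.time = rng.uniform(luca_floor, hi)
                try_accept(
                    move, McmcState(tree, state.lam_off, state.lam_on, state.pop_scale), 0.0
                )
        elif move in ("narrow_exchange", "wide_exchange"):
            tree = state.tree.copy()
            if _exchange(tree, rng, wide=move == "wide_exchange"):
                try_accept(
                    move, McmcState(tree, state.lam_off, state.lam_on, state.pop_scale), 0.0
                )
        elif move == "scale_pop":
            m = math.exp(rng.uniform(-0.3, 0.3))
            new = state.pop_scale * m
            if 0.03 <= new <= 30.0:  # log-uniform prior support
                prop = McmcState(state.tree, state.lam_off, state.lam_on, new)
                try_accept(move, prop, 0.0)  # multiplier Hastings cancels the
                # log-uniform prior density ratio
        if (it + 1) % opts.thin == 0:
            records.append(
                {
                    "iteration": it + 1,
                    "log_likelihood": state.log_likelihood,
                    "log_coalescent": state.log_coalescent,
                    "log_posterior": state.log_posterior(),
                    "lam_off": state.lam_off,
                    "lam_on": state.lam_on,
                    "pop_scale": state.pop_scale,
                    "root_age": -state.tree.mrca.time,
                    "luca_age": -state.tree.luca.time,
                }
            )
        if opts.store_trees_every and (it + 1) % opts.store_trees_every == 0:
            trees.append(state.tree.to_newick())

    acceptance = {
        m: (accepts[m] / attempts[m] if attempts[m] else math.nan) for m in moves
    }
    return McmcRun(pd.DataFrame(records), acceptance, trees, state)


def _exchange(tree: SampledTree, rng: np.random.Generator, wide: bool) -> bool:
    """Swap a subtree with its uncle (narrow) or a random non-related
    subtree (wide), preserving valid node times.  Symmetric proposal."""
    nodes = [n for n in tree.postorder() if n.parent is not None and n.parent is not tree.luca]
    if not nodes:
        return False
    if not wide:
        candidates = []
        for v in nodes:
            g = v.parent.parent
            if g is None or g is tree.luca:
                continue
            uncle = g.children[0] if g.children[1] is v.parent else g.children[1]
            if uncle is v.parent:
                continue
            if uncle.time > v.parent.time and v.time > g.time:
                candidates.append((v, uncle))
        if not candidates:
            return False
        v, u = candidates[int(rng.integers(len(candidates)))]
        _swap_parents(v, u)
        return True
    # wide: two random nodes, neither ancestral to the other, not siblings
    for _ in range(10):
        a = nodes[int(rng.integers(len(nodes)))]
        b = nodes[int(rng.integers(len(nodes)))]
        if a is b or a.parent is b.parent:
            continue
        if _is_ancestor(a, b) or _is_ancestor(b, a):
            continue
        if a.time > b.parent.time and b.time > a.parent.time:
            _swap_parents(a, b)
            return True
    return False


def _is_ancestor(a: TreeNode, b: TreeNode) -> bool:
    while b is not None:
        if b is a:
            return True
        b = b.parent
    return False


def _swap_parents(a: TreeNode, b: TreeNode) -> None:
    pa, pb = a.parent, b.parent
    pa.children[pa.children.index(a)] = b
    pb.children[pb.children.index(b)] = a
    a.parent, b.parent = pb, pa


# --------------------------------------------------------------------------
# trace summaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSummary:
    mean: float
    lower: float  # 2.5% quantile (central 95% support interval)
    upper: float  # 97.5% quantile
    ess: float
    hpd_lower: float
    hpd_upper: float


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the integrated autocorrelation time (initial positive
    sequence: sum autocorrelations until the first negative)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    tau = 1.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return float(n / tau)


def _hpd(x: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    xs = np.sort(x)
    n = len(xs)
    k = max(1, int(math.ceil(mass * n)))
    widths = xs[k - 1 :] - xs[: n - k + 1]
    i = int(np.argmin(widths))
    return float(xs[i]), float(xs[i + k - 1])


def summarize_trace(
    trace: pd.DataFrame, burnin_fraction: float = 0.1
) -> dict[str, ParameterSummary]:
    """Posterior mean, central 95% support interval, HPD and ESS per column."""
    if not 0 <= burnin_fraction <= 0.9:
        raise ValueError("burnin_fraction must lie in [0, 0.9]")
    n = len(trace)
    if n == 0 or int(n * burnin_fraction) >= n:
        raise ValueError("trace shorter than burn-in")
    kept = trace.iloc[int(n * burnin_fraction) :]
    out = {}
    for col in kept.columns:
        if col == "iteration":
            continue
        x = kept[col].to_numpy(dtype=float)
        lo, hi = np.quantile(x, [0.025, 0.975])
        hlo, hhi = _hpd(x)
        out[col] = ParameterSummary(
            float(x.mean()), float(lo), float(hi), effective_sample_size(x), hlo, hhi
        )
    return out
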