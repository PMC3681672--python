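"""Irreversible 0/1 substitution model and tree likelihood.

The model for one SGA character on a dated genealogy:

* states 0 (normal) and 1 (altered); the 1 -> 0 transition is impossible,
  so the rate matrix is Q = [[-mu, mu], [0, 0]] and over elapsed intensity
  x = mu * t the transition matrix is

      P(0->0) = exp(-x),  P(0->1) = 1 - exp(-x),  P(1->1) = 1.

* mu is a *per-character* intensity derived from the genome-wide SGA rate
  (events per biopsy genome per year) by dividing by the size of the
  character universe (by default the number of observed characters).

* the rate is a two-epoch clock: lambda_off applies during off-NSAID
  calendar time and lambda_on during on-NSAID time, switching once at
  t_switch; branch segments before baseline accrue the epoch rate in
  force at baseline (the first epoch extends indefinitely into the past).

* the likelihood is computed by Felsenstein pruning up to the MRCA and
  then transported along the LUCA stem branch and evaluated at the LUCA
  state 0 (the unaltered genome), i.e.

      L = sum_s P(0 -> s | Lambda_stem) * L_MRCA(s).

An optional ascertainment correction conditions each character on not
having been detected in any baseline biopsy, matching the preprocessing
that drops baseline-detected characters before rate inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .demography import LogisticDemography, coalescent_hazard_integral, population_size_at_age
from .matrix import SgaMatrix
from .trees import SampledTree

RATE_LOWER = 1e-5  # prior support, SGAs per biopsy genome per year
RATE_UPPER = 1e4


@dataclass
class EpochModel:
    """Two-epoch SGA clock keyed to the NSAID-use transition.

    Parameters
    ----------
    pattern : str
        ``"off_on"`` (off-NSAID first) or ``"on_off"``.
    t_switch : float
        Transition time, years since baseline (midpoint between the two
        flanking endoscopies).
    lam_off, lam_on : float
        SGA rates, events per biopsy genome per year, within prior support
        [1e-5, 1e4].
    """

    pattern: str
    t_switch: float
    lam_off: float
    lam_on: float

    def __post_init__(self) -> None:
        if self.pattern not in ("off_on", "on_off"):
            raise ValueError("pattern must be 'off_on' or 'on_off'")
        for lam in (self.lam_off, self.lam_on):
            if not (RATE_LOWER <= lam <= RATE_UPPER):
                raise ValueError(f"rate {lam} outside prior support [{RATE_LOWER}, {RATE_UPPER}]")

    @property
    def first_rate(self) -> float:
        return self.lam_off if self.pattern == "off_on" else self.lam_on

    @property
    def second_rate(self) -> float:
        return self.lam_on if self.pattern == "off_on" else self.lam_off

    def rate_at(self, t: float) -> float:
        """Genome-wide rate in force at calendar time ``t`` (years)."""
        return self.first_rate if t < self.t_switch else self.second_rate

    def epoch_durations(self, t_start: float, t_end: float) -> tuple[float, float]:
        """(first-epoch, second-epoch) years within [t_start, t_end]."""
        if t_end < t_start:
            raise ValueError("branch times must be ordered")
        first = max(0.0, min(t_end, self.t_switch) - t_start)
        return first, (t_end - t_start) - first


def transition_probabilities(rate: float, duration: float) -> np.ndarray:
    """2x2 transition matrix of the irreversible model over ``rate*duration``."""
    if rate < 0 or duration < 0:
        raise ValueError("rate and duration must be non-negative")
    p00 = math.exp(-rate * duration)
    return np.array([[p00, 1.0 - p00], [0.0, 1.0]])


def branch_expected_events(branch: tuple[float, float], epochs: EpochModel) -> float:
    """Expected genome-wide SGA events on a branch spanning (t_start, t_end)."""
    t_start, t_end = branch
    d_first, d_second = epochs.epoch_durations(t_start, t_end)
    return epochs.first_rate * d_first + epochs.second_rate * d_second


@dataclass
class TreeLikelihood:
    """Decomposed log-likelihood of a matrix on a tree."""

    log_likelihood: float  # pruning + LUCA transport (+ ascertainment if on)
    log_ascertainment: float  # per-matrix total of the conditioning term (<= 0)
    log_luca_prior: float  # optional prior on the LUCA branch duration
    per_character: np.ndarray | None = None


def luca_branch_log_prior(tree: SampledTree, mean_years: float) -> float:
    """Exponential log-prior on the LUCA->MRCA branch duration."""
    duration = tree.mrca.time - tree.luca.time
    if duration < 0 or mean_years <= 0:
        return -math.inf
    return -math.log(mean_years) - duration / mean_years


def tree_log_likelihood(
    tree: SampledTree,
    matrix: SgaMatrix,
    epochs: EpochModel,
    *,
    n_character_universe: int | None = None,
    ascertainment: str = "none",
    baseline_ids: set[str] | None = None,
    luca_prior_mean: float | None = None,
    keep_per_character: bool = False,
) -> TreeLikelihood:
    """LUCA-conditioned pruning log-likelihood of a binary SGA matrix.

    Parameters
    ----------
    n_character_universe : int, optional
        Size of the character universe: the divisor converting the
        genome-wide rate into the per-character intensity.  Defaults to
        the number of observed characters (ascertainment-naive).  When
        larger, the likelihood includes the excess as unobserved
        (all-zero) characters; in the large-universe limit the model
        converges to the Poisson event process that generates SGAs, which
        removes the upward rate bias of the saturating finite-character
        model (a character cannot be gained twice, so with the
        observed-only universe each branch's per-character intensity is
        non-negligible and rates inflate by about half that intensity).
    ascertainment : ``"none"`` or ``"baseline"``
        With ``"baseline"`` each character is conditioned on carrying
        state 0 in every biopsy of ``baseline_ids`` (the filtering that
        removed baseline-detected characters).
    luca_prior_mean : float, optional
        If given, an exponential prior on the LUCA branch duration with
        this mean (years) is evaluated and reported separately.
    """
    tips = tree.tips()
    tip_names = [t.name for t in tips]
    if set(tip_names) != set(matrix.biopsy_ids):
        raise ValueError("tree tips and matrix rows must carry the same biopsy ids")
    n_char = matrix.n_characters
    n_univ = n_character_universe if n_character_universe is not None else max(n_char, 1)
    if n_univ <= 0:
        raise ValueError("character universe must be positive")

    lp_luca = (
        luca_branch_log_prior(tree, luca_prior_mean) if luca_prior_mean is not None else 0.0
    )
    if n_char == 0:
        return TreeLikelihood(0.0, 0.0, lp_luca, np.zeros(0) if keep_per_character else None)

    row_of = {b: i for i, b in enumerate(matrix.biopsy_ids)}
    # collapse identical columns: characters sharing a tip pattern share a
    # likelihood, so prune over unique patterns weighted by multiplicity
    patterns, counts = _unique_patterns(matrix)
    if n_univ > n_char:
        # unobserved opportunities enter as all-zero characters
        patterns = np.vstack([patterns, np.zeros((1, patterns.shape[1]), dtype=patterns.dtype)])
        counts = np.concatenate([counts, [n_univ - n_char]])

    def prune(tip_partial) -> float | np.ndarray:
        """Partial likelihoods up the tree, returned as log at the LUCA.

        ``tip_partial(node)`` gives the (n, 2) partial at a tip.  The
        result has shape (n,) — per-pattern log-likelihood at LUCA state 0.
        """
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                partials[id(node)] = tip_partial(node)
                continue
            prod = None
            for child in node.children:
                lam = branch_expected_events((node.time, child.time), epochs) / n_univ
                p00 = math.exp(-lam)
                cp = partials.pop(id(child))
                # transported partial for parent state 0 and state 1
                tr = np.empty_like(cp)
                tr[:, 0] = p00 * cp[:, 0] + (1.0 - p00) * cp[:, 1]
                tr[:, 1] = cp[:, 1]
                prod = tr if prod is None else prod * tr
            partials[id(node)] = prod
        # LUCA has one child (the MRCA); its transported state-0 entry is L
        at_luca = partials[id(tree.luca)][:, 0]
        with np.errstate(divide="ignore"):
            return np.log(at_luca)

    cache = getattr(matrix, "_tip_partial_cache", None)
    if cache is None or cache[0] is not matrix.data or cache[1] != n_univ:
        tip_partial_of = {}
        for name, i in row_of.items():
            s = patterns[:, i]
            part = np.empty((len(patterns), 2))
            part[:, 0] = s == 0
            part[:, 1] = s == 1
            tip_partial_of[name] = part
        matrix._tip_partial_cache = (matrix.data, n_univ, tip_partial_of)
    else:
        tip_partial_of = cache[2]

    per_pattern = prune(lambda node: tip_partial_of[node.name])

    log_ascert = 0.0
    if ascertainment == "baseline":
        if not baseline_ids:
            raise ValueError("ascertainment='baseline' requires baseline_ids")

        def baseline_zero_partial(node) -> np.ndarray:
            if node.name in baseline_ids:
                return np.array([[1.0, 0.0]])
            return np.array([[1.0, 1.0]])

        log_p0 = float(prune(baseline_zero_partial)[0])
        if math.isinf(log_p0):
            # conditioning event has zero probability under these rates
            return TreeLikelihood(-math.inf, -math.inf, lp_luca, None)
        per_pattern = per_pattern - log_p0
        log_ascert = -n_char * log_p0
    elif ascertainment != "none":
        raise ValueError("ascertainment must be 'none' or 'baseline'")

    total = float(np.dot(counts, per_pattern))
    per_char = None
    if keep_per_character:
        inverse = _pattern_inverse(matrix)
        per_char = per_pattern[inverse]
    return TreeLikelihood(total, log_ascert, lp_luca, per_char)


def _unique_patterns(matrix: SgaMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(unique column patterns as rows, multiplicities), cached on the matrix."""
    cached = getattr(matrix, "_pattern_cache", None)
    if cached is not None and cached[0] is matrix.data:
        return cached[1], cached[2]
    patterns, inverse, counts = np.unique(
        matrix.data.T, axis=0, return_inverse=True, return_counts=True
    )
    matrix._pattern_cache = (matrix.data, patterns, counts, inverse)
    return patterns, counts


def _pattern_inverse(matrix: SgaMatrix) -> np.ndarray:
    _unique_patterns(matrix)
    return matrix._pattern_cache[3]


def logistic_coalescent_log_density(
    tree: SampledTree, demography: LogisticDemography, pop_scale: float = 1.0
) -> float:
    """Serial-sample coalescent log-density of the tree's node times.

    The effective size is the logistic crypt trajectory (times
    ``pop_scale``); between coalescent/sampling events with ``k`` active
    lineages the survival term is ``exp(-C(k,2) * int 1/N dt)`` and each
    coalescence contributes ``1/N`` at its time.  The LUCA node is a
    conditioning point, not a coalescence, and contributes no density.
    """
    if pop_scale <= 0:
        raise ValueError("pop_scale must be positive")
    events: list[tuple[float, int]] = []  # (time, lineage change)
    for node in tree.postorder():
        if node is tree.luca:
            continue
        if node.is_leaf:
            events.append((node.time, +1))
        else:
            events.append((node.time, -1))
    # process backwards in time: most recent first
    events.sort(key=lambda e: (-e[0], e[1]))
    logdens = 0.0
    k = 0
    t_prev: float | None = None
    for t, change in events:
        if t_prev is not None and k >= 2 and t < t_prev:
            integral = coalescent_hazard_integral(demography, -t_prev, -t, pop_scale)
            logdens -= 0.5 * k * (k - 1) * integral
        if change == -1:
            n_here = population_size_at_age(demography, -t, pop_scale)
            if n_here <= 0:
                raise ValueError("population size must be positive over the tree span")
            logdens -= math.log(n_here)
        k += change
        t_prev = t
    return logdens
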