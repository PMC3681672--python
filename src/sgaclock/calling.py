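"""SGA calling from SNP-array probe signals (biopsy vs matched control).

Pipeline per individual:

1.  exclude the lowest-intensity probes of the control,
2.  correct dye bias (het-BAF median recentered to 0.5, homozygous
    clusters anchored at 0 and 1),
3.  identify heterozygous probes from the control BAF,
4.  build three signal profiles per biopsy — log2(R_biopsy/R_control) at
    het probes, the same at hom probes, and mirrored BAF
    (mBAF = |BAF - 0.5| * 2) at het probes,
5.  segment each profile with multiscale Haar breakpoint detection,
6.  union all breakpoints of all profiles and biopsies into exact-
    breakpoint events,
7.  call one of eight molecular states per event per biopsy from
    threshold boxes on the segment copy-number level (pooled log2R) and
    allelic split,
8.  merge adjacent events with identical state vectors across biopsies,
9.  optionally resolve the affected haplotype where phase is known, and
10. emit the binary biopsy x character matrix.

The *allelic split* used for state calling is a noise-debiased estimate
of the BAF separation: mirroring BAF per probe folds noise upward (a
balanced segment has mean mBAF well above 0) and a few percent of the
"heterozygous" probes are leaked homozygotes sitting at mBAF ~1, so the
split is estimated robustly by inverting the folded-normal median,
``median(|N(mu, sigma)|) = median(mBAF)/2``, with sigma taken from the
control's heterozygous cluster (truncation-corrected).  Noiseless
segments give exactly the canonical mBAF levels (0, 1/3, 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import BiopsyMeta, Character, SgaMatrix
from .segment import haar_breakpoints

logger = logging.getLogger(__name__)

ALL_STATES = ("AB", "AA", "A", "0", "AAB", "AAA", "AAAA", "AABB")

#: haplotype-2 display forms of the allele-specific states
B_FORM = {"AA": "BB", "A": "B", "AAB": "BBA", "AAA": "BBB", "AAAA": "BBBB"}
IMBALANCE_STATES = tuple(B_FORM)


@dataclass
class ThresholdBox:
    """Calling box for one state: bounds on log2R and the allelic split."""

    log2r: tuple[float, float] | None  # (lo, hi), None = unconstrained
    split: tuple[float, float] | None

    def contains(self, log2r: float, split: float) -> bool:
        for bound, value in ((self.log2r, log2r), (self.split, split)):
            if bound is None:
                continue
            if math.isnan(value):
                continue  # missing dimension is unconstrained
            if not (bound[0] < value <= bound[1]):
                return False
        return True


#: canonical noiseless levels: log2R = log2(copies/2), split = |2 BAF - 1|
DEFAULT_THRESHOLDS: dict[str, ThresholdBox] = {
    "AB": ThresholdBox((-0.25, 0.25), (-0.01, 0.20)),
    "AA": ThresholdBox((-0.25, 0.25), (0.70, 1.05)),
    "A": ThresholdBox((-2.50, -0.50), (0.70, 1.05)),
    "0": ThresholdBox((-math.inf, -2.50), None),
    "AAB": ThresholdBox((0.25, 0.80), (0.20, 0.55)),
    "AAA": ThresholdBox((0.25, 0.80), (0.70, 1.05)),
    "AAAA": ThresholdBox((0.80, 1.40), (0.70, 1.05)),
    "AABB": ThresholdBox((0.80, 1.40), (-0.01, 0.20)),
}


def validate_thresholds(thresholds: dict[str, ThresholdBox]) -> None:
    """Reject configurations whose boxes overlap (calls would be ambiguous)."""

    def overlaps(a: tuple[float, float] | None, b: tuple[float, float] | None) -> bool:
        if a is None or b is None:
            return True
        return a[0] < b[1] and b[0] < a[1]

    states = [s for s in thresholds if s != "AB"]
    conflicts = [
        (s, t)
        for i, s in enumerate(states)
        for t in states[i + 1 :]
        if overlaps(thresholds[s].log2r, thresholds[t].log2r)
        and overlaps(thresholds[s].split, thresholds[t].split)
    ]
    if conflicts:
        raise ValueError(f"overlapping threshold boxes: {conflicts}")


@dataclass
class CallerConfig:
    exclude_fraction: float = 0.002
    het_low: float = 0.33
    het_high: float = 0.66
    haar_start: int = 3
    haar_end: int = 9
    fdr_q: float = 1e-4
    thresholds: dict[str, ThresholdBox] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    mixture_tol: float = 0.10
    chromosome_lengths: dict[str, int] | None = None  # event tiling bounds

    def __post_init__(self) -> None:
        if not (0 <= self.exclude_fraction < 1):
            raise ValueError("exclude_fraction must lie in [0, 1)")
        if not self.het_low < self.het_high:
            raise ValueError("het bounds must satisfy low < high")
        validate_thresholds(self.thresholds)


# --------------------------------------------------------------------------
# probe-level preprocessing
# --------------------------------------------------------------------------

def exclude_low_intensity(control: pd.DataFrame, fraction: float = 0.002) -> np.ndarray:
    """Boolean mask of retained probes (drop the lowest-R control probes).

    Exactly ``floor(fraction * n)`` probes are removed; ties in R are
    broken by genomic order (earlier probes removed first).
    """
    n = len(control)
    if n == 0:
        raise ValueError("empty probe set")
    k = int(fraction * n)
    keep = np.ones(n, dtype=bool)
    if k > 0:
        order = np.lexsort((np.arange(n), control["R"].to_numpy()))
        keep[order[:k]] = False
    return keep


def identify_heterozygous(
    control: pd.DataFrame, low: float = 0.33, high: float = 0.66
) -> np.ndarray:
    """Het mask: control BAF strictly between the bounds."""
    baf = control["BAF"].to_numpy()
    return (baf > low) & (baf < high)


def correct_dye_bias(
    samples: dict[str, pd.DataFrame],
    het_mask: np.ndarray,
    reference: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Re-center the het-BAF median to 0.5.

    Piecewise-linear warp anchored at 0 and 1 (homozygous clusters are
    fixed points); idempotent once the median is 0.5.  Dye bias is a
    property of the assay, so when ``reference`` names a sample (the
    diploid control) its median defines the warp applied to every
    sample; otherwise each sample is recentered on its own median.
    """
    out = {}
    m_ref = None
    if reference is not None:
        if het_mask.any():
            m_ref = float(np.median(samples[reference]["BAF"].to_numpy()[het_mask]))
    for sid, df in samples.items():
        baf = df["BAF"].to_numpy().astype(float)
        if not het_mask.any():
            logger.warning("no heterozygous probes; dye-bias correction skipped for %s", sid)
            out[sid] = df
            continue
        m = m_ref if m_ref is not None else float(np.median(baf[het_mask]))
        corrected = np.where(
            baf <= m,
            baf * (0.5 / m),
            0.5 + (baf - m) * (0.5 / (1.0 - m)),
        )
        df = df.copy()
        df["BAF"] = corrected
        df["X"] = df["R"] * (1.0 - corrected)
        df["Y"] = df["R"] * corrected
        out[sid] = df
    return out


@dataclass
class SignalProfiles:
    """The three per-biopsy profiles (values + full-table probe indices)."""

    het_idx: np.ndarray  # indices into the retained probe table
    hom_idx: np.ndarray
    log2r_het: np.ndarray
    log2r_hom: np.ndarray
    mbaf: np.ndarray  # at het probes
    baf_het: np.ndarray  # dye-corrected BAF at het probes (phase votes)
    mbaf_idx: np.ndarray = None  # full-table indices of the mBAF probes

    def tracks(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(probe indices, values) of the three segmentable profiles."""
        return [
            (self.het_idx, self.log2r_het),
            (self.hom_idx, self.log2r_hom),
            (self.mbaf_idx, self.mbaf),
        ]


def build_profiles(
    biopsy: pd.DataFrame, control: pd.DataFrame, het_mask: np.ndarray
) -> SignalProfiles:
    """Log-ratio and mirrored-BAF profiles; probes with nonpositive R drop
    out of the log ratios."""
    rb = biopsy["R"].to_numpy().astype(float)
    rc = control["R"].to_numpy().astype(float)
    ok = (rb > 0) & (rc > 0)
    log2r = np.full(len(rb), np.nan)
    log2r[ok] = np.log2(rb[ok] / rc[ok])
    baf = biopsy["BAF"].to_numpy().astype(float)
    het = np.flatnonzero(het_mask & ok)
    hom = np.flatnonzero(~het_mask & ok)
    het_all = np.flatnonzero(het_mask)
    return SignalProfiles(
        het_idx=het,
        hom_idx=hom,
        log2r_het=log2r[het],
        log2r_hom=log2r[hom],
        mbaf=np.abs(baf[het_all] - 0.5) * 2.0,
        baf_het=baf[het_all],
        mbaf_idx=het_all,
    )


# --------------------------------------------------------------------------
# segmentation and event construction
# --------------------------------------------------------------------------

def segment_profile(
    values: np.ndarray,
    chroms: np.ndarray,
    haar_start: int = 3,
    haar_end: int = 9,
    fdr_q: float = 1e-4,
) -> np.ndarray:
    """Per-chromosome Haar breakpoints; returns local indices into ``values``."""
    breaks: list[int] = []
    offset = 0
    for chrom in pd.unique(chroms):
        sub = values[chroms == chrom]
        for b in haar_breakpoints(np.asarray(sub, dtype=float), haar_start, haar_end, fdr_q):
            breaks.append(offset + b)
        offset += len(sub)
    return np.array(sorted(breaks), dtype=int)


@dataclass(frozen=True)
class Event:
    """One exact-breakpoint interval shared by all biopsies of an individual."""

    chrom: str
    start: int  # bp, 0-based inclusive
    end: int  # bp, exclusive
    probe_lo: int  # first probe index (retained table) in the event
    probe_hi: int  # one past the last probe index

    @property
    def size_bp(self) -> int:
        return self.end - self.start


def union_breakpoints(
    breakpoint_probe_indices: list[np.ndarray],
    probes: pd.DataFrame,
    chromosome_lengths: dict[str, int] | None = None,
) -> list[Event]:
    """Union of all profile breakpoints -> tiling events per chromosome.

    A breakpoint is identified by the retained-table index of the first
    probe right of the break; identical indices are identical breakpoints.
    Events tile each chromosome from 0 to its length (or past the last
    probe when lengths are unknown).
    """
    union: set[int] = set()
    for arr in breakpoint_probe_indices:
        union.update(int(i) for i in arr)
    chroms = probes["chrom"].to_numpy()
    pos = probes["pos"].to_numpy()
    events: list[Event] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        length = (
            chromosome_lengths[chrom]
            if chromosome_lengths and chrom in chromosome_lengths
            else int(pos[idx[-1]]) + 1
        )
        inner = sorted(i for i in union if idx[0] < i <= idx[-1])
        bounds = [idx[0]] + inner + [idx[-1] + 1]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            start = 0 if lo == idx[0] else int(pos[lo])
            end = length if hi == idx[-1] + 1 else int(pos[hi])
            events.append(Event(chrom, start, end, int(lo), int(hi)))
    return events


# --------------------------------------------------------------------------
# breakpoint consolidation and joint refinement
# --------------------------------------------------------------------------

def consolidate_breakpoints(
    detections: list[tuple[np.ndarray, str]],
    chroms: np.ndarray,
    window: int = 4,
) -> list[tuple[int, set[str]]]:
    """Cluster per-profile detections of the same physical boundary.

    Breakpoints (full-table probe indices) from different profiles or
    biopsies within ``window`` probes on the same chromosome are one
    cluster; returns (median position, owning sample ids) per cluster.
    """
    items = sorted(
        (int(b), sid) for arr, sid in detections for b in np.asarray(arr).ravel()
    )
    clusters: list[tuple[int, set[str]]] = []
    current: list[tuple[int, str]] = []
    for b, sid in items:
        if current and (b - current[-1][0] > window or chroms[b] != chroms[current[0][0]]):
            positions = [p for p, _ in current]
            clusters.append((int(np.median(positions)), {s for _, s in current}))
            current = []
        current.append((b, sid))
    if current:
        positions = [p for p, _ in current]
        clusters.append((int(np.median(positions)), {s for _, s in current}))
    return clusters


def _profile_contrast(
    p_idx: np.ndarray, p_vals: np.ndarray, lo: int, hi: int, candidates: np.ndarray,
    window: int,
) -> np.ndarray | None:
    """|z| of the left/right mean contrast per candidate breakpoint.

    ``lo``/``hi`` bound the chromosome in full-table indices; returns
    None when the profile carries no usable signal near the candidates.
    """
    sel = (p_idx >= lo) & (p_idx <= hi)
    vals = p_vals[sel]
    idx = p_idx[sel]
    n = len(vals)
    if n < 8:
        return None
    from .segment import _noise_sigma

    sigma = _noise_sigma(vals)
    if sigma <= 0:
        sigma = 1e-12
    s = np.concatenate([[0.0], np.cumsum(vals)])
    local = np.searchsorted(idx, candidates)
    z = np.full(len(candidates), np.nan)
    # windows shrink near the chromosome ends (but stay >= 3 probes)
    wl = np.minimum(window, local)
    wr = np.minimum(window, n - local)
    ok = (wl >= 3) & (wr >= 3)
    lw = local[ok]
    left = (s[lw] - s[lw - wl[ok]]) / wl[ok]
    right = (s[lw + wr[ok]] - s[lw]) / wr[ok]
    z[ok] = np.abs(right - left) / (sigma * np.sqrt(1.0 / wl[ok] + 1.0 / wr[ok]))
    return z


def _mle_stage(
    position: int,
    profiles_by_sample: dict[str, SignalProfiles],
    lo: int,
    hi: int,
    radius: int = 10,
    flank: int = 14,
    min_z: float = 3.0,
) -> tuple[int, bool]:
    """Maximum-likelihood changepoint within a bracket around ``position``.

    Flank means are estimated outside the candidate bracket; the split
    minimizing the pooled residual sum of squares (over all tracks with a
    significant level difference) is the refined breakpoint.  Per-probe
    likelihood makes the localization error essentially (sigma/delta)^2.
    """
    from .segment import _noise_sigma

    cand_lo = max(lo + 1, position - radius)
    cand_hi = min(hi, position + radius)
    if cand_hi <= cand_lo:
        return position, False
    cands = np.arange(cand_lo, cand_hi + 1)
    total = np.zeros(len(cands))
    informative = False
    for prof in profiles_by_sample.values():
        for p_idx, p_vals in prof.tracks():
            sel = (p_idx >= lo) & (p_idx <= hi)
            idx = p_idx[sel]
            vals = p_vals[sel]
            l0 = np.searchsorted(idx, cand_lo)
            l1 = np.searchsorted(idx, cand_hi + 1)
            if l0 < 3 or len(vals) - l1 < 3:
                continue
            m_left = float(np.mean(vals[max(0, l0 - flank) : l0]))
            m_right = float(np.mean(vals[l1 : l1 + flank]))
            sigma = _noise_sigma(vals)
            if sigma <= 0:
                sigma = 1e-12
            if abs(m_left - m_right) / (sigma * math.sqrt(2.0 / flank)) < min_z:
                continue
            informative = True
            # cost difference as the split moves across bracket probes
            bracket = vals[l0:l1]
            # cost(j) = sum_{i<j}(x-mL)^2 + sum_{i>=j}(x-mR)^2, up to const
            delta = (bracket - m_left) ** 2 - (bracket - m_right) ** 2
            cum = np.concatenate([[0.0], np.cumsum(delta)])  # prefix of "assign to left"
            splits = np.searchsorted(idx[l0:l1], cands)
            total += cum[splits] / sigma**2
    if not informative:
        return position, False
    return int(cands[int(np.argmin(total))]), True


def refine_breakpoint(
    position: int,
    profiles_by_sample: dict[str, SignalProfiles],
    chroms: np.ndarray,
    stages: tuple[tuple[int, int], ...] = ((25, 12),),
    min_z: float = 3.0,
    bounds: tuple[int, int] | None = None,
) -> int | None:
    """Re-localize a consolidated breakpoint at full probe resolution.

    Runs coarse-to-fine (radius, window) stages, each maximizing the sum
    of squared contrast z-scores over every biopsy-profile showing a
    significant step nearby, then a maximum-likelihood changepoint stage;
    log-ratio tracks localize to single probes, mBAF-only boundaries to
    the heterozygous-probe spacing.  Returns None when no profile shows a
    locally significant step at all — the candidate is a phantom (e.g. a
    coarse-scale echo of a distant boundary) and should be dropped.
    ``bounds`` restricts the search.
    """
    chrom = chroms[position]
    members = np.flatnonzero(chroms == chrom)
    lo, hi = int(members[0]), int(members[-1])
    if bounds is not None:
        lo, hi = max(lo, bounds[0]), min(hi, bounds[1])
    any_support = False
    for radius, window in stages:
        cands = np.arange(max(lo + 1, position - radius), min(hi, position + radius) + 1)
        if len(cands) == 0:
            continue
        score = np.zeros(len(cands))
        informative = False
        for prof in profiles_by_sample.values():
            for p_idx, p_vals in prof.tracks():
                z = _profile_contrast(p_idx, p_vals, lo, hi, cands, window)
                if z is None or np.all(np.isnan(z)):
                    continue
                z2 = np.nan_to_num(z) ** 2
                base = float(np.median(z2))
                # only tracks with a clear local peak vote, and only by the
                # height of that peak above their own baseline, so a flat
                # noisy track cannot drown a sharp one
                if np.max(z2) - base < min_z**2:
                    continue
                informative = True
                score += z2 - base
        if informative:
            any_support = True
            position = int(cands[int(np.argmax(score))])
    position, mle_support = _mle_stage(position, profiles_by_sample, lo, hi, min_z=min_z)
    if not (any_support or mle_support):
        return None
    return position


# --------------------------------------------------------------------------
# state calling
# --------------------------------------------------------------------------

@dataclass
class SgaSegmentCall:
    """State call for one event in one biopsy."""

    chrom: str
    start: int
    end: int
    state: str  # one of the 8 molecular states (A-form)
    haplotype: int | None = None  # 1 | 2 once resolved, None otherwise
    hap_unresolved: bool = False  # tie in the phase vote
    mean_log2r: float = math.nan
    mean_mbaf: float = math.nan
    split: float = math.nan
    n_probes: int = 0  # retained probes in the event span

    @property
    def display_state(self) -> str:
        if self.haplotype == 2 and self.state in B_FORM:
            return B_FORM[self.state]
        return self.state

    @property
    def is_sga(self) -> bool:
        return self.state != "AB"

    @property
    def size_bp(self) -> int:
        return self.end - self.start


def _baf_noise_sd(
    control: pd.DataFrame, het_mask: np.ndarray, window: tuple[float, float] = (0.33, 0.66)
) -> float:
    """Per-probe BAF noise sd from the control's heterozygous cluster.

    Het probes are *selected* by their control BAF lying inside the
    window, so their spread is that of a truncated normal; the raw
    robust sd is corrected by inverting the truncation.
    """
    baf = control["BAF"].to_numpy()[het_mask]
    if len(baf) < 10:
        return 0.0
    q1, q3 = np.quantile(baf, [0.25, 0.75])
    iqr_obs = float(q3 - q1)
    if iqr_obs <= 1e-6:
        return 0.0
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    half = (window[1] - window[0]) / 2.0

    def gap(sigma: float) -> float:
        a = half / sigma
        return (truncnorm.ppf(0.75, -a, a, scale=sigma)
                - truncnorm.ppf(0.25, -a, a, scale=sigma)) - iqr_obs

    if gap(0.6) < 0:  # spread beyond what any truncation can explain
        return iqr_obs / 1.349
    return float(brentq(gap, iqr_obs / 2, 0.6, xtol=1e-6))


def _invert_folded_median(med: float, sigma: float) -> float:
    """Allelic-split magnitude mu with median(|N(mu, sigma)|) = med.

    Robust to a few percent of leaked homozygous probes (which sit at
    mirrored BAF ~1 and would wreck a mean-based estimate); exact in the
    noiseless limit where the median equals mu itself.
    """
    if sigma <= 0:
        return max(med, 0.0)
    from scipy.optimize import brentq
    from scipy.stats import norm as _norm

    def half_mass(mu: float) -> float:
        return _norm.cdf((med - mu) / sigma) - _norm.cdf((-med - mu) / sigma) - 0.5

    # half_mass decreases in mu; at mu = 0 the median is ~0.674 sigma,
    # so observations below the noise floor invert to 0
    if half_mass(0.0) <= 0:
        return 0.0
    if half_mass(1.5) > 0:
        return med
    return float(brentq(half_mass, 0.0, 1.5, xtol=1e-9))


def _segment_stats(
    profiles: SignalProfiles, lo: int, hi: int, baf_noise_sd: float
) -> tuple[float, float, float]:
    """(pooled log2R, mean mBAF, debiased allelic split) over [lo, hi)."""
    in_het = (profiles.het_idx >= lo) & (profiles.het_idx < hi)
    in_hom = (profiles.hom_idx >= lo) & (profiles.hom_idx < hi)
    log2r_vals = np.concatenate([profiles.log2r_het[in_het], profiles.log2r_hom[in_hom]])
    log2r = float(np.mean(log2r_vals)) if len(log2r_vals) else math.nan
    in_mbaf = (profiles.mbaf_idx >= lo) & (profiles.mbaf_idx < hi)
    mbaf_vals = profiles.mbaf[in_mbaf]
    if len(mbaf_vals):
        mbaf = float(np.mean(mbaf_vals))
        split = 2.0 * _invert_folded_median(
            float(np.median(mbaf_vals)) / 2.0, baf_noise_sd
        )
    else:
        mbaf = split = math.nan
    return log2r, mbaf, split


def call_states(
    profiles: SignalProfiles,
    events: list[Event],
    thresholds: dict[str, ThresholdBox] | None = None,
    baf_noise_sd: float = 0.0,
    own_breakpoints: np.ndarray | None = None,
    chroms: np.ndarray | None = None,
) -> list[SgaSegmentCall]:
    """Per-event molecular state from pooled log2R and the allelic split.

    The copy-number level pools the het and hom log-ratio probes; the
    allelic split debiases the mirrored BAF for probe noise
    (``baf_noise_sd``).  When ``own_breakpoints`` (the breakpoints this
    biopsy's own profiles detected) are given, each event inherits the
    statistics of the enclosing own-segment — thresholds are applied to
    the biopsy's smoothed profiles, so events fragmented by *other*
    biopsies' breakpoints keep full statistical support.  Events
    matching no box are called AB (normal).
    """
    thresholds = thresholds if thresholds is not None else DEFAULT_THRESHOLDS
    validate_thresholds(thresholds)
    own = np.sort(np.asarray(own_breakpoints, dtype=int)) if own_breakpoints is not None else None
    calls = []
    for ev in events:
        lo, hi = ev.probe_lo, ev.probe_hi
        if own is not None and chroms is not None:
            members = np.flatnonzero(chroms == ev.chrom)
            c_lo, c_hi = int(members[0]), int(members[-1]) + 1
            inner = own[(own > c_lo) & (own < c_hi)]
            left = inner[inner <= lo]
            right = inner[inner > lo]
            lo = int(left[-1]) if len(left) else c_lo
            hi = int(right[0]) if len(right) else c_hi
        log2r, mbaf, split = _segment_stats(profiles, lo, hi, baf_noise_sd)
        state = "AB"
        for cand in ALL_STATES[1:]:
            if cand in thresholds and thresholds[cand].contains(log2r, split):
                state = cand
                break
        calls.append(
            SgaSegmentCall(
                ev.chrom, ev.start, ev.end, state,
                mean_log2r=log2r, mean_mbaf=mbaf, split=split,
                n_probes=ev.probe_hi - ev.probe_lo,
            )
        )
    return calls


def despeckle_calls(
    calls_by_sample: dict[str, list[SgaSegmentCall]], min_probes: int = 4
) -> dict[str, list[SgaSegmentCall]]:
    """Absorb tiny interior fragments into identical flanking states.

    A fragment spanning fewer than ``min_probes`` probes whose two
    contiguous neighbours carry the same call is a segmentation speckle
    (a spurious breakpoint pair); it takes the flanking call.  Applied
    per sample; idempotent.
    """
    out: dict[str, list[SgaSegmentCall]] = {}
    for sid, calls in calls_by_sample.items():
        fixed = list(calls)
        for i in range(1, len(fixed) - 1):
            cur, prev, nxt = fixed[i], fixed[i - 1], fixed[i + 1]
            if (
                cur.n_probes < min_probes
                and prev.chrom == cur.chrom == nxt.chrom
                and prev.end == cur.start
                and cur.end == nxt.start
                and prev.display_state == nxt.display_state != cur.display_state
            ):
                fixed[i] = SgaSegmentCall(
                    cur.chrom, cur.start, cur.end, prev.state,
                    haplotype=prev.haplotype, hap_unresolved=prev.hap_unresolved,
                    mean_log2r=prev.mean_log2r, mean_mbaf=prev.mean_mbaf,
                    split=prev.split, n_probes=cur.n_probes,
                )
        out[sid] = fixed
    return out


def merge_adjacent(
    calls_by_sample: dict[str, list[SgaSegmentCall]]
) -> dict[str, list[SgaSegmentCall]]:
    """Collapse adjacent events with identical state vectors across samples.

    Merging is idempotent; sizes are summed and the per-profile means are
    probe-length-weighted by bp (an approximation adequate for reporting).
    """
    samples = list(calls_by_sample)
    n_events = len(calls_by_sample[samples[0]])
    if any(len(calls_by_sample[s]) != n_events for s in samples):
        raise ValueError("samples must share the event tiling")
    merged: dict[str, list[SgaSegmentCall]] = {s: [] for s in samples}
    i = 0
    while i < n_events:
        j = i + 1
        first = calls_by_sample[samples[0]][i]
        while j < n_events:
            nxt = calls_by_sample[samples[0]][j]
            if nxt.chrom != first.chrom or nxt.start != calls_by_sample[samples[0]][j - 1].end:
                break
            if any(
                calls_by_sample[s][j].display_state != calls_by_sample[s][i].display_state
                for s in samples
            ):
                break
            j += 1
        for s in samples:
            run = calls_by_sample[s][i:j]
            w = np.array([c.size_bp for c in run], dtype=float)
            w = w / w.sum()
            merged[s].append(
                SgaSegmentCall(
                    run[0].chrom, run[0].start, run[-1].end, run[0].state,
                    haplotype=run[0].haplotype,
                    hap_unresolved=run[0].hap_unresolved,
                    mean_log2r=float(np.nansum(w * [c.mean_log2r for c in run])),
                    mean_mbaf=float(np.nansum(w * [c.mean_mbaf for c in run])),
                    split=float(np.nansum(w * [c.split for c in run])),
                )
            )
        i = j
    return merged


def assign_haplotype_states(
    calls_by_sample: dict[str, list[SgaSegmentCall]],
    profiles_by_sample: dict[str, SignalProfiles],
    probes: pd.DataFrame,
    het_mask: np.ndarray,
) -> dict[str, list[SgaSegmentCall]]:
    """Resolve the retained/gained haplotype of allelic-imbalance calls.

    ``probes`` must carry a boolean ``hap1_is_b`` phase column.  For each
    imbalance segment, every heterozygous probe votes for the haplotype
    whose allele matches the skew of the biopsy BAF; the majority wins.
    An exact 50/50 vote leaves the A-form with ``hap_unresolved`` set.
    """
    if "hap1_is_b" not in probes.columns:
        raise ValueError("probe table lacks phase (hap1_is_b)")
    hap1_is_b = probes["hap1_is_b"].to_numpy()
    het_all = np.flatnonzero(het_mask)
    out: dict[str, list[SgaSegmentCall]] = {}
    for sid, calls in calls_by_sample.items():
        prof = profiles_by_sample[sid]
        resolved = []
        # probe index bounds per call from bp coordinates
        chroms = probes["chrom"].to_numpy()
        pos = probes["pos"].to_numpy()
        for call in calls:
            if call.state not in IMBALANCE_STATES:
                resolved.append(call)
                continue
            in_seg = (
                (chroms[het_all] == call.chrom)
                & (pos[het_all] >= call.start)
                & (pos[het_all] < call.end)
            )
            baf = prof.baf_het[in_seg]
            informative = baf != 0.5
            favored_is_b = baf[informative] > 0.5
            h1_b = hap1_is_b[het_all][in_seg][informative]
            votes_h1 = int(np.sum(favored_is_b == h1_b))
            votes = len(favored_is_b)
            new = SgaSegmentCall(
                call.chrom, call.start, call.end, call.state,
                mean_log2r=call.mean_log2r, mean_mbaf=call.mean_mbaf, split=call.split,
            )
            if votes == 0 or votes_h1 * 2 == votes:
                new.hap_unresolved = True
            else:
                new.haplotype = 1 if votes_h1 * 2 > votes else 2
            resolved.append(new)
        out[sid] = resolved
    return out


def to_binary_matrix(
    calls_by_sample: dict[str, list[SgaSegmentCall]],
    meta: dict[str, BiopsyMeta] | None = None,
) -> SgaMatrix:
    """Binary matrix; a character is (interval, haplotype form).

    The two haplotype forms of the same interval (e.g. AA vs BB) are
    distinct characters; balanced or unresolved calls use the untagged
    form.  All-zero columns are dropped.
    """
    samples = list(calls_by_sample)
    char_index: dict[Character, int] = {}
    chars: list[Character] = []
    entries: list[tuple[int, int]] = []
    for si, sid in enumerate(samples):
        for call in calls_by_sample[sid]:
            if not call.is_sga:
                continue
            form = f"h{call.haplotype}" if call.haplotype else ""
            c = Character(call.chrom, call.start, call.end, form)
            if c not in char_index:
                char_index[c] = len(chars)
                chars.append(c)
            entries.append((si, char_index[c]))
    data = np.zeros((len(samples), len(chars)), dtype=np.uint8)
    for si, ci in entries:
        data[si, ci] = 1
    m = SgaMatrix(samples, chars, data, dict(meta) if meta else {})
    return m.drop_empty_characters()


def detect_clone_mixture(
    calls: list[SgaSegmentCall],
    tol: float = 0.10,
    min_probes_bp: int = 0,
    min_locations: int = 2,
) -> bool:
    """Flag a biopsy whose BAF shows splits at non-clonal plateau levels.

    A segment is suspicious when its allelic split sits away (by more
    than ``tol``) from every canonical single-clone level {0, 1/3, 1} —
    e.g. a 50/50 mixture of AB and AA clones plateaus at 0.5.  At least
    ``min_locations`` suspicious segments are required.
    """
    canonical = (0.0, 1.0 / 3.0, 1.0)
    n_suspicious = 0
    for call in calls:
        if math.isnan(call.split) or call.size_bp < min_probes_bp:
            continue
        if all(abs(call.split - level) > tol for level in canonical):
            n_suspicious += 1
    return n_suspicious >= min_locations


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class CallResult:
    matrix: SgaMatrix
    calls_by_sample: dict[str, list[SgaSegmentCall]]
    events: list[Event]
    mixture_flags: dict[str, bool]
    retained_mask: np.ndarray
    het_mask: np.ndarray  # within the retained probe table


def call_individual(
    signals: dict[str, pd.DataFrame],
    control_id: str,
    config: CallerConfig | None = None,
    probes: pd.DataFrame | None = None,
    meta: dict[str, BiopsyMeta] | None = None,
) -> CallResult:
    """Run the full caller on one individual's probe tables.

    ``signals`` maps sample id -> probe table (chrom, pos, X, Y, R, BAF),
    all on the same probe set in genomic order; ``probes`` optionally
    supplies phase (hap1_is_b) for haplotype resolution.
    """
    config = config or CallerConfig()
    control = signals[control_id]
    keep = exclude_low_intensity(control, config.exclude_fraction)
    trimmed = {sid: df[keep].reset_index(drop=True) for sid, df in signals.items()}
    probes_kept = probes[keep].reset_index(drop=True) if probes is not None else None
    control = trimmed[control_id]

    het0 = identify_heterozygous(control, config.het_low, config.het_high)
    corrected = correct_dye_bias(trimmed, het0, reference=control_id)
    control = corrected[control_id]
    het = identify_heterozygous(control, config.het_low, config.het_high)
    noise_sd = _baf_noise_sd(control, het)

    biopsy_ids = [sid for sid in corrected if sid != control_id]
    profiles: dict[str, SignalProfiles] = {}
    detections: list[tuple[np.ndarray, str]] = []
    chroms = control["chrom"].to_numpy()
    for sid in biopsy_ids:
        prof = build_profiles(corrected[sid], control, het)
        profiles[sid] = prof
        for idx, values in prof.tracks():
            local = segment_profile(
                values, chroms[idx], config.haar_start, config.haar_end, config.fdr_q
            )
            detections.append((idx[local], sid))

    clusters = consolidate_breakpoints(detections, chroms)
    own_breaks: dict[str, set[int]] = {sid: set() for sid in biopsy_ids}
    refined: set[int] = set()
    for pos, owners in clusters:
        # refine per owning biopsy first: a cluster may mix two nearby but
        # distinct physical boundaries of different biopsies; owners whose
        # profiles show no local step contributed a phantom and are dropped
        per_owner = sorted(
            (p, sid)
            for sid in owners
            if (p := refine_breakpoint(pos, {sid: profiles[sid]}, chroms)) is not None
        )
        groups: list[list[tuple[int, str]]] = []
        for p, sid in per_owner:
            if groups and p - groups[-1][-1][0] <= 3:
                groups[-1].append((p, sid))
            else:
                groups.append([(p, sid)])
        for grp in groups:
            gowners = {sid for _, sid in grp}
            if len(grp) == 1:
                b = grp[0][0]
            else:
                # a truly shared boundary: settle jointly on one position
                gpos = int(np.median([p for p, _ in grp]))
                b = refine_breakpoint(
                    gpos, {sid: profiles[sid] for sid in gowners}, chroms,
                    stages=((6, 8),),
                )
                if b is None:
                    b = gpos
            refined.add(b)
            for sid in gowners:
                own_breaks[sid].add(b)

    events = union_breakpoints(
        [np.array(sorted(refined), dtype=int)], control, config.chromosome_lengths
    )
    calls_by_sample = {
        sid: call_states(
            profiles[sid], events, config.thresholds, noise_sd,
            own_breakpoints=np.array(sorted(own_breaks[sid]), dtype=int),
            chroms=chroms,
        )
        for sid in biopsy_ids
    }
    calls_by_sample = despeckle_calls(calls_by_sample)
    calls_by_sample = merge_adjacent(calls_by_sample)
    if probes_kept is not None and "hap1_is_b" in probes_kept.columns:
        calls_by_sample = assign_haplotype_states(
            calls_by_sample, profiles, probes_kept, het
        )
    mixture = {
        sid: detect_clone_mixture(calls_by_sample[sid], config.mixture_tol)
        for sid in biopsy_ids
    }
    matrix = to_binary_matrix(calls_by_sample, meta)
    return CallResult(matrix, calls_by_sample, events, mixture, keep, het)


def calls_to_seg_frame(calls_by_sample: dict[str, list[SgaSegmentCall]]) -> pd.DataFrame:
    """SEG-like table (0-based half-open) of all per-sample calls."""
    rows = []
    for sid, calls in calls_by_sample.items():
        for c in calls:
            rows.append(
                {
                    "sample_id": sid, "chrom": c.chrom, "start": c.start, "end": c.end,
                    "state": c.display_state, "mean_log2r": c.mean_log2r,
                    "mean_mbaf": c.mean_mbaf, "allelic_split": c.split,
                }
            )
    return pd.DataFrame(rows)
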