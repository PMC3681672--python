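"""Synthetic crypt-structured Barrett's cohorts with known ground truth.

One simulated individual consists of

* a logistic crypt demography (segment initiated from a single founder
  crypt, growing toward carrying capacity),
* a serial-sample coalescent genealogy of biopsies drawn along that
  trajectory, rooted in a LUCA node at segment initiation,
* SGA events dropped on branches as a two-epoch Poisson process
  (off-NSAID rate, on-NSAID rate, one transition), each event an interval
  in one of the eight molecular states, inherited irreversibly by all
  descendants, and
* SNP-array-like probe signals (total intensity R and B-allele frequency
  BAF) per biopsy plus a normal diploid blood control, with dye bias,
  Gaussian probe noise and optional two-clone mixtures.

All coordinates are 0-based half-open base pairs; all times are calendar
years relative to baseline endoscopy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .demography import LogisticDemography, build_demography, coalescent_hazard_integral
from .likelihood import EpochModel
from .matrix import BiopsyMeta, Character, SgaMatrix
from .trees import SampledTree, TreeNode

logger = logging.getLogger(__name__)

#: Approximate GRCh37 autosome lengths in bp (rounded to 0.1 Mb).
DEFAULT_CHROMOSOMES: dict[str, int] = {
    "chr1": 249_300_000, "chr2": 243_200_000, "chr3": 198_000_000,
    "chr4": 191_200_000, "chr5": 180_900_000, "chr6": 171_100_000,
    "chr7": 159_100_000, "chr8": 146_400_000, "chr9": 141_200_000,
    "chr10": 135_500_000, "chr11": 135_000_000, "chr12": 133_900_000,
    "chr13": 115_200_000, "chr14": 107_300_000, "chr15": 102_500_000,
    "chr16": 90_400_000, "chr17": 81_200_000, "chr18": 78_100_000,
    "chr19": 59_100_000, "chr20": 63_000_000, "chr21": 48_100_000,
    "chr22": 51_300_000,
}

SGA_STATES = ("AA", "A", "0", "AAB", "AAA", "AAAA", "AABB")
#: Relative frequencies of the seven altered states (losses and
#: copy-neutral LOH dominate segmental SGA spectra in Barrett's biopsies).
DEFAULT_STATE_WEIGHTS: dict[str, float] = {
    "AA": 0.25, "A": 0.30, "0": 0.05, "AAB": 0.20,
    "AAA": 0.10, "AAAA": 0.05, "AABB": 0.05,
}


@dataclass
class GenomeModel:
    """Chromosome lengths and the SGA event-size distribution."""

    chromosomes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMOSOMES))
    size_min_bp: float = 1e5  # log-uniform event-size bounds
    size_max_bp: float = 1e8
    state_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATE_WEIGHTS))

    @property
    def total_bp(self) -> int:
        return sum(self.chromosomes.values())

    def draw_interval(self, rng: np.random.Generator) -> tuple[str, int, int]:
        """Draw an event interval: chromosome by length, log-uniform size."""
        chroms = list(self.chromosomes)
        lengths = np.array([self.chromosomes[c] for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
        size = int(round(math.exp(rng.uniform(math.log(self.size_min_bp),
                                              math.log(self.size_max_bp)))))
        size = min(size, self.chromosomes[chrom])
        start = int(rng.integers(0, self.chromosomes[chrom] - size + 1))
        return chrom, start, start + size

    def draw_state(self, rng: np.random.Generator) -> str:
        states = list(self.state_weights)
        w = np.array([self.state_weights[s] for s in states], dtype=float)
        return states[rng.choice(len(states), p=w / w.sum())]


@dataclass(frozen=True)
class SgaEvent:
    """One SGA acquisition on one branch of the genealogy."""

    event_id: int
    branch: str  # id (name) of the child node of the branch carrying the event
    time: float  # calendar years (relative to baseline)
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    state: str  # one of the seven altered molecular states
    haplotype: int  # 1 or 2: the retained / duplicated parental haplotype

    @property
    def character(self) -> Character:
        return Character(self.chrom, self.start, self.end, f"{self.state}.h{self.haplotype}")


@dataclass
class TrueEventLog:
    """Ground-truth event list plus the tips each event is inherited by."""

    events: list[SgaEvent]
    carriers: dict[int, frozenset[str]]  # event_id -> tip names below the branch

    def events_of_tip(self, tip_name: str) -> list[SgaEvent]:
        """Events on the ancestral path of a tip, oldest first."""
        mine = [e for e in self.events if tip_name in self.carriers[e.event_id]]
        return sorted(mine, key=lambda e: e.time)


# --------------------------------------------------------------------------
# genealogy simulation
# --------------------------------------------------------------------------

def simulate_genealogy(
    demography: LogisticDemography,
    sampling: list[tuple[float, list[str]]],
    rng: np.random.Generator | int,
    pop_scale: float = 1.0,
    luca_age: float | None = None,
) -> SampledTree:
    """Serial-sample coalescent genealogy under the logistic trajectory.

    ``sampling`` lists (sample_time_years, tip_names) per endoscopy.
    Going back in time, pairs coalesce with intensity 1/N(t); lineages not
    coalesced by segment initiation are forced to coalesce there (the
    founder crypt), which is logged.  The MRCA is attached to a LUCA node
    at ``luca_age`` years before baseline (default: the demography's
    initiation time).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sum(len(names) for _, names in sampling) < 2:
        raise ValueError("need at least two tips")
    T_init = demography.T_init
    luca_age = T_init if luca_age is None else luca_age

    # events in backward time: age = -calendar_time
    schedule = sorted(sampling, key=lambda s: -s[0])  # latest sample first
    active: list[TreeNode] = []
    idx = 0
    age = -schedule[0][0]
    forced = False
    eps = 1e-9

    def hazard_to(a_hi: float, k: int, a_lo: float) -> float:
        return 0.5 * k * (k - 1) * coalescent_hazard_integral(demography, a_lo, a_hi, pop_scale)

    while True:
        while idx < len(schedule) and -schedule[idx][0] <= age + 1e-15:
            t_s, names = schedule[idx]
            for nm in names:
                active.append(TreeNode(nm, t_s))
            idx += 1
        if idx >= len(schedule) and len(active) == 1:
            break
        next_age = -schedule[idx][0] if idx < len(schedule) else math.inf
        k = len(active)
        if k >= 2:
            target = float(rng.exponential(1.0))
            # cap the search at the forced-coalescence horizon
            a_cap = T_init - eps
            if age >= a_cap or hazard_to(a_cap, k, age) < target:
                a_event = math.inf  # would fall beyond initiation
            else:
                a_event = brentq(
                    lambda a: hazard_to(a, k, age) - target, age, a_cap, xtol=1e-12
                )
            if a_event <= next_age:
                if a_event is math.inf or a_event > T_init - eps:
                    # force remaining coalescences at initiation
                    forced = True
                    a_forced = T_init - eps * (len(active) - 1)
                    while len(active) > 1:
                        i, j = rng.choice(len(active), size=2, replace=False)
                        parent = TreeNode(time=-a_forced)
                        parent.add_child(active[i])
                        parent.add_child(active[j])
                        active = [n for idx2, n in enumerate(active) if idx2 not in (i, j)]
                        active.append(parent)
                        a_forced += eps
                    break
                i, j = rng.choice(k, size=2, replace=False)
                parent = TreeNode(time=-a_event)
                parent.add_child(active[i])
                parent.add_child(active[j])
                active = [n for idx2, n in enumerate(active) if idx2 not in (i, j)]
                active.append(parent)
                age = a_event
                continue
        if next_age is math.inf:
            # single lineage left but samples exhausted handled above; if
            # k < 2 with no more samples we cannot progress
            break
        age = next_age
    mrca = active[0]
    if forced:
        logger.info("lineages not fully coalesced by initiation; forced MRCA at %.3f y", T_init)
    luca = TreeNode("LUCA", min(-luca_age, mrca.time - eps))
    luca.add_child(mrca)
    tree = SampledTree(luca)
    _name_internal_nodes(tree)
    return tree


def _name_internal_nodes(tree: SampledTree) -> None:
    """Deterministic ids for internal nodes (used as branch ids)."""
    i = 0
    for node in tree.postorder():
        if not node.is_leaf and node.name is None:
            node.name = f"n{i}"
            i += 1


# --------------------------------------------------------------------------
# SGA event simulation
# --------------------------------------------------------------------------

def simulate_sga_events(
    tree: SampledTree,
    epochs: EpochModel,
    genome: GenomeModel,
    rng: np.random.Generator | int,
    homoplasy_prob: float = 0.01,
) -> tuple[SgaMatrix, TrueEventLog]:
    """Drop SGA events on branches as a two-epoch Poisson process.

    Within each branch, calendar time in the first epoch accrues events at
    that epoch's genome-wide rate and likewise for the second; an event
    draws an interval, a molecular state and a haplotype, and is inherited
    by every tip below its branch.  With probability ``homoplasy_prob`` an
    event reuses the interval/state/haplotype of a previous event
    (convergent evolution), sharing its matrix column.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    events: list[SgaEvent] = []
    carriers: dict[int, frozenset[str]] = {}
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))

    eid = 0
    for child, t0, t1 in tree.branches():
        # split the branch at the epoch boundary
        pieces = []
        if t0 < epochs.t_switch < t1:
            pieces = [(t0, epochs.t_switch, epochs.first_rate),
                      (epochs.t_switch, t1, epochs.second_rate)]
        elif t1 <= epochs.t_switch:
            pieces = [(t0, t1, epochs.first_rate)]
        else:
            pieces = [(t0, t1, epochs.second_rate)]
        for (a, b, lam) in pieces:
            n = rng.poisson(lam * (b - a))
            for t_event in sorted(rng.uniform(a, b, size=n)):
                if events and rng.uniform() < homoplasy_prob:
                    src = events[int(rng.integers(len(events)))]
                    chrom, start, end = src.chrom, src.start, src.end
                    state, hap = src.state, src.haplotype
                else:
                    chrom, start, end = genome.draw_interval(rng)
                    state = genome.draw_state(rng)
                    hap = int(rng.integers(1, 3))
                ev = SgaEvent(eid, child.name, float(t_event), chrom, start, end, state, hap)
                events.append(ev)
                carriers[eid] = below[id(child)]
                eid += 1

    log = TrueEventLog(events, carriers)
    return true_presence_matrix(tree, log), log


def true_presence_matrix(tree: SampledTree, log: TrueEventLog) -> SgaMatrix:
    """Ground-truth binary matrix: tips x distinct event characters."""
    tips = tree.tip_names()
    chars: list[Character] = []
    char_index: dict[Character, int] = {}
    cols: list[set[str]] = []
    for ev in log.events:
        c = ev.character
        if c not in char_index:
            char_index[c] = len(chars)
            chars.append(c)
            cols.append(set())
        cols[char_index[c]].update(log.carriers[ev.event_id])
    data = np.zeros((len(tips), len(chars)), dtype=np.uint8)
    for j, carrier_set in enumerate(cols):
        for nm in carrier_set:
            data[tips.index(nm), j] = 1
    return SgaMatrix(tips, chars, data)


# --------------------------------------------------------------------------
# array-signal simulation
# --------------------------------------------------------------------------

def make_probe_map(
    genome: GenomeModel,
    n_probes: int,
    rng: np.random.Generator | int,
    het_fraction: float = 0.30,
) -> pd.DataFrame:
    """Evenly spaced SNP probes with control genotypes and known phase.

    Columns: chrom, pos, genotype (B-allele copies 0/1/2 in the control),
    hap1_is_b (phase of heterozygous probes).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    total = genome.total_bp
    rows = []
    for chrom, length in genome.chromosomes.items():
        n_c = max(2, int(round(n_probes * length / total)))
        pos = np.linspace(0, length - 1, n_c).astype(np.int64)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    probes = pd.concat(rows, ignore_index=True)
    n = len(probes)
    hom_fraction = (1.0 - het_fraction) / 2.0
    genotype = rng.choice([0, 1, 2], size=n, p=[hom_fraction, het_fraction, hom_fraction])
    probes["genotype"] = genotype.astype(np.int8)
    probes["hap1_is_b"] = rng.uniform(size=n) < 0.5
    # phase of homozygous probes is degenerate; normalize for determinism
    probes.loc[probes.genotype == 0, "hap1_is_b"] = False
    probes.loc[probes.genotype == 2, "hap1_is_b"] = True
    return probes


# canonical copy number and B-copy arithmetic of the eight states; ``g`` is
# the control B-copy count and ``a_h`` the B-ness (0/1) of the event haplotype
def _apply_state(state: str, g: np.ndarray, a_h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if state == "A":
        return np.ones_like(g, dtype=float), a_h.astype(float)
    if state == "0":
        return np.zeros_like(g, dtype=float), np.zeros_like(g, dtype=float)
    if state == "AA":
        return np.full(len(g), 2.0), 2.0 * a_h
    if state == "AAB":
        return np.full(len(g), 3.0), g + a_h.astype(float)
    if state == "AAA":
        return np.full(len(g), 3.0), 3.0 * a_h
    if state == "AAAA":
        return np.full(len(g), 4.0), 4.0 * a_h
    if state == "AABB":
        return np.full(len(g), 4.0), 2.0 * g.astype(float)
    raise ValueError(f"unknown state {state!r}")


def _tip_expected_signal(
    probes: pd.DataFrame, events: list[SgaEvent]
) -> tuple[np.ndarray, np.ndarray]:
    """Expected (copy number, B copies) per probe after applying events.

    Events are applied oldest-first relative to the germline configuration;
    where events overlap on one lineage the later event overrides.
    """
    n = len(probes)
    g = probes["genotype"].to_numpy().astype(float)
    cp = np.full(n, 2.0)
    b = g.copy()
    for ev in events:
        mask = (
            (probes["chrom"].to_numpy() == ev.chrom)
            & (probes["pos"].to_numpy() >= ev.start)
            & (probes["pos"].to_numpy() < ev.end)
        )
        if not mask.any():
            continue
        hap1_b = probes["hap1_is_b"].to_numpy()[mask]
        g_m = probes["genotype"].to_numpy()[mask]
        # B-ness of the event haplotype at each probe
        if ev.haplotype == 1:
            a_h = np.where(g_m == 1, hap1_b, g_m == 2).astype(float)
        else:
            a_h = np.where(g_m == 1, ~hap1_b, g_m == 2).astype(float)
        cp_m, b_m = _apply_state(ev.state, g_m, a_h)
        cp[mask] = cp_m
        b[mask] = b_m
    return cp, b


def _dye_bias_map(baf: np.ndarray, het_median: float) -> np.ndarray:
    """Piecewise-linear BAF warp anchoring 0 -> 0, 0.5 -> het_median, 1 -> 1."""
    lo = baf <= 0.5
    out = np.empty_like(baf)
    out[lo] = baf[lo] * (het_median / 0.5)
    out[~lo] = het_median + (baf[~lo] - 0.5) * ((1.0 - het_median) / 0.5)
    return out


def simulate_array_signals(
    event_log: TrueEventLog,
    tree: SampledTree,
    probes: pd.DataFrame,
    rng: np.random.Generator | int,
    noise_sd: float = 0.15,
    baf_noise_sd: float | None = None,
    dye_bias: float = 0.53,
    mixture_fraction: float = 0.3,
    mixed_tips: set[str] | None = None,
    control_id: str = "control",
) -> dict[str, pd.DataFrame]:
    """Per-sample probe tables (sample_id, chrom, pos, X, Y, R, BAF).

    ``noise_sd`` is the Gaussian noise of the total-intensity channel R;
    the BAF channel of genotyping arrays is cluster-calibrated and much
    tighter, so its noise defaults to ``noise_sd / 3``.  The control
    sample carries no events.  Mixed biopsies blend the tip clone with
    its parent clone (pendant-branch events removed) at
    ``mixture_fraction``; signals mix allele-wise before noise.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not (0 <= mixture_fraction < 0.5):
        raise ValueError("mixture_fraction must lie in [0, 0.5)")
    if baf_noise_sd is None:
        baf_noise_sd = noise_sd / 3.0
    if (probes["pos"] < 0).any():
        raise ValueError("invalid probe_map: negative positions")
    mixed_tips = mixed_tips or set()
    out: dict[str, pd.DataFrame] = {}

    def emit(sample_id: str, cp: np.ndarray, b: np.ndarray) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            baf = np.where(cp > 0, b / np.maximum(cp, 1e-12), 0.5)
        r = cp / 2.0
        baf = _dye_bias_map(np.clip(baf, 0.0, 1.0), dye_bias)
        if baf_noise_sd > 0:
            baf = np.clip(baf + rng.normal(0.0, baf_noise_sd, len(baf)), 0.0, 1.0)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, len(r))
        r = np.maximum(r, 1e-3)
        x = r * (1.0 - baf)
        y = r * baf
        return pd.DataFrame(
            {
                "sample_id": sample_id,
                "chrom": probes["chrom"].to_numpy(),
                "pos": probes["pos"].to_numpy(),
                "X": x,
                "Y": y,
                "R": r,
                "BAF": baf,
            }
        )

    # control: germline diploid
    g = probes["genotype"].to_numpy().astype(float)
    out[control_id] = emit(control_id, np.full(len(probes), 2.0), g.copy())

    pendant_branch = {t.name: t.name for t in tree.tips()}
    for tip in tree.tip_names():
        events = event_log.events_of_tip(tip)
        cp, b = _tip_expected_signal(probes, events)
        if tip in mixed_tips:
            parent_events = [e for e in events if e.branch != pendant_branch[tip]]
            cp2, b2 = _tip_expected_signal(probes, parent_events)
            w = mixture_fraction
            cp_mix = (1 - w) * cp + w * cp2
            b_mix = (1 - w) * b + w * b2
            out[tip] = emit(tip, cp_mix, b_mix)
        else:
            out[tip] = emit(tip, cp, b)
    return out


# --------------------------------------------------------------------------
# whole-individual bundle
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for one synthetic individual.

    Defaults reproduce the cohort's design: 5 endoscopies over 12 years,
    12 biopsies, an off->on NSAID transition, off/on SGA rates of 8 and
    0.6 events per genome per year, and a crypt demography (50k-crypt
    capacity, 30k crypts at baseline, 600-day doubling time from a 5%
    branching fraction at 30 days' visibility) that puts segment
    initiation about 27 years before baseline.
    """

    n_timepoints: int = 5
    n_biopsies: int = 12
    followup_years: float = 12.0
    n_off_timepoints: int = 3  # endoscopies before the NSAID transition
    pattern: str = "off_on"
    lam_off: float = 8.0
    lam_on: float = 0.6
    K: float = 50_000.0
    N_t: float = 30_000.0
    T_r: float = 600.0  # days; = 30-day branching visibility / I_b 0.05
    pop_scale: float = 1.0
    n_probes: int = 100_000
    noise_sd: float = 0.15
    baf_noise_sd: float | None = None  # default: noise_sd / 3
    dye_bias: float = 0.53
    mixture_prob: float = 0.15
    mixture_fraction: float = 0.3
    homoplasy_prob: float = 0.01
    size_min_bp: float = 1e5
    size_max_bp: float = 1e8
    segment_cm: tuple[float, float] = (35.0, 44.0)  # levels above the GEJ

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("need at least two endoscopies")
        # keep at least one endoscopy on each side of the NSAID transition
        self.n_off_timepoints = max(1, min(self.n_off_timepoints, self.n_timepoints - 1))

    def timepoints(self) -> np.ndarray:
        return np.linspace(0.0, self.followup_years, self.n_timepoints)

    @property
    def t_switch(self) -> float:
        """Midpoint between the last pre- and first post-transition endoscopy."""
        tp = self.timepoints()
        return float(0.5 * (tp[self.n_off_timepoints - 1] + tp[self.n_off_timepoints]))


@dataclass
class SyntheticIndividual:
    """Full ground-truth bundle for one simulated individual."""

    individual_id: str
    config: CohortConfig
    demography: LogisticDemography
    epochs: EpochModel
    genome: GenomeModel
    tree: SampledTree
    event_log: TrueEventLog
    truth_matrix: SgaMatrix
    meta: dict[str, BiopsyMeta]
    mixed_tips: set[str]
    probes: pd.DataFrame | None = None
    signals: dict[str, pd.DataFrame] | None = None

    @property
    def control_id(self) -> str:
        return f"{self.individual_id}_blood"


def simulate_individual(
    config: CohortConfig,
    seed: int | np.random.Generator,
    individual_id: str = "ind01",
    with_signals: bool = False,
) -> SyntheticIndividual:
    """Simulate one individual end to end (genealogy, events, metadata,
    and optionally probe-level array signals)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    demography = build_demography(config.K, config.N_t, config.T_r)
    epochs = EpochModel(config.pattern, config.t_switch, config.lam_off, config.lam_on)
    genome = GenomeModel(size_min_bp=config.size_min_bp, size_max_bp=config.size_max_bp)

    tp = config.timepoints()
    counts = np.full(config.n_timepoints, config.n_biopsies // config.n_timepoints)
    counts[: config.n_biopsies % config.n_timepoints] += 1
    sampling = []
    bi = 0
    for t, c in zip(tp, counts):
        names = [f"{individual_id}_b{bi + k:02d}" for k in range(c)]
        bi += c
        sampling.append((float(t), names))
    tree = simulate_genealogy(demography, sampling, rng, pop_scale=config.pop_scale)
    matrix, event_log = simulate_sga_events(
        tree, epochs, genome, rng, homoplasy_prob=config.homoplasy_prob
    )

    # metadata: NSAID status per endoscopy, levels assigned to clade blocks
    status_of_time = {
        float(t): ("off" if i < config.n_off_timepoints else "on")
        if config.pattern == "off_on"
        else ("on" if i < config.n_off_timepoints else "off")
        for i, t in enumerate(tp)
    }
    tip_order = tree.tip_names()  # clade-contiguous traversal order
    lo, hi = config.segment_cm
    levels = {
        nm: round(lo + (hi - lo) * (k + 0.5) / len(tip_order), 1)
        for k, nm in enumerate(tip_order)
    }
    meta: dict[str, BiopsyMeta] = {}
    for t, names in sampling:
        for nm in names:
            meta[nm] = BiopsyMeta(individual_id, nm, t, levels[nm], status_of_time[t])
    control_id = f"{individual_id}_blood"
    meta[control_id] = BiopsyMeta(individual_id, control_id, 0.0, lo, status_of_time[0.0],
                                  is_control=True)
    matrix.meta = {nm: meta[nm] for nm in matrix.biopsy_ids}

    mixed = {nm for nm in tree.tip_names() if rng.uniform() < config.mixture_prob}
    ind = SyntheticIndividual(
        individual_id, config, demography, epochs, genome, tree, event_log,
        matrix, meta, mixed,
    )
    if with_signals:
        probes = make_probe_map(genome, config.n_probes, rng)
        ind.probes = probes
        ind.signals = simulate_array_signals(
            event_log, tree, probes, rng,
            noise_sd=config.noise_sd, baf_noise_sd=config.baf_noise_sd,
            dye_bias=config.dye_bias,
            mixture_fraction=config.mixture_fraction, mixed_tips=mixed,
            control_id=control_id,
        )
    return ind
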