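"""Ground-truth evaluation of caller output on synthetic individuals.

Recovery is scored per simulated event: an event is *recovered* when
every biopsy that inherits it calls its molecular state (and, for
allelic-imbalance states, its haplotype) over the event's span, with
both breakpoints within a tolerance measured in informative probes —
the probes that actually carry signal for that state: every retained
probe for copy-number states, heterozygous probes only for copy-neutral
LOH, whose boundaries cannot be localized more finely than the
heterozygous probe spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calling import CallResult, IMBALANCE_STATES
from .cohort import SgaEvent, SyntheticIndividual


@dataclass
class EventRecovery:
    event: SgaEvent
    n_probes: int
    recovered: bool
    state_ok: bool
    max_breakpoint_error: int  # informative probes; -1 when the state is wrong


def _informative_positions(result: CallResult, probes_pos, probes_chrom,
                           chrom: str, het_only: bool) -> np.ndarray:
    mask = probes_chrom == chrom
    if het_only:
        mask = mask & result.het_mask
    return probes_pos[mask]


def isolated_events(
    ind: SyntheticIndividual, min_size_bp: float = 0.0, margin_bp: float = 0.0
) -> list[SgaEvent]:
    """Events cleanly attributable to their own boundaries.

    Excludes events that overlap — or approach within ``margin_bp`` of —
    another event in any biopsy that carries both: overlaps make the
    visible state a composite, and a neighbouring boundary inside the
    margin confounds whose breakpoint is whose."""
    log = ind.event_log
    out = []
    for ev in log.events:
        if ev.end - ev.start < min_size_bp:
            continue
        clean = True
        for other in log.events:
            if other.event_id == ev.event_id or other.chrom != ev.chrom:
                continue
            if other.start < ev.end + margin_bp and ev.start - margin_bp < other.end:
                if log.carriers[ev.event_id] & log.carriers[other.event_id]:
                    clean = False
                    break
        if clean:
            out.append(ev)
    return out


def score_event_recovery(
    ind: SyntheticIndividual,
    result: CallResult,
    min_probes: int = 50,
    tolerance_probes: int = 2,
) -> list[EventRecovery]:
    """Score recovery of isolated simulated events spanning enough probes."""
    probes = ind.probes[result.retained_mask].reset_index(drop=True)
    pos = probes["pos"].to_numpy()
    chroms = probes["chrom"].to_numpy()
    # isolation margin: the caller's refinement radius in median probe
    # spacing — heterozygous-probe spacing for copy-neutral LOH, whose
    # signal lives only at het probes
    gaps = np.diff(pos)
    margin_bp = 30.0 * float(np.median(gaps[gaps > 0]))  # within-chromosome gaps
    het_pos = pos[result.het_mask]
    het_gaps = np.diff(het_pos)
    margin_het_bp = 30.0 * float(np.median(het_gaps[het_gaps > 0]))
    candidates = {
        e.event_id for e in isolated_events(ind, margin_bp=margin_bp) if e.state != "AA"
    } | {
        e.event_id for e in isolated_events(ind, margin_bp=margin_het_bp) if e.state == "AA"
    }
    out = []
    for ev in ind.event_log.events:
        if ev.event_id not in candidates:
            continue
        het_only = ev.state == "AA"
        info = _informative_positions(result, pos, chroms, ev.chrom, het_only)
        inside = (info >= ev.start) & (info < ev.end)
        n_inside = int(inside.sum())
        all_pos = pos[chroms == ev.chrom]
        n_span = int(((all_pos >= ev.start) & (all_pos < ev.end)).sum())
        if n_span < min_probes:
            continue
        state_ok = True
        worst = 0
        for tip in sorted(ind.event_log.carriers[ev.event_id]):
            calls = result.calls_by_sample[tip]
            hits = [
                c for c in calls
                if c.chrom == ev.chrom and c.start < ev.end and ev.start < c.end
                and c.state == ev.state
                and (ev.state not in IMBALANCE_STATES or c.haplotype in (ev.haplotype, None))
            ]
            if not hits:
                state_ok = False
                break
            # clip to the contiguous run around the best-overlapping call so a
            # neighbouring same-state event does not pollute the boundaries
            hits.sort(key=lambda c: c.start)
            best = max(
                range(len(hits)),
                key=lambda i: min(hits[i].end, ev.end) - max(hits[i].start, ev.start),
            )
            run = [hits[best]]
            for c in hits[best + 1 :]:
                if c.start == run[-1].end:
                    run.append(c)
                else:
                    break
            for c in reversed(hits[:best]):
                if c.end == run[0].start:
                    run.insert(0, c)
                else:
                    break
            covered = sum(min(c.end, ev.end) - max(c.start, ev.start) for c in run)
            if covered < 0.5 * (ev.end - ev.start):
                # majority of the span miscalled; boundary errors are
                # meaningless, count as a state failure
                state_ok = False
                break
            called_lo = min(c.start for c in run)
            called_hi = max(c.end for c in run)
            for true_bp, called_bp in ((ev.start, called_lo), (ev.end, called_hi)):
                err = int(np.sum((info >= min(true_bp, called_bp))
                                 & (info < max(true_bp, called_bp))))
                worst = max(worst, err)
        if not state_ok:
            out.append(EventRecovery(ev, n_inside, False, False, -1))
        else:
            out.append(
                EventRecovery(ev, n_inside, worst <= tolerance_probes, True, worst)
            )
    return out
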