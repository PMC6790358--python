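"""Cross-sample peak registration by nearest-neighbour connecting (NNC).

Peaks from all samples (carrying time-shift-corrected rts) are grouped into
registered components. For each item its candidates are the items of other
samples within the m/z (0.01 Da) and rt (0.1 min) tolerances, ordered by
|delta rt| ascending; a pair merges only when each is the other's first
candidate (mutual nearest neighbours), and a group can never hold two peaks
from one sample. Scanning repeats until no further merge is possible; every
leftover peak becomes a singleton component.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .models import Component, ComponentTable, EICPeak


def candidate_peaks(p: EICPeak, pool: list[EICPeak],
                    mz_tol: float = 0.01, rt_tol: float = 0.1) -> list[EICPeak]:
    """Candidates of ``p`` in other samples, |drt| ascending, ties |dmz|."""
    cands = [q for q in pool
             if q.sample_id != p.sample_id
             and abs(q.apex_mz - p.apex_mz) <= mz_tol
             and abs(q.apex_rt - p.apex_rt) <= rt_tol]
    cands.sort(key=lambda q: (abs(q.apex_rt - p.apex_rt), abs(q.apex_mz - p.apex_mz)))
    return cands


class _Group:
    """A forming component: member peaks keyed by sample, mean (rt, mz)."""

    __slots__ = ("members", "mean_rt", "mean_mz")

    def __init__(self, peak: EICPeak):
        self.members: dict[str, EICPeak] = {peak.sample_id: peak}
        self.mean_rt = peak.apex_rt
        self.mean_mz = peak.apex_mz

    def merge(self, other: "_Group") -> None:
        self.members.update(other.members)
        rts = [p.apex_rt for p in self.members.values()]
        mzs = [p.apex_mz for p in self.members.values()]
        self.mean_rt = float(np.mean(rts))
        self.mean_mz = float(np.mean(mzs))

    def key(self) -> tuple:
        return (self.mean_rt, self.mean_mz, min(self.members))


def _first_candidate(i: int, groups: list[_Group], mz_tol: float, rt_tol: float) -> int | None:
    """Index of group ``i``'s first candidate, or None.

    Candidates are other groups within both tolerances of the
    member-mean (rt, mz) that share no sample with group ``i``; nearest by
    |drt| first, |dmz| second, then a deterministic key.
    """
    g = groups[i]
    best: tuple | None = None
    best_j: int | None = None
    for j, h in enumerate(groups):
        if j == i:
            continue
        if g.members.keys() & h.members.keys():
            continue
        drt = abs(h.mean_rt - g.mean_rt)
        dmz = abs(h.mean_mz - g.mean_mz)
        if drt > rt_tol or dmz > mz_tol:
            continue
        k = (drt, dmz, h.key())
        if best is None or k < best:
            best, best_j = k, j
    return best_j


def nnc_register(all_peaks: list[EICPeak],
                 mz_tol: float = 0.01, rt_tol: float = 0.1) -> ComponentTable:
    """Register peaks from all samples into components via mutual-first-candidate merging.

    Components partition the input exactly; output is independent of input
    ordering (items are scanned in a canonical (rt, mz, sample) order).
    Component ids are assigned in (mean_rt, mean_mz) order.
    """
    samples = sorted({p.sample_id for p in all_peaks})
    groups = [_Group(p) for p in sorted(all_peaks, key=lambda p: (p.apex_rt, p.apex_mz, p.sample_id))]

    for _ in range(max(1, len(groups))):  # hard cap guarantees termination
        firsts = [_first_candidate(i, groups, mz_tol, rt_tol) for i in range(len(groups))]
        merge_pairs = [(i, j) for i, j in enumerate(firsts)
                       if j is not None and i < j and firsts[j] == i]
        if not merge_pairs:
            break
        dead = set()
        for i, j in merge_pairs:
            groups[i].merge(groups[j])
            dead.add(j)
        groups = [g for k, g in enumerate(groups) if k not in dead]
        groups.sort(key=_Group.key)

    groups.sort(key=lambda g: (g.mean_rt, g.mean_mz))
    components = []
    for cid, g in enumerate(groups):
        comp = Component(component_id=cid, members=dict(g.members))
        comp.recompute_means()
        components.append(comp)

    heights = pd.DataFrame(
        [[(c.members[s].height if s in c.members else np.nan) for s in samples]
         for c in components],
        index=[c.component_id for c in components], columns=samples)
    areas = pd.DataFrame(
        [[(c.members[s].area if s in c.members else np.nan) for s in samples]
         for c in components],
        index=[c.component_id for c in components], columns=samples)
    return ComponentTable(components=components, samples=samples,
                          heights=heights, areas=areas)
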