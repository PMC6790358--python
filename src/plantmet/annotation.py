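"""Ion-clustering peak annotation: from EIC peaks to metabolite spectra.

Bottom-up, within one sample. Isotope pairs ([M+H]+ with its 13C
isotopologue [M+1+H]+, spacing 1.00336 Da) are seeded under an initial
shape-similarity cut-off (0.9) and a tight rt tolerance (0.02 min). The
observed isotope-pair similarity then sets a per-ion adaptive cut-off —
a noisy ion whose own isotopologue only reaches 0.93 cannot be held to a
0.99 standard. Further isotopologues (M+2, M+3) and adducts (Na+, K+,
NH4+) are recognised by their characteristic mass offsets, [M+H]+ ions are
clustered by shape and rt (dragging their satellites), clusters are
reconciled with the cross-sample Meta-ID grouping, and each confirmed
metabolite yields a derived mass spectrum.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import shape_similarity
from .models import ComponentTable, DerivedSpectrum, EICPeak, IonCluster, MetaGroup

ISO_DELTA = 1.00336  # 13C - 12C
# neutral-mass offsets relative to [M+H]+
DEFAULT_ADDUCTS = {
    "NH4_adduct": 17.02655,  # NH4 - H
    "Na_adduct": 21.98194,   # Na - H
    "K_adduct": 37.95588,    # K - H
}
ISO_ROLES = {2: "M2H", 3: "M3H"}


@dataclass
class IsotopePair:
    mh: EICPeak
    m1h: EICPeak
    similarity: float
    cutoff: float = 0.9


def seed_isotope_pairs(peaks: list[EICPeak],
                       shape_cutoff0: float = 0.9,
                       rt_tol: float = 0.02,
                       iso_mz_delta: float = ISO_DELTA,
                       iso_mz_tol: float = 0.005) -> list[IsotopePair]:
    """Find ([M+H]+, [M+1+H]+) pairs in one sample's peak list.

    A pair requires the isotope spacing within ``iso_mz_tol``, apex rts
    within ``rt_tol``, shape similarity >= ``shape_cutoff0`` and the
    isotopologue weaker than the monoisotopic peak. Each peak takes part
    in at most one pair (best similarity wins).
    """
    cands: list[tuple[float, EICPeak, EICPeak]] = []
    by_rt = sorted(peaks, key=lambda p: p.apex_rt)
    for i, p in enumerate(by_rt):
        for q in by_rt[i + 1:]:
            if q.apex_rt - p.apex_rt > rt_tol:
                break
            lo, hi = sorted((p, q), key=lambda r: r.apex_mz)
            if abs((hi.apex_mz - lo.apex_mz) - iso_mz_delta) > iso_mz_tol:
                continue
            if hi.height >= lo.height:
                continue
            sim = shape_similarity(lo, hi)
            if sim >= shape_cutoff0:
                cands.append((sim, lo, hi))
    # similarity first (rounded so float noise cannot decide), then the
    # taller monoisotopic candidate: an (M+1, M+2) pair must not shadow the
    # true (M, M+1) pair of the same isotope ladder
    cands.sort(key=lambda c: (-round(c[0], 6), -c[1].height))
    used: set[int] = set()
    pairs: list[IsotopePair] = []
    for sim, mh, m1h in cands:
        if id(mh) in used or id(m1h) in used:
            continue
        used.add(id(mh))
        used.add(id(m1h))
        pairs.append(IsotopePair(mh=mh, m1h=m1h, similarity=sim))
    return pairs


def adaptive_cutoff(pair: IsotopePair,
                    shape_cutoff0: float = 0.9,
                    margin: float = 0.02,
                    cutoff_floor: float = 0.8) -> float:
    """Per-ion shape threshold from the observed isotope-pair similarity.

    max(floor, min(initial cut-off, similarity - margin)): never stricter
    than the initial 0.9, degrades gracefully for noisy peaks, never below
    the floor.
    """
    return max(cutoff_floor, min(shape_cutoff0, pair.similarity - margin))


@dataclass
class AnnotatedIon:
    """An [M+H]+ ion with its adaptive threshold and satellite peaks."""

    mh: EICPeak
    cutoff: float
    satellites: dict[str, EICPeak] = field(default_factory=dict)  # role -> peak

    def all_peaks(self) -> list[tuple[EICPeak, str]]:
        out = [(self.mh, "MH")]
        out += [(p, role) for role, p in sorted(self.satellites.items())]
        return out


def extend_annotations(pairs: list[IsotopePair], peaks: list[EICPeak],
                       adduct_table: dict[str, float] | None = None,
                       rt_tol: float = 0.02,
                       iso_mz_tol: float = 0.005,
                       iso_mz_delta: float = ISO_DELTA,
                       shape_cutoff0: float = 0.9,
                       margin: float = 0.02,
                       cutoff_floor: float = 0.8) -> list[AnnotatedIon]:
    """Attach further isotopologues and adducts to each seeded [M+H]+ ion.

    Each MH ion looks for peaks at +2/+3 isotope spacings and at the adduct
    mass offsets, within the m/z tolerance, rt tolerance and its adaptive
    shape threshold. A satellite claimed by several MH ions goes to the one
    with the higher shape similarity.
    """
    if adduct_table is None:
        adduct_table = DEFAULT_ADDUCTS
    ions = [AnnotatedIon(mh=p.mh, cutoff=adaptive_cutoff(p, shape_cutoff0, margin, cutoff_floor))
            for p in pairs]
    for ion, pair in zip(ions, pairs):
        ion.satellites["M1H"] = pair.m1h

    claimed: dict[int, tuple[float, AnnotatedIon, str]] = {}  # peak id -> (sim, ion, role)
    taken = {id(p.mh) for p in pairs} | {id(p.m1h) for p in pairs}
    deltas = {ISO_ROLES[k]: k * iso_mz_delta for k in ISO_ROLES}
    deltas.update(adduct_table)
    for ion in ions:
        for role, delta in deltas.items():
            target = ion.mh.apex_mz + delta
            best: tuple[float, EICPeak] | None = None
            for q in peaks:
                if id(q) in taken:
                    continue
                if abs(q.apex_mz - target) > iso_mz_tol:
                    continue
                if abs(q.apex_rt - ion.mh.apex_rt) > rt_tol:
                    continue
                sim = shape_similarity(ion.mh, q)
                if sim < ion.cutoff:
                    continue
                if best is None or sim > best[0]:
                    best = (sim, q)
            if best is None:
                continue
            sim, q = best
            prev = claimed.get(id(q))
            if prev is None or sim > prev[0]:
                claimed[id(q)] = (sim, ion, role, q)
    for sim, ion, role, peak in claimed.values():
        ion.satellites[role] = peak
    return ions


def cluster_mh_ions(ions: list[AnnotatedIon], peaks: list[EICPeak],
                    rt_tol: float = 0.02) -> list[IonCluster]:
    """Cluster [M+H]+ ions by shape and rt; admit orphans as fragments.

    Average-linkage agglomeration under hard gates: two clusters may merge
    only if every cross-pair of MH ions has shape similarity >= both ions'
    adaptive thresholds and apex rts within ``rt_tol``; merges proceed in
    order of decreasing average similarity. Unannotated peaks are then
    admitted to a cluster as in-source fragments when they pass every
    member MH ion's threshold and the rt gate against the cluster
    consensus.
    """
    clusters: list[list[AnnotatedIon]] = [[ion] for ion in ions]

    def _gate(a: AnnotatedIon, b: AnnotatedIon) -> float | None:
        if abs(a.mh.apex_rt - b.mh.apex_rt) > rt_tol:
            return None
        sim = shape_similarity(a.mh, b.mh)
        if sim < a.cutoff or sim < b.cutoff:
            return None
        return sim

    while len(clusters) > 1:
        best: tuple[float, int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                sims = []
                ok = True
                for a in clusters[i]:
                    for b in clusters[j]:
                        s = _gate(a, b)
                        if s is None:
                            ok = False
                            break
                        sims.append(s)
                    if not ok:
                        break
                if ok and sims:
                    avg = float(np.mean(sims))
                    if best is None or avg > best[0]:
                        best = (avg, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]

    annotated_ids = set()
    for ion in ions:
        annotated_ids.add(id(ion.mh))
        annotated_ids.update(id(p) for p in ion.satellites.values())

    out: list[IonCluster] = []
    for ci, members in enumerate(clusters):
        roles: dict[int, str] = {}
        peak_ids: list[int] = []
        for ion in members:
            for p, role in ion.all_peaks():
                roles[p.peak_id] = role
                peak_ids.append(p.peak_id)
        rt = float(np.mean([ion.mh.apex_rt for ion in members]))
        cutoff = max(ion.cutoff for ion in members)
        out.append(IonCluster(cluster_id=ci, member_peak_ids=peak_ids,
                              roles=roles, apex_rt=rt, adaptive_cutoff=cutoff))

    # orphan admission as fragments
    for q in peaks:
        if id(q) in annotated_ids:
            continue
        best: tuple[float, IonCluster] | None = None
        for cl, members in zip(out, clusters):
            if abs(q.apex_rt - cl.apex_rt) > rt_tol:
                continue
            sims = [shape_similarity(ion.mh, q) for ion in members]
            if any(s < ion.cutoff for s, ion in zip(sims, members)):
                continue
            avg = float(np.mean(sims))
            if best is None or avg > best[0]:
                best = (avg, cl)
        if best is not None:
            cl = best[1]
            cl.member_peak_ids.append(q.peak_id)
            cl.roles[q.peak_id] = "fragment"

    out.sort(key=lambda c: c.apex_rt)
    for i, c in enumerate(out):
        c.cluster_id = i
    return out


def annotate_sample(peaks: list[EICPeak], **params) -> list[IonCluster]:
    """Full within-sample pass: seed, adapt, extend, cluster."""
    seed_kw = {k: params[k] for k in ("shape_cutoff0", "rt_tol", "iso_mz_delta", "iso_mz_tol")
               if k in params}
    pairs = seed_isotope_pairs(peaks, **seed_kw)
    ext_kw = {k: params[k] for k in ("adduct_table", "rt_tol", "iso_mz_tol", "iso_mz_delta",
                                     "shape_cutoff0", "margin", "cutoff_floor") if k in params}
    ions = extend_annotations(pairs, peaks, **ext_kw)
    return cluster_mh_ions(ions, peaks, rt_tol=params.get("rt_tol", 0.02))


def reconcile_with_screening(clusters_by_sample: dict[str, list[IonCluster]],
                             metas: list[MetaGroup],
                             table: ComponentTable,
                             min_votes: int | None = None
                             ) -> tuple[dict[int, list[int]], list[dict]]:
    """Confirm metabolites where within-sample and cross-sample evidence agree.

    Two components support each other when their peaks co-cluster within a
    sample in at least ``min_votes`` samples (default: majority of samples)
    AND they share a Meta ID. Connected sets under that AND-rule become
    confirmed metabolites (ids in rt order). Pairs with only one kind of
    evidence are reported as partial evidence.

    Returns (metabolite_id -> component ids, partial-evidence records).
    """
    import networkx as nx

    n_samples = len(table.samples)
    if min_votes is None:
        min_votes = int(np.ceil(n_samples / 2))

    meta_of = {}
    for m in metas:
        for cid in m.member_component_ids:
            meta_of[cid] = m.meta_id

    # map peak ids back to components, per sample
    comp_of_peak: dict[str, dict[int, int]] = {s: {} for s in table.samples}
    for comp in table.components:
        for s, p in comp.members.items():
            comp_of_peak[s][p.peak_id] = comp.component_id

    # co-clustering votes per component pair
    votes: dict[tuple[int, int], int] = {}
    for s, clusters in clusters_by_sample.items():
        lookup = comp_of_peak.get(s, {})
        for cl in clusters:
            cids = sorted({lookup[pid] for pid in cl.member_peak_ids if pid in lookup})
            for i in range(len(cids)):
                for j in range(i + 1, len(cids)):
                    key = (cids[i], cids[j])
                    votes[key] = votes.get(key, 0) + 1

    G = nx.Graph()
    partial: list[dict] = []
    for (a, b), v in sorted(votes.items()):
        same_meta = a in meta_of and b in meta_of and meta_of[a] == meta_of[b]
        if v >= min_votes and same_meta:
            G.add_edge(a, b)
        elif v >= min_votes:
            partial.append({"components": (a, b), "evidence": "co_cluster_only", "votes": v})
    for m in metas:
        ids = m.member_component_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                key = tuple(sorted((ids[i], ids[j])))
                if votes.get(key, 0) < min_votes:
                    partial.append({"components": key, "evidence": "meta_id_only",
                                    "votes": votes.get(key, 0)})

    comp_by_id = {c.component_id: c for c in table.components}
    groups = [sorted(g) for g in nx.connected_components(G)]
    # screened singletons that never linked still stand as 1-ion metabolites
    linked = {c for g in groups for c in g}
    for m in metas:
        for cid in m.member_component_ids:
            if cid not in linked:
                groups.append([cid])
    groups.sort(key=lambda g: np.mean([comp_by_id[c].mean_rt for c in g]))
    assignments = {mid: g for mid, g in enumerate(groups)}
    return assignments, partial


def derive_spectrum(metabolite_id: int, component_ids: list[int],
                    table: ComponentTable,
                    clusters_by_sample: dict[str, list[IonCluster]] | None = None
                    ) -> DerivedSpectrum:
    """Assemble the metabolite's derived mass spectrum from its best sample.

    The source sample is the one where the metabolite's tallest ion is
    highest; entries are (apex m/z, height, role) of every member peak
    there, mz-ascending. Duplicate m/z entries are kept distinct.
    """
    comp_by_id = {c.component_id: c for c in table.components}
    best_sample, best_h = None, -np.inf
    for s in table.samples:
        h = max((comp_by_id[c].members[s].height
                 for c in component_ids if s in comp_by_id[c].members), default=None)
        if h is not None and h > best_h:
            best_sample, best_h = s, h
    if best_sample is None:
        raise ValueError(f"metabolite {metabolite_id}: no member peak in any sample")

    role_of: dict[int, str] = {}
    if clusters_by_sample is not None:
        for cl in clusters_by_sample.get(best_sample, []):
            role_of.update(cl.roles)

    entries = []
    for cid in component_ids:
        p = comp_by_id[cid].members.get(best_sample)
        if p is None:
            continue
        entries.append((p.apex_mz, p.height, role_of.get(p.peak_id, "unknown")))
    return DerivedSpectrum(metabolite_id=metabolite_id, entries=entries,
                           source_sample=best_sample)
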