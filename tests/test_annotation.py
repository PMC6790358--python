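"""Ion-clustering annotation: isotope seeding, adaptive cut-off, clustering,
reconciliation with the cross-sample Meta-ID grouping, derived spectra."""
import numpy as np
import pytest

from plantmet.annotation import (DEFAULT_ADDUCTS, ISO_DELTA, IsotopePair,
                                 adaptive_cutoff, annotate_sample, cluster_mh_ions,
                                 derive_spectrum, extend_annotations,
                                 reconcile_with_screening, seed_isotope_pairs)
from plantmet.models import Component, ComponentTable, MetaGroup

from conftest import gaussian_peak


def ion_family(sample_id, rt, mh_mz, mh_height=1e5, sigma=0.05, start_id=0,
               iso_ratio=0.30, adduct=None, fragments=(), rt_shift=0.0):
    """[M+H]+ with its M+1 isotopologue and optional satellites, shared shape."""
    peaks = [gaussian_peak(sample_id, rt, mh_mz, mh_height, sigma, peak_id=start_id),
             gaussian_peak(sample_id, rt + rt_shift, mh_mz + ISO_DELTA,
                           mh_height * iso_ratio, sigma, peak_id=start_id + 1)]
    nid = start_id + 2
    if adduct:
        peaks.append(gaussian_peak(sample_id, rt, mh_mz + DEFAULT_ADDUCTS[adduct],
                                   mh_height * 0.3, sigma, peak_id=nid))
        nid += 1
    for frag_mz, rf in fragments:
        peaks.append(gaussian_peak(sample_id, rt, frag_mz, mh_height * rf, sigma,
                                   peak_id=nid))
        nid += 1
    return peaks


class TestIsotopeSeeding:
    def test_clean_pair_found(self):
        peaks = ion_family("s", 2.29, 611.161, iso_ratio=0.30)
        pairs = seed_isotope_pairs(peaks)
        assert len(pairs) == 1
        assert pairs[0].mh.apex_mz == pytest.approx(611.161)
        assert pairs[0].m1h.apex_mz == pytest.approx(611.161 + ISO_DELTA)

    def test_rt_displaced_isotope_rejected(self):
        peaks = ion_family("s", 2.29, 611.161, rt_shift=0.05)
        assert seed_isotope_pairs(peaks, rt_tol=0.02) == []

    def test_reversed_intensities_rejected(self):
        peaks = ion_family("s", 2.29, 611.161, iso_ratio=1.4)
        assert seed_isotope_pairs(peaks) == []

    def test_wrong_spacing_rejected(self):
        peaks = [gaussian_peak("s", 2.29, 611.161, 1e5, peak_id=0),
                 gaussian_peak("s", 2.29, 611.161 + 1.02, 3e4, peak_id=1)]
        assert seed_isotope_pairs(peaks, iso_mz_tol=0.005) == []


class TestAdaptiveCutoff:
    @pytest.mark.parametrize("sim,expected", [
        (0.999, 0.9),   # clean pair: initial cut-off retained
        (0.93, 0.90),   # sim - margin above the initial cut-off: capped
        (0.89, 0.87),   # noisy pair: relaxed to sim - margin
        (0.80, 0.8),    # floor case
    ])
    def test_formula(self, sim, expected):
        pair = IsotopePair(mh=None, m1h=None, similarity=sim)
        assert adaptive_cutoff(pair) == pytest.approx(expected)


class TestExtendAnnotations:
    def test_na_adduct_recognised(self):
        peaks = ion_family("s", 2.29, 611.161, adduct="Na_adduct")
        pairs = seed_isotope_pairs(peaks)
        ions = extend_annotations(pairs, peaks)
        assert "Na_adduct" in ions[0].satellites
        assert ions[0].satellites["Na_adduct"].apex_mz == pytest.approx(611.161 + 21.98194)

    def test_dissimilar_adduct_candidate_unannotated(self):
        peaks = ion_family("s", 2.29, 611.161)
        # candidate at the Na offset but with a much wider profile
        bad = gaussian_peak("s", 2.29, 611.161 + 21.98194, 3e4, sigma=0.25, peak_id=9)
        pairs = seed_isotope_pairs(peaks)
        ions = extend_annotations(pairs, peaks + [bad])
        assert "Na_adduct" not in ions[0].satellites

    def test_contested_adduct_goes_to_better_matching_mh(self):
        fam1 = ion_family("s", 2.29, 611.161, sigma=0.05, start_id=0)
        fam2 = ion_family("s", 2.30, 430.4, sigma=0.10, start_id=10)
        # one Na-adduct peak at fam1's offset, with fam1's (narrow) shape
        contested = gaussian_peak("s", 2.29, 611.161 + 21.98194, 2e4, sigma=0.05,
                                  peak_id=20)
        # also reachable from fam2? give fam2 an identical-offset target
        peaks = fam1 + fam2 + [contested]
        pairs = seed_isotope_pairs(peaks)
        ions = extend_annotations(pairs, peaks, rt_tol=0.02)
        owner = [i for i in ions if "Na_adduct" in i.satellites]
        assert len(owner) == 1
        assert owner[0].mh.apex_mz == pytest.approx(611.161)

    def test_m2_isotopologue_recognised(self):
        peaks = ion_family("s", 2.29, 611.161)
        peaks.append(gaussian_peak("s", 2.29, 611.161 + 2 * ISO_DELTA, 5e3, peak_id=9))
        pairs = seed_isotope_pairs(peaks)
        ions = extend_annotations(pairs, peaks)
        assert "M2H" in ions[0].satellites


class TestClustering:
    def test_two_shape_distinct_coeluting_metabolites_deconvoluted(self):
        # the co-elution scenario: same rt, width ratio >= 1.5
        a = ion_family("s", 2.29, 611.161, sigma=0.04, start_id=0,
                       fragments=[(465.103, 0.5), (303.050, 0.4), (129.055, 0.3)])
        b = ion_family("s", 2.29, 430.913, sigma=0.08, start_id=10,
                       fragments=[(268.860, 0.6)])
        clusters = annotate_sample(a + b)
        assert len(clusters) == 2
        sizes = sorted(len(c.member_peak_ids) for c in clusters)
        assert sizes == [3, 5]

    def test_singleton_cluster(self):
        peaks = ion_family("s", 2.29, 611.161)
        clusters = annotate_sample(peaks)
        assert len(clusters) == 1

    def test_distant_rt_never_merged(self):
        a = ion_family("s", 2.0, 611.161, sigma=0.05, start_id=0)
        b = ion_family("s", 2.5, 430.4, sigma=0.05, start_id=10)
        clusters = annotate_sample(a + b)
        assert len(clusters) == 2

    def test_fragment_orphan_admitted(self):
        peaks = ion_family("s", 2.29, 611.161,
                           fragments=[(465.103, 0.5), (303.050, 0.4)])
        clusters = annotate_sample(peaks)
        assert len(clusters) == 1
        roles = sorted(clusters[0].roles.values())
        assert roles.count("fragment") == 2

    def test_cluster_soundness_gates_hold(self):
        from plantmet.alignment import shape_similarity
        a = ion_family("s", 2.29, 611.161, sigma=0.04, start_id=0)
        b = ion_family("s", 2.29, 500.2, sigma=0.045, start_id=10)
        peaks = a + b
        clusters = annotate_sample(peaks)
        by_id = {p.peak_id: p for p in peaks}
        for cl in clusters:
            mhs = [by_id[pid] for pid, role in cl.roles.items() if role == "MH"]
            for i, p in enumerate(mhs):
                for q in mhs[i + 1:]:
                    assert abs(p.apex_rt - q.apex_rt) <= 0.02 + 1e-9
                    assert shape_similarity(p, q) >= cl.adaptive_cutoff - 0.1001


def _component_table(samples, families_per_sample):
    """Build a ComponentTable from per-sample peak families (same layout)."""
    comps = {}
    for s, peaks in families_per_sample.items():
        for p in peaks:
            key = round(p.apex_mz, 3)
            comps.setdefault(key, {})[s] = p
    components = []
    import pandas as pd

    for cid, key in enumerate(sorted(comps)):
        c = Component(cid, comps[key])
        c.recompute_means()
        components.append(c)
    heights = pd.DataFrame([[c.members[s].height if s in c.members else np.nan
                             for s in samples] for c in components],
                           index=range(len(components)), columns=samples)
    return ComponentTable(components=components, samples=samples,
                          heights=heights, areas=heights.copy())


class TestReconciliation:
    samples = ["a", "b", "c"]

    def _setup(self, correlated=True, co_cluster=True):
        families = {}
        pid = 0
        for s in self.samples:
            rt_b = 2.29 if co_cluster else 5.0
            fam_a = ion_family(s, 2.29, 611.161, sigma=0.05, start_id=pid)
            fam_b = ion_family(s, rt_b, 430.4, sigma=0.05 if not co_cluster else 0.09,
                               start_id=pid + 100)
            families[s] = fam_a + fam_b
            pid += 200
        table = _component_table(self.samples, families)
        clusters = {s: annotate_sample(ps) for s, ps in families.items()}
        # meta grouping: both metabolites share a Meta ID iff "correlated"
        if correlated:
            metas = [MetaGroup(0, [c.component_id for c in table.components])]
        else:
            a_ids = [c.component_id for c in table.components if c.mean_mz < 500]
            b_ids = [c.component_id for c in table.components if c.mean_mz >= 500]
            metas = [MetaGroup(0, b_ids), MetaGroup(1, a_ids)]
        return table, clusters, metas

    def test_and_rule_confirms_same_metabolite(self):
        table, clusters, metas = self._setup(correlated=True, co_cluster=False)
        # fam_a components share meta 0? here all share one meta but never
        # co-cluster across metabolites (rt 2.29 vs 5.0): within-metabolite
        # pairs confirm, cross pairs stay partial
        confirmed, partial = reconcile_with_screening(clusters, metas, table)
        assert len(confirmed) == 2
        kinds = {p["evidence"] for p in partial}
        assert kinds == {"meta_id_only"}

    def test_co_cluster_without_meta_is_partial_only(self):
        table, clusters, metas = self._setup(correlated=False, co_cluster=True)
        confirmed, partial = reconcile_with_screening(clusters, metas, table)
        # the two ion families co-elute but differ in shape: they never
        # co-cluster, and their metas are separate, so two metabolites
        assert len(confirmed) == 2
        for mid, cids in confirmed.items():
            mzs = [table.component_by_id(c).mean_mz for c in cids]
            assert max(mzs) - min(mzs) < 300  # families not mixed

    def test_full_confirmation_requires_both_evidences(self):
        table, clusters, metas = self._setup(correlated=True, co_cluster=False)
        confirmed, _ = reconcile_with_screening(clusters, metas, table)
        for mid, cids in confirmed.items():
            mzs = [table.component_by_id(c).mean_mz for c in cids]
            assert max(mzs) - min(mzs) < 2  # only MH + M1H together


class TestDerivedSpectrum:
    def test_entries_sorted_by_mz(self):
        families = {s: ion_family(s, 2.29, 611.161,
                                  fragments=[(465.103, 0.5), (303.050, 0.4)])
                    for s in ["a", "b"]}
        table = _component_table(["a", "b"], families)
        clusters = {s: annotate_sample(ps) for s, ps in families.items()}
        cids = [c.component_id for c in table.components]
        sp = derive_spectrum(0, cids, table, clusters)
        mzs = [e[0] for e in sp.entries]
        assert mzs == sorted(mzs)
        assert mzs[0] == pytest.approx(303.050)
        assert len(sp.entries) == 4
        roles = [e[2] for e in sp.entries]
        assert roles.count("fragment") == 2 and "MH" in roles and "M1H" in roles

    def test_single_ion_metabolite(self):
        families = {s: [gaussian_peak(s, 2.0, 301.141, peak_id=0)] for s in ["a", "b"]}
        table = _component_table(["a", "b"], families)
        sp = derive_spectrum(0, [0], table, None)
        assert len(sp.entries) == 1

    def test_absent_metabolite_errors(self):
        families = {"a": [gaussian_peak("a", 2.0, 301.141, peak_id=0)]}
        table = _component_table(["a"], families)
        table.components[0].members = {}
        with pytest.raises(ValueError):
            derive_spectrum(0, [0], table, None)
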