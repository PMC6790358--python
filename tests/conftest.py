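import numpy as np
import pytest

from plantmet.models import EICPeak, IonTrace, Run, Scan


def gaussian_trace(rts, center, sigma, height, mz=300.0, baseline=None):
    y = height * np.exp(-((rts - center) ** 2) / (2 * sigma**2))
    if baseline is not None:
        y = y + baseline
    return IonTrace(mz_center=mz, rts=np.asarray(rts, float),
                    intensities=y, member_points=[])


def gaussian_peak(sample_id, apex_rt, apex_mz, height=1e5, sigma=0.05,
                  step=0.01, n_half=20, peak_id=-1, tail=0.0):
    """An EICPeak carrying an analytic (optionally tailed) Gaussian shape."""
    rts = apex_rt + step * np.arange(-n_half, n_half + 1)
    shape = height * np.exp(-((rts - apex_rt) ** 2) / (2 * sigma**2))
    if tail > 0:
        shape = shape + 0.5 * height * np.exp(
            -((rts - apex_rt) ** 2) / (2 * (tail * sigma) ** 2)) * (rts > apex_rt)
    return EICPeak(sample_id=sample_id, apex_rt=apex_rt, apex_mz=apex_mz,
                   left_rt=rts[0], right_rt=rts[-1], height=float(shape.max()),
                   area=float(shape.sum()), shape_rts=rts, shape=shape,
                   peak_id=peak_id)


@pytest.fixture
def simple_run():
    """30-scan run: one ion at m/z 301.141 plus one noise centroid per scan."""
    rng = np.random.default_rng(42)
    scans = []
    for i in range(30):
        t = 0.02 * i
        mzs = [301.1410 + rng.normal(0, 0.001), rng.uniform(100, 600)]
        ints = [1e4, 200.0]
        order = np.argsort(mzs)
        scans.append(Scan(rt=t, mz_values=np.array(mzs)[order],
                          intensities=np.array(ints)[order]))
    return Run(sample_id="s1", scans=scans, group_label="A")


@pytest.fixture(scope="session")
def benchmark_outputs():
    """Full pipeline products on the default synthetic benchmark (seed 11).

    Session-scoped: several acceptance checks reuse the same run.
    """
    from plantmet.alignment import align_samples
    from plantmet.annotation import annotate_sample, reconcile_with_screening
    from plantmet.eic import extract_sample_peaks
    from plantmet.registration import nnc_register
    from plantmet.screening import anova_screen, assign_meta_ids
    from plantmet.simulate import GeneratorConfig, generate_dataset

    cfg = GeneratorConfig(effect_fraction=1.0)
    runs, truth = generate_dataset(cfg, seed=11)
    peaks = {r.sample_id: extract_sample_peaks(r) for r in runs}
    aligned, warps = align_samples(peaks)
    table = nnc_register([p for ps in aligned.values() for p in ps])
    results = anova_screen(table, truth.groups, alpha=0.05)
    metas = assign_meta_ids(results, table)
    clusters = {sid: annotate_sample(ps) for sid, ps in aligned.items()}
    confirmed, partial = reconcile_with_screening(clusters, metas, table)
    return dict(runs=runs, truth=truth, peaks=peaks, aligned=aligned, warps=warps,
                table=table, results=results, metas=metas, clusters=clusters,
                confirmed=confirmed, partial=partial)
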