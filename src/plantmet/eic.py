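"""EIC construction, baseline correction and scale-space peak detection.

EICs are built by ion-density clustering in m/z: ions of one metabolite hit
nearly identical m/z in consecutive scans, so within a small tolerance
(default 0.01 Da) their density along the m/z axis exceeds any background
noise. Realised as 1-D clustering: pool every centroid of the run, sort by
m/z, split at gaps wider than the tolerance, and keep clusters with enough
members to be a real trace.

Baseline drift is removed by a local-minimum method: window minima of the
trace are connected by linear interpolation and subtracted, twice.

Peaks are detected in Gaussian scale space: the trace is smoothed at
successively larger scales and ridge lines (maxima persisting across
scales) are followed; ridges long enough and with sufficient
signal-to-noise become peaks, quantified by apex height and by summed
response over the elution window.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .models import EICPeak, IonTrace, Run


def build_eics(run: Run, mz_tol: float = 0.01, min_points: int | None = None) -> list[IonTrace]:
    """Cluster all centroids of a run into ion traces by m/z density.

    Pool every centroid, sort by m/z, split where the gap between
    neighbouring centroids exceeds ``mz_tol``, and discard clusters with
    fewer than ``min_points`` members (default: 1% of the scan count,
    floor 5 — a chromatographic peak a few seconds wide must survive, a
    stray background ion must not). Surviving clusters wider than 2*mz_tol
    are re-split at their largest internal gaps so each trace stays within
    tolerance of its centre.
    """
    n_scans = len(run.scans)
    if n_scans == 0:
        return []
    if min_points is None:
        min_points = max(5, int(0.01 * n_scans))

    scan_idx = []
    mzs = []
    intens = []
    for i, sc in enumerate(run.scans):
        scan_idx.append(np.full(sc.mz_values.size, i))
        mzs.append(sc.mz_values)
        intens.append(sc.intensities)
    if not mzs:
        return []
    scan_idx = np.concatenate(scan_idx)
    mzs = np.concatenate(mzs)
    intens = np.concatenate(intens)
    if mzs.size == 0:
        return []

    order = np.argsort(mzs, kind="stable")
    mzs, intens, scan_idx = mzs[order], intens[order], scan_idx[order]

    # split at m/z gaps > mz_tol
    gaps = np.diff(mzs)
    boundaries = np.flatnonzero(gaps > mz_tol) + 1
    clusters = np.split(np.arange(mzs.size), boundaries)

    rts = run.rts
    traces: list[IonTrace] = []

    def _emit(idx: np.ndarray) -> None:
        if idx.size < min_points:
            return
        span = mzs[idx[-1]] - mzs[idx[0]]
        if span > 2 * mz_tol and idx.size >= 2 * min_points:
            g = np.diff(mzs[idx])
            cut = int(np.argmax(g)) + 1
            if g[cut - 1] > 0:
                _emit(idx[:cut])
                _emit(idx[cut:])
                return
        w = intens[idx]
        total = w.sum()
        mz_center = float(np.average(mzs[idx], weights=w) if total > 0 else mzs[idx].mean())
        profile = np.zeros(n_scans)
        np.add.at(profile, scan_idx[idx].astype(int), intens[idx])
        members = [(int(scan_idx[j]), float(mzs[j]), float(intens[j])) for j in idx]
        traces.append(IonTrace(mz_center=mz_center, rts=rts.copy(),
                               intensities=profile, member_points=members))

    for cl in clusters:
        _emit(cl)
    traces.sort(key=lambda t: t.mz_center)
    return traces


def correct_baseline(trace: IonTrace, window_min: float = 2.0, n_iter: int = 2) -> IonTrace:
    """Subtract a local-minimum baseline from a trace.

    The rt axis is tiled with windows of ``window_min`` minutes; the
    minimum point in each window becomes a baseline node, nodes are joined
    by linear interpolation, and the interpolant is subtracted (negative
    residues clipped at 0). Two passes by default. A flat trace maps to
    all-zero; a clean peak on a zero baseline is essentially unchanged.
    """
    rts = trace.rts
    y = trace.intensities.astype(float).copy()
    if y.size < 3:
        return IonTrace(trace.mz_center, rts, np.clip(y - y.min(), 0, None),
                        trace.member_points, trace.scan_offset)
    for _ in range(n_iter):
        edges = np.arange(rts[0], rts[-1] + window_min, window_min)
        node_rt, node_y = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (rts >= lo) & (rts < hi) if hi < edges[-1] else (rts >= lo) & (rts <= hi)
            if not sel.any():
                continue
            j = np.flatnonzero(sel)[np.argmin(y[sel])]
            node_rt.append(rts[j])
            node_y.append(y[j])
        if len(node_rt) < 2:
            base = np.full_like(y, min(node_y) if node_y else y.min())
        else:
            base = np.interp(rts, node_rt, node_y)
        y = np.clip(y - base, 0.0, None)
    return IonTrace(trace.mz_center, rts, y, trace.member_points, trace.scan_offset)


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (plateau: leftmost point)."""
    if y.size < 3:
        return np.array([], dtype=int)
    out = []
    i = 1
    n = y.size
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[j]:
                j += 1
            if j < n - 1 and y[j + 1] < y[j]:
                out.append(i)
                i = j + 1
                continue
        i += 1
    return np.asarray(out, dtype=int)


def _mad_noise(y: np.ndarray) -> float:
    """Robust noise scale from the median absolute deviation."""
    med = np.median(y)
    return float(1.4826 * np.median(np.abs(y - med)))


def detect_peaks(trace: IonTrace,
                 sigmas: tuple[float, ...] = tuple(range(1, 11)),
                 min_ridge_length: int = 3,
                 min_snr: float = 3.0,
                 sample_id: str = "") -> list[EICPeak]:
    """Scale-space ridge-line peak detection on a baseline-corrected trace.

    The trace is smoothed with Gaussian kernels of each sigma (in scan
    steps, ascending). Ridges start at maxima of the smallest scale and are
    linked across successive scales to the nearest maximum within
    +-(sigma+2) steps. A ridge is accepted when it persists for at least
    ``min_ridge_length`` scales and its apex SNR (apex height over the
    MAD-derived noise of the trace's non-peak region) reaches ``min_snr``.
    Apex is the ridge position at the smallest scale; boundaries are the
    nearest flanking local minima of the lightly smoothed trace.
    """
    y = trace.intensities.astype(float)
    rts = trace.rts
    n = y.size
    if n < 3 or not np.any(y > 0):
        return []
    sigmas = sorted(sigmas)
    smoothed = [gaussian_filter1d(y, s, mode="nearest") for s in sigmas]
    maxima = [_local_maxima(sm) for sm in smoothed]

    # ridge linking, smallest scale outward
    ridges: list[list[int]] = [[m] for m in maxima[0]]
    active = list(range(len(ridges)))
    for level in range(1, len(sigmas)):
        win = sigmas[level] + 2
        cand = maxima[level]
        next_active = []
        used = set()
        for ridx in active:
            pos = ridges[ridx][-1]
            if cand.size == 0:
                continue
            d = np.abs(cand - pos)
            k = int(np.argmin(d))
            if d[k] <= win and k not in used:
                ridges[ridx].append(int(cand[k]))
                used.add(k)
                next_active.append(ridx)
        active = next_active

    light = smoothed[0]
    accepted: dict[int, tuple[int, float, int]] = {}  # apex -> (len, height, top_level)
    for ridge in ridges:
        if len(ridge) < min_ridge_length:
            continue
        # refine apex: local max of lightly smoothed trace near the
        # smallest-scale ridge position
        a = ridge[0]
        lo = max(0, a - int(sigmas[0]) - 2)
        hi = min(n, a + int(sigmas[0]) + 3)
        a = lo + int(np.argmax(light[lo:hi]))
        prev = accepted.get(a)
        if prev is None or (len(ridge), y[a]) > (prev[0], prev[1]):
            accepted[a] = (len(ridge), float(y[a]), len(ridge) - 1)

    if not accepted:
        return []

    # boundaries: walk downhill to the nearest flanking local minima of the
    # lightly smoothed trace
    def _bounds(a: int) -> tuple[int, int]:
        l = a
        while l > 0 and light[l - 1] < light[l]:
            l -= 1
        r = a
        while r < n - 1 and light[r + 1] < light[r]:
            r += 1
        return l, r

    # noise from non-peak region
    mask = np.ones(n, bool)
    bounds = {}
    for a in accepted:
        l, r = _bounds(a)
        bounds[a] = (l, r)
        mask[max(0, l):min(n, r + 1)] = False
    noise_region = y[mask]
    noise = _mad_noise(noise_region) if noise_region.size >= 5 else 0.0
    if noise <= 0:
        noise = 1e-12  # noiseless trace: SNR gate passes trivially

    peaks: list[EICPeak] = []
    for a, (_, h, top) in accepted.items():
        l, r = bounds[a]
        if r - l < 2 or h <= 0:
            continue
        # SNR measured on the ridge's largest-scale smoothing: genuine
        # peaks survive heavy smoothing, noise bumps collapse into the
        # smoothed background
        sm = smoothed[top]
        bg = float(np.median(sm[mask])) if mask.any() else 0.0
        if (sm[a] - bg) / noise < min_snr:
            continue
        apex_mz = trace.mz_center
        best = None
        for si, mz, _inten in trace.member_points:
            d = abs(si - trace.scan_offset - a)
            if best is None or d < best[0]:
                best = (d, mz)
        if best is not None and best[0] <= 1:
            apex_mz = best[1]
        shape = y[l:r + 1].copy()
        peaks.append(EICPeak(
            sample_id=sample_id,
            apex_rt=float(rts[a]),
            apex_mz=float(apex_mz),
            left_rt=float(rts[l]),
            right_rt=float(rts[r]),
            height=float(y[a]),
            area=float(shape.sum()),
            shape_rts=rts[l:r + 1].copy(),
            shape=shape,
            trace_ref=trace.scan_offset,
        ))
    peaks.sort(key=lambda p: p.apex_rt)
    return peaks


def extract_sample_peaks(run: Run,
                         mz_tol: float = 0.01,
                         min_points: int | None = None,
                         baseline_window_min: float = 2.0,
                         sigmas: tuple[float, ...] = tuple(range(1, 11)),
                         min_ridge_length: int = 3,
                         min_snr: float = 3.0) -> list[EICPeak]:
    """Full per-sample extraction: build EICs, correct baselines, detect peaks.

    Returns the sample's EIC peak list (each peak marked by apex m/z and rt),
    sorted by (apex_rt, apex_mz), with stable per-sample peak ids.
    """
    peaks: list[EICPeak] = []
    for ti, trace in enumerate(build_eics(run, mz_tol=mz_tol, min_points=min_points)):
        corrected = correct_baseline(trace, window_min=baseline_window_min)
        for p in detect_peaks(corrected, sigmas=sigmas, min_ridge_length=min_ridge_length,
                              min_snr=min_snr, sample_id=run.sample_id):
            p.trace_ref = ti
            peaks.append(p)
    peaks.sort(key=lambda p: (p.apex_rt, p.apex_mz))
    for i, p in enumerate(peaks):
        p.peak_id = i
    return peaks
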