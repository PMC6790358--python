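"""Retention-time shift correction against an automatically chosen reference.

The sample with the most detected peaks becomes the reference. For each
test sample a similarity matrix is built over (reference peak, test peak)
pairs that satisfy the m/z (0.01 Da) and rt (0.5 min) search tolerances;
similarity is the Pearson correlation of the two peaks' elution profiles
resampled onto a common relative-time grid. Dynamic programming finds the
monotone matching maximising accumulated similarity; matched pairs become
anchors of a piecewise-linear warp of the test sample's rt axis onto the
reference's.
"""
from __future__ import annotations

import copy
import logging

import numpy as np

from .models import EICPeak

logger = logging.getLogger(__name__)

INVALID = np.nan


def select_reference(samples: dict[str, list[EICPeak]]) -> str:
    """Sample with the greatest total peak count; ties by lexicographic id."""
    if len(samples) < 2:
        raise ValueError("need >= 2 samples to align")
    return max(sorted(samples), key=lambda s: len(samples[s]))


def _resample_shape(p: EICPeak, n_points: int = 50) -> np.ndarray:
    """Peak shape resampled to ``n_points`` over +-2 half-widths of its apex."""
    hw = max(p.half_width, 1e-6)
    grid = np.linspace(-2 * hw, 2 * hw, n_points)
    return np.interp(grid + p.apex_rt, p.shape_rts, p.shape, left=0.0, right=0.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 for degenerate (constant) vectors."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _shape_corr(p: EICPeak, q: EICPeak, n_points: int) -> float:
    # a degenerate (constant) raw shape carries no elution information
    if np.ptp(p.shape) == 0 or np.ptp(q.shape) == 0:
        return 0.0
    return _pearson(_resample_shape(p, n_points), _resample_shape(q, n_points))


def peak_similarity(p: EICPeak, q: EICPeak,
                    mz_tol: float = 0.01, rt_tol: float = 0.5,
                    n_points: int = 50) -> float:
    """Shape similarity of two peaks, or NaN when outside the search gates."""
    if abs(p.apex_mz - q.apex_mz) > mz_tol or abs(p.apex_rt - q.apex_rt) > rt_tol:
        return INVALID
    return _shape_corr(p, q, n_points)


def shape_similarity(p: EICPeak, q: EICPeak, n_points: int = 50) -> float:
    """Pearson shape similarity without m/z or rt gates (annotation use)."""
    return _shape_corr(p, q, n_points)


def build_similarity_matrix(ref_peaks: list[EICPeak], test_peaks: list[EICPeak],
                            mz_tol: float = 0.01, rt_tol: float = 0.5,
                            n_points: int = 50) -> np.ndarray:
    """(ref x test) Pearson similarity matrix; disallowed pairs are NaN.

    Rows and columns follow the rt order of the supplied peak lists.
    """
    S = np.full((len(ref_peaks), len(test_peaks)), INVALID)
    for i, p in enumerate(ref_peaks):
        for j, q in enumerate(test_peaks):
            if abs(p.apex_mz - q.apex_mz) <= mz_tol and abs(p.apex_rt - q.apex_rt) <= rt_tol:
                S[i, j] = _shape_corr(p, q, n_points)
    return S


def align_dp(S: np.ndarray, min_match: float = 0.5) -> list[tuple[int, int]]:
    """Monotone matching maximising accumulated similarity.

    Standard global-alignment DP over the rt-ordered row/column sequences:
    matching a valid pair gains its similarity, leaving a row or column
    unmatched gains 0; NaN pairs cannot match. Returns matched (row, col)
    pairs, strictly increasing in both indices, with pairs below
    ``min_match`` dropped from the returned anchors.
    """
    n, m = S.shape
    if n == 0 or m == 0:
        return []
    score = np.zeros((n + 1, m + 1))
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0: skip-row, 1: skip-col, 2: match
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = score[i - 1, j]
            mv = 0
            if score[i, j - 1] > best:
                best, mv = score[i, j - 1], 1
            s = S[i - 1, j - 1]
            if not np.isnan(s) and score[i - 1, j - 1] + s > best:
                best, mv = score[i - 1, j - 1] + s, 2
            score[i, j], move[i, j] = best, mv
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        mv = move[i, j]
        if mv == 2:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif mv == 1:
            j -= 1
        else:
            i -= 1
    pairs.reverse()
    return [(i, j) for i, j in pairs if S[i, j] >= min_match]


def dp_score(S: np.ndarray) -> float:
    """Optimal accumulated-similarity score of the monotone matching."""
    n, m = S.shape
    score = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(score[i - 1, j], score[i, j - 1])
            s = S[i - 1, j - 1]
            if not np.isnan(s):
                best = max(best, score[i - 1, j - 1] + s)
            score[i, j] = best
    return float(score[n, m])


class WarpFunction:
    """Piecewise-linear monotone map from test rt to reference rt.

    Inside the anchor range the map interpolates the anchors exactly;
    outside it, the shift at the nearest anchor is held constant (identity
    offset continuation). With no anchors the map is the identity.
    """

    def __init__(self, test_rts: np.ndarray, ref_rts: np.ndarray):
        self.test_rts = np.asarray(test_rts, dtype=float)
        self.ref_rts = np.asarray(ref_rts, dtype=float)

    def __call__(self, rt):
        rt = np.asarray(rt, dtype=float)
        scalar = rt.ndim == 0
        rt = np.atleast_1d(rt)
        if self.test_rts.size == 0:
            out = rt.copy()
        else:
            shift = self.ref_rts - self.test_rts
            out = rt + np.interp(rt, self.test_rts, shift)
        return float(out[0]) if scalar else out

    @property
    def n_anchors(self) -> int:
        return int(self.test_rts.size)


def fit_warp(anchors: list[tuple[float, float, float]]) -> WarpFunction:
    """Fit a warp from (test_rt, ref_rt, similarity) anchor triples.

    Anchors are sorted by test rt; any pair inverted on the reference axis
    is resolved by dropping the lower-similarity anchor, so the result is
    strictly monotone.
    """
    if not anchors:
        return WarpFunction(np.array([]), np.array([]))
    kept = sorted(anchors, key=lambda a: a[0])
    changed = True
    while changed and len(kept) > 1:
        changed = False
        for k in range(len(kept) - 1):
            a, b = kept[k], kept[k + 1]
            if b[0] <= a[0] or b[1] <= a[1]:  # inverted or duplicated pair
                kept.pop(k if a[2] < b[2] else k + 1)
                changed = True
                break
    t = np.array([a[0] for a in kept])
    r = np.array([a[1] for a in kept])
    return WarpFunction(t, r)


def align_sample(ref_peaks: list[EICPeak], test_peaks: list[EICPeak],
                 mz_tol: float = 0.01, rt_tol: float = 0.5,
                 min_match: float = 0.5, n_points: int = 50) -> tuple[list[EICPeak], WarpFunction]:
    """Warp one test sample's peaks onto the reference rt axis."""
    ref_sorted = sorted(ref_peaks, key=lambda p: (p.apex_rt, p.apex_mz))
    test_sorted = sorted(test_peaks, key=lambda p: (p.apex_rt, p.apex_mz))
    S = build_similarity_matrix(ref_sorted, test_sorted, mz_tol, rt_tol, n_points)
    pairs = align_dp(S, min_match=min_match)
    anchors = [(test_sorted[j].apex_rt, ref_sorted[i].apex_rt, S[i, j]) for i, j in pairs]
    warp = fit_warp(anchors)
    if warp.n_anchors == 0:
        logger.warning("no alignment anchors found; applying identity warp")
    out = []
    for p in test_peaks:
        q = copy.copy(p)
        q.apex_rt = warp(p.apex_rt)
        q.left_rt = warp(p.left_rt)
        q.right_rt = warp(p.right_rt)
        q.shape_rts = warp(p.shape_rts)
        out.append(q)
    return out, warp


def align_samples(samples: dict[str, list[EICPeak]], reference_id: str | None = None,
                  mz_tol: float = 0.01, rt_tol: float = 0.5,
                  min_match: float = 0.5, n_points: int = 50
                  ) -> tuple[dict[str, list[EICPeak]], dict[str, WarpFunction]]:
    """Align every sample's peak list to the reference; reference unchanged."""
    if reference_id is None:
        reference_id = select_reference(samples)
    ref_peaks = samples[reference_id]
    aligned: dict[str, list[EICPeak]] = {}
    warps: dict[str, WarpFunction] = {}
    for sid, peaks in samples.items():
        if sid == reference_id:
            aligned[sid] = peaks
            warps[sid] = WarpFunction(np.array([]), np.array([]))
        else:
            aligned[sid], warps[sid] = align_sample(
                ref_peaks, peaks, mz_tol, rt_tol, min_match, n_points)
    return aligned, warps
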