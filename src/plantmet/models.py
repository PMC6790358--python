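"""Core domain types shared by all pipeline stages.

Units are fixed package-wide: retention times in minutes, m/z in Da,
intensities in arbitrary detector counts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class Scan:
    """One centroided MS1 spectrum acquired at a retention time.

    ``mz_values`` must be strictly increasing; ``intensities`` is the same
    length and non-negative.
    """

    rt: float
    mz_values: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz_values.shape != self.intensities.shape:
            raise ValueError("mz_values and intensities must have equal length")
        if self.rt < 0:
            raise ValueError(f"negative retention time: {self.rt}")
        if self.mz_values.size > 1 and not np.all(np.diff(self.mz_values) > 0):
            order = np.argsort(self.mz_values, kind="stable")
            self.mz_values = self.mz_values[order]
            self.intensities = self.intensities[order]
        if np.any(self.intensities < 0):
            raise ValueError("negative intensity in scan")


@dataclass
class Run:
    """A single sample's acquisition: rt-ordered centroid scans."""

    sample_id: str
    scans: list[Scan]
    group_label: str = ""

    def __post_init__(self) -> None:
        self.scans = sorted(self.scans, key=lambda s: s.rt)

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    def validate(self) -> None:
        if len(self.scans) < 2:
            raise ValueError(f"run {self.sample_id!r} has < 2 scans")
        if not np.all(np.diff(self.rts) > 0):
            raise ValueError(f"run {self.sample_id!r} scan rts not strictly increasing")


@dataclass
class IonTrace:
    """Extracted ion chromatogram: one narrow-m/z ion over the run's scan grid.

    ``intensities[i]`` is 0 on scans where the trace has no member centroid,
    so the trace is defined on a contiguous rt window.
    """

    mz_center: float
    rts: np.ndarray
    intensities: np.ndarray
    member_points: list[tuple[int, float, float]]  # (scan_index, mz, intensity)
    scan_offset: int = 0  # run scan index of rts[0]

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)


@dataclass
class EICPeak:
    """One detected chromatographic peak, characterised by its apex."""

    sample_id: str
    apex_rt: float
    apex_mz: float
    left_rt: float
    right_rt: float
    height: float
    area: float
    shape_rts: np.ndarray  # rt support of the shape vector (minutes)
    shape: np.ndarray  # baseline-corrected intensities on shape_rts
    trace_ref: int = -1
    peak_id: int = -1

    def __post_init__(self) -> None:
        self.shape_rts = np.asarray(self.shape_rts, dtype=float)
        self.shape = np.asarray(self.shape, dtype=float)

    @property
    def half_width(self) -> float:
        return max(self.apex_rt - self.left_rt, self.right_rt - self.apex_rt)


@dataclass
class Component:
    """Cross-sample registered ion: at most one EIC peak per sample."""

    component_id: int
    members: dict[str, EICPeak]
    mean_mz: float = 0.0
    mean_rt: float = 0.0

    def recompute_means(self) -> None:
        self.mean_mz = float(np.mean([p.apex_mz for p in self.members.values()]))
        self.mean_rt = float(np.mean([p.apex_rt for p in self.members.values()]))


@dataclass
class ComponentTable:
    """Registered components x samples quantification matrices.

    Heights/areas hold NaN where a component was not detected in a sample
    (missing, distinct from zero).
    """

    components: list[Component]
    samples: list[str]
    heights: "object" = None  # pandas DataFrame, set by builder
    areas: "object" = None

    def component_by_id(self, cid: int) -> Component:
        for c in self.components:
            if c.component_id == cid:
                return c
        raise KeyError(cid)


@dataclass
class ScreenResult:
    component_id: int
    f_statistic: float
    p_value: float
    significant: bool
    testable: bool = True


@dataclass
class MetaGroup:
    meta_id: int
    member_component_ids: list[int]
    pairwise_correlations: Optional[np.ndarray] = None


@dataclass
class IonAnnotation:
    peak_ref: int  # EICPeak.peak_id
    role: str  # MH | M1H | M2H | M3H | Na_adduct | K_adduct | NH4_adduct | fragment | unknown
    metabolite_id: int = -1


@dataclass
class IonCluster:
    cluster_id: int
    member_peak_ids: list[int]
    roles: dict[int, str]
    apex_rt: float
    adaptive_cutoff: float


@dataclass
class DerivedSpectrum:
    metabolite_id: int
    entries: list[tuple[float, float, str]]  # (mz, intensity, role), mz-ascending
    source_sample: str = ""

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e[0])
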