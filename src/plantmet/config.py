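"""Pipeline configuration: every stage tolerance in one validated object."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    # inputs
    input_files: list[str] = field(default_factory=list)
    group_map: dict[str, str] = field(default_factory=dict)  # sample -> group
    output_dir: str = "plantmet_out"
    seed: int = 0

    # eic_extraction
    mz_tol: float = 0.01            # Da, EIC density-clustering tolerance
    min_points: int | None = None   # trace size filter; None = 1% of scans, floor 5
    baseline_window_min: float = 2.0
    sigmas: list[float] = field(default_factory=lambda: list(range(1, 11)))
    min_ridge_length: int = 3
    min_snr: float = 3.0

    # time_alignment
    align_mz_tol: float = 0.01
    align_rt_tol: float = 0.5
    min_match: float = 0.5
    resample_points: int = 50

    # peak_registration
    reg_mz_tol: float = 0.01
    reg_rt_tol: float = 0.1

    # peak_screening
    alpha: float = 0.05
    corr_threshold: float = 0.9
    mcd_support: float = 0.75
    coelution_rt_tol: float = 0.1
    response: str = "height"        # height | area
    p_adjust: str = "none"          # none | BH

    # ion_annotation
    shape_cutoff0: float = 0.9
    anno_rt_tol: float = 0.02
    iso_mz_tol: float = 0.005
    margin: float = 0.02
    cutoff_floor: float = 0.8
    min_votes: int | None = None    # None = majority of samples
    adduct_table: dict[str, float] | None = None

    def validate(self) -> list[str]:
        """Return every validation problem (empty list = valid)."""
        errs = []
        for name in ("mz_tol", "baseline_window_min", "min_snr", "align_mz_tol",
                     "align_rt_tol", "reg_mz_tol", "reg_rt_tol", "coelution_rt_tol",
                     "anno_rt_tol", "iso_mz_tol"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("alpha", "corr_threshold", "mcd_support", "min_match",
                     "shape_cutoff0", "cutoff_floor"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                errs.append(f"{name} must be in (0, 1], got {v}")
        if self.response not in ("height", "area"):
            errs.append(f"response must be 'height' or 'area', got {self.response!r}")
        if self.p_adjust not in ("none", "BH"):
            errs.append(f"p_adjust must be 'none' or 'BH', got {self.p_adjust!r}")
        return errs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        import yaml

        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path
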