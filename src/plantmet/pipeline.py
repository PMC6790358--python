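"""Five-stage pipeline orchestration with cached, inspectable intermediates.

Stages: extract -> align -> register -> screen -> annotate. Every stage
writes its result as TSV/JSON into the output directory; a rerun with an
unchanged config and inputs reuses cached intermediates. All randomness
(the MCD subset search) is seeded from the config.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .alignment import align_samples
from .annotation import annotate_sample, derive_spectrum, reconcile_with_screening
from .config import PipelineConfig
from .eic import extract_sample_peaks
from .models import EICPeak, Run
from .registration import nnc_register
from .screening import anova_screen, assign_meta_ids

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    for f in cfg.input_files:
        p = Path(f)
        if p.exists():
            payload += hashlib.sha256(p.read_bytes()).digest()
    return hashlib.sha256(payload).hexdigest()[:16]


def _peaks_to_records(peaks: list[EICPeak]) -> list[dict]:
    return [
        {
            "peak_id": p.peak_id, "sample_id": p.sample_id,
            "apex_rt": p.apex_rt, "apex_mz": p.apex_mz,
            "left_rt": p.left_rt, "right_rt": p.right_rt,
            "height": p.height, "area": p.area, "trace_ref": p.trace_ref,
            "shape_rts": [round(float(x), 6) for x in p.shape_rts],
            "shape": [round(float(x), 3) for x in p.shape],
        }
        for p in peaks
    ]


def _peaks_from_records(recs: list[dict]) -> list[EICPeak]:
    return [
        EICPeak(sample_id=r["sample_id"], apex_rt=r["apex_rt"], apex_mz=r["apex_mz"],
                left_rt=r["left_rt"], right_rt=r["right_rt"], height=r["height"],
                area=r["area"], shape_rts=np.asarray(r["shape_rts"]),
                shape=np.asarray(r["shape"]), trace_ref=r["trace_ref"],
                peak_id=r["peak_id"])
        for r in recs
    ]


def save_peaks(peaks_by_sample: dict[str, list[EICPeak]], path: Path) -> None:
    path.write_text(json.dumps({s: _peaks_to_records(ps) for s, ps in peaks_by_sample.items()}))


def load_peaks(path: Path) -> dict[str, list[EICPeak]]:
    data = json.loads(path.read_text())
    return {s: _peaks_from_records(recs) for s, recs in data.items()}


def peaks_tsv(peaks_by_sample: dict[str, list[EICPeak]], path: Path) -> None:
    rows = [{"sample_id": p.sample_id, "peak_id": p.peak_id,
             "apex_mz": round(p.apex_mz, 5), "apex_rt": round(p.apex_rt, 4),
             "left_rt": round(p.left_rt, 4), "right_rt": round(p.right_rt, 4),
             "height": round(p.height, 1), "area": round(p.area, 1)}
            for ps in peaks_by_sample.values() for p in ps]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class Pipeline:
    """Runs the five stages over the configured input files."""

    def __init__(self, config: PipelineConfig, runs: list[Run] | None = None):
        errs = config.validate()
        if errs:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errs))
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._runs = runs
        self._hash = None if runs is not None else _config_hash(config)

    # -- caching ----------------------------------------------------------
    def _cached(self, name: str) -> Path | None:
        if self._hash is None:
            return None
        p = self.out / name
        stamp = self.out / f"{name}.hash"
        if p.exists() and stamp.exists() and stamp.read_text() == self._hash:
            return p
        return None

    def _stamp(self, name: str) -> None:
        if self._hash is not None:
            (self.out / f"{name}.hash").write_text(self._hash)

    # -- stages -----------------------------------------------------------
    def load_runs(self) -> list[Run]:
        if self._runs is not None:
            return self._runs
        runs = []
        seen_groups = self.cfg.group_map
        for f in self.cfg.input_files:
            sid = Path(f).stem
            try:
                runs.append(msio.read_run(f, sample_id=sid,
                                          group_label=seen_groups.get(sid, "")))
            except msio.MSFileError as exc:
                raise StageError("extract", f"sample {sid}: {exc}") from exc
        self._runs = runs
        return runs

    def extract(self) -> dict[str, list[EICPeak]]:
        cached = self._cached("peaks_extracted.json")
        if cached:
            logger.info("extract: using cached %s", cached)
            return load_peaks(cached)
        cfg = self.cfg
        peaks = {}
        for run in self.load_runs():
            try:
                peaks[run.sample_id] = extract_sample_peaks(
                    run, mz_tol=cfg.mz_tol, min_points=cfg.min_points,
                    baseline_window_min=cfg.baseline_window_min,
                    sigmas=tuple(cfg.sigmas), min_ridge_length=cfg.min_ridge_length,
                    min_snr=cfg.min_snr)
            except Exception as exc:
                raise StageError("extract", f"sample {run.sample_id}: {exc}") from exc
            logger.info("extract: %s -> %d peaks", run.sample_id, len(peaks[run.sample_id]))
        save_peaks(peaks, self.out / "peaks_extracted.json")
        peaks_tsv(peaks, self.out / "peaks_extracted.tsv")
        self._stamp("peaks_extracted.json")
        return peaks

    def align(self, peaks: dict[str, list[EICPeak]]) -> dict[str, list[EICPeak]]:
        cached = self._cached("peaks_aligned.json")
        if cached:
            logger.info("align: using cached %s", cached)
            return load_peaks(cached)
        cfg = self.cfg
        if len(peaks) < 2:
            raise StageError("align", "need >= 2 samples")
        aligned, warps = align_samples(peaks, mz_tol=cfg.align_mz_tol,
                                       rt_tol=cfg.align_rt_tol, min_match=cfg.min_match,
                                       n_points=cfg.resample_points)
        anchor_rows = [{"sample_id": s, "test_rt": round(t, 4), "ref_rt": round(r, 4)}
                       for s, w in warps.items()
                       for t, r in zip(w.test_rts, w.ref_rts)]
        pd.DataFrame(anchor_rows, columns=["sample_id", "test_rt", "ref_rt"]).to_csv(
            self.out / "alignment_anchors.tsv", sep="\t", index=False)
        for s, w in warps.items():
            logger.info("align: %s -> %d anchors", s, w.n_anchors)
        save_peaks(aligned, self.out / "peaks_aligned.json")
        self._stamp("peaks_aligned.json")
        return aligned

    def register(self, aligned: dict[str, list[EICPeak]]):
        cfg = self.cfg
        all_peaks = [p for ps in aligned.values() for p in ps]
        table = nnc_register(all_peaks, mz_tol=cfg.reg_mz_tol, rt_tol=cfg.reg_rt_tol)
        logger.info("register: %d peaks -> %d components", len(all_peaks), len(table.components))
        msio.write_component_table(table, self.out / "component_table.tsv")
        return table

    def screen(self, table):
        cfg = self.cfg
        groups = {s: self.cfg.group_map.get(s, "") for s in table.samples}
        if len({g for g in groups.values() if g}) < 2:
            raise StageError("screen", "need >= 2 sample groups")
        results = anova_screen(table, groups, alpha=cfg.alpha,
                               response=cfg.response, p_adjust=cfg.p_adjust)
        metas = assign_meta_ids(results, table, corr_threshold=cfg.corr_threshold,
                                coelution_rt_tol=cfg.coelution_rt_tol,
                                mcd_support=cfg.mcd_support, response=cfg.response,
                                random_state=cfg.seed)
        n_sig = sum(r.significant for r in results)
        logger.info("screen: %d significant of %d testable; %d Meta groups",
                    n_sig, sum(r.testable for r in results), len(metas))
        meta_of = {c: m.meta_id for m in metas for c in m.member_component_ids}
        rows = [{"component_id": r.component_id, "F": r.f_statistic, "p": r.p_value,
                 "significant": r.significant, "testable": r.testable,
                 "meta_id": meta_of.get(r.component_id, "")}
                for r in results]
        pd.DataFrame(rows).to_csv(self.out / "screening.tsv", sep="\t", index=False)
        return results, metas

    def annotate(self, aligned, table, metas):
        cfg = self.cfg
        clusters = {}
        for sid, ps in aligned.items():
            clusters[sid] = annotate_sample(
                ps, shape_cutoff0=cfg.shape_cutoff0, rt_tol=cfg.anno_rt_tol,
                iso_mz_tol=cfg.iso_mz_tol, margin=cfg.margin,
                cutoff_floor=cfg.cutoff_floor, adduct_table=cfg.adduct_table)
            logger.info("annotate: %s -> %d ion clusters", sid, len(clusters[sid]))
        confirmed, partial = reconcile_with_screening(clusters, metas, table,
                                                      min_votes=cfg.min_votes)
        logger.info("annotate: %d confirmed metabolites, %d partial-evidence pairs",
                    len(confirmed), len(partial))
        spectra = []
        for mid, cids in confirmed.items():
            try:
                spectra.append(derive_spectrum(mid, cids, table, clusters))
            except ValueError:
                continue
        msio.write_msp(spectra, self.out / "derived_spectra.msp")
        (self.out / "partial_evidence.json").write_text(json.dumps(partial, indent=1))

        meta_of = {c: m.meta_id for m in metas for c in m.member_component_ids}
        met_of = {c: mid for mid, cids in confirmed.items() for c in cids}
        extra = pd.DataFrame({
            "meta_id": {c.component_id: meta_of.get(c.component_id, np.nan) for c in table.components},
            "metabolite_id": {c.component_id: met_of.get(c.component_id, np.nan) for c in table.components},
        })
        msio.write_component_table(table, self.out / "component_table_annotated.tsv",
                                   extra_columns=extra)
        return clusters, confirmed, partial, spectra

    def run(self):
        """Execute all five stages; returns the pipeline products."""
        peaks = self.extract()
        aligned = self.align(peaks)
        table = self.register(aligned)
        results, metas = self.screen(table)
        clusters, confirmed, partial, spectra = self.annotate(aligned, table, metas)
        return {
            "peaks": peaks, "aligned": aligned, "table": table,
            "screen_results": results, "metas": metas, "clusters": clusters,
            "confirmed": confirmed, "partial": partial, "spectra": spectra,
        }


def run_pipeline(config: PipelineConfig, runs: list[Run] | None = None):
    """Convenience wrapper: build a :class:`Pipeline` and run it."""
    return Pipeline(config, runs=runs).run()
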