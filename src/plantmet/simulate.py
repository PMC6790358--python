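"""Synthetic centroided UPLC-HRMS runs with full ground truth.

Each simulated metabolite emits an [M+H]+ ion, its 13C isotopologues with
binomial carbon-count ratios, optionally an adduct (Na+/K+/NH4+) and
in-source fragments — all sharing one Gaussian (optionally
exponentially-tailed) elution profile per sample. Samples carry smooth
monotone rt warps, per-ion lognormal abundance noise, centroid m/z jitter,
low-intensity noise ions and optional column-bleed traces. Between-group
abundance effects are injected into a configurable fraction of
metabolites. Everything is deterministic given the seed, and the generator
records the ground truth needed to score every pipeline stage.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import DEFAULT_ADDUCTS, ISO_DELTA
from .models import Run, Scan

FRAGMENT_LOSSES = [146.05791, 162.05282, 308.11073]  # deoxyhexose, hexose, rutinose


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark."""

    n_groups: int = 2
    samples_per_group: int = 3
    n_metabolites: int = 20
    effect_fraction: float = 0.3   # fraction of metabolites with a group effect
    effect_size: float = 4.0       # multiplicative between-group effect
    rt_start: float = 1.0          # minutes
    rt_end: float = 10.0
    scan_interval: float = 0.02    # minutes; ~0.8 s/scan, typical UPLC MS1 rate
    peak_sigma_range: tuple[float, float] = (0.03, 0.08)  # minutes
    mz_range: tuple[float, float] = (150.0, 800.0)
    base_height_range: tuple[float, float] = (2e4, 5e5)   # [M+H]+ apex counts
    intensity_cv: float = 0.10     # lognormal CV of per-sample ion heights
    mz_jitter_sd: float = 0.002    # Da, centroid mass jitter
    warp_amplitude: float = 0.2    # minutes, max |rt shift| per sample
    warp_period: float = 8.0       # minutes, sine-warp period
    min_rt_spacing: float = 0.1    # minutes between metabolite centers; 0 = unconstrained
    noise_ion_factor: float = 5.0  # noise ions per true ion
    noise_height_range: tuple[float, float] = (300.0, 2000.0)
    n_carbons: int = 27            # rutin-like; sets isotope ratios
    n_isotopes: int = 2            # isotopologues beyond M (M+1, M+2)
    adduct_prob: float = 1.0       # chance a metabolite shows one adduct
    fragment_choices: tuple[int, ...] = (0, 1, 2)  # fragments per metabolite
    tailing_tau: float = 0.0       # min; >0 adds exponential tailing
    baseline_bleed: int = 2        # constant-m/z bleed traces per run
    detector_floor: float = 50.0   # centroids below this are not recorded

    def validate(self) -> None:
        if self.rt_end - self.rt_start < 10 * self.peak_sigma_range[1]:
            raise ValueError("rt range too short for the configured peak widths")
        if self.warp_amplitude * 2 * math.pi / self.warp_period >= 1:
            raise ValueError("warp amplitude/period makes the warp non-monotone")


@dataclass
class TrueIon:
    mz: float
    role: str
    response_factor: float


@dataclass
class TrueMetabolite:
    metabolite_id: int
    ions: list[TrueIon]
    rt_center: float
    peak_sigma: float
    base_height: float
    effect_multiplier: float  # 1.0 = null metabolite
    abundance: dict[str, float] = field(default_factory=dict)  # sample -> multiplier


@dataclass
class SampleWarp:
    """rt' = rt + a sin(2 pi rt / period + phase): smooth, monotone."""

    amplitude: float
    period: float
    phase: float

    def apply(self, rt):
        return rt + self.amplitude * np.sin(2 * np.pi * np.asarray(rt) / self.period + self.phase)

    def invert(self, rt_warped):
        """Numerical inverse (bisection; the warp is strictly monotone)."""
        rt_warped = np.atleast_1d(np.asarray(rt_warped, dtype=float))
        lo = rt_warped - abs(self.amplitude) - 1e-6
        hi = rt_warped + abs(self.amplitude) + 1e-6
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            mask = self.apply(mid) < rt_warped
            lo = np.where(mask, mid, lo)
            hi = np.where(mask, hi, mid)
        out = 0.5 * (lo + hi)
        return out if out.size > 1 else float(out[0])


@dataclass
class GroundTruth:
    config: GeneratorConfig
    seed: int
    metabolites: list[TrueMetabolite]
    warps: dict[str, SampleWarp]
    groups: dict[str, str]  # sample -> group label
    ion_heights: dict[str, dict[tuple[int, int], float]] = field(default_factory=dict)
    # sample -> (metabolite_id, ion_index) -> apex height emitted

    def true_ion_count(self) -> int:
        return sum(len(m.ions) for m in self.metabolites)

    def to_json(self, path: str | Path) -> Path:
        d = {
            "config": dataclasses.asdict(self.config),
            "seed": self.seed,
            "groups": self.groups,
            "warps": {s: dataclasses.asdict(w) for s, w in self.warps.items()},
            "metabolites": [
                {**dataclasses.asdict(m),
                 "ions": [dataclasses.asdict(i) for i in m.ions]}
                for m in self.metabolites
            ],
            "ion_heights": {s: {f"{k[0]}:{k[1]}": v for k, v in d2.items()}
                            for s, d2 in self.ion_heights.items()},
        }
        path = Path(path)
        path.write_text(json.dumps(d, indent=1, default=list))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        cfgd = d["config"]
        for k, v in cfgd.items():
            if isinstance(v, list):
                cfgd[k] = tuple(v)
        cfg = GeneratorConfig(**cfgd)
        mets = []
        for md in d["metabolites"]:
            ions = [TrueIon(**i) for i in md.pop("ions")]
            mets.append(TrueMetabolite(ions=ions, **md))
        warps = {s: SampleWarp(**w) for s, w in d["warps"].items()}
        heights = {s: {tuple(int(x) for x in k.split(":")): v for k, v in d2.items()}
                   for s, d2 in d["ion_heights"].items()}
        return cls(config=cfg, seed=d["seed"], metabolites=mets, warps=warps,
                   groups=d["groups"], ion_heights=heights)


def _isotope_ratios(n_carbons: int, n_isotopes: int) -> list[float]:
    """P(k heavy carbons)/P(0) for k=1..n, binomial with p(13C)=0.0107."""
    p = 0.0107
    base = (1 - p) ** n_carbons
    out = []
    for k in range(1, n_isotopes + 1):
        out.append(math.comb(n_carbons, k) * p**k * (1 - p) ** (n_carbons - k) / base)
    return out


def generate_dataset(config: GeneratorConfig | None = None, seed: int = 0
                     ) -> tuple[list[Run], GroundTruth]:
    """Simulate all samples of the study; returns (runs, ground truth)."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    groups: dict[str, str] = {}
    sample_ids: list[str] = []
    for g in range(cfg.n_groups):
        for r in range(cfg.samples_per_group):
            sid = f"G{g + 1}S{r + 1}"
            sample_ids.append(sid)
            groups[sid] = f"group{g + 1}"

    iso_ratios = _isotope_ratios(cfg.n_carbons, cfg.n_isotopes)
    iso_roles = ["M1H", "M2H", "M3H"]

    n_effect = int(round(cfg.effect_fraction * cfg.n_metabolites))
    metabolites: list[TrueMetabolite] = []
    margin = 4 * cfg.peak_sigma_range[1] + cfg.warp_amplitude

    # rt centers with a minimum spacing: chromatographic methods are set up
    # to resolve their analytes; deliberate co-elution is a separate scenario
    centers: list[float] = []
    for _ in range(10000):
        if len(centers) >= cfg.n_metabolites:
            break
        c = float(rng.uniform(cfg.rt_start + margin, cfg.rt_end - margin))
        if all(abs(c - c0) >= cfg.min_rt_spacing for c0 in centers):
            centers.append(c)
    if len(centers) < cfg.n_metabolites:
        raise ValueError("cannot place metabolites with the requested rt spacing")

    for mid in range(cfg.n_metabolites):
        mz = float(rng.uniform(*cfg.mz_range))
        ions = [TrueIon(mz=mz, role="MH", response_factor=1.0)]
        for k, ratio in enumerate(iso_ratios):
            ions.append(TrueIon(mz=mz + (k + 1) * ISO_DELTA, role=iso_roles[k],
                                response_factor=float(ratio)))
        if rng.random() < cfg.adduct_prob:
            role = rng.choice(sorted(DEFAULT_ADDUCTS))
            ions.append(TrueIon(mz=mz + DEFAULT_ADDUCTS[role], role=str(role),
                                response_factor=float(rng.uniform(0.15, 0.5))))
        n_frag = int(rng.choice(cfg.fragment_choices))
        losses = rng.choice(FRAGMENT_LOSSES, size=n_frag, replace=False)
        for loss in losses:
            if mz - loss > 80.0:
                ions.append(TrueIon(mz=mz - float(loss), role="fragment",
                                    response_factor=float(rng.uniform(0.2, 0.8))))
        metabolites.append(TrueMetabolite(
            metabolite_id=mid,
            ions=ions,
            rt_center=centers[mid],
            peak_sigma=float(rng.uniform(*cfg.peak_sigma_range)),
            base_height=float(rng.uniform(*cfg.base_height_range)),
            effect_multiplier=cfg.effect_size if mid < n_effect else 1.0,
        ))

    warps: dict[str, SampleWarp] = {}
    for i, sid in enumerate(sample_ids):
        amp = 0.0 if i == 0 else float(rng.uniform(0.3, 1.0) * cfg.warp_amplitude)
        warps[sid] = SampleWarp(amplitude=amp, period=cfg.warp_period,
                                phase=float(rng.uniform(0, 2 * np.pi)))

    sigma_ln = math.sqrt(math.log(1 + cfg.intensity_cv**2))
    for m in metabolites:
        for sid in sample_ids:
            eff = m.effect_multiplier if groups[sid] != "group1" else 1.0
            m.abundance[sid] = float(eff * rng.lognormal(-sigma_ln**2 / 2, sigma_ln))

    truth = GroundTruth(config=cfg, seed=seed, metabolites=metabolites,
                        warps=warps, groups=groups)

    n_noise = int(cfg.noise_ion_factor * truth.true_ion_count())
    runs: list[Run] = []
    for sid in sample_ids:
        warp = warps[sid]
        n_scans = int(round((cfg.rt_end - cfg.rt_start) / cfg.scan_interval)) + 1
        # irregular grid: small jitter on the nominal scan interval
        steps = cfg.scan_interval * (1 + rng.uniform(-0.05, 0.05, n_scans - 1))
        rts = cfg.rt_start + np.concatenate([[0.0], np.cumsum(steps)])

        events: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []  # (scan idx, mz, inten)
        heights: dict[tuple[int, int], float] = {}
        for m in metabolites:
            center = float(warp.apply(m.rt_center))
            prof = np.exp(-((rts - center) ** 2) / (2 * m.peak_sigma**2))
            if cfg.tailing_tau > 0:
                from scipy.ndimage import uniform_filter1d

                tail = np.exp(-np.clip(rts - center, 0, None) / cfg.tailing_tau)
                prof = uniform_filter1d(prof * 0.7 + 0.3 * prof * tail, 3)
            for ii, ion in enumerate(m.ions):
                h = m.base_height * m.abundance[sid] * ion.response_factor \
                    * float(rng.lognormal(-sigma_ln**2 / 2, sigma_ln))
                heights[(m.metabolite_id, ii)] = h
                inten = h * prof
                sel = np.flatnonzero(inten >= cfg.detector_floor)
                if sel.size == 0:
                    continue
                mzs = ion.mz + rng.normal(0, cfg.mz_jitter_sd, sel.size)
                events.append((sel, mzs, inten[sel]))
        truth.ion_heights[sid] = heights

        # noise ions: small single-trace gaussians at random (mz, rt)
        for _ in range(n_noise):
            nh = float(rng.uniform(*cfg.noise_height_range))
            nrt = float(rng.uniform(cfg.rt_start, cfg.rt_end))
            nsig = float(rng.uniform(0.01, 0.04))
            nmz = float(rng.uniform(*cfg.mz_range))
            inten = nh * np.exp(-((rts - nrt) ** 2) / (2 * nsig**2))
            sel = np.flatnonzero(inten >= cfg.detector_floor)
            if sel.size == 0:
                continue
            events.append((sel, nmz + rng.normal(0, cfg.mz_jitter_sd, sel.size), inten[sel]))

        # column bleed: constant m/z, slow baseline drift across the run
        for _ in range(cfg.baseline_bleed):
            bmz = float(rng.uniform(*cfg.mz_range))
            drift = rng.uniform(500, 1500) * (1 + 0.5 * np.sin(2 * np.pi * rts / (rts[-1] - rts[0])
                                                               + rng.uniform(0, 2 * np.pi)))
            sel = np.arange(rts.size)
            events.append((sel, bmz + rng.normal(0, cfg.mz_jitter_sd, sel.size), drift))

        per_scan_mz: list[list[float]] = [[] for _ in range(rts.size)]
        per_scan_int: list[list[float]] = [[] for _ in range(rts.size)]
        for sel, mzs, inten in events:
            for k, si in enumerate(sel):
                per_scan_mz[si].append(float(mzs[k]))
                per_scan_int[si].append(float(inten[k]))
        scans = []
        for si, t in enumerate(rts):
            mz = np.asarray(per_scan_mz[si])
            it = np.asarray(per_scan_int[si])
            order = np.argsort(mz)
            scans.append(Scan(rt=float(t), mz_values=mz[order], intensities=it[order]))
        runs.append(Run(sample_id=sid, scans=scans, group_label=groups[sid]))

    return runs, truth


def score_against_truth(truth: GroundTruth,
                        peaks_by_sample: dict[str, list] | None = None,
                        aligned_by_sample: dict[str, list] | None = None,
                        table=None,
                        screen_results=None,
                        confirmed: dict[int, list[int]] | None = None,
                        mz_tol: float = 0.01, rt_tol: float = 0.05) -> dict:
    """Score pipeline outputs against the generator's ground truth.

    Reports, for whichever outputs are supplied: peak-detection
    recall/precision (a true ion matches a detected peak within ``mz_tol``
    and ``rt_tol`` of its warped position), post-alignment rt RMSE against
    the reference axis, registration adjusted-Rand index vs true ion
    identity, ANOVA screening sensitivity/specificity, and
    metabolite-confirmation recall/purity.
    """
    report: dict = {}
    cfg = truth.config

    def _true_positions(sid):
        out = []
        warp = truth.warps[sid]
        for m in truth.metabolites:
            for ii, ion in enumerate(m.ions):
                h = truth.ion_heights[sid].get((m.metabolite_id, ii), 0.0)
                if h >= 4 * cfg.detector_floor:  # detectably present
                    out.append((ion.mz, float(warp.apply(m.rt_center)), m.metabolite_id, ii))
        return out

    if peaks_by_sample is not None:
        tp = fp = fn = 0
        for sid, peaks in peaks_by_sample.items():
            matched = set()
            truths = _true_positions(sid)
            for mz, rt, mid, ii in truths:
                hit = any(abs(p.apex_mz - mz) <= mz_tol and abs(p.apex_rt - rt) <= rt_tol
                          for p in peaks)
                if hit:
                    tp += 1
                    matched.add((mid, ii))
                else:
                    fn += 1
            for p in peaks:
                if not any(abs(p.apex_mz - mz) <= mz_tol and abs(p.apex_rt - rt) <= rt_tol
                           for mz, rt, _, _ in truths):
                    fp += 1
        report["detection_recall"] = tp / max(1, tp + fn)
        report["detection_precision"] = tp / max(1, tp + fp)

    if aligned_by_sample is not None:
        errs = []
        for sid, peaks in aligned_by_sample.items():
            truths = _true_positions(sid)
            for p in peaks:
                # match against unwarped (reference-axis) true positions
                for m in truth.metabolites:
                    for ion in m.ions:
                        if abs(p.apex_mz - ion.mz) <= mz_tol and abs(p.apex_rt - m.rt_center) <= 3 * rt_tol:
                            errs.append(p.apex_rt - m.rt_center)
                            break
        report["alignment_rt_rmse"] = float(np.sqrt(np.mean(np.square(errs)))) if errs else np.nan

    if table is not None:
        from sklearn.metrics import adjusted_rand_score

        labels_true, labels_pred = [], []
        for comp in table.components:
            for sid, p in comp.members.items():
                truths = _true_positions(sid)
                ident = None
                for mz, rt, mid, ii in truths:
                    if abs(p.apex_mz - mz) <= mz_tol:
                        ident = (mid, ii)
                        break
                if ident is not None:
                    labels_true.append(ident)
                    labels_pred.append(comp.component_id)
        if labels_true:
            keys = {k: i for i, k in enumerate(dict.fromkeys(labels_true))}
            report["registration_ari"] = float(adjusted_rand_score(
                [keys[k] for k in labels_true], labels_pred))

    if screen_results is not None and table is not None:
        effect_mids = {m.metabolite_id for m in truth.metabolites if m.effect_multiplier != 1.0}
        comp_truth = {}
        for comp in table.components:
            mids = set()
            for sid, p in comp.members.items():
                for mz, rt, mid, ii in _true_positions(sid):
                    if abs(p.apex_mz - mz) <= mz_tol and abs(p.apex_rt - truth.warps[sid].apply(
                            [t.rt_center for t in truth.metabolites if t.metabolite_id == mid][0])) <= 3 * rt_tol:
                        mids.add(mid)
            comp_truth[comp.component_id] = mids
        tp = fn = fp = tn = 0
        for r in screen_results:
            if not r.testable:
                continue
            mids = comp_truth.get(r.component_id, set())
            is_effect = bool(mids & effect_mids)
            is_true_null = bool(mids) and not is_effect
            if is_effect and r.significant:
                tp += 1
            elif is_effect:
                fn += 1
            elif is_true_null and r.significant:
                fp += 1
            elif is_true_null:
                tn += 1
        report["screening_sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
        report["screening_specificity"] = tn / (tn + fp) if tn + fp else float("nan")

    if confirmed is not None and table is not None:
        comp_to_mid: dict[int, int] = {}
        for comp in table.components:
            votes: dict[int, int] = {}
            for sid, p in comp.members.items():
                for mz, rt, mid, ii in _true_positions(sid):
                    if abs(p.apex_mz - mz) <= mz_tol and abs(p.apex_rt - rt) <= 3 * rt_tol:
                        votes[mid] = votes.get(mid, 0) + 1
                        break
            if votes:
                comp_to_mid[comp.component_id] = max(votes, key=votes.get)
        n_pure = 0
        merged = 0
        recovered_mids: set[int] = set()
        for mid_out, cids in confirmed.items():
            true_mids = {comp_to_mid[c] for c in cids if c in comp_to_mid}
            if len(true_mids) == 1:
                n_pure += 1
                recovered_mids.update(true_mids)
            elif len(true_mids) > 1:
                merged += 1
        report["confirmation_purity"] = n_pure / max(1, len(confirmed))
        report["cross_metabolite_merges"] = merged
        report["metabolites_recovered"] = len(recovered_mids)
    return report
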