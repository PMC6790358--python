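"""Statistical peak screening and Meta-ID grouping.

Registered components are screened by one-way fixed-effects ANOVA on peak
heights across experimental groups. Screened (significant) components are
then linked when the robust Pearson correlation of their heights across
samples — computed from a minimum-covariance-determinant (MCD) scatter
estimate so outlying samples cannot dominate — exceeds a threshold
(default 0.9) and their mean rts co-elute; connected sets share a Meta ID,
flagging ions that putatively originate from one metabolite.
"""
from __future__ import annotations

import numpy as np
import scipy.stats
from sklearn.covariance import MinCovDet

from .models import ComponentTable, MetaGroup, ScreenResult


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Textbook one-way fixed-effects ANOVA: (F, p).

    Degenerate cases follow the natural limits: no between-group variance
    gives (0, 1); between-group variance with zero within-group variance
    gives (inf, 0).
    """
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n = int(ns.sum())
    grand = float(np.concatenate(groups).mean())
    ssb = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    dfb, dfw = k - 1, n - k
    if dfb <= 0 or dfw <= 0:
        return np.nan, np.nan
    if ssb <= 1e-300 * max(1.0, ssw):
        return 0.0, 1.0
    if ssw <= 1e-300 * ssb:
        return np.inf, 0.0
    f = (ssb / dfb) / (ssw / dfw)
    p = float(scipy.stats.f.sf(f, dfb, dfw))
    return f, p


def anova_screen(table: ComponentTable, groups: dict[str, str],
                 alpha: float = 0.05, response: str = "height",
                 p_adjust: str = "none") -> list[ScreenResult]:
    """One-way ANOVA per component on peak heights (or areas) across groups.

    Missing cells are dropped (unbalanced ANOVA, no imputation). A
    component needs observations in >= 2 samples of each of >= 2 groups to
    be testable; untestable components are flagged and excluded from the
    significance ranking. Results are sorted by p ascending.
    """
    resp = table.heights if response == "height" else table.areas
    results: list[ScreenResult] = []
    labels = sorted(set(groups.values()))
    for comp in table.components:
        row = resp.loc[comp.component_id]
        obs = {lab: row[[s for s in table.samples if groups.get(s) == lab]].dropna().to_numpy(dtype=float)
               for lab in labels}
        usable = [v for v in obs.values() if v.size >= 2]
        if len(usable) < 2:
            results.append(ScreenResult(comp.component_id, np.nan, np.nan,
                                        significant=False, testable=False))
            continue
        f, p = one_way_anova(usable)
        results.append(ScreenResult(comp.component_id, f, p, significant=False))

    testable = [r for r in results if r.testable]
    if p_adjust == "BH" and testable:
        from statsmodels.stats.multitest import multipletests

        rej, _, _, _ = multipletests([r.p_value for r in testable], alpha=alpha, method="fdr_bh")
        for r, rj in zip(testable, rej):
            r.significant = bool(rj)
    else:
        for r in testable:
            r.significant = bool(r.p_value < alpha)
    results.sort(key=lambda r: (not r.testable, r.p_value if r.testable else np.inf))
    return results


def robust_pairwise_correlation(x: np.ndarray, y: np.ndarray,
                                mcd_support: float = 0.75,
                                random_state: int = 0) -> float | None:
    """Outlier-resistant Pearson correlation of two height vectors.

    Pairs with a missing value in either vector are dropped. With >= 10
    complete pairs, an MCD scatter estimate of the bivariate sample flags
    gross outlying samples by robust Mahalanobis distance
    (median-rescaled; cut-off at 5x a Bonferroni-adjusted chi-square(2)
    quantile; never more than the contamination budget 1 - mcd_support)
    and the Pearson correlation is computed on the retained samples — so
    on outlier-free data the value coincides with plain Pearson, while
    gross outliers are eliminated before they can distort the
    coefficient. Below 10 pairs the MCD subset search is unstable and
    plain Pearson is used. Returns None with < 5 pairs (undefined), 0.0
    when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 5:
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    if x.size >= 10:
        import warnings

        mcd = MinCovDet(support_fraction=mcd_support, random_state=random_state)
        with warnings.catch_warnings():
            # exactly collinear pairs make the MCD scatter singular; the
            # distance-based trim below is still well defined
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            mcd.fit(np.column_stack([x, y]))
        # rescale distances so their median matches the chi2(2) median:
        # corrects the small-sample bias of the MCD scatter while gross
        # outliers stay orders of magnitude beyond any cutoff
        d = mcd.dist_
        med = np.median(d)
        if med > 0:
            d = d * (scipy.stats.chi2.ppf(0.5, df=2) / med)
        # only *gross* outliers are eliminated: rescaled MCD distances of
        # clean data are heavy-tailed, so the Bonferroni chi2 cutoff alone
        # over-flags; a 5x margin keeps clean samples intact (plain-Pearson
        # equivalence) while genuine outliers sit far beyond it
        cutoff = 5.0 * scipy.stats.chi2.ppf(1.0 - 0.001 / d.size, df=2)
        inlier = d <= cutoff
        # never eliminate more than the contamination budget implied by the
        # support fraction: flagging more means the scatter estimate itself
        # is suspect, and wholesale trimming of small samples can flip r
        budget = int(np.floor((1.0 - mcd_support) * d.size))
        if (~inlier).sum() > budget:
            keep_rank = np.argsort(d)[: d.size - budget]
            inlier = np.zeros(d.size, dtype=bool)
            inlier[keep_rank] = True
        if inlier.sum() >= 5:
            x, y = x[inlier], y[inlier]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(r, -1.0, 1.0)) if np.isfinite(r) else 0.0


def assign_meta_ids(screened: list[ScreenResult], table: ComponentTable,
                    corr_threshold: float = 0.9,
                    coelution_rt_tol: float = 0.1,
                    mcd_support: float = 0.75,
                    response: str = "height",
                    random_state: int = 0,
                    use_rt_gate: bool = True) -> list[MetaGroup]:
    """Group significant components into MetaGroups by robust correlation.

    Builds a graph over significant components with an edge where the
    robust correlation of their heights >= ``corr_threshold`` and (when the
    rt gate is on) the component mean rts lie within
    ``coelution_rt_tol``. Connected components of the graph become
    MetaGroups (transitive merging); meta ids are ordered by group mean rt.
    """
    import networkx as nx

    sig_ids = [r.component_id for r in screened if r.significant]
    resp = table.heights if response == "height" else table.areas
    comp_by_id = {c.component_id: c for c in table.components}
    G = nx.Graph()
    G.add_nodes_from(sig_ids)
    for a_pos, cid_a in enumerate(sig_ids):
        for cid_b in sig_ids[a_pos + 1:]:
            ca, cb = comp_by_id[cid_a], comp_by_id[cid_b]
            if use_rt_gate and abs(ca.mean_rt - cb.mean_rt) > coelution_rt_tol:
                continue
            r = robust_pairwise_correlation(
                resp.loc[cid_a].to_numpy(dtype=float),
                resp.loc[cid_b].to_numpy(dtype=float),
                mcd_support=mcd_support, random_state=random_state)
            if r is not None and r >= corr_threshold:
                G.add_edge(cid_a, cid_b)

    comps = [sorted(c) for c in nx.connected_components(G)]
    comps.sort(key=lambda ids: np.mean([comp_by_id[c].mean_rt for c in ids]))
    return [MetaGroup(meta_id=i, member_component_ids=ids) for i, ids in enumerate(comps)]
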