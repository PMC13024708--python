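"""EGTA calcium-switch analysis across measurement platforms.

Chelating extracellular calcium with EGTA opens tight junctions
reversibly; the assay records a resistance-like quantity (TEER for 2D
inserts, fitted Rb for the 3D device, Ussing-chamber resistance ex vivo)
at three phases -- baseline, after 30 min of 5 mM EGTA, and after a
30 min washout.  Because absolute electrical values are not comparable
across platforms, every replicate is normalized to its own baseline;
platform summaries and significance tests operate on the dimensionless
normalized values.

Within each platform the phases are compared with a one-way ANOVA plus
pairwise baseline-vs-phase t-tests, Holm-Sidak adjusted.  Since the
normalized baseline is identically 1, a paired baseline-vs-phase t-test
reduces to a one-sample t-test of the normalized phase values against 1.
"Recovery" is operationalized as non-significance of baseline-vs-washout
at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, NormalizationError

__all__ = [
    "PHASES",
    "CalciumSwitchSeries",
    "NormalizedSeries",
    "AnovaResult",
    "normalize",
    "platform_summary",
    "one_way_anova",
    "holm_sidak",
    "compare_phases",
    "pearson",
    "stars",
]

PHASES = ("baseline", "egta", "washout")

#: Prism-style significance thresholds and their asterisk labels.
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.005, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Asterisk code for a p-value (*, **, ***, **** at 0.05/0.005/0.001/0.0001)."""
    for thr, label in STAR_THRESHOLDS:
        if p < thr:
            return label
    return "ns"


@dataclass(frozen=True)
class CalciumSwitchSeries:
    """Baseline/EGTA/washout resistances of one replicate, platform-native units."""

    replicate_id: str
    platform: str
    baseline: float
    egta: float
    washout: float


@dataclass(frozen=True)
class NormalizedSeries:
    """A calcium-switch series divided by its own baseline (dimensionless)."""

    replicate_id: str
    platform: str
    baseline: float
    egta: float
    washout: float

    def __post_init__(self) -> None:
        if self.baseline != 1.0:
            raise DomainError("normalized baseline must equal 1 exactly")

    def value(self, phase: str) -> float:
        if phase not in PHASES:
            raise DomainError(f"unknown phase {phase!r}")
        return getattr(self, phase)


def normalize(series: CalciumSwitchSeries) -> NormalizedSeries:
    """Divide each phase by the replicate's baseline.

    Scale-invariant by construction: multiplying a raw series by any
    positive constant leaves the output unchanged.
    """
    if series.baseline <= 0:
        raise NormalizationError(
            f"baseline must be > 0 to normalize, got {series.baseline}"
        )
    return NormalizedSeries(
        replicate_id=series.replicate_id,
        platform=series.platform,
        baseline=1.0,
        egta=series.egta / series.baseline,
        washout=series.washout / series.baseline,
    )


def platform_summary(series) -> pd.DataFrame:
    """Mean and sample SD of normalized values per platform per phase."""
    rows = [
        {"platform": s.platform, "phase": ph, "value": s.value(ph)}
        for s in series
        for ph in PHASES
    ]
    if not rows:
        return pd.DataFrame(columns=["platform", "phase", "mean", "sd", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["platform", "phase"], sort=False)["value"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    out["phase"] = pd.Categorical(out["phase"], categories=PHASES, ordered=True)
    return out.sort_values(["platform", "phase"]).reset_index(drop=True)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df: tuple
    pvalue: float


def one_way_anova(groups) -> AnovaResult:
    """Classic fixed-effects one-way ANOVA (between/within mean squares).

    Degenerate input with zero between- and within-group variability
    returns ``F = 0, p = 1``; zero within-group variability with distinct
    means returns ``F = inf, p = 0``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise DomainError("need >= 2 groups with >= 2 values each")
    n_total = sum(a.size for a in arrs)
    grand = sum(a.sum() for a in arrs) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b = len(arrs) - 1
    df_w = n_total - len(arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(f=0.0, df=(df_b, df_w), pvalue=1.0)
        return AnovaResult(f=float("inf"), df=(df_b, df_w), pvalue=0.0)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f=float(f), df=(df_b, df_w), pvalue=p)


def holm_sidak(pvalues) -> list:
    """Holm-Sidak step-down adjusted p-values, returned in input order.

    Sorted ascending, ``adj_i = 1 - (1 - p_(i))**(m - i + 1)`` with a
    monotone running maximum; adjusted values never fall below the raw
    ones and are capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p = 1 inputs hit log1p(-1)
        adj = multipletests(p, alpha=0.05, method="holm-sidak")[1]
    return [float(v) for v in np.maximum(adj, p)]


def _one_sample_vs_baseline(values: np.ndarray):
    """Paired baseline-vs-phase t on normalized data = one-sample t vs 1."""
    if np.allclose(values, 1.0):
        return 0.0, 1.0
    res = stats.ttest_1samp(values, 1.0)
    return float(res.statistic), float(res.pvalue)


def compare_phases(series, family: str = "baseline", alpha: float = 0.05) -> pd.DataFrame:
    """Within-platform phase comparisons with Holm-Sidak adjustment.

    Parameters
    ----------
    series : list of NormalizedSeries
        Normalized replicates, >= 3 per platform (platforms with fewer
        are skipped with a warning).
    family : {"baseline", "all"}
        Adjustment family per platform: ``"baseline"`` (default, m = 2)
        covers baseline-vs-EGTA and baseline-vs-washout, matching the
        comparisons drawn in the study's figures; ``"all"`` (m = 3) adds
        EGTA-vs-washout.
    alpha : float
        Significance level for the ``significant`` and ``recovered`` flags.

    Returns
    -------
    DataFrame with one row per platform per comparison: ``platform,
    comparison, n, statistic, p_raw, p_adj, stars, significant,
    anova_f, anova_p, recovered`` where ``recovered`` (per platform)
    means the baseline-vs-washout adjusted p is >= alpha.
    """
    if family not in ("baseline", "all"):
        raise DomainError("family must be 'baseline' or 'all'")
    by_platform: dict = {}
    for s in series:
        by_platform.setdefault(s.platform, []).append(s)
    rows = []
    for platform, reps in by_platform.items():
        if len(reps) < 3:
            warnings.warn(
                f"platform {platform!r} has {len(reps)} replicates (< 3); skipped",
                stacklevel=2,
            )
            continue
        egta = np.array([r.egta for r in reps])
        wash = np.array([r.washout for r in reps])
        ones = np.ones_like(egta)
        anova = one_way_anova([ones, egta, wash])
        comps = [
            ("baseline_vs_egta", *_one_sample_vs_baseline(egta)),
            ("baseline_vs_washout", *_one_sample_vs_baseline(wash)),
        ]
        if family == "all":
            if np.allclose(egta, wash):
                comps.append(("egta_vs_washout", 0.0, 1.0))
            else:
                r = stats.ttest_rel(egta, wash)
                comps.append(("egta_vs_washout", float(r.statistic), float(r.pvalue)))
        adj = holm_sidak([c[2] for c in comps])
        wash_adj = adj[1]
        for (name, t, p), pa in zip(comps, adj):
            rows.append(
                {
                    "platform": platform,
                    "comparison": name,
                    "n": len(reps),
                    "statistic": t,
                    "p_raw": p,
                    "p_adj": pa,
                    "stars": stars(pa),
                    "significant": pa < alpha,
                    "anova_f": anova.f,
                    "anova_p": anova.pvalue,
                    "recovered": wash_adj >= alpha,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "platform", "comparison", "n", "statistic", "p_raw", "p_adj",
            "stars", "significant", "anova_f", "anova_p", "recovered",
        ],
    )


def pearson(x, y) -> float:
    """Sample Pearson correlation; NaN (reported missing) on zero variance."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise DomainError("x and y must have equal length")
    if xa.size < 3:
        raise DomainError("need >= 3 points")
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        return float("nan")
    return float(stats.pearsonr(xa, ya).statistic)
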