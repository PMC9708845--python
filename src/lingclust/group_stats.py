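"""Between-cluster comparisons of clinical, cognitive, and functional variables.

The battery mirrors a standard two-group clinical comparison: Student's
pooled-variance t-tests per variable (with an automatic Welch fallback
when the two-variance F-test rejects homoskedasticity at α = 0.05),
Fisher's exact test for the treatment-type contingency, Benjamini–Hochberg
FDR adjustment applied jointly to the eight QLS + PANSS comparisons, and
within-cluster Pearson correlations between the linguistic component
scores and the cognitive / theory-of-mind subscores.

Degrees of freedom vary across variables because missing values are
removed pairwise per variable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: The PANSS items whose sum forms the disorganization composite.
DISORGANIZATION_ITEMS = ("P2", "N5", "N7", "G5", "G10", "G11", "G12", "G13")

#: Variables whose p-values are FDR-adjusted as one family (QLS + PANSS).
FDR_FAMILY = (
    "qls_ire",
    "qls_iro",
    "qls_pa",
    "qls_total",
    "panss_positive",
    "panss_negative",
    "panss_general",
    "panss_disorganization",
)

#: Continuous variables compared without adjustment.
UNADJUSTED_VARIABLES = (
    "age",
    "education",
    "illness_duration",
    "age_of_onset",
    "cpz_dose",
    "bacs_total",
    "tom_total",
    "bacs_verbal_memory",
    "bacs_digit_sequencing",
    "bacs_token_task",
    "bacs_semantic_fluency",
    "bacs_symbol_coding",
    "bacs_tower_of_london",
    "tom_sequencing",
    "tom_questionnaire",
)

#: Subscores correlated with the component scores within each cluster.
CORRELATION_SUBSCORES = (
    "bacs_verbal_memory",
    "bacs_digit_sequencing",
    "bacs_token_task",
    "bacs_semantic_fluency",
    "bacs_symbol_coding",
    "bacs_tower_of_london",
    "tom_sequencing",
    "tom_questionnaire",
)


class StatsError(ValueError):
    """Degenerate statistical input."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    welch: bool = False
    p_adj: float | None = None


def disorganization_score(items: dict[str, float]) -> float:
    """Sum of the eight disorganization-dimension PANSS items.

    Items are conceptual disorganization (P2), difficulty in abstraction
    (N5), stereotyped thinking (N7), mannerism (G5), disorientation (G10),
    poor attention (G11), lack of judgment and insight (G12), and
    disturbance of volition (G13); each is scored 1–7 so the composite
    lies in [8, 56].  A missing item makes the composite missing.
    """
    vals = []
    for name in DISORGANIZATION_ITEMS:
        v = items.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            logger.warning("disorganization composite: item %s missing", name)
            return float("nan")
        if not 1 <= v <= 7:
            raise StatsError(f"PANSS item {name}={v} outside [1, 7]")
        vals.append(v)
    return float(sum(vals))


def pooled_t_test(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TTestResult:
    """Student's pooled-variance two-sample t from group summaries."""
    if n1 < 2 or n2 < 2:
        raise StatsError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise StatsError("group sds must be positive")
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return TTestResult(t=float(t), df=n1 + n2 - 2, p=float(p))


def pooled_t_test_raw(x1, x2, welch: bool = False) -> TTestResult:
    """Two-sample t from raw data (pooled by default, Welch on request)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    if len(x1) < 2 or len(x2) < 2:
        raise StatsError("each group needs n >= 2 after missing removal")
    res = stats.ttest_ind(x1, x2, equal_var=not welch)
    df = float(res.df) if welch else len(x1) + len(x2) - 2
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue), welch=welch)


def variance_f_test(s1: float, n1: int, s2: float, n2: int) -> tuple[float, float]:
    """Two-sided F-test comparing two variances (F = s1²/s2²)."""
    if n1 < 2 or n2 < 2 or s1 <= 0 or s2 <= 0:
        raise StatsError("degenerate variance test input")
    F = (s1 / s2) ** 2
    cdf = stats.f.cdf(F, n1 - 1, n2 - 1)
    p = 2 * min(cdf, 1 - cdf)
    return float(F), float(min(p, 1.0))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise StatsError("table must be a non-negative integer 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("all-zero margin")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _shapiro_advisory(x: np.ndarray, variable: str, cluster: int) -> None:
    # advisory only: flags non-normality in a log, never changes the test
    if len(x) >= 3 and np.ptp(x) > 0:
        _, p = stats.shapiro(x)
        if p < 0.05:
            logger.warning(
                "variable %s, cluster %d: Shapiro-Wilk p=%.3g (non-normal)",
                variable, cluster, p,
            )


def compare_clusters(
    clinical: pd.DataFrame,
    labels,
    shapiro_advisory: bool = True,
) -> pd.DataFrame:
    """Per-variable between-cluster comparison report.

    Continuous variables get a pooled t-test (Welch fallback when the
    F-test on the two variances rejects at 0.05); the ``treatment`` column
    (atypical/typical) gets Fisher's exact test; the eight QLS + PANSS
    p-values are BH-adjusted jointly, everything else is reported raw.
    Returns one row per variable: means ± sd per cluster, t, df, p, p_adj.
    """
    y = np.asarray(labels)
    clusters = np.unique(y)
    if len(clusters) != 2:
        raise StatsError("compare_clusters expects exactly 2 clusters")
    c1, c2 = clusters
    rows: list[dict] = []
    for var in UNADJUSTED_VARIABLES + FDR_FAMILY:
        if var not in clinical.columns:
            continue
        x1 = clinical.loc[y == c1, var].to_numpy(dtype=float)
        x2 = clinical.loc[y == c2, var].to_numpy(dtype=float)
        x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
        if len(x1) < 2 or len(x2) < 2:
            logger.warning("variable %s: fewer than 2 per cluster; skipped", var)
            continue
        if shapiro_advisory:
            _shapiro_advisory(x1, var, int(c1))
            _shapiro_advisory(x2, var, int(c2))
        s1, s2 = np.std(x1, ddof=1), np.std(x2, ddof=1)
        welch = False
        if s1 > 0 and s2 > 0:
            _, p_f = variance_f_test(s1, len(x1), s2, len(x2))
            welch = p_f < 0.05
        res = pooled_t_test_raw(x1, x2, welch=welch)
        rows.append(
            {
                "variable": var,
                "mean_1": float(np.mean(x1)),
                "sd_1": float(s1),
                "n_1": len(x1),
                "mean_2": float(np.mean(x2)),
                "sd_2": float(s2),
                "n_2": len(x2),
                "test": "welch_t" if welch else "pooled_t",
                "statistic": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    if "treatment" in clinical.columns:
        tab = np.array(
            [
                [
                    int(np.sum((y == c) & (clinical["treatment"] == kind)))
                    for kind in ("atypical", "typical")
                ]
                for c in (c1, c2)
            ]
        )
        rows.append(
            {
                "variable": "treatment",
                "mean_1": float(tab[0, 0]), "sd_1": float(tab[0, 1]), "n_1": int(tab[0].sum()),
                "mean_2": float(tab[1, 0]), "sd_2": float(tab[1, 1]), "n_2": int(tab[1].sum()),
                "test": "fisher_exact",
                "statistic": float("nan"),
                "df": float("nan"),
                "p": fisher_exact_2x2(tab),
            }
        )
    report = pd.DataFrame(rows).set_index("variable")
    report["p_adj"] = np.nan
    family = [v for v in FDR_FAMILY if v in report.index]
    if family:
        report.loc[family, "p_adj"] = bh_adjust(report.loc[family, "p"].to_numpy())
    return report


def cluster_correlations(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    min_pairs: int = 4,
) -> dict[int, pd.DataFrame]:
    """Within-cluster Pearson correlations of component scores with subscores.

    Pairwise-complete observations per cell; cells with fewer than
    ``min_pairs`` complete pairs are left missing.  Returns one long-form
    frame per cluster (pc, subscore, r, p, n, significant at ``alpha``,
    unadjusted).
    """
    y = np.asarray(labels)
    out: dict[int, pd.DataFrame] = {}
    subscores = [c for c in CORRELATION_SUBSCORES if c in clinical.columns]
    for cluster in np.unique(y):
        mask = y == cluster
        rows = []
        for pc in scores.columns:
            for sub in subscores:
                a = scores.loc[mask, pc].to_numpy(dtype=float)
                b = clinical.loc[mask, sub].to_numpy(dtype=float)
                ok = ~(np.isnan(a) | np.isnan(b))
                n = int(ok.sum())
                if n < min_pairs or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                    r, p = float("nan"), float("nan")
                else:
                    r, p = stats.pearsonr(a[ok], b[ok])
                rows.append(
                    {
                        "pc": pc,
                        "subscore": sub,
                        "r": float(r),
                        "p": float(p),
                        "n": n,
                        "significant": bool(p < alpha) if not math.isnan(p) else False,
                    }
                )
        out[int(cluster)] = pd.DataFrame(rows)
    return out
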