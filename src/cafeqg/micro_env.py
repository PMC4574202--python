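"""Genetic heterogeneity of within-line environmental variance.

Inbred lines share a genotype, so variation among replicate vials of
one line is environmental; if the *magnitude* of that variation differs
between lines more than sampling allows, micro-environmental variance
is itself under genetic control. Two classic variance-heterogeneity
tests quantify this: a one-way ANOVA on absolute deviations of each
vial from its line mean (Levene) or line median (Brown-Forsythe). The
per-line summary statistic is the coefficient of environmental
variation, CV_E = 100 * sigma_E / mean, which partially removes the
dependence of the variance on the mean.

Cross-trait and cross-sex relationships are summarized by Pearson
correlations of line means with t-based P-values and Fisher-z
confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VarianceHeterogeneityResult",
    "CorrelationResult",
    "variance_heterogeneity_test",
    "cve_table",
    "pearson_correlation",
    "mean_variance_association",
    "cross_trait_correlations",
]

logger = logging.getLogger(__name__)


@dataclass
class VarianceHeterogeneityResult:
    test: str            # "levene" or "brown_forsythe"
    sex: str
    df_num: int          # k - 1
    df_den: int          # N - k
    F: float
    P: float
    n_lines: int
    n_dropped: int       # single-vial lines excluded


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    n: int
    r: float
    P: float
    ci_low: float
    ci_high: float

    @property
    def r2(self) -> float:
        return self.r**2


def variance_heterogeneity_test(
    vials: pd.DataFrame,
    sex: str,
    center: str = "median",
    value: str = "intake",
) -> VarianceHeterogeneityResult:
    """Levene / Brown-Forsythe test for unequal within-line variances.

    Each vial is transformed to its absolute deviation from the line's
    center (mean -> Levene, median -> Brown-Forsythe; medians use the
    usual midpoint convention for even counts) and a one-way ANOVA F is
    computed across lines. Lines with fewer than two vials carry no
    variance information and are dropped with a warning.

    Both variants rely on the F reference distribution asymptotically;
    with very few vials per line the mean-centred test is
    anticonservative (see the methods note).
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    df = vials
    if "quarantined" in df.columns:
        df = df.loc[~df["quarantined"]]
    df = df.loc[(df["sex"] == sex) & df[value].notna()]
    groups = [g.to_numpy(float) for _, g in df.groupby("line")[value]]
    kept = [g for g in groups if len(g) >= 2]
    dropped = len(groups) - len(kept)
    if dropped:
        logger.warning("%d line(s) with a single vial dropped from %s test",
                       dropped, center)
    if len(kept) < 2:
        raise ValueError("need at least 2 lines with at least 2 vials")
    centerfun = np.mean if center == "mean" else np.median
    devs = [np.abs(g - centerfun(g)) for g in kept]
    F, P = stats.f_oneway(*devs)
    k = len(kept)
    n = sum(len(g) for g in kept)
    return VarianceHeterogeneityResult(
        test="levene" if center == "mean" else "brown_forsythe",
        sex=sex,
        df_num=k - 1,
        df_den=n - k,
        F=float(F),
        P=float(P),
        n_lines=k,
        n_dropped=dropped,
    )


def cve_table(
    line_table: pd.DataFrame, min_reps: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-line CV_E values per sex from a line phenotype table.

    ``line_table`` is the output of :func:`cafeqg.cafe_io.summarize_lines`
    (indexed by line x sex with ``n_reps``, ``mean``, ``sd``). Returns
    ``(cve, excluded)`` where ``cve`` has one row per usable line x sex
    and ``excluded`` lists dropped cells with the reason.
    """
    rows, excl = [], []
    for (line, sex), rec in line_table.iterrows():
        if rec["n_reps"] < min_reps:
            excl.append((line, sex, f"fewer than {min_reps} replicates"))
        elif not np.isfinite(rec["sd"]):
            excl.append((line, sex, "SD undefined"))
        elif rec["mean"] <= 0:
            excl.append((line, sex, "non-positive mean"))
        else:
            rows.append((line, sex, 100.0 * rec["sd"] / rec["mean"]))
    cve = pd.DataFrame(rows, columns=["line", "sex", "cve"]).set_index(["line", "sex"])
    excluded = pd.DataFrame(excl, columns=["line", "sex", "reason"])
    return cve, excluded


def pearson_correlation(
    x, y, labels: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Pearson correlation of paired line values with a Fisher-z CI.

    Pairs with a missing member are dropped. P is the two-sided t-based
    value on n-2 df; the 95% CI is ``tanh(atanh(r) +- 1.96 / sqrt(n-3))``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, P = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.96 / np.sqrt(n - 3)
    return CorrelationResult(
        pair=labels,
        n=n,
        r=float(r),
        P=float(P),
        ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)),
    )


def mean_variance_association(
    line_table: pd.DataFrame, min_reps: int = 3
) -> dict[str, CorrelationResult]:
    """Mean vs CV_E per sex, and the cross-sex CV_E correlation.

    Returns a dict with keys ``mean_cve_F``, ``mean_cve_M`` and
    ``cve_F_M``; each value's ``r2`` is the fraction of CV_E variance
    explained by the mean (or by the other sex).
    """
    cve, _ = cve_table(line_table, min_reps=min_reps)
    wide_cve = cve["cve"].unstack()
    means = line_table["mean"].unstack()
    out: dict[str, CorrelationResult] = {}
    for sex in ("F", "M"):
        joined = pd.concat([means[sex], wide_cve[sex]], axis=1, keys=["mean", "cve"]).dropna()
        out[f"mean_cve_{sex}"] = pearson_correlation(
            joined["mean"], joined["cve"], labels=(f"mean_{sex}", f"cve_{sex}")
        )
    both = wide_cve.dropna()
    out["cve_F_M"] = pearson_correlation(
        both["F"], both["M"], labels=("cve_F", "cve_M")
    )
    return out


def cross_trait_correlations(
    focal: pd.Series, other_traits: pd.DataFrame
) -> pd.DataFrame:
    """Correlate a focal line-mean trait with a line x trait table.

    One row per other trait: n, r, P (unadjusted, mirroring nominal
    reporting), Fisher-z CI, and a Benjamini-Hochberg adjusted P column
    for convenience.
    """
    rows = []
    for trait in other_traits.columns:
        joined = pd.concat([focal, other_traits[trait]], axis=1).dropna()
        if len(joined) < 4 or joined.iloc[:, 1].nunique() < 2:
            logger.warning("trait %s skipped (too few complete lines)", trait)
            continue
        res = pearson_correlation(
            joined.iloc[:, 0], joined.iloc[:, 1], labels=(str(focal.name), trait)
        )
        rows.append(
            dict(trait=trait, n=res.n, r=res.r, P=res.P,
                 ci_low=res.ci_low, ci_high=res.ci_high)
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["P_bh"] = multipletests(table["P"], method="fdr_bh")[1]
    return table
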