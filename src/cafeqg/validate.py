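"""Statistics for the functional-validation designs.

Two experimental designs confirm candidate genes and variants:

* RNAi knockdowns versus a common driver control — many-to-one Dunnett
  tests on mean intake (family-wise error controlled) and two-group
  Levene tests on within-genotype variance, per sex;
* SNP-based crosses — F1 genotypes homozygous for the major or minor
  allele of a focal variant in randomized outbred backgrounds, compared
  by a two-sample t-test per sex, with the F1 genotype (not the vial)
  as the experimental unit.

Dunnett adjusted P-values use the classic one-factor decomposition of
the many-to-one correlation structure (rho_ij = lambda_i lambda_j with
lambda_i = sqrt(n_i / (n_i + n_0))), which makes the max-|T| tail an
exact two-dimensional integral for any sample sizes; it is evaluated
by Gauss-Hermite x Gauss-Legendre quadrature, so results are
deterministic. The k = 1 case reduces exactly to the pooled two-sample
t-test.

The Beavis-effect report compares a validated allele effect with the
(threshold-selected, hence upward-biased) GWA estimate of the same
contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, roots_hermite, roots_legendre

__all__ = [
    "ComparisonResult",
    "dunnett_test",
    "dunnett_max_abs_t_sf",
    "pairwise_levene",
    "snp_cross_test",
    "beavis_comparison",
]

logger = logging.getLogger(__name__)

_HERMITE_NODES = 96
_LEGENDRE_NODES = 160


@dataclass
class ComparisonResult:
    group: str
    sex: str | None
    mean_diff: float      # group - reference
    statistic: float
    P: float
    test: str             # "dunnett_mean", "levene_variance", "t_test"
    n_group: int
    n_ref: int
    unit: str = "vial"


def _quad_nodes():
    xh, wh = roots_hermite(_HERMITE_NODES)
    xl, wl = roots_legendre(_LEGENDRE_NODES)
    # map Legendre nodes from (-1, 1) to (0, 1)
    return xh * np.sqrt(2.0), wh / np.sqrt(np.pi), (xl + 1) / 2.0, wl / 2.0


_NODES = _quad_nodes()


@lru_cache(maxsize=256)
def _chi_nodes(df: int) -> np.ndarray:
    """Pooled-SD quadrature abscissae: chi_df / sqrt(df) quantiles."""
    su = _NODES[2]
    return np.sqrt(stats.chi2.ppf(su, df) / df)


def dunnett_max_abs_t_sf(t, lambdas: np.ndarray, df: int):
    """P(max_j |T_j| >= t) for the many-to-one comparison family.

    T_j share a pooled chi denominator with ``df`` degrees of freedom
    and have numerator correlations lambda_i * lambda_j. Exact under
    normality; evaluated by tensor quadrature. ``t`` may be a scalar or
    an array of thresholds (evaluated jointly).
    """
    t_arr = np.atleast_1d(np.asarray(t, float))
    lam = np.asarray(lambdas, float)
    s = np.sqrt(1.0 - lam**2)
    z, wz, _, wu = _NODES
    u = _chi_nodes(int(df))                          # denominator draws
    tu = t_arr[:, None] * u[None, :]                 # (nt, nu)
    lz = lam[None, :] * z[:, None]                   # (nz, k)
    upper = (tu[:, :, None, None] - lz[None, None, :, :]) / s
    lower = (-tu[:, :, None, None] - lz[None, None, :, :]) / s
    probs = np.prod(ndtr(upper) - ndtr(lower), axis=3)
    cdf = np.einsum("u,tuz,z->t", wu, probs, wz)
    sf = np.clip(1.0 - cdf, 0.0, 1.0)
    sf[t_arr <= 0] = 1.0
    return float(sf[0]) if np.isscalar(t) or np.ndim(t) == 0 else sf


def dunnett_test(
    groups: dict[str, np.ndarray],
    control: str,
    sex: str | None = None,
) -> list[ComparisonResult]:
    """Dunnett many-to-one comparisons of group means with a control.

    Every non-control group is compared with the control using the
    pooled within-group variance; P-values are adjusted for the family
    of k comparisons. With a single treatment the adjusted P equals the
    pooled two-sample t-test exactly.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    names = [g for g in groups if g != control]
    if not names:
        raise ValueError("no treatment groups")
    arrays = {g: np.asarray(v, float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    n0 = len(arrays[control])
    m0 = arrays[control].mean()
    ss = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df = sum(len(v) for v in arrays.values()) - len(arrays)
    if ss == 0:
        raise ValueError("zero pooled variance; comparisons undefined")
    s2 = ss / df
    lambdas = np.array([np.sqrt(len(arrays[g]) / (len(arrays[g]) + n0)) for g in names])
    diffs = np.array([arrays[g].mean() - m0 for g in names])
    ses = np.array([np.sqrt(s2 * (1 / len(arrays[g]) + 1 / n0)) for g in names])
    tstats = diffs / ses
    if len(names) == 1:
        pvals = np.array([2 * stats.t.sf(abs(tstats[0]), df)])
    else:
        pvals = dunnett_max_abs_t_sf(np.abs(tstats), lambdas, df)
    out = []
    for i, g in enumerate(names):
        v = arrays[g]
        diff = diffs[i]
        tstat = tstats[i]
        p = float(pvals[i])
        out.append(
            ComparisonResult(
                group=g, sex=sex, mean_diff=float(diff), statistic=float(tstat),
                P=max(p, np.finfo(float).tiny), test="dunnett_mean",
                n_group=len(v), n_ref=n0,
            )
        )
    return out


def pairwise_levene(
    group: np.ndarray, control: np.ndarray,
    sex: str | None = None, label: str = "group",
) -> ComparisonResult:
    """Two-group Levene test (mean-centred absolute deviations).

    A one-way ANOVA with k = 2 on |y - group mean|, testing whether the
    knockdown's within-genotype variance differs from the control's.
    """
    a = np.asarray(group, float)
    b = np.asarray(control, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    F, P = stats.levene(a, b, center="mean")
    return ComparisonResult(
        group=label, sex=sex,
        mean_diff=float(a.std(ddof=1) ** 2 - b.std(ddof=1) ** 2),
        statistic=float(F), P=float(P), test="levene_variance",
        n_group=len(a), n_ref=len(b),
    )


def snp_cross_test(
    data: pd.DataFrame,
    classes: tuple[str, str] = ("major", "minor"),
    value: str = "intake",
    unit: str = "genotype",
) -> dict[str, ComparisonResult]:
    """Major- versus minor-allele contrast from F1-cross vial data.

    ``data`` needs columns ``allele_class``, ``genotype``, ``sex`` and
    the value column. With ``unit="genotype"`` (default) each F1
    genotype is reduced to its mean and the two-sample t-test runs on
    genotype means — the genotype is the randomized experimental unit.
    If a class has a single genotype the test falls back to vial level
    with a warning. Effect = first-class mean - second-class mean.
    """
    first, second = classes
    found = set(data["allele_class"].unique())
    if set(classes) - found:
        raise ValueError(f"allele classes {classes} not both present (found {sorted(found)})")
    if len(found) != 2:
        raise ValueError(f"expected exactly two allele classes, found {sorted(found)}")
    out: dict[str, ComparisonResult] = {}
    for sex, sub in data.groupby("sex"):
        used_unit = unit
        if unit == "genotype":
            counts = sub.groupby("allele_class")["genotype"].nunique()
            if (counts < 2).any():
                logger.warning(
                    "a class has a single F1 genotype in sex %s; falling back to "
                    "vial-level units", sex,
                )
                used_unit = "vial"
        if used_unit == "genotype":
            means = sub.groupby(["allele_class", "genotype"])[value].mean()
            a = means.loc[first].to_numpy(float)
            b = means.loc[second].to_numpy(float)
        else:
            a = sub.loc[sub["allele_class"] == first, value].to_numpy(float)
            b = sub.loc[sub["allele_class"] == second, value].to_numpy(float)
        tstat, P = stats.ttest_ind(a, b, equal_var=True)
        out[str(sex)] = ComparisonResult(
            group=f"{first}-vs-{second}", sex=str(sex),
            mean_diff=float(a.mean() - b.mean()),
            statistic=float(tstat), P=float(P), test="t_test",
            n_group=len(a), n_ref=len(b), unit=used_unit,
        )
    return out


def beavis_comparison(gwa_effect: float, validated_effect: float) -> dict:
    """Compare a validated effect with its (selected) GWA estimate.

    Effect sizes estimated at loci that passed a significance threshold
    are upward-biased (the winner's-curse / Beavis effect), so the
    validated effect is expected to be smaller. Both effects must be on
    the same allele-contrast convention. Returns both values, their
    ratio (validated / GWA), the implied attenuation, and whether the
    direction replicated.
    """
    if gwa_effect == 0:
        raise ValueError("GWA effect is zero; ratio undefined")
    ratio = validated_effect / gwa_effect
    direction_replicated = ratio > 0
    if not direction_replicated:
        logger.warning("validated effect direction does not replicate the GWA sign")
    return {
        "gwa_effect": float(gwa_effect),
        "validated_effect": float(validated_effect),
        "ratio": float(ratio),
        "attenuation": float(1.0 - ratio),
        "direction_replicated": bool(direction_replicated),
    }
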