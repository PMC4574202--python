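"""REML variance components, ANOVA tables, heritability and r_GS.

Implements the two-way mixed model for per-fly intake,

    Y = mu + Sex + Line + Sex:Line + E,

with Sex fixed and Line, Sex:Line random, and the per-sex reduced model
``Y = mu + Line + E``. Variance components are estimated by restricted
maximum likelihood using average-information (AI) Newton steps with an
EM fallback that guarantees a monotone restricted likelihood, and
non-negativity enforced by projection. Standard errors come from the
inverse AI matrix at the optimum.

Because both random factors are nested within line, the marginal
covariance is block-diagonal by line; blocks with identical replication
patterns share one covariance inverse, so a 182-line panel costs a few
milliseconds per iteration.

Derived summaries: broad-sense heritability
``H2 = (s2_L + s2_SL) / (s2_L + s2_SL + s2_E)`` (pooled) or
``s2_L / (s2_L + s2_E)`` (per sex), and the cross-sex genetic
correlation ``r_GS = cov_MF / (sigma_LM * sigma_LF)`` with the
covariance of line means in the numerator and per-sex REML among-line
SDs in the denominator (a plain Pearson correlation of line means is
reported alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "MixedModelFit",
    "GeneticCorrelation",
    "fit_two_way_mixed",
    "fit_one_way_random",
    "broad_sense_heritability",
    "cross_sex_genetic_correlation",
]

logger = logging.getLogger(__name__)

REML_RTOL = 1e-10
REML_MAXIT = 200


@dataclass
class VarianceComponents:
    """REML estimates for one model fit."""

    model: str                      # "pooled", "female" or "male"
    sigma2_line: float
    sigma2_error: float
    se_line: float
    se_error: float
    sigma2_sexline: float | None = None
    se_sexline: float | None = None
    loglik: float = np.nan          # restricted log-likelihood at the optimum
    iterations: int = 0
    grad_norm: float = np.nan
    converged: bool = False
    n_obs: int = 0
    n_lines: int = 0

    def as_dict(self) -> dict:
        out = {
            "model": self.model,
            "sigma2_line": self.sigma2_line,
            "se_line": self.se_line,
            "sigma2_error": self.sigma2_error,
            "se_error": self.se_error,
            "loglik": self.loglik,
            "iterations": self.iterations,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_lines": self.n_lines,
        }
        if self.sigma2_sexline is not None:
            out["sigma2_sexline"] = self.sigma2_sexline
            out["se_sexline"] = self.se_sexline
        return out


@dataclass
class MixedModelFit:
    components: VarianceComponents
    anova: pd.DataFrame


@dataclass
class GeneticCorrelation:
    r_gs: float                # REML-denominator convention (primary)
    r_gs_raw: float            # before clamping to [-1, 1]
    r_pearson: float           # Pearson correlation of line means
    cov_mf: float
    sigma_lm: float
    sigma_lf: float
    n_lines: int
    clamped: bool


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# blocked AI-REML engine

class _BlockedREML:
    """REML for V = sum_j s_j Z_j Z_j' + s_E I, block-diagonal by line.

    ``factors`` are per-observation level codes; every factor must be
    nested within the blocking factor. Blocks with identical local
    designs are batched.
    """

    def __init__(self, y, X, block_codes, factors):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        self.n, self.p = X.shape
        self.k = len(factors)
        self.q = [len(pd.unique(f)) for f in factors]  # levels per factor
        groups: dict = {}
        codes = np.asarray(block_codes)
        for b in pd.unique(codes):
            idx = np.flatnonzero(codes == b)
            Zs = []
            for f in factors:
                local = np.asarray(f)[idx]
                levs = pd.unique(local)
                Zs.append((local[:, None] == levs[None, :]).astype(float))
            sig = (len(idx),) + tuple(Z.tobytes() for Z in Zs)
            groups.setdefault(sig, ([], Zs))[0].append(idx)
        self.groups = []
        for sig, (idxs, Zs) in groups.items():
            idx_arr = np.stack(idxs)                     # (B, n_b)
            self.groups.append(
                dict(
                    idx=idx_arr,
                    Y=y[idx_arr],                        # (B, n_b)
                    X=X[idx_arr],                        # (B, n_b, p)
                    Zs=Zs,
                    A=[Z @ Z.T for Z in Zs],
                )
            )
        self.v0 = float(np.var(y))
        self.floor = max(self.v0, 1e-12) * 1e-10

    def _assemble(self, sig):
        p, k = self.p, self.k
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        ldV = 0.0
        per_group = []
        for g in self.groups:
            nb = g["Y"].shape[1]
            V = sig[-1] * np.eye(nb)
            for j in range(k):
                V += sig[j] * g["A"][j]
            c = np.linalg.cholesky(V)
            Vi = np.linalg.inv(V)
            B = g["Y"].shape[0]
            ldV += B * 2.0 * np.sum(np.log(np.diag(c)))
            ViX = np.einsum("nm,bmp->bnp", Vi, g["X"])
            XtViX += np.einsum("bnp,bnq->pq", g["X"], ViX)
            XtViy += np.einsum("bnp,bn->p", ViX, g["Y"])
            ytViy += np.einsum("bn,nm,bm->", g["Y"], Vi, g["Y"])
            per_group.append((Vi, ViX))
        cW = np.linalg.cholesky(XtViX)
        beta = np.linalg.solve(XtViX, XtViy)
        yPy = ytViy - XtViy @ beta
        ll = -0.5 * (ldV + 2.0 * np.sum(np.log(np.diag(cW))) + yPy)
        Winv = np.linalg.inv(XtViX)

        # Py per group, then score and AI accumulators
        k1 = k + 1
        trViA = np.zeros(k1)
        T = np.zeros((k1, p, p))
        quad = np.zeros(k1)
        C = np.zeros((k1, k1))
        XtVif = np.zeros((k1, p))
        for g, (Vi, ViX) in zip(self.groups, per_group):
            B, nb = g["Y"].shape
            R = g["Y"] - g["X"] @ beta
            Py = R @ Vi                                   # (B, n_b)
            As = g["A"] + [np.eye(nb)]
            fs = [Py @ A for A in As]                     # f_j = A_j P y
            Vifs = [f @ Vi for f in fs]
            for j in range(k1):
                trViA[j] += B * np.trace(Vi @ As[j])
                ViAVi = Vi @ As[j] @ Vi
                T[j] += np.einsum("bnp,nm,bmq->pq", g["X"], ViAVi, g["X"])
                quad[j] += np.einsum("bn,bn->", Py, fs[j])
                XtVif[j] += np.einsum("bnp,bn->p", g["X"], Vifs[j])
            for i in range(k1):
                for j in range(i, k1):
                    C[i, j] += np.einsum("bn,bn->", fs[i], Vifs[j])
        trPV = np.array([trViA[j] - np.sum(Winv * T[j]) for j in range(k1)])
        score = -0.5 * (trPV - quad)
        AI = np.zeros((k1, k1))
        for i in range(k1):
            for j in range(i, k1):
                AI[i, j] = AI[j, i] = 0.5 * (
                    C[i, j] if j >= i else C[j, i]
                ) - 0.5 * XtVif[i] @ Winv @ XtVif[j]
        return ll, score, AI, trPV, quad

    def fit(self, rtol=REML_RTOL, maxit=REML_MAXIT):
        k1 = self.k + 1
        if self.v0 <= 1e-12:
            # degenerate data: no variation at all, every component is zero
            return dict(
                sigma=np.zeros(k1), se=np.zeros(k1), loglik=np.inf,
                iterations=0, grad_norm=0.0, converged=True, trace=[],
            )
        sig = np.full(k1, max(self.v0, 1e-12) / k1)
        ll, score, AI, trPV, quad = self._assemble(sig)
        trace = [(sig.copy(), ll)]
        converged = False
        it = 0
        for it in range(1, maxit + 1):
            try:
                step = np.linalg.solve(AI + 1e-12 * np.eye(k1), score)
            except np.linalg.LinAlgError:
                step = score / np.maximum(np.diag(AI), 1e-12)
            new = np.maximum(sig + step, self.floor)
            try:
                out = self._assemble(new)
                ok = out[0] >= ll - 1e-9
            except np.linalg.LinAlgError:
                ok = False
            if not ok:
                # monotone EM fallback
                qs = np.array(self.q + [self.n], float)
                new = np.maximum(
                    sig + sig**2 / qs * (quad - trPV), self.floor
                )
                out = self._assemble(new)
            rel = np.max(np.abs(new - sig) / np.maximum(np.abs(sig), self.floor))
            if out[0] < ll - 1e-6:
                raise ConvergenceError(
                    "restricted likelihood decreased; EM fallback failed", trace
                )
            sig = new
            ll, score, AI, trPV, quad = out
            trace.append((sig.copy(), ll))
            if rel < rtol:
                converged = True
                break
        if not converged:
            logger.warning("REML hit max iterations (%d); treating as non-converged", maxit)
        # zero out components pinned at the floor
        est = np.where(sig <= 2 * self.floor, 0.0, sig)
        try:
            se = np.sqrt(np.clip(np.diag(np.linalg.pinv(AI)), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(k1, np.nan)
        return dict(
            sigma=est,
            se=se,
            loglik=ll,
            iterations=it,
            grad_norm=float(np.linalg.norm(score)),
            converged=converged,
            trace=trace,
        )


# ---------------------------------------------------------------------------
# model fits

def _clean(vials: pd.DataFrame, value: str) -> pd.DataFrame:
    df = vials
    if "quarantined" in df.columns:
        df = df.loc[~df["quarantined"]]
    df = df.loc[df[value].notna(), :]
    return df


def fit_two_way_mixed(
    vials: pd.DataFrame, value: str = "intake", anova: bool = True
) -> MixedModelFit:
    """Fit Y = mu + Sex + Line + Sex:Line + E by REML.

    ``vials`` must carry ``line``, ``sex`` and the value column. Returns
    the variance components (line, sex-by-line, error) with standard
    errors plus a Type III ANOVA table with synthesized denominators
    for the random terms (skipped when ``anova=False``, e.g. inside
    simulation loops where only the components matter).
    """
    df = _clean(vials, value)
    sexes = set(df["sex"].unique())
    if sexes != {"F", "M"}:
        raise ValueError(
            f"two-way model needs both sexes; found {sorted(sexes)} "
            "(use fit_one_way_random for single-sex data)"
        )
    if df["line"].nunique() < 2:
        raise ValueError("need at least 2 lines")
    y = df[value].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), (df["sex"] == "F").astype(float)])
    line = df["line"].to_numpy()
    cell = (df["line"].astype(str) + "|" + df["sex"].astype(str)).to_numpy()
    res = _BlockedREML(y, X, line, [line, cell]).fit()
    comp = VarianceComponents(
        model="pooled",
        sigma2_line=float(res["sigma"][0]),
        sigma2_sexline=float(res["sigma"][1]),
        sigma2_error=float(res["sigma"][2]),
        se_line=float(res["se"][0]),
        se_sexline=float(res["se"][1]),
        se_error=float(res["se"][2]),
        loglik=float(res["loglik"]),
        iterations=res["iterations"],
        grad_norm=res["grad_norm"],
        converged=res["converged"],
        n_obs=len(y),
        n_lines=df["line"].nunique(),
    )
    if not comp.converged:
        raise ConvergenceError("two-way REML did not converge", res["trace"])
    table = _anova_two_way(df, value) if anova else pd.DataFrame()
    return MixedModelFit(components=comp, anova=table)


def fit_one_way_random(
    vials: pd.DataFrame, sex: str, value: str = "intake", anova: bool = True
) -> MixedModelFit:
    """Fit the per-sex reduced model Y = mu + Line + E by REML.

    For balanced data the estimates equal the ANOVA moment estimators
    ``((MS_L - MS_E) / n_reps, MS_E)`` truncated at zero.
    """
    df = _clean(vials, value)
    df = df.loc[df["sex"] == sex]
    if df.empty:
        raise ValueError(f"no records for sex {sex!r}")
    counts = df.groupby("line")[value].count()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 lines with at least 2 replicates")
    y = df[value].to_numpy(float)
    X = np.ones((len(df), 1))
    line = df["line"].to_numpy()
    res = _BlockedREML(y, X, line, [line]).fit()
    comp = VarianceComponents(
        model="female" if sex == "F" else "male",
        sigma2_line=float(res["sigma"][0]),
        sigma2_error=float(res["sigma"][1]),
        se_line=float(res["se"][0]),
        se_error=float(res["se"][1]),
        loglik=float(res["loglik"]),
        iterations=res["iterations"],
        grad_norm=res["grad_norm"],
        converged=res["converged"],
        n_obs=len(y),
        n_lines=df["line"].nunique(),
    )
    if not comp.converged:
        raise ConvergenceError("one-way REML did not converge", res["trace"])
    table = _anova_one_way(df, value) if anova else pd.DataFrame()
    return MixedModelFit(components=comp, anova=table)


# ---------------------------------------------------------------------------
# Type III ANOVA with synthesized denominators

def _sum_coded(df: pd.DataFrame):
    """Sum-to-zero-coded design pieces for sex, line and interaction."""
    n = len(df)
    intercept = np.ones((n, 1))
    sex = np.where(df["sex"].to_numpy() == "F", 1.0, -1.0)[:, None]
    lines = pd.unique(df["line"])
    L = (df["line"].to_numpy()[:, None] == lines[None, :]).astype(float)
    Lc = L[:, :-1] - L[:, -1:]
    inter = sex * Lc
    return intercept, sex, Lc, inter, L


def _rss(y, M):
    if M.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    r = y - M @ beta
    return float(r @ r)


def _proj_fro2(M, Z):
    """||P_M Z||_F^2 via least squares (column space projection)."""
    if M.shape[1] == 0:
        return 0.0
    Q, _ = np.linalg.qr(M)
    QtZ = Q.T @ Z
    return float(np.sum(QtZ * QtZ))


def _anova_two_way(df: pd.DataFrame, value: str) -> pd.DataFrame:
    y = df[value].to_numpy(float)
    one, sex, Lc, inter, L = _sum_coded(df)
    cellcodes = pd.unique(df["line"].astype(str) + "|" + df["sex"].astype(str))
    cell = (
        (df["line"].astype(str) + "|" + df["sex"].astype(str)).to_numpy()[:, None]
        == cellcodes[None, :]
    ).astype(float)

    full = np.column_stack([one, sex, Lc, inter])
    rank_full = np.linalg.matrix_rank(full)
    rss_full = _rss(y, full)
    df_err = len(y) - rank_full
    ms_err = rss_full / df_err

    terms = {
        "Sex": np.column_stack([one, Lc, inter]),
        "Line": np.column_stack([one, sex, inter]),
        "Sex x Line": np.column_stack([one, sex, Lc]),
    }
    rows = []
    ems = {}  # term -> (coef of s2_SL, coef of s2_L) in its expected mean square
    pf_L = _proj_fro2(full, L)
    pf_SL = _proj_fro2(full, cell)
    for name, red in terms.items():
        rss_red = _rss(y, red)
        dfa = rank_full - np.linalg.matrix_rank(red)
        ss = max(rss_red - rss_full, 0.0)
        c_sl = (pf_SL - _proj_fro2(red, cell)) / dfa
        c_l = (pf_L - _proj_fro2(red, L)) / dfa
        ems[name] = (c_sl, c_l)
        rows.append([name, dfa, ss, ss / dfa])

    ss_sl = rows[2][2]
    ms_sl = rows[2][3]
    df_sl = rows[2][1]
    c_sl_own = ems["Sex x Line"][0]
    out = []
    for name, dfa, ss, ms in rows:
        if name == "Sex x Line":
            denom, denom_df = ms_err, df_err
        else:
            # synthesize a * MS_SL + (1 - a) * MS_E matching the s2_SL
            # coefficient of the null expectation (Satterthwaite df)
            a = ems[name][0] / c_sl_own if c_sl_own > 0 else 0.0
            denom = a * ms_sl + (1 - a) * ms_err
            denom_df = denom**2 / (
                (a * ms_sl) ** 2 / df_sl + ((1 - a) * ms_err) ** 2 / df_err
            )
        F = ms / denom
        P = float(stats.f.sf(F, dfa, denom_df))
        out.append(
            dict(source=name, df=dfa, ss=ss, ms=ms, F=F, P=P, denom_df=denom_df)
        )
    out.append(
        dict(source="Error", df=df_err, ss=rss_full, ms=ms_err, F=np.nan, P=np.nan,
             denom_df=np.nan)
    )
    return pd.DataFrame(out)


def _anova_one_way(df: pd.DataFrame, value: str) -> pd.DataFrame:
    y = df[value].to_numpy(float)
    groups = [g.to_numpy(float) for _, g in df.groupby("line")[value]]
    k = len(groups)
    n = len(y)
    gm = y.mean()
    ss_l = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
    ss_e = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_l, df_e = k - 1, n - k
    ms_l, ms_e = ss_l / df_l, ss_e / df_e
    F = ms_l / ms_e
    P = float(stats.f.sf(F, df_l, df_e))
    return pd.DataFrame(
        [
            dict(source="Line", df=df_l, ss=ss_l, ms=ms_l, F=F, P=P, denom_df=df_e),
            dict(source="Error", df=df_e, ss=ss_e, ms=ms_e, F=np.nan, P=np.nan,
                 denom_df=np.nan),
        ]
    )


# ---------------------------------------------------------------------------
# derived summaries

def broad_sense_heritability(components: VarianceComponents | tuple, mode: str | None = None) -> float:
    """Broad-sense heritability from variance components.

    Pooled: ``(s2_L + s2_SL) / (s2_L + s2_SL + s2_E)``; per sex:
    ``s2_L / (s2_L + s2_E)``. Accepts a :class:`VarianceComponents`
    (mode inferred from its model tag) or a plain tuple
    ``(s2_L, s2_SL, s2_E)`` / ``(s2_L, s2_E)``.
    """
    if isinstance(components, VarianceComponents):
        s2l = components.sigma2_line
        s2sl = components.sigma2_sexline
        s2e = components.sigma2_error
        if mode is None:
            mode = "pooled" if components.model == "pooled" else "per_sex"
    else:
        vals = tuple(float(v) for v in components)
        if len(vals) == 3:
            s2l, s2sl, s2e = vals
            mode = mode or "pooled"
        elif len(vals) == 2:
            s2l, s2e = vals
            s2sl = None
            mode = mode or "per_sex"
        else:
            raise ValueError("expected 2 or 3 variance components")
    for v in (s2l, s2sl, s2e):
        if v is not None and (not np.isfinite(v) or v < 0):
            raise ValueError("variance components must be finite and non-negative")
    if mode == "pooled":
        if s2sl is None:
            raise ValueError("pooled H2 needs a sex-by-line component")
        total = s2l + s2sl + s2e
        if total == 0:
            raise ValueError("all variance components are zero; H2 undefined")
        return (s2l + s2sl) / total
    if mode == "per_sex":
        total = s2l + s2e
        if total == 0:
            raise ValueError("all variance components are zero; H2 undefined")
        return s2l / total
    raise ValueError(f"unknown mode {mode!r}")


def cross_sex_genetic_correlation(
    vials: pd.DataFrame,
    value: str = "intake",
    per_sex_fits: tuple[MixedModelFit, MixedModelFit] | None = None,
) -> GeneticCorrelation:
    """Cross-sex genetic correlation of line means.

    Numerator: sample covariance of female and male line means over
    lines measured in both sexes. Denominator (primary convention):
    square roots of the per-sex REML among-line variance components.
    The plain Pearson correlation of line means is reported alongside.
    If |r_GS| exceeds 1 (possible because numerator and denominators
    come from different estimators) the primary value is clamped with a
    warning and the raw value retained.
    """
    df = _clean(vials, value)
    means = df.groupby(["line", "sex"])[value].mean().unstack()
    if "F" not in means.columns or "M" not in means.columns:
        raise ValueError("both sexes required")
    complete = means.dropna()
    if len(complete) < 3:
        raise ValueError("need at least 3 lines measured in both sexes")
    cov_mf = float(np.cov(complete["F"], complete["M"], ddof=1)[0, 1])
    if per_sex_fits is None:
        fit_f = fit_one_way_random(vials, "F", value, anova=False)
        fit_m = fit_one_way_random(vials, "M", value, anova=False)
    else:
        fit_f, fit_m = per_sex_fits
    sigma_lf = float(np.sqrt(fit_f.components.sigma2_line))
    sigma_lm = float(np.sqrt(fit_m.components.sigma2_line))
    if sigma_lf == 0 or sigma_lm == 0:
        raise ValueError("a per-sex among-line component is zero; r_GS undefined")
    raw = cov_mf / (sigma_lm * sigma_lf)
    clamped = abs(raw) > 1
    if clamped:
        logger.warning("r_GS = %.3f outside [-1, 1]; clamping", raw)
    r_pearson = float(np.corrcoef(complete["F"], complete["M"])[0, 1])
    return GeneticCorrelation(
        r_gs=float(np.clip(raw, -1.0, 1.0)),
        r_gs_raw=float(raw),
        r_pearson=r_pearson,
        cov_mf=cov_mf,
        sigma_lm=sigma_lm,
        sigma_lf=sigma_lf,
        n_lines=len(complete),
        clamped=bool(clamped),
    )
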