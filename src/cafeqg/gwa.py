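"""Genome-wide association for mean and CV_E of food intake.

Inbred homozygous lines give a line-level association problem: each
line contributes one trait value per coding (female, male, their
average, or their difference — the last is formally the sex-by-line
interaction) and a 0/2 genotype per variant. The scan is two-step:

1. line-level traits are adjusted for Wolbachia infection and
   polymorphic inversion karyotypes by linear-model residuals;
2. a single-variant mixed model accounts for residual polygenic
   relatedness: the null model ``y = mu + g + e`` with
   ``g ~ N(0, s2_g * K)`` (K a centred-genotype relatedness matrix) is
   fitted once by REML, then every variant is tested by generalized
   least squares under that fixed covariance (the population-parameters-
   previously-estimated scheme).

Effects are reported per allele (half the homozygous-class difference,
since inbred genotypes move two alleles at once). Variants reaching
nominal P < 1e-5 are flagged ``top``; Bonferroni flags use
``0.05 / n_tested``. Candidate genes are assigned to a variant when its
position falls within the gene span extended by 1 kb on each side
(1-based inclusive coordinates throughout, matching variant IDs like
``3R_13637022_SNP`` and GFF3 input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "GenotypePanel",
    "GeneModel",
    "load_genotype_panel",
    "filter_variants",
    "covariate_adjust",
    "compute_grm",
    "lmm_association",
    "trait_vectors",
    "load_gene_models",
    "annotate_variants",
]

logger = logging.getLogger(__name__)

TOP_P = 1e-5
ANNOTATION_WINDOW = 1000


@dataclass
class GenotypePanel:
    """Line x variant homozygous genotype matrix with metadata.

    ``genotypes``: DataFrame indexed by line, columns variant IDs,
    values in {0, 2, NaN} (minor-allele dose; lines are fully inbred so
    heterozygotes do not occur). ``variants``: indexed by variant ID
    with ``chrom``, ``pos``, ``type``. ``covariates``: per-line frame
    (e.g. ``wolbachia``, inversion karyotype columns), optional.
    """

    genotypes: pd.DataFrame
    variants: pd.DataFrame
    covariates: pd.DataFrame | None = None

    @property
    def lines(self) -> pd.Index:
        return self.genotypes.index

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def maf(self) -> pd.Series:
        """Minor-allele frequency per variant from non-missing lines."""
        freq = self.genotypes.mean(axis=0, skipna=True) / 2.0
        return pd.Series(np.minimum(freq, 1 - freq), index=self.genotypes.columns,
                         name="maf")

    def validate(self) -> None:
        vals = self.genotypes.to_numpy(float)
        bad = ~(np.isnan(vals) | (vals == 0) | (vals == 2))
        if bad.any():
            raise ValueError("genotypes must be 0, 2 or missing (inbred homozygosity)")
        if not self.genotypes.columns.equals(self.variants.index):
            raise ValueError("variant sidecar does not match genotype columns")


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str


def load_genotype_panel(
    geno_path: str | Path,
    variants_path: str | Path,
    covariates_path: str | Path | None = None,
) -> GenotypePanel:
    """Read the tab-delimited genotype dialect written by the simulator.

    ``geno_path``: line x variant matrix, first column ``line``;
    ``variants_path``: 4 columns id/chrom/pos/type; optional per-line
    covariate table.
    """
    geno = pd.read_csv(geno_path, sep="\t", index_col=0)
    variants = pd.read_csv(variants_path, sep="\t").set_index("id")
    covariates = None
    if covariates_path is not None:
        covariates = pd.read_csv(covariates_path, sep="\t", index_col=0)
    panel = GenotypePanel(genotypes=geno, variants=variants.loc[geno.columns],
                          covariates=covariates)
    panel.validate()
    return panel


def filter_variants(
    panel: GenotypePanel, maf_min: float = 0.05, max_missing: float = 0.2
) -> GenotypePanel:
    """Drop variants below the MAF floor (inclusive boundary kept) or
    with too much missingness."""
    maf = panel.maf()
    miss = panel.genotypes.isna().mean(axis=0)
    keep = (maf >= maf_min) & (miss <= max_missing)
    n_drop = int((~keep).sum())
    logger.info("MAF/missingness filter: kept %d of %d variants",
                int(keep.sum()), panel.n_variants)
    if keep.sum() == 0:
        raise ValueError("no variants pass the MAF/missingness filter")
    return GenotypePanel(
        genotypes=panel.genotypes.loc[:, keep],
        variants=panel.variants.loc[keep],
        covariates=panel.covariates,
    )


# ---------------------------------------------------------------------------
# covariate adjustment

def covariate_adjust(
    trait: pd.Series, covariates: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Adjust a line-level trait for Wolbachia / inversion covariates.

    Fits an ordinary linear model of the trait on every covariate
    column (object/categorical columns are dummy-coded) and returns a
    per-term ANOVA table (Type III: each term dropped from the full
    model) plus the adjusted trait = residuals + grand mean. Lines with
    missing covariates are dropped with a warning; covariate columns
    with a single level are dropped (adjustment is then the identity
    for them). A rank-deficient design raises, naming aliased terms.
    """
    joined = pd.concat([trait.rename("_trait"), covariates], axis=1, join="inner")
    n_missing = int(joined.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%d line(s) dropped for missing trait/covariates", n_missing)
    joined = joined.dropna()
    y = joined["_trait"].to_numpy(float)
    terms: dict[str, np.ndarray] = {}
    for col in covariates.columns:
        v = joined[col]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            levels = sorted(v.astype(str).unique())
            if len(levels) < 2:
                logger.info("covariate %s has a single level; dropped", col)
                continue
            # sum-to-zero dummy block
            D = (v.astype(str).to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
            terms[col] = D[:, :-1] - D[:, -1:]
        else:
            arr = v.to_numpy(float)
            if np.ptp(arr) == 0:
                logger.info("covariate %s is constant; dropped", col)
                continue
            terms[col] = (arr - arr.mean())[:, None]
    one = np.ones((len(joined), 1))
    if not terms:
        table = pd.DataFrame(columns=["term", "df", "ss", "F", "P"])
        return table, trait.loc[joined.index].copy()
    full = np.column_stack([one] + list(terms.values()))
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        aliased = _aliased_terms(one, terms)
        raise ValueError(f"confounded covariates (rank-deficient design): {aliased}")
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    resid = y - full @ beta
    rss_full = float(resid @ resid)
    df_err = len(y) - full.shape[1]
    ms_err = rss_full / df_err
    rows = []
    for name in terms:
        red = np.column_stack([one] + [m for t, m in terms.items() if t != name])
        b, *_ = np.linalg.lstsq(red, y, rcond=None)
        rss_red = float(((y - red @ b) ** 2).sum())
        dfa = terms[name].shape[1]
        ss = max(rss_red - rss_full, 0.0)
        F = (ss / dfa) / ms_err
        rows.append(dict(term=name, df=dfa, ss=ss, F=F,
                         P=float(stats.f.sf(F, dfa, df_err))))
    table = pd.DataFrame(rows)
    adjusted = pd.Series(resid + y.mean(), index=joined.index, name=trait.name)
    return table, adjusted


def _aliased_terms(one, terms) -> list[str]:
    kept = [one]
    aliased = []
    for name, m in terms.items():
        cand = np.column_stack(kept + [m])
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            aliased.append(name)
        else:
            kept.append(m)
    return aliased


# ---------------------------------------------------------------------------
# relatedness and the mixed-model scan

def compute_grm(panel: GenotypePanel) -> pd.DataFrame:
    """Centred-genotype relatedness matrix, K = Mc Mc' / (m * mean var).

    Missing genotypes are replaced by the variant mean (they then
    contribute nothing to that variant's cross-products). Scaling by
    the mean per-variant variance (1/n denominator) makes the diagonal
    average exactly 1; the matrix is positive semi-definite by
    construction.
    """
    M = panel.genotypes.to_numpy(float)
    col_mean = np.nanmean(M, axis=0)
    Mc = np.where(np.isnan(M), 0.0, M - col_mean)
    var = (Mc**2).mean(axis=0)
    mean_var = var.mean()
    if mean_var == 0:
        raise ValueError("all variants monomorphic; relatedness undefined")
    K = (Mc @ Mc.T) / (Mc.shape[1] * mean_var)
    return pd.DataFrame(K, index=panel.lines, columns=panel.lines)


def _null_reml(y: np.ndarray, lam: np.ndarray, U: np.ndarray):
    """REML of y = mu + g + e with g ~ N(0, s2_g K), via K's eigensystem.

    Profiles the total variance and optimizes the heritability ratio
    h = s2_g / (s2_g + s2_e) on (0, 1) by bounded scalar search, with
    the boundary h = 0 (no polygenic signal) checked explicitly.
    """
    n = len(y)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_rll(h):
        d = h * lam + (1 - h)
        w = 1.0 / d
        xwx = np.sum(xt * xt * w)
        beta = np.sum(xt * yt * w) / xwx
        r = yt - xt * beta
        quad = np.sum(r * r * w)
        s2 = quad / (n - 1)
        return 0.5 * (
            np.sum(np.log(d)) + np.log(xwx) + (n - 1) * (np.log(s2) + 1)
        )

    res = minimize_scalar(neg_rll, bounds=(1e-6, 1 - 1e-6), method="bounded",
                          options={"xatol": 1e-10})
    h = float(res.x)
    if neg_rll(1e-12) <= res.fun:
        h = 0.0
    d = h * lam + (1 - h)
    w = 1.0 / d
    xwx = np.sum(xt * xt * w)
    beta = np.sum(xt * yt * w) / xwx
    quad = np.sum((yt - xt * beta) ** 2 * w)
    s2_total = quad / (n - 1)
    return h, s2_total


def lmm_association(
    trait: pd.Series,
    panel: GenotypePanel,
    grm: pd.DataFrame | None = None,
    coding: str = "trait",
    top_p: float = TOP_P,
    bonferroni_alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-variant mixed-model scan of a line-level trait.

    Returns one row per tested variant: ``effect`` (per allele), ``se``,
    ``t``, ``P`` (t reference, n - 2 df), ``maf``, ``n``, plus ``top``
    and ``bonferroni`` flags. With ``grm=None`` (or an identity matrix)
    the scan reduces exactly to ordinary least squares. Missing
    genotypes drop the line for that variant only.
    """
    lines = trait.dropna().index.intersection(panel.lines)
    if len(lines) < 3:
        raise ValueError("too few lines with trait and genotypes")
    if len(lines) < 30:
        logger.warning("only %d lines in the scan; power will be poor", len(lines))
    y = trait.loc[lines].to_numpy(float)
    G = panel.genotypes.loc[lines].to_numpy(float)
    n = len(y)

    if grm is None:
        h = 0.0
        lam = np.ones(n)
        U = np.eye(n)
    else:
        K = grm.loc[lines, lines].to_numpy(float)
        if K.shape != (n, n):
            raise ValueError("GRM does not cover all trait lines")
        lam, U = np.linalg.eigh(K)
        lam = np.clip(lam, 0.0, None)
        h, _ = _null_reml(y, lam, U)

    d = h * lam + (1 - h)        # variance shape under the null fit
    w = 1.0 / d
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)

    X2 = G / 2.0                  # homozygous-class indicator (0/1), possibly NaN
    complete = ~np.isnan(X2)
    effects = np.full(G.shape[1], np.nan)
    ses = np.full(G.shape[1], np.nan)
    ts = np.full(G.shape[1], np.nan)
    ps = np.full(G.shape[1], np.nan)
    ns = complete.sum(axis=0)

    full_cols = np.flatnonzero(complete.all(axis=0))
    if len(full_cols):
        Xt = U.T @ X2[:, full_cols]                    # rotated genotypes
        s0 = np.sum(w * ones_t * ones_t)
        sx = (w * ones_t) @ Xt
        sy = np.sum(w * ones_t * yt)
        sxy = (w * yt) @ Xt
        sxx = w @ (Xt * Xt)
        syy = np.sum(w * yt * yt)
        det = s0 * sxx - sx**2
        ok = det > 1e-12 * s0 * np.maximum(sxx, 1e-300)
        slope = np.where(ok, (s0 * sxy - sx * sy) / np.where(ok, det, 1.0), np.nan)
        mu = (sy - slope * sx) / s0
        # residual quadratic form per variant
        r2 = (
            syy
            - 2 * slope * sxy - 2 * mu * sy
            + slope**2 * sxx + 2 * slope * mu * sx + mu**2 * s0
        )
        dof = n - 2
        s2 = r2 / dof
        se_slope = np.sqrt(s2 * s0 / np.where(ok, det, np.nan))
        tstat = slope / se_slope
        pval = 2 * stats.t.sf(np.abs(tstat), dof)
        effects[full_cols] = slope / 2.0               # per-allele units
        ses[full_cols] = se_slope / 2.0
        ts[full_cols] = tstat
        ps[full_cols] = pval

    part_cols = np.flatnonzero(~complete.all(axis=0))
    for j in part_cols:
        mask = complete[:, j]
        if mask.sum() < 3 or np.ptp(X2[mask, j]) == 0:
            continue
        if grm is None:
            Vi = np.eye(int(mask.sum()))
        else:
            Ksub = grm.loc[lines, lines].to_numpy(float)[np.ix_(mask, mask)]
            Vi = np.linalg.inv(h * Ksub + (1 - h) * np.eye(int(mask.sum())))
        Xj = np.column_stack([np.ones(int(mask.sum())), X2[mask, j]])
        yj = y[mask]
        XtVi = Xj.T @ Vi
        cov = np.linalg.inv(XtVi @ Xj)
        beta = cov @ XtVi @ yj
        r = yj - Xj @ beta
        dof = int(mask.sum()) - 2
        s2 = float(r @ Vi @ r) / dof
        se = np.sqrt(s2 * cov[1, 1])
        tstat = beta[1] / se
        effects[j] = beta[1] / 2.0
        ses[j] = se / 2.0
        ts[j] = tstat
        ps[j] = float(2 * stats.t.sf(abs(tstat), dof))

    maf = panel.maf()
    records = pd.DataFrame(
        {
            "variant": panel.genotypes.columns,
            "coding": coding,
            "effect": effects,
            "se": ses,
            "t": ts,
            "P": ps,
            "maf": maf.to_numpy(),
            "n": ns,
        }
    )
    tested = records["P"].notna()
    n_tested = int(tested.sum())
    records["top"] = tested & (records["P"] < top_p)
    records["bonferroni"] = tested & (records["P"] < bonferroni_alpha / max(n_tested, 1))
    records.attrs["h2_null"] = h
    records.attrs["n_tested"] = n_tested
    return records.sort_values("P", kind="stable").reset_index(drop=True)


def trait_vectors(line_table: pd.DataFrame, min_reps: int = 3) -> dict[str, pd.Series]:
    """The eight trait codings scanned in the study.

    From a per line x sex summary table, build mean and CV_E vectors
    for females, males, the sex average (F+M)/2 and the sex difference
    F-M (the latter two only for lines with both sexes).
    """
    from .micro_env import cve_table

    means = line_table["mean"].unstack()
    cve, _ = cve_table(line_table, min_reps=min_reps)
    cves = cve["cve"].unstack()
    out: dict[str, pd.Series] = {}
    for label, wide in (("mean", means), ("cve", cves)):
        both = wide.dropna()
        out[f"{label}_female"] = wide.get("F", pd.Series(dtype=float)).dropna()
        out[f"{label}_male"] = wide.get("M", pd.Series(dtype=float)).dropna()
        out[f"{label}_avg"] = (both["F"] + both["M"]) / 2.0
        out[f"{label}_diff"] = both["F"] - both["M"]
    return {k: v.rename(k) for k, v in out.items()}


# ---------------------------------------------------------------------------
# gene annotation

def load_gene_models(gff_path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene spans from a GFF3 file (1-based inclusive)."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        symbol = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(gene_id=gene_id, symbol=symbol, chrom=feat.seqid,
                      start=feat.start, end=feat.end, strand=feat.strand or ".")
        )
    return genes


def annotate_variants(
    records: pd.DataFrame,
    genes: list[GeneModel],
    panel_variants: pd.DataFrame,
    window: int = ANNOTATION_WINDOW,
) -> pd.DataFrame:
    """Assign every gene within ``window`` bp of each variant.

    A variant at position p is assigned gene g when
    ``g.start - window <= p <= g.end + window`` on the same chromosome
    arm (1-based inclusive on both sides). Variants on chromosomes with
    no gene models are left unannotated with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; +1 makes the gene end inclusive
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - window, g.end + window + 1, g
        )
    known = set(trees)
    out = records.copy()
    assigned = []
    warned: set[str] = set()
    for vid in out["variant"]:
        meta = panel_variants.loc[vid]
        chrom, pos = meta["chrom"], int(meta["pos"])
        if chrom not in known:
            if chrom not in warned:
                logger.warning("no gene models for chromosome %s; variants left "
                               "unannotated", chrom)
                warned.add(chrom)
            assigned.append([])
            continue
        hits = sorted(iv.data.symbol for iv in trees[chrom][pos])
        assigned.append(hits)
    out["genes"] = assigned
    return out
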