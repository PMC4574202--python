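"""Variant filtering, covariate adjustment, GRM, LMM scan, annotation."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from cafeqg.gwa import (
    GenotypePanel,
    annotate_variants,
    compute_grm,
    covariate_adjust,
    filter_variants,
    lmm_association,
    load_gene_models,
    trait_vectors,
)


def make_panel(G, lines=None, chrom="2L"):
    n, m = G.shape
    lines = lines or [f"l{i:03d}" for i in range(n)]
    ids = [f"{chrom}_{i + 1}_SNP" for i in range(m)]
    variants = pd.DataFrame({"chrom": chrom, "pos": range(1, m + 1), "type": "SNP"},
                            index=pd.Index(ids, name="id"))
    return GenotypePanel(
        genotypes=pd.DataFrame(G, index=pd.Index(lines, name="line"), columns=ids),
        variants=variants,
    )


def random_panel(rng, n=100, m=80, maf=(0.05, 0.5)):
    freqs = rng.uniform(*maf, m)
    return make_panel(2 * (rng.random((n, m)) < freqs).astype(float))


# ---------------------------------------------------------------------------
# filtering

def test_maf_boundary_inclusive():
    n = 100
    G = np.zeros((n, 3))
    G[:4, 0] = 2    # MAF 0.04 -> removed
    G[:5, 1] = 2    # MAF 0.05 -> retained (inclusive)
    G[:50, 2] = 2   # MAF 0.50 -> retained
    panel = make_panel(G)
    kept = filter_variants(panel, maf_min=0.05)
    assert list(kept.genotypes.columns) == ["2L_2_SNP", "2L_3_SNP"]


def test_monomorphic_removed():
    G = np.zeros((20, 2))
    G[:10, 1] = 2
    kept = filter_variants(make_panel(G), maf_min=0.05)
    assert list(kept.genotypes.columns) == ["2L_2_SNP"]


def test_filter_count_matches_bruteforce(study):
    panel = study["panel"]
    kept = filter_variants(panel, maf_min=0.05)
    G = panel.genotypes.to_numpy(float)
    freq = np.nanmean(G, axis=0) / 2
    maf = np.minimum(freq, 1 - freq)
    assert kept.n_variants == int((maf >= 0.05).sum())


def test_empty_filter_result_raises():
    G = np.zeros((20, 2))
    with pytest.raises(ValueError):
        filter_variants(make_panel(G), maf_min=0.05)


# ---------------------------------------------------------------------------
# covariate adjustment

def test_single_level_covariate_is_identity():
    rng = np.random.default_rng(0)
    trait = pd.Series(rng.normal(size=30), index=[f"l{i}" for i in range(30)])
    cov = pd.DataFrame({"wolbachia": ["no"] * 30}, index=trait.index)
    table, adjusted = covariate_adjust(trait, cov)
    assert table.empty
    pd.testing.assert_series_equal(adjusted, trait)


def test_adjusted_trait_orthogonal_to_design():
    rng = np.random.default_rng(1)
    idx = [f"l{i}" for i in range(60)]
    cov = pd.DataFrame(
        {
            "wolbachia": rng.choice(["yes", "no"], 60),
            "inv3rk": rng.choice(["ST", "INV"], 60),
        },
        index=idx,
    )
    trait = pd.Series(rng.normal(12, 3, 60), index=idx)
    table, adjusted = covariate_adjust(trait, cov)
    resid = adjusted - adjusted.mean()
    for col in cov.columns:
        d = (cov[col] == cov[col].iloc[0]).astype(float)
        assert abs(np.dot(resid, d - d.mean())) < 1e-8
    assert set(table["term"]) == {"wolbachia", "inv3rk"}


def test_confounded_covariates_raise():
    rng = np.random.default_rng(2)
    idx = [f"l{i}" for i in range(20)]
    w = rng.choice(["yes", "no"], 20)
    cov = pd.DataFrame({"wolbachia": w, "copy": w}, index=idx)
    trait = pd.Series(rng.normal(size=20), index=idx)
    with pytest.raises(ValueError, match="copy"):
        covariate_adjust(trait, cov)


def test_wolbachia_detection_rate_matches_analytic_power():
    """Detection of a planted 1 uL infection effect at 182 lines tracks
    the noncentral-F power of the same two-group comparison."""
    from scipy import stats

    sd = np.sqrt(10.0)  # line-mean residual SD at study scale
    hits = 0
    n_seeds = 60
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        idx = [f"l{i}" for i in range(182)]
        infected = rng.random(182) < 0.5
        trait = pd.Series(
            12 + 1.0 * infected + rng.normal(0, sd, 182), index=idx
        )
        cov = pd.DataFrame({"wolbachia": np.where(infected, "yes", "no")}, index=idx)
        table, _ = covariate_adjust(trait, cov)
        hits += table.set_index("term").loc["wolbachia", "P"] < 0.05
    rate = hits / n_seeds
    # analytic oracle: balanced two-sample t at n = 91 per group
    ncp = 1.0 / (sd * np.sqrt(2 / 91.0))
    crit = stats.f.isf(0.05, 1, 180)
    power = stats.ncf.sf(crit, 1, 180, ncp**2)
    se = np.sqrt(power * (1 - power) / n_seeds)
    assert abs(rate - power) < 3 * se + 0.02


# ---------------------------------------------------------------------------
# GRM

def test_identical_lines_share_diagonal_value():
    rng = np.random.default_rng(3)
    G = 2 * (rng.random((10, 200)) < 0.3).astype(float)
    G[1] = G[0]
    grm = compute_grm(make_panel(G))
    assert grm.iloc[0, 1] == pytest.approx(grm.iloc[0, 0], abs=1e-12)


def test_grm_diagonal_mean_one_and_psd(study):
    grm = compute_grm(filter_variants(study["panel"]))
    assert np.diag(grm).mean() == pytest.approx(1.0, abs=1e-10)
    eig = np.linalg.eigvalsh(grm.to_numpy())
    assert eig.min() >= -1e-8
    assert np.allclose(grm, grm.T)


def test_independent_lines_have_near_zero_relatedness():
    rng = np.random.default_rng(4)
    grm = compute_grm(random_panel(rng, n=80, m=400))
    off = grm.to_numpy()[~np.eye(80, dtype=bool)]
    assert abs(off.mean()) < 0.05


# ---------------------------------------------------------------------------
# LMM scan

def test_identity_grm_equals_ols_exactly():
    rng = np.random.default_rng(5)
    panel = random_panel(rng, n=60, m=40)
    y = pd.Series(12 + 3 * rng.normal(size=60), index=panel.lines)
    eye = pd.DataFrame(np.eye(60), index=panel.lines, columns=panel.lines)
    with_eye = lmm_association(y, panel, eye).set_index("variant")
    ols = lmm_association(y, panel, None).set_index("variant")
    assert np.allclose(with_eye["effect"], ols["effect"], atol=1e-10)
    assert np.allclose(with_eye["P"], ols["P"], atol=1e-10)


def test_allele_relabel_flips_effect_keeps_p():
    rng = np.random.default_rng(6)
    panel = random_panel(rng, n=60, m=20)
    y = pd.Series(12 + 3 * rng.normal(size=60), index=panel.lines)
    rec = lmm_association(y, panel, None).set_index("variant")
    flipped = make_panel(2 - panel.genotypes.to_numpy())
    rec_f = lmm_association(y, flipped, None).set_index("variant")
    assert np.allclose(rec["effect"].to_numpy(), -rec_f["effect"].to_numpy())
    assert np.allclose(rec["P"].to_numpy(), rec_f["P"].to_numpy(), atol=1e-12)


def test_missing_genotypes_complete_case_matches_subset_scan():
    rng = np.random.default_rng(7)
    panel = random_panel(rng, n=50, m=5)
    G = panel.genotypes.to_numpy().copy()
    G[:6, 2] = np.nan
    panel_miss = make_panel(G)
    y = pd.Series(12 + rng.normal(size=50), index=panel_miss.lines)
    rec = lmm_association(y, panel_miss, None).set_index("variant")
    assert rec.loc["2L_3_SNP", "n"] == 44
    sub = make_panel(G[6:, 2:3], lines=list(panel_miss.lines[6:]))
    rec_sub = lmm_association(y.iloc[6:], sub, None).set_index("variant")
    assert rec.loc["2L_3_SNP", "P"] == pytest.approx(
        rec_sub["P"].iloc[0], rel=1e-9)


def test_null_scan_calibrated_and_confounding_corrected():
    """With family structure, the unadjusted scan is inflated while the
    GRM-adjusted scan holds its size — the reason the adjustment exists."""
    rng = np.random.default_rng(8)
    p_adj, p_un = [], []
    for _ in range(15):
        n_fam, fam_size, m, fst = 24, 5, 200, 0.3
        n = n_fam * fam_size
        p = rng.uniform(0.1, 0.5, m)
        a, b = p * (1 - fst) / fst, (1 - p) * (1 - fst) / fst
        fam = np.repeat(np.arange(n_fam), fam_size)
        G = np.zeros((n, m))
        for f in range(n_fam):
            pf = rng.beta(a, b)
            G[fam == f] = 2 * (rng.random((fam_size, m)) < pf)
        panel = make_panel(G)
        y = pd.Series(
            12 + 1.5 * rng.normal(size=n_fam)[fam] + rng.normal(size=n),
            index=panel.lines,
        )
        grm = compute_grm(panel)
        p_adj.append(lmm_association(y, panel, grm)["P"].to_numpy())
        p_un.append(lmm_association(y, panel, None)["P"].to_numpy())
    frac_adj = (np.concatenate(p_adj) < 0.05).mean()
    frac_un = (np.concatenate(p_un) < 0.05).mean()
    assert 0.025 < frac_adj < 0.075
    assert frac_un > 0.10


def test_trait_vectors_codings(study):
    traits = trait_vectors(study["line_table"])
    assert set(traits) == {
        "mean_female", "mean_male", "mean_avg", "mean_diff",
        "cve_female", "cve_male", "cve_avg", "cve_diff",
    }
    common = traits["mean_avg"].index
    f = traits["mean_female"].loc[common]
    m = traits["mean_male"].loc[common]
    assert np.allclose(traits["mean_avg"], (f + m) / 2)
    assert np.allclose(traits["mean_diff"], f - m)


# ---------------------------------------------------------------------------
# annotation

GFF = textwrap.dedent(
    """\
    ##gff-version 3
    3R\ttest\tgene\t13637196\t13640000\t.\t+\t.\tID=FBgn0001;Name=CG18012
    3R\ttest\tgene\t10000\t20000\t.\t-\t.\tID=FBgn0002;Name=geneB
    2L\ttest\tgene\t5000\t6000\t.\t+\t.\tID=FBgn0003;Name=geneC
    """
)


@pytest.fixture()
def genes(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF)
    return load_gene_models(p)


def _records_for(positions, chrom="3R"):
    ids = [f"{chrom}_{p}_SNP" for p in positions]
    rec = pd.DataFrame({"variant": ids, "P": 1e-6})
    meta = pd.DataFrame({"chrom": chrom, "pos": positions, "type": "SNP"},
                        index=pd.Index(ids, name="id"))
    return rec, meta


def test_gene_models_loaded(genes):
    byname = {g.symbol: g for g in genes}
    assert byname["CG18012"].start == 13637196
    assert byname["geneB"].strand == "-"


def test_annotation_window_boundaries(genes):
    # gene body 10000..20000: hits at exactly 1 kb beyond either end,
    # misses at 1001 bp; variant inside the body is assigned
    rec, meta = _records_for([9000, 8999, 21000, 21001, 15000])
    out = annotate_variants(rec, genes, meta, window=1000).set_index("variant")
    assert out.loc["3R_9000_SNP", "genes"] == ["geneB"]
    assert out.loc["3R_8999_SNP", "genes"] == []
    assert out.loc["3R_21000_SNP", "genes"] == ["geneB"]
    assert out.loc["3R_21001_SNP", "genes"] == []
    assert out.loc["3R_15000_SNP", "genes"] == ["geneB"]


def test_upstream_variant_within_window(genes):
    # 174 bp upstream of the CG18012 start
    rec, meta = _records_for([13637196 - 174])
    out = annotate_variants(rec, genes, meta)
    assert out["genes"].iloc[0] == ["CG18012"]


def test_unknown_chromosome_left_unannotated(genes):
    rec, meta = _records_for([5500], chrom="4")
    out = annotate_variants(rec, genes, meta)
    assert out["genes"].iloc[0] == []


def test_assignment_matches_bruteforce_scan(genes):
    rng = np.random.default_rng(9)
    positions = rng.integers(1, 30000, size=200)
    rec, meta = _records_for(sorted(set(positions.tolist())))
    out = annotate_variants(rec, genes, meta, window=1000)
    w = 1000
    for _, row in out.iterrows():
        pos = int(meta.loc[row["variant"], "pos"])
        expect = sorted(
            g.symbol for g in genes
            if g.chrom == "3R" and g.start - w <= pos <= g.end + w
        )
        assert row["genes"] == expect
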