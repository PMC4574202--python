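"""Synthetic line-structured feeding-assay and genotype data.

Generates vial-level capillary-feeder (CAFE) phenotypes and homozygous
inbred-line genotypes with the statistical structure the downstream
analyses assume: a two-way mixed model for per-fly intake

    Y = mu + L + S + L:S + E

with line (``L``) and sex-by-line (``L:S``) random effects, a fixed sex
effect, heritable within-line standard deviations (so the coefficient of
environmental variation CV_E varies genetically across lines), optional
planted mean- and variance-effect variants, a Wolbachia-like binary
covariate, and an evaporation offset per assay batch so the full
raw-data adjustment path is exercised end to end.

All randomness flows from a single integer seed through named
``numpy.random`` child streams (line effects, within-line SDs,
genotypes, covariates, evaporation, vial noise), so regenerating with
the same configuration is bit-identical and adding variants does not
perturb phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "SimulatedDataset",
    "simulate_phenotypes",
    "simulate_genotypes",
    "simulate_study",
    "write_phenotypes",
    "write_genotypes",
    "write_truth",
]

_SEXES = ("F", "M")
_ARMS = ("2L", "2R", "3L", "3R", "X")

# stream names, in spawn order; order is part of the determinism contract
_STREAMS = ("line", "sigma", "genotype", "covariate", "evaporation", "noise")


@dataclass
class SimulationConfig:
    """Parameters of one simulated inbred-line feeding study.

    Defaults reproduce the design and variance scale of the source
    study: 182 lines x 2 sexes x 6 replicate vials of 8 flies, among-line
    variance 8.21, sex-by-line variance 1.92 and mean within-line variance
    12.66 (squared intake-score units), females out-consuming males.
    """

    n_lines: int = 182
    n_reps: int = 6
    flies_per_vial: int = 8
    grand_mean: float = 12.0      # adjusted intake score, per fly
    sex_effect: float = 0.9       # mu_F - mu_M
    var_line: float = 8.21        # sigma^2_L
    var_sexline: float = 1.92     # sigma^2_SL
    var_error_mean: float = 12.66  # E[sigma^2_E] across lines
    cve_heritability: float = 0.4  # among-line share of log within-line-SD variance
    cve_dispersion: float = 0.3    # total SD of log within-line SD at heritability 1
    cross_sex_line_corr: float = 1.0  # corr of female/male line effects
    n_variants: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    # (variant index, allele-substitution effect, sex pattern in
    #  {"both", "female", "male", "opposite"})
    causal_mean_effects: Sequence[tuple[int, float, str]] = field(default_factory=list)
    # (variant index, multiplicative effect on within-line SD per minor homozygote)
    causal_var_effects: Sequence[tuple[int, float]] = field(default_factory=list)
    wolbachia_freq: float = 0.5
    wolbachia_effect: float = 0.0
    mortality: float = 0.05       # per-fly probability of dying during the assay
    evap_mean: float = 1.5        # mean evaporation per vial over 24 h (uL)
    evap_batch_sd: float = 0.2    # spread of the shared per-batch constant
    evap_noise_sd: float = 0.05   # vial-to-vial evaporation noise
    n_control_vials: int = 3      # fly-free vials per batch
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")
        for name in ("var_line", "var_sexline", "var_error_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.cve_heritability <= 1.0:
            raise ValueError("cve_heritability must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not -1.0 <= self.cross_sex_line_corr <= 1.0:
            raise ValueError("cross_sex_line_corr must be in [-1, 1]")
        for idx, _, pattern in self.causal_mean_effects:
            if not 0 <= idx < self.n_variants:
                raise ValueError(f"causal mean-effect index {idx} out of range")
            if pattern not in ("both", "female", "male", "opposite"):
                raise ValueError(f"unknown sex pattern {pattern!r}")
        for idx, mult in self.causal_var_effects:
            if not 0 <= idx < self.n_variants:
                raise ValueError(f"causal variance-effect index {idx} out of range")
            if mult <= 0:
                raise ValueError("variance-effect multipliers must be positive")


@dataclass
class SimulatedTruth:
    """Ground truth stored alongside every generated dataset."""

    line_ids: list[str]
    line_effects: pd.DataFrame       # line x sex genotypic deviations (L + L:S)
    line_sigma: pd.DataFrame         # line x sex true within-line SDs
    wolbachia: pd.Series             # line -> "yes"/"no"
    causal_mean_effects: list[tuple[int, float, str]]
    causal_var_effects: list[tuple[int, float]]
    batch_evaporation: pd.Series     # batch -> true shared offset (uL)


@dataclass
class SimulatedDataset:
    """Vial-level records, fly-free evaporation controls, and the truth."""

    vials: pd.DataFrame
    controls: pd.DataFrame
    truth: SimulatedTruth


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _line_ids(n: int) -> list[str]:
    return [f"line_{i + 1:03d}" for i in range(n)]


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw a biallelic homozygous line x variant genotype panel.

    Variants are independent (no linkage disequilibrium): each gets an
    allele frequency uniform on ``maf_range`` and each line is homozygous
    minor (coded 2) with that probability, else homozygous major (0).
    Returns a :class:`cafeqg.gwa.GenotypePanel`.
    """
    from .gwa import GenotypePanel  # local import to avoid a cycle

    config.validate()
    if rng is None:
        rng = _streams(config.seed)["genotype"]
    n, m = config.n_lines, config.n_variants
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    geno = 2 * (rng.random(size=(n, m)) < freqs).astype(np.int8)
    arms = rng.choice(_ARMS, size=m)
    pos = rng.integers(1, 25_000_000, size=m)
    variants = pd.DataFrame(
        {
            "chrom": arms,
            "pos": pos,
            "type": "SNP",
        }
    )
    variants["id"] = [
        f"{c}_{p}_{t}" for c, p, t in zip(variants.chrom, variants.pos, variants.type)
    ]
    lines = _line_ids(n)
    matrix = pd.DataFrame(geno, index=pd.Index(lines, name="line"), columns=variants["id"])
    return GenotypePanel(genotypes=matrix, variants=variants.set_index("id"))


def _draw_line_structure(config: SimulationConfig, streams) -> SimulatedTruth:
    n = config.n_lines
    lines = _line_ids(n)
    rng = streams["line"]

    # bivariate line effects with cross-sex correlation; at corr 1 this is
    # the classic shared line main effect
    r = config.cross_sex_line_corr
    z = rng.standard_normal((n, 2))
    lf = z[:, 0]
    lm = r * z[:, 0] + np.sqrt(max(0.0, 1 - r**2)) * z[:, 1]
    sd_l = np.sqrt(config.var_line)
    sl = rng.normal(0.0, np.sqrt(config.var_sexline), size=(n, 2))
    effects = pd.DataFrame(
        {"F": sd_l * lf + sl[:, 0], "M": sd_l * lm + sl[:, 1]},
        index=pd.Index(lines, name="line"),
    )

    # heritable within-line SDs: per-line log-SD effect shared between the
    # sexes; its variance is the heritable share of the log-SD dispersion.
    # The non-heritable share is carried by sampling noise of the SD itself.
    srng = streams["sigma"]
    tau2 = config.cve_heritability * config.cve_dispersion**2
    a = srng.normal(0.0, np.sqrt(tau2), size=n)
    # E[sigma^2] = exp(2 mu + 2 tau2) = var_error_mean
    mu = 0.5 * np.log(config.var_error_mean) - tau2 if config.var_error_mean > 0 else -np.inf
    sigma = np.exp(mu + a) if config.var_error_mean > 0 else np.zeros(n)
    line_sigma = pd.DataFrame(
        {"F": sigma, "M": sigma.copy()}, index=pd.Index(lines, name="line")
    )

    crng = streams["covariate"]
    wolb = pd.Series(
        np.where(crng.random(n) < config.wolbachia_freq, "yes", "no"),
        index=pd.Index(lines, name="line"),
        name="wolbachia",
    )
    return SimulatedTruth(
        line_ids=lines,
        line_effects=effects,
        line_sigma=line_sigma,
        wolbachia=wolb,
        causal_mean_effects=list(config.causal_mean_effects),
        causal_var_effects=list(config.causal_var_effects),
        batch_evaporation=pd.Series(dtype=float),
    )


def _apply_causal(config: SimulationConfig, truth: SimulatedTruth, panel) -> None:
    if panel is None:
        if config.causal_mean_effects or config.causal_var_effects:
            raise ValueError("causal effects requested but no genotype panel supplied")
        return
    geno = panel.genotypes.loc[truth.line_ids]
    for idx, alpha, pattern in config.causal_mean_effects:
        g = geno.iloc[:, idx].to_numpy(float)  # 0 / 2 minor-allele dose
        shift = alpha * g  # homozygous classes differ by 2*alpha
        if pattern in ("both", "female"):
            truth.line_effects["F"] += shift
        if pattern in ("both", "male"):
            truth.line_effects["M"] += shift
        if pattern == "opposite":
            truth.line_effects["F"] += shift
            truth.line_effects["M"] -= shift
    for idx, mult in config.causal_var_effects:
        g = geno.iloc[:, idx].to_numpy(float)
        factor = np.power(mult, g / 2.0)  # minor homozygotes get SD * mult
        truth.line_sigma["F"] *= factor
        truth.line_sigma["M"] *= factor


def simulate_phenotypes(config: SimulationConfig, panel=None) -> SimulatedDataset:
    """Generate vial-level assay records by inverting the analysis model.

    Per-fly intake for line *l*, sex *s*, vial *r* is
    ``grand_mean ± sex_effect/2 + L_ls + wolbachia + N(0, sigma_ls^2)``;
    the recorded vial value is intake x flies alive plus the batch
    evaporation offset, so the raw table must be put back through the
    evaporation / live-fly adjustment before analysis.

    Parameters
    ----------
    config : SimulationConfig
    panel : GenotypePanel, optional
        Required when the config plants causal variants; their effects
        enter the line means (mean-QTL) or within-line SDs (variance-QTL).
    """
    config.validate()
    streams = _streams(config.seed)
    truth = _draw_line_structure(config, streams)
    return _phenotypes_from_truth(config, streams, truth, panel)


def simulate_study(config: SimulationConfig):
    """Jointly draw genotypes and phenotypes so planted variants act.

    Returns ``(SimulatedDataset, GenotypePanel)``; the panel carries the
    Wolbachia status drawn for the phenotypes as a line covariate.
    """
    config.validate()
    streams = _streams(config.seed)
    panel = simulate_genotypes(config, rng=streams["genotype"]) if config.n_variants else None
    truth = _draw_line_structure(config, streams)
    # re-run phenotype generation with the already-drawn structure
    dataset = _phenotypes_from_truth(config, streams, truth, panel)
    if panel is not None:
        panel.covariates = truth.wolbachia.to_frame()
    return dataset, panel


def _phenotypes_from_truth(config, streams, truth, panel) -> SimulatedDataset:
    _apply_causal(config, truth, panel)
    reps = config.n_reps
    erng = streams["evaporation"]
    batches = [f"b{r + 1}" for r in range(reps)]
    batch_offset = pd.Series(
        config.evap_mean + erng.normal(0.0, config.evap_batch_sd, size=reps),
        index=pd.Index(batches, name="batch"),
    ).clip(lower=0.0)
    truth.batch_evaporation = batch_offset
    ctrl_rows = []
    for b in batches:
        evap = batch_offset[b] + erng.normal(0.0, config.evap_noise_sd, size=config.n_control_vials)
        for v in np.clip(evap, 0.0, None):
            ctrl_rows.append((b, float(v)))
    controls = pd.DataFrame(ctrl_rows, columns=["batch", "evap_ul"])
    nrng = streams["noise"]
    wolb_shift = np.where(truth.wolbachia.to_numpy() == "yes", config.wolbachia_effect, 0.0)
    half = config.sex_effect / 2.0
    rows = []
    for li, line in enumerate(truth.line_ids):
        for s in _SEXES:
            mu_ls = (
                config.grand_mean
                + (half if s == "F" else -half)
                + truth.line_effects.loc[line, s]
                + wolb_shift[li]
            )
            sig = truth.line_sigma.loc[line, s]
            intake = mu_ls + nrng.normal(0.0, 1.0, size=reps) * sig
            alive = config.flies_per_vial - nrng.binomial(config.flies_per_vial, config.mortality, size=reps)
            evap = batch_offset.to_numpy() + nrng.normal(0.0, config.evap_noise_sd, size=reps)
            total = intake * alive + np.clip(evap, 0.0, None)
            for r in range(reps):
                rows.append((line, s, r + 1, float(total[r]), int(alive[r]), batches[r]))
    vials = pd.DataFrame(
        rows, columns=["line", "sex", "replicate", "total_ul", "flies_alive", "batch"]
    )
    return SimulatedDataset(vials=vials, controls=controls, truth=truth)


# ---------------------------------------------------------------------------
# on-disk formats (tab-delimited text; truth as YAML)

def write_phenotypes(dataset: SimulatedDataset, outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vial_path = outdir / "vials.tsv"
    ctrl_path = outdir / "controls.tsv"
    dataset.vials.to_csv(vial_path, sep="\t", index=False)
    dataset.controls.to_csv(ctrl_path, sep="\t", index=False)
    return vial_path, ctrl_path


def write_genotypes(panel, outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno_path = outdir / "genotypes.tsv"
    var_path = outdir / "variants.tsv"
    panel.genotypes.to_csv(geno_path, sep="\t")
    panel.variants.reset_index()[["id", "chrom", "pos", "type"]].to_csv(
        var_path, sep="\t", index=False
    )
    if panel.covariates is not None:
        panel.covariates.to_csv(outdir / "covariates.tsv", sep="\t")
    return geno_path, var_path


def write_truth(truth: SimulatedTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "line_ids": truth.line_ids,
        "line_effects": {s: truth.line_effects[s].round(10).tolist() for s in _SEXES},
        "line_sigma": {s: truth.line_sigma[s].round(10).tolist() for s in _SEXES},
        "wolbachia": truth.wolbachia.tolist(),
        "causal_mean_effects": [list(t) for t in truth.causal_mean_effects],
        "causal_var_effects": [list(t) for t in truth.causal_var_effects],
        "batch_evaporation": {
            str(k): float(v) for k, v in truth.batch_evaporation.items()
        },
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def config_from_yaml(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    for key in ("causal_mean_effects", "causal_var_effects"):
        if key in raw:
            raw[key] = [tuple(item) for item in raw[key]]
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg
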