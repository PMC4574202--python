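"""Reading and reducing vial-level capillary-feeder (CAFE) assay data.

The raw unit is one vial: a group of flies of one sex and line drinking
from capillaries over 24 h. The observed capillary loss mixes true
consumption with evaporation, so each batch of vials is paired with
fly-free control vials in the same humid chamber. Adjusted per-fly
intake is

    adjusted = (total_consumed - mean evaporation of the batch) / flies_alive

Per line x sex the table is reduced to replicate count, mean intake,
within-line standard deviation (n-1 denominator) and the coefficient of
environmental variation CV_E = 100 * SD / mean.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "load_assay_table",
    "adjust_consumption",
    "summarize_lines",
]

logger = logging.getLogger(__name__)

VIAL_COLUMNS = ("line", "sex", "replicate", "total_ul", "flies_alive")
CONTROL_COLUMNS = ("batch", "evap_ul")
GLOBAL_BATCH = "all"

_SEX_SYNONYMS = {
    "f": "F", "female": "F", "females": "F",
    "m": "M", "male": "M", "males": "M",
}


class SchemaError(ValueError):
    """An input table is missing required columns or malformed."""


def _read_delimited(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str, comment="#")


def _normalize_sex(values: pd.Series) -> pd.Series:
    out = values.astype(str).str.strip().map(
        lambda v: _SEX_SYNONYMS.get(v.lower(), v.upper())
    )
    bad = sorted(set(out) - {"F", "M"})
    if bad:
        raise SchemaError(f"unrecognized sex codes: {bad}")
    return out


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[converted.isna() & df[column].notna()]
    if len(bad):
        # +2 for the header line and 1-based numbering
        rows = ", ".join(str(i + 2) for i in bad[:5])
        raise SchemaError(
            f"{path}: non-numeric values in column {column!r} at file line(s) {rows}"
        )
    return converted


def load_assay_table(
    assay_path: str | Path,
    controls_path: str | Path | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load vial records and evaporation controls from delimited text.

    Returns ``(vials, controls)``. Vials with ``flies_alive == 0`` are
    kept but marked ``quarantined`` (they carry no per-fly information);
    a warning is logged. When the assay table has no ``batch`` column a
    single global batch is assumed (the assay runs in one shared humid
    chamber), and a missing controls file yields a zero-evaporation
    control for that batch.
    """
    vials = _read_delimited(assay_path, sep)
    missing = [c for c in VIAL_COLUMNS if c not in vials.columns]
    if missing:
        raise SchemaError(f"{assay_path}: missing required column(s): {missing}")
    vials = vials.copy()
    vials["sex"] = _normalize_sex(vials["sex"])
    vials["replicate"] = _numeric(vials, "replicate", assay_path).astype(int)
    vials["total_ul"] = _numeric(vials, "total_ul", assay_path)
    vials["flies_alive"] = _numeric(vials, "flies_alive", assay_path).astype(int)
    if "batch" not in vials.columns:
        vials["batch"] = GLOBAL_BATCH

    dup = vials.duplicated(subset=["line", "sex", "replicate"], keep=False)
    if dup.any():
        pairs = vials.loc[dup, ["line", "sex", "replicate"]].drop_duplicates()
        raise SchemaError(
            f"{assay_path}: replicate indices not unique within line x sex: "
            f"{pairs.to_records(index=False).tolist()[:5]}"
        )
    n_neg_total = int((vials["total_ul"] < 0).sum())
    if n_neg_total:
        # kept, not rejected: flooring would bias low-consumption lines
        logger.warning("%d vial(s) with negative total_ul retained (will be "
                       "flagged after adjustment)", n_neg_total)

    vials["quarantined"] = vials["flies_alive"] < 1
    n_q = int(vials["quarantined"].sum())
    if n_q:
        logger.warning(
            "%d vial(s) with no flies alive quarantined (kept, excluded from analysis)",
            n_q,
        )

    if controls_path is None:
        controls = pd.DataFrame(
            {"batch": sorted(vials["batch"].unique()), "evap_ul": 0.0}
        )
        logger.warning("no evaporation controls supplied; assuming zero evaporation")
    else:
        controls = _read_delimited(controls_path, sep)
        missing = [c for c in CONTROL_COLUMNS if c not in controls.columns]
        if missing:
            raise SchemaError(f"{controls_path}: missing required column(s): {missing}")
        controls = controls.copy()
        controls["evap_ul"] = _numeric(controls, "evap_ul", controls_path)
        if (controls["evap_ul"] < 0).any():
            raise SchemaError(f"{controls_path}: negative evap_ul values")
    return vials, controls


def adjust_consumption(vials: pd.DataFrame, controls: pd.DataFrame) -> pd.DataFrame:
    """Evaporation- and live-fly-adjust vial totals to per-fly intake.

    Adds an ``intake`` column (uL/fly) and a ``negative_intake`` flag;
    negative values are retained, not floored (flooring would bias
    low-consumption lines upward). Quarantined vials get NaN intake.

    Raises
    ------
    ValueError
        If any vial's batch has no evaporation control.
    """
    batch_evap = controls.groupby("batch")["evap_ul"].mean()
    orphans = sorted(set(vials["batch"]) - set(batch_evap.index))
    if orphans:
        raise ValueError(f"batch(es) without evaporation controls: {orphans}")
    out = vials.copy()
    if "quarantined" not in out.columns:
        out["quarantined"] = out["flies_alive"] < 1
    evap = out["batch"].map(batch_evap)
    flies = out["flies_alive"].where(out["flies_alive"] >= 1)
    out["intake"] = (out["total_ul"] - evap) / flies
    out["negative_intake"] = out["intake"] < 0
    n_neg = int(out["negative_intake"].sum())
    if n_neg:
        logger.warning("%d vial(s) with negative adjusted intake flagged", n_neg)
    return out


def summarize_lines(
    adjusted: pd.DataFrame,
    value: str = "intake",
    min_reps: int = 3,
) -> pd.DataFrame:
    """Reduce adjusted vials to a per line x sex phenotype table.

    Returns a frame indexed by (line, sex) with columns ``n_reps``,
    ``mean``, ``sd`` (sample SD, n-1 denominator; NaN when n < 2),
    ``cve`` (percent; NaN when the mean is non-positive), and a boolean
    ``cve_ok`` marking cells that meet the replicate minimum and have a
    positive mean, i.e. are usable for CV_E analyses.
    """
    usable = adjusted
    if "quarantined" in usable.columns:
        usable = usable.loc[~usable["quarantined"]]
    usable = usable.loc[usable[value].notna()]
    grouped = usable.groupby(["line", "sex"])[value]
    table = grouped.agg(n_reps="count", mean="mean", sd=lambda v: v.std(ddof=1))
    table["cve"] = np.where(
        (table["mean"] > 0) & table["sd"].notna(),
        100.0 * table["sd"] / table["mean"],
        np.nan,
    )
    table["cve_ok"] = (
        (table["n_reps"] >= min_reps)
        & (table["mean"] > 0)
        & table["sd"].notna()
    )
    return table.sort_index()
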