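"""Reading, validating and writing long-format assay tables.

All tables are tidy, tab-separated UTF-8 text with a mandatory header and
one observation per row; missing values are empty fields.

An assay table carries, per row, either the two raw allele signals
(``signal_N``, ``signal_9``, arbitrary intensity units) or a precomputed
``n_fraction`` in percent — or both, in which case they must agree.
"""
from __future__ import annotations

import math
from os import PathLike
from typing import Iterable

import numpy as np
import pandas as pd

from .model import GROUPS, TISSUE_STAGE, TISSUES


class AssayFormatError(ValueError):
    """The file does not have the expected columns/shape."""


class AssayValidationError(ValueError):
    """The file parsed but carries invalid or inconsistent records."""


#: Canonical columns of a validated assay frame.
ASSAY_COLUMNS = (
    "gene_id",
    "pathway",
    "individual_id",
    "group",
    "tissue",
    "stage",
    "signal_n",
    "signal_9",
    "n_fraction",
    "below_detection",
)

_CONSISTENCY_TOL = 1e-6  # percent


def compute_n_fraction(
    signal_n: float, signal_9: float, detection_limit: float = 0.0
) -> float:
    """Percent contribution of the japonica homeolog: N/(9+N) x 100.

    Returns NaN (the *undefined* flag) when both signals are zero or both
    fall below ``detection_limit`` — the measurement then carries no
    allelic information and classifies as NO_EXPRESSION downstream.

    Raises
    ------
    ValueError
        If either signal is negative or not finite.
    """
    if not (math.isfinite(signal_n) and math.isfinite(signal_9)):
        raise ValueError("allele signals must be finite")
    if signal_n < 0 or signal_9 < 0:
        raise ValueError(
            f"allele signals must be nonnegative, got ({signal_n}, {signal_9})"
        )
    if (signal_n == 0 and signal_9 == 0) or (
        signal_n < detection_limit and signal_9 < detection_limit
    ):
        return float("nan")
    return signal_n / (signal_n + signal_9) * 100.0


def _n_fraction_array(
    signal_n: np.ndarray, signal_9: np.ndarray, detection_limit: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised n-fraction; returns (fraction with NaN, below_detection)."""
    signal_n = np.asarray(signal_n, dtype=float)
    signal_9 = np.asarray(signal_9, dtype=float)
    below = ((signal_n == 0) & (signal_9 == 0)) | (
        (signal_n < detection_limit) & (signal_9 < detection_limit)
    )
    total = signal_n + signal_9
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(below, np.nan, signal_n / np.where(total > 0, total, np.nan) * 100.0)
    return frac, below


def read_assay_table(
    path: str | PathLike, detection_limit: float = 0.0
) -> pd.DataFrame:
    """Read and validate a long-format assay table.

    Parameters
    ----------
    path
        TSV with columns ``gene_id, [pathway], individual_id, group, tissue,
        [stage], [signal_N, signal_9 | n_fraction]``.
    detection_limit
        Raw-signal threshold below which a measurement is considered
        undetected. Rows with both signals below it are retained but
        flagged ``below_detection`` (they later classify as NO_EXPRESSION).

    Returns
    -------
    DataFrame with the canonical :data:`ASSAY_COLUMNS`, one row per
    (gene, individual, tissue) measurement.
    """
    if detection_limit < 0:
        raise ValueError("detection_limit must be >= 0")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "individual_id", "group", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise AssayFormatError(f"missing required columns: {sorted(missing)}")
    has_signals = {"signal_N", "signal_9"} <= set(df.columns)
    has_fraction = "n_fraction" in df.columns
    if not (has_signals or has_fraction):
        raise AssayFormatError(
            "need either columns (signal_N, signal_9) or column n_fraction"
        )
    return validate_assay_frame(
        df, detection_limit=detection_limit, source=str(path)
    )


def _parse_float(value: str, line: int, column: str, errors: list[str]) -> float:
    if value == "":
        return float("nan")
    try:
        return float(value)
    except ValueError:
        errors.append(f"line {line}: {column}={value!r} is not a number")
        return float("nan")


def validate_assay_frame(
    df: pd.DataFrame, detection_limit: float = 0.0, source: str = "<frame>"
) -> pd.DataFrame:
    """Validate a raw (string-typed) assay frame into canonical form.

    Line numbers in error messages count the header as line 1, matching
    the on-disk file.
    """
    errors: list[str] = []
    n = len(df)
    lines = np.arange(2, n + 2)  # data starts on line 2

    gene = df["gene_id"].astype(str)
    ind = df["individual_id"].astype(str)
    group = df["group"].astype(str)
    tissue = df["tissue"].astype(str)
    pathway = df["pathway"].astype(str) if "pathway" in df.columns else pd.Series([""] * n)

    for i, (g, t) in enumerate(zip(group, tissue)):
        if g not in GROUPS:
            errors.append(f"line {lines[i]}: unknown group {g!r}")
        if t not in TISSUES:
            errors.append(f"line {lines[i]}: unknown tissue {t!r}")
    if errors:
        raise AssayValidationError(f"{source}: " + "; ".join(errors))

    stage = tissue.map(TISSUE_STAGE)
    if "stage" in df.columns:
        given = df["stage"].astype(str)
        bad = (given != "") & (given != stage)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(
                f"line {lines[i]}: tissue {tissue.iloc[i]} is sampled at "
                f"{stage.iloc[i]}, not {given.iloc[i]}"
            )

    def col_floats(name: str) -> np.ndarray:
        if name not in df.columns:
            return np.full(n, np.nan)
        return np.array(
            [
                _parse_float(v, lines[i], name, errors)
                for i, v in enumerate(df[name].astype(str))
            ]
        )

    sig_n = col_floats("signal_N")
    sig_9 = col_floats("signal_9")
    frac_given = col_floats("n_fraction")

    has_sig = ~np.isnan(sig_n) & ~np.isnan(sig_9)
    has_frac = ~np.isnan(frac_given)
    for i in np.flatnonzero(~has_sig & ~has_frac):
        errors.append(
            f"line {lines[i]}: needs either both allele signals or n_fraction"
        )
    for i in np.flatnonzero(has_sig & ((sig_n < 0) | (sig_9 < 0))):
        errors.append(f"line {lines[i]}: negative allele signal")
    for i in np.flatnonzero(has_frac & ((frac_given < 0) | (frac_given > 100))):
        errors.append(f"line {lines[i]}: n_fraction outside [0, 100]")
    if errors:
        raise AssayValidationError(f"{source}: " + "; ".join(errors))

    frac_sig, below = _n_fraction_array(
        np.where(has_sig, sig_n, 0.0), np.where(has_sig, sig_9, 0.0), detection_limit
    )
    below = below & has_sig
    # rows given only a fraction can never be flagged below-detection
    n_fraction = np.where(has_sig, frac_sig, frac_given)

    both = has_sig & has_frac & ~np.isnan(frac_sig)
    clash = both & (np.abs(frac_sig - frac_given) > _CONSISTENCY_TOL)
    for i in np.flatnonzero(clash):
        errors.append(
            f"line {lines[i]}: n_fraction {frac_given[i]:.6f} inconsistent with "
            f"signals ({frac_sig[i]:.6f})"
        )

    key = pd.MultiIndex.from_arrays([gene, ind, tissue])
    dup = key.duplicated(keep=False)
    if dup.any():
        seen = sorted({(gene.iloc[i], ind.iloc[i], tissue.iloc[i]) for i in np.flatnonzero(dup)})
        errors.append(f"duplicate (gene, individual, tissue) records: {seen[:5]}")
    if errors:
        raise AssayValidationError(f"{source}: " + "; ".join(errors))

    return pd.DataFrame(
        {
            "gene_id": gene.to_numpy(),
            "pathway": pathway.to_numpy(),
            "individual_id": ind.to_numpy(),
            "group": group.to_numpy(),
            "tissue": tissue.to_numpy(),
            "stage": stage.to_numpy(),
            "signal_n": np.where(has_sig, sig_n, np.nan),
            "signal_9": np.where(has_sig, sig_9, np.nan),
            "n_fraction": n_fraction,
            "below_detection": below,
        }
    )


def read_sample_sheet(path: str | PathLike) -> pd.DataFrame:
    """Read a sample sheet mapping individuals to plant groups."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"individual_id", "group"} - set(df.columns)
    if missing:
        raise AssayFormatError(f"sample sheet missing columns: {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        dups = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
        raise AssayValidationError(f"duplicate individual_ids in sample sheet: {dups}")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        raise AssayValidationError(
            f"unknown groups in sample sheet: {sorted(df.loc[bad, 'group'].unique())}"
        )
    return df[["individual_id", "group"]].copy()


def check_individuals(records: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Require that every assayed individual appears in the sample sheet."""
    known = set(sheet["individual_id"])
    unknown = sorted(set(records["individual_id"]) - known)
    if unknown:
        raise AssayValidationError(
            f"individuals missing from sample sheet: {unknown}"
        )


def read_calibration_table(path: str | PathLike) -> pd.DataFrame:
    """Read a calibration table of known DNA mix ratios vs observed fractions.

    Columns: ``gene_id, ratio_n, ratio_9, observed_fraction``. An
    ``expected_fraction`` column is derived from the mix ratio.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "ratio_n", "ratio_9", "observed_fraction"} - set(df.columns)
    if missing:
        raise AssayFormatError(f"calibration table missing columns: {sorted(missing)}")
    if (df["ratio_n"] <= 0).any() or (df["ratio_9"] <= 0).any():
        raise AssayValidationError("mix ratio parts must be positive")
    obs = df["observed_fraction"]
    if ((obs < 0) | (obs > 100)).any():
        raise AssayValidationError("observed_fraction outside [0, 100]")
    out = df.copy()
    out["expected_fraction"] = (
        df["ratio_n"] / (df["ratio_n"] + df["ratio_9"]) * 100.0
    )
    return out


def write_table(df: pd.DataFrame, path: str | PathLike) -> None:
    """Write a tidy TSV (tab-separated, empty fields for missing values)."""
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")
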