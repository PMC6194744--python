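"""Known-ratio calibration QC for allele-specific assays.

Genome-specificity of each gene's primer/probe set is validated with
parental DNA mixed in known ratios (1:3, 1:2, 1:1, 2:1, 3:1). The observed
N-fraction is regressed on the expected one and the assay passes when the
squared correlation exceeds a threshold (R^2 > 0.9 by default, strict
inequality). Fractions rather than raw ratios are used as the regression
variable: they are bounded and symmetric in the two alleles, whereas
ratio space is unbounded and asymmetric.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model import CalibrationResult

#: The five standard mix ratios (N parts, 9 parts).
STANDARD_RATIOS: tuple[tuple[int, int], ...] = ((1, 3), (1, 2), (1, 1), (2, 1), (3, 1))

DEFAULT_R2_THRESHOLD = 0.9


class CalibrationError(ValueError):
    """Degenerate or insufficient calibration data."""


def expected_fraction_from_ratio(ratio_n: float, ratio_9: float) -> float:
    """Expected N-fraction (percent) of a ratio_n : ratio_9 DNA mix."""
    if ratio_n <= 0 or ratio_9 <= 0:
        raise ValueError("mix ratio parts must be positive")
    return ratio_n / (ratio_n + ratio_9) * 100.0


def fit_calibration(
    points: pd.DataFrame,
    threshold: float = DEFAULT_R2_THRESHOLD,
    gene_id: str | None = None,
) -> CalibrationResult:
    """Fit observed vs expected N-fraction for one gene's mixes.

    ``points`` needs columns ``expected_fraction`` and
    ``observed_fraction`` (plus ``gene_id`` unless given explicitly).
    Ordinary least squares of observed on expected; ``r_squared`` is the
    squared Pearson correlation, which coincides with the regression R^2
    for a simple linear fit.
    """
    if gene_id is None:
        genes = points["gene_id"].unique()
        if len(genes) != 1:
            raise ValueError(f"expected one gene per fit, got {list(genes)}")
        gene_id = str(genes[0])
    x = points["expected_fraction"].to_numpy(dtype=float)
    y = points["observed_fraction"].to_numpy(dtype=float)
    if len(x) < 2:
        raise CalibrationError(f"{gene_id}: need >= 2 calibration points, got {len(x)}")
    if np.ptp(x) == 0:
        raise CalibrationError(
            f"{gene_id}: all expected fractions identical ({x[0]}); degenerate design"
        )
    if np.ptp(y) == 0:
        # constant observed response carries zero correlation
        slope, intercept, r2 = 0.0, float(y[0]), 0.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2
    return CalibrationResult(
        gene_id=gene_id,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        passed=r2 > threshold,
        n_points=len(x),
    )


def fit_all(
    calibration: pd.DataFrame, threshold: float = DEFAULT_R2_THRESHOLD
) -> pd.DataFrame:
    """Fit every gene in a calibration table; one row per gene."""
    rows = [
        fit_calibration(sub, threshold=threshold, gene_id=str(gene))
        for gene, sub in calibration.groupby("gene_id", sort=True)
    ]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "slope": [r.slope for r in rows],
            "intercept": [r.intercept for r in rows],
            "r_squared": [r.r_squared for r in rows],
            "n_points": [r.n_points for r in rows],
            "passed": [r.passed for r in rows],
        }
    )


def filter_assays(
    results: Iterable[CalibrationResult] | pd.DataFrame,
    records: pd.DataFrame,
    strict: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only records of genes whose calibration passed.

    Parameters
    ----------
    results
        Per-gene :class:`CalibrationResult` objects or a frame from
        :func:`fit_all`.
    records
        Validated assay frame.
    strict
        If True, a record gene without any calibration is an error;
        otherwise such genes are dropped with a warning.

    Returns
    -------
    (kept records, QC report frame with a row per gene and its fate).
    """
    if isinstance(results, pd.DataFrame):
        passed = dict(zip(results["gene_id"], results["passed"]))
    else:
        passed = {r.gene_id: r.passed for r in results}
    genes = pd.unique(records["gene_id"])
    uncalibrated = [g for g in genes if g not in passed]
    if uncalibrated:
        if strict:
            raise CalibrationError(
                f"genes without calibration: {sorted(uncalibrated)}"
            )
        warnings.warn(
            f"dropping {len(uncalibrated)} uncalibrated genes: {sorted(uncalibrated)}",
            stacklevel=2,
        )
    fate = {
        g: ("pass" if passed.get(g) else "fail" if g in passed else "uncalibrated")
        for g in genes
    }
    report = pd.DataFrame(
        {"gene_id": list(genes), "qc": [fate[g] for g in genes]}
    ).sort_values("gene_id").reset_index(drop=True)
    keep = records["gene_id"].map(lambda g: fate.get(g) == "pass")
    return records.loc[keep].reset_index(drop=True), report
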