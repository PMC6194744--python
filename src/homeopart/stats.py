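"""Nonparametric comparisons of TSS scores.

Two tests, both two-sided:

- Mann-Whitney rank-sum for independent samples (between plant groups,
  or root vs leaf within a group).
- Wilcoxon matched-pairs signed-rank for within-individual contrasts
  (e.g. the same individuals scored at both growth stages).

Small samples (n1 + n2 <= 12, or <= 12 nonzero pairs) are evaluated by
exact enumeration of all group labelings resp. sign assignments, which
handles ties exactly; larger samples use the normal approximation with
tie and continuity corrections. P-values are reported unadjusted, with an
optional Holm-adjusted column for multi-contrast reports.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import TestResult

#: Largest combined sample size evaluated by exact enumeration.
EXACT_LIMIT = 12

# enough resamples that scipy enumerates exactly: C(12,6) = 924 labelings,
# 2^12 = 4096 sign vectors
_EXACT = sps.PermutationMethod(n_resamples=10_000)


def _mw_exact_single(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p when one sample has a single value."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, a.size

    def u_of(idx: tuple[int, ...]) -> float:
        sel = set(idx)
        xa = pooled[list(idx)]
        xb = pooled[[i for i in range(n) if i not in sel]]
        return float(np.sum(xa[:, None] > xb) + 0.5 * np.sum(xa[:, None] == xb))

    observed = u_of(tuple(range(n1)))
    us = [u_of(idx) for idx in combinations(range(n), n1)]
    ge = sum(u >= observed for u in us)
    le = sum(u <= observed for u in us)
    return observed, min(1.0, 2 * min(ge, le) / len(us))


def mann_whitney(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = 0.05
) -> TestResult:
    """Two-sided Mann-Whitney rank-sum test.

    Exact by enumeration of all C(n1+n2, n1) labelings when
    n1 + n2 <= 12 (ties handled exactly); otherwise the normal
    approximation with tie and continuity corrections. The statistic is
    the U of ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if a.size + b.size <= EXACT_LIMIT:
        if min(a.size, b.size) == 1:
            # enumeration over labelings, done directly (the resampling
            # machinery needs >= 2 observations per sample)
            u, p = _mw_exact_single(a, b)
            return TestResult(
                test="MANN_WHITNEY", statistic=u, p_value=p,
                n1=int(a.size), n2=int(b.size), alpha=alpha, method="exact",
            )
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=_EXACT)
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return TestResult(
        test="MANN_WHITNEY",
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        n1=int(a.size),
        n2=int(b.size),
        alpha=alpha,
        method=method,
    )


def wilcoxon_matched(
    pairs: Iterable[tuple[float, float]] | np.ndarray, alpha: float = 0.05
) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped. Exact by enumeration of all 2^k sign
    assignments for k <= 12 nonzero pairs; otherwise the normal
    approximation with tie and continuity corrections. If every
    difference is zero the result is degenerate (p = 1, flagged).
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an iterable of (x, y) tuples")
    if arr.shape[0] == 0:
        raise ValueError("need at least one pair")
    diffs = arr[:, 0] - arr[:, 1]
    nz = diffs[diffs != 0]
    n = arr.shape[0]
    if nz.size == 0:
        return TestResult(
            test="WILCOXON_MATCHED", statistic=0.0, p_value=1.0,
            n1=n, n2=n, alpha=alpha, method="exact", degenerate=True,
        )
    if nz.size == 1:
        # two sign assignments, each with probability 1/2: p is always 1
        return TestResult(
            test="WILCOXON_MATCHED", statistic=float(nz[0] < 0),
            p_value=1.0, n1=n, n2=n, alpha=alpha, method="exact",
        )
    if nz.size <= EXACT_LIMIT:
        res = sps.wilcoxon(nz, alternative="two-sided", method=_EXACT)
        method = "exact"
    else:
        res = sps.wilcoxon(
            nz, alternative="two-sided", method="approx", correction=True
        )
        method = "asymptotic"
    return TestResult(
        test="WILCOXON_MATCHED",
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        n1=n,
        n2=n,
        alpha=alpha,
        method=method,
    )


@dataclass(frozen=True)
class Contrast:
    """One comparison between two cells of the score table.

    A cell is a (group, tissue_set) pair. ``test`` is ``"mann_whitney"``
    (independent samples) or ``"wilcoxon_matched"`` (paired on
    individual_id, e.g. the same plants at two stages).
    """

    name: str
    test: str
    cell_a: tuple[str, str]
    cell_b: tuple[str, str]


def default_design(scores: pd.DataFrame) -> list[Contrast]:
    """The comparisons reported throughout the study, for available cells.

    Between-group Mann-Whitney for every group pair within each
    within-stage set; Mann-Whitney root-vs-leaf development TSS within
    each group; paired Wilcoxon tillering-vs-booting within each group.
    """
    cells = set(map(tuple, scores[["group", "tissue_set"]].drop_duplicates().to_numpy()))
    groups = sorted({g for g, _ in cells})
    design: list[Contrast] = []
    for ts in ("tillering", "booting", "all"):
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                if (ga, ts) in cells and (gb, ts) in cells:
                    design.append(
                        Contrast(f"{ga}_vs_{gb}_{ts}", "mann_whitney", (ga, ts), (gb, ts))
                    )
    for g in groups:
        if (g, "root_dev") in cells and (g, "leaf_dev") in cells:
            design.append(
                Contrast(f"{g}_root_vs_leaf_dev", "mann_whitney", (g, "root_dev"), (g, "leaf_dev"))
            )
        if (g, "tillering") in cells and (g, "booting") in cells:
            design.append(
                Contrast(f"{g}_tillering_vs_booting", "wilcoxon_matched", (g, "tillering"), (g, "booting"))
            )
    return design


def _cell(scores: pd.DataFrame, cell: tuple[str, str]) -> pd.DataFrame:
    g, ts = cell
    return scores[(scores["group"] == g) & (scores["tissue_set"] == ts)]


def compare_all(
    scores: pd.DataFrame,
    design: Sequence[Contrast] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run a list of contrasts over a per-individual score table.

    Returns one row per contrast with the raw two-sided p-value, a
    Holm-adjusted p-value, and the significance call at ``alpha`` on the
    raw p-value (no correction was applied in the original analysis; the
    Holm column is provided alongside).
    """
    if design is None:
        design = default_design(scores)
    rows = []
    for c in design:
        da, db = _cell(scores, c.cell_a), _cell(scores, c.cell_b)
        if da.empty or db.empty:
            warnings.warn(f"contrast {c.name}: missing cell, skipped", stacklevel=2)
            continue
        if c.test == "mann_whitney":
            res = mann_whitney(da["percent_tss"], db["percent_tss"], alpha=alpha)
        elif c.test == "wilcoxon_matched":
            merged = da.merge(
                db, on="individual_id", suffixes=("_a", "_b"), how="inner"
            )
            if merged.empty:
                warnings.warn(
                    f"contrast {c.name}: no shared individuals, skipped", stacklevel=2
                )
                continue
            res = wilcoxon_matched(
                merged[["percent_tss_a", "percent_tss_b"]].to_numpy(), alpha=alpha
            )
        else:
            raise ValueError(f"unknown test {c.test!r} in contrast {c.name}")
        rows.append(
            {
                "contrast": c.name,
                "test": res.test,
                "statistic": res.statistic,
                "n1": res.n1,
                "n2": res.n2,
                "p_value": res.p_value,
                "method": res.method,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "contrast", "test", "statistic", "n1", "n2",
            "p_value", "method", "degenerate",
        ],
    )
    if not out.empty:
        out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
        out["significant"] = out["p_value"] < alpha
    else:
        out["p_holm"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
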