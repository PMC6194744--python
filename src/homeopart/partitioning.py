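"""Tissue-specific silencing, subfunctionalization and nonfunctionalization.

For a gene x individual and a set of tissues, each homeolog's calls are
split into tissues where it is *silenced* (complete bias against it),
*expressed*, or neutral (NO_EXPRESSION, which is evidence for neither):

- **TSS** (tissue-specific silencing): the homeolog is silenced in at
  least one measured tissue of the set and expressed in at least one
  other. Within-stage TSS uses the tillering or booting tissue sets (or
  all six tissues); development TSS uses the leaf or root pair across the
  two growth stages.
- **Reciprocal TSS** (subfunctionalization): both homeologs of a gene
  have TSS events in the same set — the duplicates partition the
  expression domain. Recorded once per gene x individual x set.
- **Nonfunctionalization**: a homeolog silenced in *all* measured tissues
  of the set.

A gene x individual needs at least two measured tissues in a set to be
scorable; otherwise it is excluded from both numerator and denominator
(TSS is undefined without a contrast).

The TSS percentage for an individual counts (gene, homeolog, tissue)
triples: the numerator is the number of triples where the homeolog is
silenced in that tissue as part of a TSS event, the denominator the
number of triples with a measured call among scorable genes. An
alternative convention counting each gene once per tissue (collapsing
homeologs) is available via ``unit="gene"``.
"""
from __future__ import annotations

from dataclasses import asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    EventKind,
    HOMEOLOGS,
    PartitionEvent,
    TISSUE_SETS,
    resolve_tissue_set,
)


class InsufficientDataError(ValueError):
    """Not enough measured tissues/genes to score."""


def _set_summary(calls: pd.DataFrame, members: Sequence[str]) -> pd.DataFrame:
    """Per gene x individual summary of silencing within a tissue set.

    Columns: group, n_meas, sil_N, exp_N, sil_9, exp_9, eligible,
    tss_N, tss_9, nonfunc_N, nonfunc_9, reciprocal.
    """
    sub = calls[calls["tissue"].isin(members)]
    if sub.empty:
        return pd.DataFrame(
            columns=[
                "gene_id", "individual_id", "group", "n_meas",
                "sil_N", "exp_N", "sil_9", "exp_9", "eligible",
                "tss_N", "tss_9", "nonfunc_N", "nonfunc_9", "reciprocal",
            ]
        )
    g = sub.groupby(["gene_id", "individual_id"], sort=True, observed=True)
    out = g.agg(
        group=("group", "first"),
        n_meas=("tissue", "size"),
        sil_N=("silenced_n", "sum"),
        exp_N=("expressed_n", "sum"),
        sil_9=("silenced_9", "sum"),
        exp_9=("expressed_9", "sum"),
    ).reset_index()
    out["eligible"] = out["n_meas"] >= 2
    for h in HOMEOLOGS:
        sil, exp = out[f"sil_{h}"], out[f"exp_{h}"]
        out[f"tss_{h}"] = out["eligible"] & (sil >= 1) & (exp >= 1)
        out[f"nonfunc_{h}"] = out["eligible"] & (sil == out["n_meas"])
    out["reciprocal"] = out["tss_N"] & out["tss_9"]
    return out


def detect_tss(
    calls: pd.DataFrame, tissue_set: str | Sequence[str]
) -> list[PartitionEvent]:
    """List partitioning events for every gene x individual in ``calls``.

    ``calls`` is a classified assay frame (see
    :func:`homeopart.bias.classify_table`); pass a single gene x
    individual's rows to evaluate just that locus. Gene x individual
    pairs with fewer than two measured tissues in the set yield no
    events (they are insufficient-data, excluded from scoring).
    """
    set_name, members = resolve_tissue_set(tissue_set)
    sub = calls[calls["tissue"].isin(members)]
    events: list[PartitionEvent] = []
    for (gene, ind), grp in sub.groupby(["gene_id", "individual_id"], sort=True):
        if len(grp) < 2:
            continue
        group = grp["group"].iloc[0]
        tss_homeologs = []
        for h, sil_col, exp_col in (
            ("N", "silenced_n", "expressed_n"),
            ("9", "silenced_9", "expressed_9"),
        ):
            sil = tuple(t for t in members if t in set(grp.loc[grp[sil_col], "tissue"]))
            exp = tuple(t for t in members if t in set(grp.loc[grp[exp_col], "tissue"]))
            if sil and len(sil) == len(grp):
                events.append(
                    PartitionEvent(
                        gene_id=gene, individual_id=ind, group=group,
                        homeolog=h, tissue_set=set_name,
                        kind=EventKind.NONFUNCTIONALIZATION,
                        silenced_in=sil, expressed_in=(),
                    )
                )
            elif sil and exp:
                events.append(
                    PartitionEvent(
                        gene_id=gene, individual_id=ind, group=group,
                        homeolog=h, tissue_set=set_name, kind=EventKind.TSS,
                        silenced_in=sil, expressed_in=exp,
                    )
                )
                tss_homeologs.append(h)
        if len(tss_homeologs) == 2:
            events.append(
                PartitionEvent(
                    gene_id=gene, individual_id=ind, group=group,
                    homeolog=None, tissue_set=set_name,
                    kind=EventKind.RECIPROCAL_TSS,
                )
            )
    return events


def events_to_frame(events: Iterable[PartitionEvent]) -> pd.DataFrame:
    """Tidy frame of events (tissue lists comma-joined)."""
    rows = []
    for e in events:
        d = asdict(e)
        d["kind"] = e.kind.value
        d["homeolog"] = e.homeolog or ""
        d["silenced_in"] = ",".join(e.silenced_in)
        d["expressed_in"] = ",".join(e.expressed_in)
        rows.append(d)
    cols = [
        "gene_id", "individual_id", "group", "homeolog", "tissue_set",
        "kind", "silenced_in", "expressed_in",
    ]
    return pd.DataFrame(rows, columns=cols)


def score_tss(
    calls: pd.DataFrame,
    tissue_set: str | Sequence[str],
    unit: str = "homeolog",
) -> pd.DataFrame:
    """Per-individual TSS percentage over a tissue set.

    Returns one row per individual with ``numerator``, ``denominator``
    and ``percent_tss``. ``unit="homeolog"`` counts (gene, homeolog,
    tissue) triples (the default); ``unit="gene"`` counts each gene once
    per tissue, a tissue contributing when either homeolog is TSS-silenced
    there.
    """
    if unit not in ("homeolog", "gene"):
        raise ValueError(f"unit must be 'homeolog' or 'gene', got {unit!r}")
    set_name, members = resolve_tissue_set(tissue_set)
    summ = _set_summary(calls, members)
    summ = summ[summ["eligible"]]
    if summ.empty:
        raise InsufficientDataError(
            f"no gene x individual with >= 2 measured tissues in set {set_name!r}"
        )
    num_n = np.where(summ["tss_N"], summ["sil_N"], 0)
    num_9 = np.where(summ["tss_9"], summ["sil_9"], 0)
    if unit == "homeolog":
        numerator = num_n + num_9
        denominator = 2 * summ["n_meas"].to_numpy()
    else:
        # a tissue counts once if either homeolog is TSS-silenced in it;
        # within one tissue both cannot be silenced simultaneously (that
        # would be NO_EXPRESSION), so the counts simply add
        numerator = num_n + num_9
        denominator = summ["n_meas"].to_numpy()
    per = pd.DataFrame(
        {
            "individual_id": summ["individual_id"].to_numpy(),
            "group": summ["group"].to_numpy(),
            "numerator": numerator,
            "denominator": denominator,
        }
    )
    scores = (
        per.groupby(["individual_id", "group"], sort=True, observed=True)
        .sum()
        .reset_index()
    )
    scores.insert(1, "tissue_set", set_name)
    scores["percent_tss"] = scores["numerator"] / scores["denominator"] * 100.0
    return scores


def score_development_tss(
    calls: pd.DataFrame, organ: str, unit: str = "homeolog"
) -> pd.DataFrame:
    """TSS caused by development: same organ compared across the stages.

    ``organ`` is ``"leaf"`` (L1 vs L2) or ``"root"`` (R1 vs R2). A
    homeolog counts when silenced at one stage and expressed at the
    other.
    """
    sets = {"leaf": "leaf_dev", "root": "root_dev"}
    if organ not in sets:
        raise ValueError(f"organ must be 'leaf' or 'root', got {organ!r}")
    return score_tss(calls, sets[organ], unit=unit)


def score_all(
    calls: pd.DataFrame,
    tissue_sets: Iterable[str] = ("tillering", "booting", "all", "leaf_dev", "root_dev"),
    unit: str = "homeolog",
) -> pd.DataFrame:
    """Concatenated per-individual scores over several tissue sets."""
    frames = []
    for ts in tissue_sets:
        try:
            frames.append(score_tss(calls, ts, unit=unit))
        except InsufficientDataError:
            continue
    if not frames:
        raise InsufficientDataError("no tissue set could be scored")
    return pd.concat(frames, ignore_index=True)


def summarize_groups(scores: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean TSS percentage with standard error.

    One row per (group, tissue_set): ``mean_percent_tss``,
    ``se`` (sample SD / sqrt(n); NaN when n = 1) and ``n`` individuals.
    """
    def _agg(s: pd.Series) -> pd.Series:
        n = len(s)
        return pd.Series(
            {
                "mean_percent_tss": s.mean(),
                "se": s.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n": n,
            }
        )

    out = (
        scores.groupby(["group", "tissue_set"], sort=True, observed=True)["percent_tss"]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def count_reciprocal(
    events: Iterable[PartitionEvent], groups: Sequence[str] | None = None
) -> int:
    """Number of reciprocal-TSS cases, optionally restricted to groups."""
    return sum(
        1
        for e in events
        if e.kind is EventKind.RECIPROCAL_TSS
        and (groups is None or e.group in groups)
    )
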