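"""Shared data model for homeolog expression partitioning.

The experimental design assayed here: a japonica ("N") x indica ("9") rice
system with four plant groups — an in-vitro parental RNA mix (MIX), F1
hybrids, and reciprocal synthetic allotetraploids (NN99, 99NN) — each
individual sampled in up to six tissues across two growth stages: mature
leaf (L1) and root (R1) at tillering; mature leaf (L2), root (R2), flag
leaf (F) and young spike (S) at booting.

Every measurement is the relative contribution of the japonica homeolog to
total transcripts, the *N-fraction*: N/(9+N) x 100.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

#: Plant groups. PARENT_N / PARENT_9 are the pure parents (used for
#: calibration mixes), the remaining four are the assayed groups.
GROUPS: tuple[str, ...] = ("PARENT_N", "PARENT_9", "MIX", "F1", "NN99", "99NN")

#: The four groups whose expression partitioning is scored.
ASSAY_GROUPS: tuple[str, ...] = ("MIX", "F1", "NN99", "99NN")

#: The two allotetraploid groups.
TETRAPLOID_GROUPS: tuple[str, ...] = ("NN99", "99NN")

#: The two homeologs / parental alleles.
HOMEOLOGS: tuple[str, str] = ("N", "9")

TISSUES: tuple[str, ...] = ("L1", "R1", "L2", "R2", "F", "S")

STAGES: tuple[str, str] = ("TILLERING", "BOOTING")

#: Fixed tissue -> growth-stage mapping of the sampling design.
TISSUE_STAGE: dict[str, str] = {
    "L1": "TILLERING",
    "R1": "TILLERING",
    "L2": "BOOTING",
    "R2": "BOOTING",
    "F": "BOOTING",
    "S": "BOOTING",
}

#: Tissue classes used to parameterise silencing probabilities.
TISSUE_CLASS: dict[str, str] = {
    "L1": "leaf",
    "L2": "leaf",
    "R1": "root",
    "R2": "root",
    "F": "flag",
    "S": "spike",
}

#: Named tissue sets over which tissue-specific silencing is scored.
#: "tillering" / "booting" compare tissues within one growth stage,
#: "all" spans all six tissues, and the *_dev sets compare the same organ
#: across the two stages (development-specific silencing).
TISSUE_SETS: dict[str, tuple[str, ...]] = {
    "tillering": ("L1", "R1"),
    "booting": ("L2", "R2", "F", "S"),
    "all": ("L1", "R1", "L2", "R2", "F", "S"),
    "leaf_dev": ("L1", "L2"),
    "root_dev": ("R1", "R2"),
}


class BiasCategory(str, enum.Enum):
    """Relative-expression category of one measurement.

    The seven numeric categories partition the N-fraction axis [0, 100];
    NO_EXPRESSION is the separate both-copies-silent state (both allele
    signals below the detection limit).
    """

    COMPLETE_9 = "COMPLETE_9"    # [0, 5): japonica copy silenced
    STRONG_9 = "STRONG_9"        # [5, 20)
    BIASED_9 = "BIASED_9"        # [20, 40)
    EQUIVALENT = "EQUIVALENT"    # [40, 60)
    BIASED_N = "BIASED_N"        # [60, 80)
    STRONG_N = "STRONG_N"        # [80, 95)
    COMPLETE_N = "COMPLETE_N"    # [95, 100]: indica copy silenced
    NO_EXPRESSION = "NO_EXPRESSION"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Mirror pairs under f -> 100 - f (away from interval boundaries).
MIRROR_CATEGORY: dict[BiasCategory, BiasCategory] = {
    BiasCategory.COMPLETE_9: BiasCategory.COMPLETE_N,
    BiasCategory.STRONG_9: BiasCategory.STRONG_N,
    BiasCategory.BIASED_9: BiasCategory.BIASED_N,
    BiasCategory.EQUIVALENT: BiasCategory.EQUIVALENT,
    BiasCategory.BIASED_N: BiasCategory.BIASED_9,
    BiasCategory.STRONG_N: BiasCategory.STRONG_9,
    BiasCategory.COMPLETE_N: BiasCategory.COMPLETE_9,
}


class EventKind(str, enum.Enum):
    """Kinds of expression-partitioning events for a gene x individual."""

    TSS = "TSS"
    RECIPROCAL_TSS = "RECIPROCAL_TSS"
    NONFUNCTIONALIZATION = "NONFUNCTIONALIZATION"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PartitionEvent:
    """One expression-partitioning finding for a gene x individual.

    ``homeolog`` is ``"N"`` or ``"9"`` for TSS / nonfunctionalization and
    ``None`` for reciprocal TSS (which involves both homeologs).
    ``silenced_in`` / ``expressed_in`` are the tissues of ``tissue_set``
    where the homeolog was called silenced resp. expressed.
    """

    gene_id: str
    individual_id: str
    group: str
    homeolog: str | None
    tissue_set: str
    kind: EventKind
    silenced_in: tuple[str, ...] = ()
    expressed_in: tuple[str, ...] = ()


@dataclass(frozen=True)
class CalibrationResult:
    """Observed-vs-expected fit of one gene's known-ratio DNA mixes."""

    gene_id: str
    slope: float
    intercept: float
    r_squared: float
    passed: bool
    n_points: int


@dataclass(frozen=True)
class TestResult:
    """Outcome of one nonparametric comparison."""

    test: str                 # "MANN_WHITNEY" | "WILCOXON_MATCHED"
    statistic: float
    p_value: float
    n1: int
    n2: int
    alpha: float = 0.05
    method: str = "exact"     # "exact" | "asymptotic"
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def resolve_tissue_set(tissue_set: str | Sequence[str]) -> tuple[str, tuple[str, ...]]:
    """Return ``(name, members)`` for a named or explicit tissue set."""
    if isinstance(tissue_set, str):
        if tissue_set not in TISSUE_SETS:
            raise KeyError(
                f"unknown tissue set {tissue_set!r}; known: {sorted(TISSUE_SETS)}"
            )
        return tissue_set, TISSUE_SETS[tissue_set]
    members = tuple(tissue_set)
    if not members:
        raise ValueError("tissue set must be nonempty")
    unknown = [t for t in members if t not in TISSUES]
    if unknown:
        raise ValueError(f"unknown tissues in set: {unknown}")
    return "+".join(members), members
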