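"""Synthetic assay data with the study's structure and known ground truth.

The generator emulates a MassARRAY-style allele-ratio survey: 30 genes
drawn from eight key pathways, measured in six tissues (L1, R1 at
tillering; L2, R2, F, S at booting) across four plant groups (MIX n=6,
F1 n=6, NN99 n=7, 99NN n=7), with group- and tissue-class-dependent
silencing frequencies and bounded beta-distributed measurement noise on
the allelic fraction.

Per gene x individual x tissue, each homeolog is independently silenced
with a configurable probability; a homeolog may instead be
nonfunctionalized (silenced in every tissue), and reciprocal
tissue-specific silencing patterns (the two homeologs silenced in
complementary tissues) can be injected either at random or at a
deterministic count for bookkeeping tests. A tissue with both homeologs
silenced emits no signal (the no-expression state).

True N-fractions are the gene's baseline bias when both copies are
expressed, or epsilon / 100 - epsilon under single-homeolog silencing
(a small leak keeps classification exercised near the 5% / 95% category
boundaries). Observed fractions add beta noise parameterised by a mean
and a concentration; raw allele signals are emitted so the reader path
is exercised end to end.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.polynomial.legendre import leggauss
from scipy import stats as sps

from .model import (
    ASSAY_GROUPS,
    HOMEOLOGS,
    TISSUE_CLASS,
    TISSUE_SETS,
    TISSUE_STAGE,
    TISSUES,
    resolve_tissue_set,
)

#: Pathway labels used to name synthetic genes (eight key pathways:
#: circadian/photomorphogenesis, chromosome regulators, housekeeping, ion
#: transport, chlorophyll metabolism, photosynthesis, nitrogen metabolism,
#: TCA cycle).
PATHWAYS: tuple[str, ...] = ("CP", "CR", "HK", "IP", "Chl", "PS", "N", "TCA")

#: Booting-stage tissues used for reciprocal-TSS injection.
_BOOTING = TISSUE_SETS["booting"]

SilencingMap = Mapping[tuple[str, str, str], float]


def uniform_silencing(p: float, groups: Sequence[str] = ASSAY_GROUPS) -> dict:
    """A silencing map with one probability everywhere."""
    classes = sorted(set(TISSUE_CLASS.values()))
    return {(g, c, h): p for g in groups for c in classes for h in HOMEOLOGS}


def silencing_from_nested(nested: Mapping) -> dict:
    """Build a silencing map from ``{group: {class: p | {homeolog: p}}}``."""
    out: dict[tuple[str, str, str], float] = {}
    for g, classes in nested.items():
        for c, v in classes.items():
            if isinstance(v, Mapping):
                for h, p in v.items():
                    out[(g, c, str(h))] = float(p)
            else:
                for h in HOMEOLOGS:
                    out[(g, c, h)] = float(v)
    return out


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    The default group sizes and tissue panel mirror the study design;
    the default silencing map is the null model (nothing silenced).
    Use :func:`paper_like` for the study-conditions preset.
    """

    n_genes: int = 30
    group_sizes: dict = field(
        default_factory=lambda: {"MIX": 6, "F1": 6, "NN99": 7, "99NN": 7}
    )
    silencing_prob: dict = field(default_factory=lambda: uniform_silencing(0.0))
    reciprocal_prob: dict = field(default_factory=dict)  # group -> prob
    inject_reciprocal: dict = field(default_factory=dict)  # group -> exact count
    nonfunc_prob: float = 0.0
    baseline_mean: float = 50.0          # percent
    baseline_concentration: float = 8.0  # beta concentration of gene baselines
    noise_concentration: float = 500.0   # beta noise precision; inf = no noise
    detection_dropout: float = 0.0
    silenced_leak: float = 1.0           # epsilon, percent
    total_signal: float = 1000.0         # arbitrary intensity units
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g} size must be >= 1")
        probs = list(self.silencing_prob.values()) + list(self.reciprocal_prob.values())
        probs += [self.nonfunc_prob, self.detection_dropout]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < self.baseline_mean < 100:
            raise ValueError("baseline_mean must be in (0, 100)")
        if self.baseline_concentration <= 0 or self.noise_concentration <= 0:
            raise ValueError("concentration parameters must be > 0")
        if not 0 <= self.silenced_leak < 50:
            raise ValueError("silenced_leak must be in [0, 50) percent")

    def silencing(self, group: str, tissue: str, homeolog: str) -> float:
        return float(self.silencing_prob.get((group, TISSUE_CLASS[tissue], homeolog), 0.0))


def paper_like(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-conditions preset.

    Per-tissue, per-homeolog silencing frequencies encode the study's
    qualitative structure: F1 hybrids nearly free of silencing, the
    parental mix and both tetraploids substantially higher, the 99NN
    direction above NN99, and roots well above leaves (which drives
    development-specific TSS). Reciprocal-TSS patterns are injected in
    the tetraploids at a low per-locus rate, and a small
    nonfunctionalization rate silences an occasional homeolog everywhere.
    """
    silencing = silencing_from_nested(
        {
            "MIX": {"leaf": 0.08, "root": 0.12, "flag": 0.08, "spike": 0.08},
            "F1": {"leaf": 0.02, "root": 0.02, "flag": 0.02, "spike": 0.02},
            "NN99": {"leaf": 0.06, "root": 0.20, "flag": 0.08, "spike": 0.08},
            "99NN": {"leaf": 0.08, "root": 0.28, "flag": 0.10, "spike": 0.10},
        }
    )
    cfg = SimulationConfig(
        silencing_prob=silencing,
        reciprocal_prob={"NN99": 0.03, "99NN": 0.03},
        nonfunc_prob=0.01,
        noise_concentration=500.0,
        detection_dropout=0.02,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def config_from_yaml(path: str | PathLike) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file.

    ``silencing_prob`` may be nested ``{group: {class: p}}`` or a single
    number applied uniformly; ``preset: paper_like`` starts from the
    study preset and applies the remaining keys as overrides.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    preset = raw.pop("preset", None)
    if "silencing_prob" in raw:
        sp = raw["silencing_prob"]
        raw["silencing_prob"] = (
            uniform_silencing(float(sp)) if isinstance(sp, (int, float))
            else silencing_from_nested(sp)
        )
    if preset == "paper_like":
        return paper_like(**raw)
    if preset is not None:
        raise ValueError(f"unknown preset {preset!r}")
    return SimulationConfig(**raw)


def _individuals(config: SimulationConfig) -> tuple[list[str], list[str]]:
    ids, groups = [], []
    for g, n in config.group_sizes.items():
        for k in range(1, n + 1):
            ids.append(f"{g}_{k}")
            groups.append(g)
    return ids, groups


def simulate(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one dataset; returns ``(records, truth)``.

    ``records`` is a validated assay frame (canonical columns, raw allele
    signals plus derived n_fraction); ``truth`` has one row per gene x
    individual x tissue with the pre-noise state of each homeolog
    (``expressed`` / ``silenced``), the true N-fraction, the
    reciprocal-injection flag and the dropout flag. The same seed yields
    byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    G = config.n_genes
    gene_ids = np.array(
        [f"{PATHWAYS[i % len(PATHWAYS)]}{i + 1:02d}" for i in range(G)]
    )
    pathways = np.array([PATHWAYS[i % len(PATHWAYS)] for i in range(G)])
    ind_ids, ind_groups = _individuals(config)
    I, T = len(ind_ids), len(TISSUES)
    n = G * I * T

    gi = np.repeat(np.arange(G), I * T)
    ii = np.tile(np.repeat(np.arange(I), T), G)
    ti = np.tile(np.arange(T), G * I)
    group_of = np.array(ind_groups)[ii]
    tissue_of = np.array(TISSUES)[ti]

    # gene baselines (percent), shared across individuals and tissues
    m0 = config.baseline_mean / 100.0
    c0 = config.baseline_concentration
    baseline = rng.beta(m0 * c0, (1 - m0) * c0, size=G) * 100.0

    # per-tissue independent silencing draws
    p_n = np.array(
        [config.silencing(g, t, "N") for g, t in zip(group_of, tissue_of)]
    )
    p_9 = np.array(
        [config.silencing(g, t, "9") for g, t in zip(group_of, tissue_of)]
    )
    sil_n = rng.random(n) < p_n
    sil_9 = rng.random(n) < p_9

    # nonfunctionalization: a homeolog silenced in every tissue
    nf_n = rng.random(G * I) < config.nonfunc_prob
    nf_9 = rng.random(G * I) < config.nonfunc_prob
    slot = gi * I + ii  # gene x individual slot of each row

    # reciprocal-TSS injection: N silenced in one booting tissue, 9 in
    # another; random per locus, skipped when either homeolog is
    # nonfunctionalized
    group_of_slot = np.array(ind_groups)[np.tile(np.arange(I), G)]
    r_prob = np.array(
        [config.reciprocal_prob.get(g, 0.0) for g in group_of_slot]
    )
    inject = (rng.random(G * I) < r_prob) & ~nf_n & ~nf_9
    t1 = rng.integers(0, len(_BOOTING), size=G * I)
    t2 = (t1 + rng.integers(1, len(_BOOTING), size=G * I)) % len(_BOOTING)

    # deterministic placement: first k gene x individual slots per group
    # (gene-major order), fixed tissues (N off in L2, 9 off in R2);
    # nonfunctionalization is cleared there so the count stays exact
    if config.inject_reciprocal:
        for g, k in config.inject_reciprocal.items():
            slots = np.flatnonzero(group_of_slot == g)[:k]
            inject[slots] = True
            nf_n[slots] = False
            nf_9[slots] = False
            t1[slots] = _BOOTING.index("L2")
            t2[slots] = _BOOTING.index("R2")

    sil_n |= nf_n[slot]
    sil_9 |= nf_9[slot]
    booting_idx = np.array([TISSUES.index(t) for t in _BOOTING])
    forced_n = inject[slot] & (ti == booting_idx[t1][slot])
    forced_9 = inject[slot] & (ti == booting_idx[t2][slot])
    sil_n |= forced_n
    sil_9 |= forced_9

    both = sil_n & sil_9
    eps = config.silenced_leak
    true_frac = np.where(
        sil_n & ~sil_9, eps, np.where(sil_9 & ~sil_n, 100.0 - eps, baseline[gi])
    )

    if math.isinf(config.noise_concentration):
        obs = true_frac.copy()
    else:
        c = config.noise_concentration
        m = np.clip(true_frac / 100.0, 1e-9, 1 - 1e-9)
        obs = rng.beta(m * c, (1 - m) * c) * 100.0

    signal_n = np.where(both, 0.0, config.total_signal * obs / 100.0)
    signal_9 = np.where(both, 0.0, config.total_signal - signal_n)
    dropped = rng.random(n) < config.detection_dropout

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids[gi],
            "individual_id": np.array(ind_ids)[ii],
            "group": group_of,
            "tissue": tissue_of,
            "state_n": np.where(both, "no_expression", np.where(sil_n, "silenced", "expressed")),
            "state_9": np.where(both, "no_expression", np.where(sil_9, "silenced", "expressed")),
            "true_fraction": np.where(both, np.nan, true_frac),
            "reciprocal_injected": inject[slot],
            "dropped": dropped,
        }
    )
    records = pd.DataFrame(
        {
            "gene_id": gene_ids[gi],
            "pathway": pathways[gi],
            "individual_id": np.array(ind_ids)[ii],
            "group": group_of,
            "tissue": tissue_of,
            "stage": pd.Series(tissue_of).map(TISSUE_STAGE).to_numpy(),
            "signal_n": signal_n,
            "signal_9": signal_9,
            "n_fraction": np.where(both, np.nan, obs),
            "below_detection": both,
        }
    )[~dropped].reset_index(drop=True)
    return records, truth


def records_to_raw(records: pd.DataFrame) -> pd.DataFrame:
    """The on-disk raw-table view (columns as read_assay_table expects)."""
    out = records[
        ["gene_id", "pathway", "individual_id", "group", "tissue", "signal_n", "signal_9"]
    ].rename(columns={"signal_n": "signal_N"})
    return out


def simulate_calibration(
    gene_ids: Sequence[str],
    noise_sd: float = 2.0,
    n_bad: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic known-ratio calibration table.

    Each gene is measured at the five standard mixes (1:3, 1:2, 1:1,
    2:1, 3:1) with Gaussian read-out noise (``noise_sd`` percent,
    truncated to [0, 100]). The last ``n_bad`` genes respond flat at 50%
    regardless of the mix, emulating a probe without genome specificity.
    """
    from .calibration import STANDARD_RATIOS, expected_fraction_from_ratio

    rng = np.random.default_rng(seed)
    rows = []
    bad = set(gene_ids[len(gene_ids) - n_bad:]) if n_bad else set()
    for g in gene_ids:
        for rn, r9 in STANDARD_RATIOS:
            exp = expected_fraction_from_ratio(rn, r9)
            center = 50.0 if g in bad else exp
            obs = float(np.clip(center + rng.normal(0.0, noise_sd), 0.0, 100.0))
            rows.append(
                {
                    "gene_id": g,
                    "ratio_n": rn,
                    "ratio_9": r9,
                    "observed_fraction": obs,
                    "expected_fraction": exp,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analytic expectation of the TSS percentage under the generator
# ---------------------------------------------------------------------------

def _call_probs(config: SimulationConfig) -> tuple[float, float]:
    """(q_sil, q_cross): P(called silenced | truly silenced) and
    P(called silenced | partner silenced, i.e. true fraction 100-eps)."""
    if math.isinf(config.noise_concentration):
        return (1.0 if config.silenced_leak < 5.0 else 0.0), 0.0
    c = config.noise_concentration
    m = config.silenced_leak / 100.0
    q_sil = float(sps.beta.cdf(0.05, m * c, (1 - m) * c))
    m_hi = 1 - m
    q_cross = float(sps.beta.cdf(0.05, m_hi * c, (1 - m_hi) * c))
    return q_sil, q_cross


def _baseline_nodes(config: SimulationConfig, n_nodes: int = 48):
    """Gauss-Legendre nodes/weights for integrating over gene baselines."""
    x, w = leggauss(n_nodes)
    b = 0.5 * (x + 1.0)  # map to (0, 1)
    m0 = config.baseline_mean / 100.0
    c0 = config.baseline_concentration
    pdf = sps.beta.pdf(b, m0 * c0, (1 - m0) * c0)
    weights = 0.5 * w * pdf
    return b, weights / weights.sum()  # normalise the quadrature mass


def expected_tss_percent(
    config: SimulationConfig, group: str, tissue_set: str | Sequence[str]
) -> float:
    """Exact expected TSS percentage for one group over a tissue set.

    Computes E[numerator] / E[denominator] of the per-individual score
    under the generator, by conditioning on nonfunctionalization of each
    homeolog and on reciprocal-injection placement, and using the
    independence of per-tissue call states within each conditioning
    stratum. Noise misclassification enters through the beta-noise CDF;
    the false-silencing rate of a co-expressed tissue is integrated over
    the gene-baseline distribution. The E-ratio approximation is exact up
    to O(1/n_genes) and negligible at the default 30 genes.
    """
    config.validate()
    _, members = resolve_tissue_set(tissue_set)
    T = len(members)
    d = config.detection_dropout
    g_nf = config.nonfunc_prob
    r = float(config.reciprocal_prob.get(group, 0.0))
    q_sil, q_cross = _call_probs(config)
    b_nodes, b_weights = _baseline_nodes(config)

    # false-silencing probability of a co-expressed tissue at baseline b
    if math.isinf(config.noise_concentration):
        fp_n = (b_nodes * 100.0 < 5.0).astype(float)
        fp_9 = (b_nodes * 100.0 >= 95.0).astype(float)
    else:
        c = config.noise_concentration
        fp_n = sps.beta.cdf(0.05, b_nodes * c, (1 - b_nodes) * c)
        fp_9 = sps.beta.sf(0.95, b_nodes * c, (1 - b_nodes) * c)

    booting_in_set = [t for t in _BOOTING]
    pairs = [
        (a, b) for a in booting_in_set for b in booting_in_set if a != b
    ]

    def e_num_homeolog(h: str, nf_h: bool, nf_o: bool, forced_h, forced_o) -> np.ndarray:
        """E[TSS numerator] for homeolog h given the conditioning, as a
        vector over baseline nodes."""
        fp = fp_n if h == "N" else fp_9
        s_list, e_list = [], []
        for t in members:
            p_h = 1.0 if (nf_h or t == forced_h) else config.silencing(group, t, h)
            other = "9" if h == "N" else "N"
            p_o = 1.0 if (nf_o or t == forced_o) else config.silencing(group, t, other)
            s_t = (
                p_h * (1 - p_o) * q_sil
                + (1 - p_h) * p_o * q_cross
                + (1 - p_h) * (1 - p_o) * fp
            )
            e_t = (
                p_h * (1 - p_o) * (1 - q_sil)
                + (1 - p_h) * p_o * (1 - q_cross)
                + (1 - p_h) * (1 - p_o) * (1 - fp)
            )
            s_list.append((1 - d) * s_t)
            e_list.append((1 - d) * e_t)
        # fp is a vector over baseline nodes, so s_t/e_t are (nodes,) each
        s = np.array(s_list)  # shape (T, nodes)
        e = np.array(e_list)
        # E[#SIL * 1(#EXP >= 1)] = sum_t s_t (1 - prod_{u != t} (1 - e_u))
        one_minus_e = 1.0 - e
        prod_all = np.prod(one_minus_e, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            prod_wo = np.where(one_minus_e > 0, prod_all / one_minus_e, 0.0)
        # recompute exactly where (1 - e_u) == 0 (leave-one-out product)
        zero_cols = np.flatnonzero((one_minus_e <= 0).any(axis=0))
        for j in zero_cols:
            for t in range(T):
                prod_wo[t, j] = np.prod(np.delete(one_minus_e[:, j], t))
        return np.sum(s * (1.0 - prod_wo), axis=0)

    def weighted_num(h: str) -> float:
        total = np.zeros_like(b_nodes)
        for nf_h, w_h in ((True, g_nf), (False, 1 - g_nf)):
            for nf_o, w_o in ((True, g_nf), (False, 1 - g_nf)):
                w = w_h * w_o
                if w == 0:
                    continue
                if nf_h or nf_o or r == 0:
                    total += w * e_num_homeolog(h, nf_h, nf_o, None, None)
                else:
                    total += w * (1 - r) * e_num_homeolog(h, False, False, None, None)
                    for tn, t9 in pairs:
                        fh, fo = (tn, t9) if h == "N" else (t9, tn)
                        total += (
                            w * r / len(pairs)
                        ) * e_num_homeolog(h, False, False, fh, fo)
        return float(np.sum(total * b_weights))

    # E[measured * 1(measured >= 2)] per homeolog
    e_den = T * (1 - d) - T * (1 - d) * d ** (T - 1)
    num = weighted_num("N") + weighted_num("9")
    return 100.0 * num / (2 * e_den)


# ---------------------------------------------------------------------------
# recovery of truth from calls
# ---------------------------------------------------------------------------

def _truth_events(truth: pd.DataFrame, members: Sequence[str]) -> pd.DataFrame:
    """Per (gene, individual, homeolog) truth TSS/nonfunc flags over a set."""
    sub = truth[truth["tissue"].isin(members) & ~truth["dropped"]]
    rows = []
    for (gene, ind), grp in sub.groupby(["gene_id", "individual_id"], sort=True):
        if len(grp) < 2:
            continue
        for h in HOMEOLOGS:
            state = grp[f"state_{'n' if h == 'N' else '9'}"]
            n_sil = int((state == "silenced").sum())
            n_exp = int((state == "expressed").sum())
            rows.append(
                {
                    "gene_id": gene,
                    "individual_id": ind,
                    "homeolog": h,
                    "tss": n_sil >= 1 and n_exp >= 1,
                    "nonfunc": n_sil == len(grp),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "individual_id", "homeolog", "tss", "nonfunc"])


def recovery_report(
    truth: pd.DataFrame,
    events: Iterable,
    tissue_set: str | Sequence[str],
) -> dict:
    """Sensitivity/specificity of TSS and nonfunctionalization calls.

    Compares detected events against the generator's pre-noise states at
    the (gene, individual, homeolog) level, over the gene x individual
    pairs with at least two measured tissues in the set. With noise off
    and no dropout both sensitivities and specificities are 1.
    """
    from .model import EventKind

    set_name, members = resolve_tissue_set(tissue_set)
    t = _truth_events(truth, members)
    units = set(zip(t["gene_id"], t["individual_id"], t["homeolog"]))
    called_tss, called_nf = set(), set()
    for e in events:
        if e.tissue_set != set_name or e.homeolog is None:
            continue
        key = (e.gene_id, e.individual_id, e.homeolog)
        if key not in units:
            raise ValueError(f"event for unknown unit {key}")
        if e.kind is EventKind.TSS:
            called_tss.add(key)
        elif e.kind is EventKind.NONFUNCTIONALIZATION:
            called_nf.add(key)

    def _rates(truth_flags: pd.Series, called: set) -> dict:
        keys = list(zip(t["gene_id"], t["individual_id"], t["homeolog"]))
        is_true = truth_flags.to_numpy(bool)
        is_called = np.array([k in called for k in keys])
        tp = int((is_true & is_called).sum())
        fn = int((is_true & ~is_called).sum())
        fp = int((~is_true & is_called).sum())
        tn = int((~is_true & ~is_called).sum())
        return {
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        }

    return {
        "tissue_set": set_name,
        "n_units": len(t),
        "tss": _rates(t["tss"], called_tss),
        "nonfunctionalization": _rates(t["nonfunc"], called_nf),
    }
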