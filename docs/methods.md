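# Methods

## Data model

A dataset is a long-format table with one row per gene x individual x
tissue measurement, carrying either raw allele intensities
(`signal_N`, `signal_9`) or a precomputed N-fraction in percent (or
both, checked for consistency to 1e-6). The tissue-to-stage mapping is
fixed by the sampling design (L1, R1 at tillering; L2, R2, F, S at
booting) and contradictions are rejected, as are duplicate
(gene, individual, tissue) records. The N-fraction

    f = signal_N / (signal_N + signal_9) x 100

is undefined — flagged, not a number — when both signals are zero or
both fall below the detection limit; such records are retained and
classify as NO_EXPRESSION. The detection limit defaults to 0 (only
exact double zeros are undetected) because the platform publishes no
threshold; it is a parameter of `read_assay_table` for instruments
with a known noise floor.

## Bias classification

The seven categories partition [0, 100] with left-closed half-open
intervals, the top interval closed at 100: [0,5) completely 9-biased,
[5,20) strongly 9-biased, [20,40) 9-biased, [40,60) equivalent, [60,80)
N-biased, [80,95) strongly N-biased, [95,100] completely N-biased.
Boundary membership is a convention: the bands are printed as touching
ranges, so a deterministic tie-break is required, and under continuous
measurement noise the choice affects only measure-zero inputs. Only the
two complete-bias categories generate allele-specific silencing calls
(completely 9-biased silences N, completely N-biased silences 9);
NO_EXPRESSION silences both copies at once and is kept as its own
state — it is deliberately *not* evidence of allele-specific silencing.
"Equal" vs "unequal" expression of the two copies is operationalised as
the equivalent band vs any other expressed category, the only equality
band the scheme defines.

## Calibration QC

Genome-specificity of each assay is validated on parental DNA mixed at
1:3, 1:2, 1:1, 2:1 and 3:1 (expected N-fractions 25, 33.3, 50, 66.7,
75). Observed is regressed on expected by ordinary least squares and
R² is the squared Pearson correlation — identical to the regression R²
for a simple linear fit, and symmetric in which axis is regressed. An
assay passes at R² > 0.9, strict inequality. Fractions rather than raw
N:9 ratios are the regression variable: fraction space is bounded and
treats the two alleles symmetrically, whereas ratio space is unbounded
and asymmetric under allele exchange. Degenerate designs (fewer than
two points, or all expected values identical) are errors, not silent
zeros; a flat observed response is R² = 0. Filtering drops all records
of failing genes; genes with no calibration at all are an error in
strict mode and a warning-plus-drop in lenient mode.

## Silencing partitioning

Tissue sets: `tillering` {L1, R1}, `booting` {L2, R2, F, S}, `all`
(six tissues), and the development pairs `leaf_dev` {L1, L2} and
`root_dev` {R1, R2} comparing the same organ across stages. For one
gene x individual and set, per homeolog:

- **TSS**: silenced in >= 1 measured tissue of the set and expressed in
  >= 1 other.
- **Nonfunctionalization**: silenced in *all* measured tissues. A
  homeolog therefore never carries both calls for the same set.
- **Reciprocal TSS**: both homeologs have TSS events in the set;
  recorded once per gene x individual x set, matching the counting of
  discrete subfunctionalization cases.

NO_EXPRESSION tissues are neutral: they count as neither silenced nor
expressed for either homeolog, since the both-off state is defined
separately from allele silencing. A gene x individual needs at least
two measured tissues in the set; otherwise it is excluded from both
sides of the score (TSS is undefined without a contrast).

The per-individual score counts (gene, homeolog, tissue) triples:
numerator = triples where the homeolog is silenced in that tissue as
part of a TSS event; denominator = measured triples of scorable genes;
%TSS = 100 x numerator / denominator. This is the only reading of a
"per (gene x tissue)" percentage that spans both homeologs and yields
one number per individual. Because the unit is genuinely ambiguous, a
second convention counting each gene once per tissue is available via
`unit="gene"`; the default is the homeolog-triple unit. Group summaries
report the mean over individuals ± standard error (sample SD / sqrt(n);
undefined-flagged for singleton groups).

## Nonparametric tests

Mann-Whitney (independent samples) and Wilcoxon matched-pairs
(within-individual contrasts), both two-sided. For n1 + n2 <= 12
(Mann-Whitney) or <= 12 nonzero pairs (Wilcoxon, zero differences
dropped) the p-value is exact by complete enumeration of labelings /
sign assignments, which handles ties without approximation; beyond
that, the normal approximation with tie and continuity corrections is
used, and the output records which route was taken. The continuity
correction makes mid-range approximate p-values deliberately
conservative (up to ~0.05 above the exact value at n = 7 per group);
in the rejection region the two agree to well under 0.01, and the null
rejection rate at alpha = 0.05 is calibrated (checked at [0.03, 0.07]
over 5,000 simulations). P-values are reported unadjusted — matching
the original single-comparison reporting style — with a Holm-adjusted
column alongside for modern multi-contrast use. An all-zero-difference
Wilcoxon input yields a degenerate, flagged p = 1.

## Synthetic data generator

The generator emulates the study design: 30 genes named after eight
key pathways, groups MIX (6), F1 (6), NN99 (7), 99NN (7), six tissues
per individual. What it models:

- **Silencing**: per gene x individual x tissue, each homeolog is
  independently silenced with probability `silencing_prob[(group,
  tissue class, homeolog)]` where tissue classes are leaf {L1, L2},
  root {R1, R2}, flag {F} and spike {S}.
- **Nonfunctionalization**: with probability `nonfunc_prob` a homeolog
  is silenced in every tissue of a gene x individual.
- **Reciprocal TSS injection**: with probability `reciprocal_prob[group]`
  (or a deterministic per-group count for bookkeeping tests, placed in
  the first gene x individual slots with N off in L2 and 9 off in R2),
  the two homeologs are forced silent in two distinct booting tissues.
- **True fractions**: the gene's baseline bias (drawn once per gene
  from a beta distribution with mean `baseline_mean` = 50% and
  concentration 8, giving a realistic spread of parental expression
  differences across genes) when both copies are on; epsilon or
  100 - epsilon under single-copy silencing, with leak epsilon = 1% so
  classification is exercised near the 5%/95% boundaries rather than at
  exactly 0/100. Both copies silenced emits zero signals (NO_EXPRESSION).
- **Noise**: observed fractions are beta-distributed around the truth,
  parameterised by mean and concentration. The default concentration of
  500 gives an SD of ~2.2 percentage points at f = 50, a plausible
  precision for a mass-spectrometry allele-ratio read-out; the platform
  publishes no error model, so this is a modelling choice and is
  user-tunable. `inf` switches noise off.
- **Dropout**: each measurement is missing with probability 0.02.

The `paper_like` preset fixes per-tissue silencing probabilities that
encode the study's qualitative findings as generator truth — F1 0.02
everywhere; MIX 0.08 (root 0.12); NN99 leaf 0.06 / root 0.20 / flag and
spike 0.08; 99NN leaf 0.08 / root 0.28 / flag and spike 0.10 — plus
nonfunc_prob 0.01 and reciprocal_prob 0.03 in the tetraploids. These
orderings (mix and tetraploids above F1, 99NN above NN99, root far
above leaf) are preset configuration, not hard-coded analysis results.

What the generator does **not** model: correlated silencing between
neighbouring tissues beyond the injected patterns, per-gene variation
in silencing propensity, assay-specific amplification bias, or any
mass-spectrometry physics. Passing recovery tests therefore shows the
scoring machinery is correct under independent per-tissue silencing
with bounded noise — not that real assay error is beta-distributed.

## Analytic expectation for recovery tests

The expected TSS percentage under the generator is computed exactly
rather than by a second simulation. Conditioning on each homeolog's
nonfunctionalization status and on the reciprocal-injection placement,
the call state of a tissue (dropped / no-expression / called silenced /
called expressed) is independent across tissues, with probabilities
assembled from the silencing probabilities, the beta-noise CDF at the
5% and 95% thresholds (the probability a truly silenced copy is called
silenced, and the false-silencing probability of a co-expressed tissue,
the latter integrated over the gene-baseline distribution by normalised
Gauss-Legendre quadrature). For independent tissue states the TSS
numerator has the closed form

    E[#silenced · 1(#expressed >= 1)] = sum_t s_t (1 - prod_{u != t} (1 - e_u))

and the denominator is E[measured · 1(measured >= 2)]. The reported
nominal value is E[num]/E[den]; the ratio-of-expectations bias is
O(1/n_genes) and far below the Monte-Carlo resolution of the recovery
tests (200 replicates, 3-SE criterion).

## Numerical and scale choices

Acceptance-level simulations use 200 replicates of the full 30-gene
design for recovery/ordering checks and 5,000 draws for test
calibration; at these sizes the whole suite runs in about a minute.
Output tables are written with `%.10g` float formatting, which makes
fixed-seed pipelines byte-reproducible while keeping round-trip error
(~1e-8 percent) far below the record-consistency tolerance. All
randomness flows through `numpy.random.default_rng` seeded once per
simulation.

## Known limitations

- The original study's numeric headline values cannot be reproduced:
  its raw per-assay measurements exist only as supplementary figure
  images. The package reproduces the *procedure* and validates it on
  synthetic data with known truth.
- Bias classification is categorical by design; no continuous allelic
  imbalance model (e.g. beta-binomial tests) is provided.
- The reciprocal-TSS count depends on the tissue set it is evaluated
  over; with independent per-tissue silencing the chance co-occurrence
  of TSS in both homeologs is common at moderate silencing rates, so
  counts over large sets are dominated by coincidence rather than
  injected subfunctionalization. Interpret counts per set.
- Calibration QC fits a straight line only; probe-efficiency or
  dose-response curvature is out of scope.
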