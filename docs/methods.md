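# Methods

## Data model

The unit of analysis is a binary presence/absence matrix `X` with rows =
fungal strains and columns = virus species; `X[s, v] = 1` means virus `v` was
detected in strain `s` by RT-PCR. The matrix is validated on construction
(cells strictly 0/1, unique non-empty strain and virus ids) and is the single
source of every probability downstream: all Supports are strain fractions of
the *mined subset*. By default the mined subset is the strains carrying at
least one virus — a virus-free strain is part of the survey but contributes
nothing to co-occurrence estimation — and it can be widened to all strains
with `MiningConfig(include_virus_free_strains=True)`.

"Not tested" is not representable: the input contract treats RT-PCR calls as
complete, so absence of a record in long-format input means absence of the
virus.

## Rule mining

Each virus contributes a present item and an absent item. A rule is an
antecedent set of 1–3 items over distinct viruses plus a single consequent
item over a further virus; antecedent and consequent sets sharing a virus are
excluded structurally (a contradictory item set has support 0 by definition
and is never generated). Rules are ordered: `{A}⇒{B}` and `{B}⇒{A}` are
separate candidates with equal Support and Lift but generally different
Confidence.

Enumeration is Apriori with anti-monotone pruning, vectorized as matrix
products over the item-indicator matrix: item counts are exact integers
accumulated in float32 and promoted to float64 before any division, so
Support/Confidence/Lift are computed with the same floating-point operations
a direct count-and-divide evaluation would use (the test suite exploits this
to demand agreement with a brute-force enumerator at 1e-12). Output order is
canonical (antecedent items lexicographic by virus id with True before
False, then consequent), making rule tables bit-identical across runs.

Default floors are `min_support = min_confidence = 3/V` for V virus species,
reflecting the survey regime in which nearly every strain carries at least
three viruses. A candidate must satisfy both floors; the antecedent's own
frequency then satisfies the support floor automatically. The published
summary cutoffs (e.g. Support ≥ 0.073 and per-form minimum Lifts) are read as
post-hoc descriptions of retained rule sets, not as mining inputs; they can
be reproduced via the optional `min_support` / `min_lift` floors of
`filter_significant_rules`.

## Significance: permutation null and dynamic Lift threshold

Lift is 1 under independence, but its sampling spread depends strongly on a
rule's Support and Confidence stratum (rare item sets produce noisy, heavy-
tailed Lifts). A single global cutoff therefore either leaks false positives
in low-support strata or starves high-support ones. The dynamic threshold is
built as follows:

1. **Null model** — each virus column is permuted independently across the
   mined strains (`numpy` per-column permutation). This preserves every
   per-virus prevalence and the strain count exactly and destroys cross-virus
   association in expectation. An independent-Bernoulli alternative with
   plug-in prevalences is available (`null_model="bernoulli"`) for
   sensitivity analysis; permutation is the default because it conditions on
   the observed margins.
2. **Null pool** — candidate rules are re-mined on each of `n_permutations`
   (default 200) null matrices with the same mining config, pooling their
   (Support, Confidence, Lift) triples. Per-permutation random streams are
   spawned from one master seed (`numpy.random.SeedSequence`), so the whole
   calibration is reproducible from a single integer.
3. **Stratification** — strata are the grid of Support and Confidence
   deciles *of the observed candidate set* (inner edges only, so the strata
   always cover [0, 1]; duplicate quantiles collapse). Strata with no null
   rules are flagged unusable and fall back to the global null quantile.
4. **Threshold** — per stratum, the upper (1 − α) empirical quantile of the
   null Lifts, with the order-statistic convention
   `sorted(x)[ceil(q·n) − 1]` (the smallest value whose empirical CDF ≥ q).
   With the strictly-greater pass rule this leaves at most an α fraction of
   the null sample above the threshold; for null lifts 0.01…1.00 and
   α = 0.05 the threshold is exactly 0.95.

A candidate is retained iff its Lift **strictly exceeds** its stratum
threshold. The implemented FPR definition is: the expected proportion of
candidate rules passing the threshold when all viruses are mutually
independent. This is the only reading the construction can guarantee; the
per-replicate FPR experiment (`virorules.experiments.measure_null_fpr`)
measures it directly and lands just under α (≈ 4.8% at α = 5%), slightly
conservative because of threshold ties under the strict comparison.

For multi-form runs each rule form (one-to-one, two-to-one, three-to-one) is
calibrated separately with its own candidate-decile strata, over a single
permutation sweep (`calibrate_forms`). The sweep reduces every null rule to
a (stratum, float32 Lift) pair immediately, so survey-scale two-to-one
calibrations (10⁸ pooled null rules) stay within ordinary memory.

## Rule typology

One-to-one types are the four state patterns: I `F⇒F`, II `T⇒T`, III `T⇒F`,
IV `F⇒T`. Multi-antecedent labels sort antecedent states True-first
(`TF⇒T`, not `FT⇒T`) because the antecedent is a set; two antecedents yield
8 labels, three yield 16. The grouped-matrix export aggregates rules by
(antecedent item set, consequent item) with count, max Lift and max Support
per cell — the tabular equivalent of the balloon-plot display; every rule
lands in exactly one cell.

## Lineage validation

A parent strain "predicts" every significant rule whose full virus set
(antecedent ∪ consequent viruses) is contained in the parent's detected
viruses — including absence items, which must also reference viruses the
parent carries, since only those can be followed through virus loss. On an
offspring with virus set S an item `(v, state)` is satisfied iff
`(v ∈ S) == state`; a rule *holds* on the offspring iff its antecedent is
not fully satisfied (vacuously true) or its consequent is satisfied, and is
*confirmed* iff it holds on every offspring. Accuracy is
100 · confirmed / predicted per rule form, undefined (NaN, never 0) when
nothing is predicted. Material implication with the all-offspring
conjunction is the strictest reading under which a presence/absence table
can falsify a rule. Transfectant lineages are treated identically to
single-spore and protoplast lineages.

## Synthetic data

`generate_null_matrix` draws independent Bernoulli cells with per-virus
prevalences; the default spectrum is 76 values log-spaced from 1/405 to 0.8
over 405 strains, emulating a survey's long-tailed virus-frequency
distribution and deliberately stressing the low-support strata of the
calibration. `generate_planted_matrix` additionally overwrites designated
target columns from conditional distributions given already-sampled source
states (pairwise `P(B|A)` / `P(B|¬A)`, or a full 4-row table for
two-antecedent conditionals), sampling in topological order of the planted
DAG, and returns the ground truth for recovery scoring. The expected Lift of
`{A=T}⇒{B=T}` under a planted pair has the closed form
`p_B|A / (P(A)·p_B|A + (1−P(A))·p_B|¬A)`, used by the generator's own tests.

`generate_lineages` gives each offspring each parental virus independently
with `retention_prob` (default 0.8 — offspring keep most but not all
parental viruses, matching the regime where validation panels of 6–20
offspring are informative), then resolves configured incompatible pairs by
dropping one member at random. Offspring never gain viruses.

What the generator does **not** emulate: real within-host compatibility.
Offspring lose viruses *independently at random*, so even a planted
co-occurring pair is frequently split across offspring and presence-type
rules validate far below 100% on simulated lineages — unlike real surveys,
where near-100% confirmation reflects biological co-transmission. Passing
the pipeline tests on synthetic lineages therefore demonstrates the
bookkeeping (predicted/confirmed/accuracy, vacuous-truth handling), not any
biological claim; the accuracy-equals-100 guarantees are tested on lineages
constructed to obey a rule set exactly.

## Numerical choices and problem sizes

- Thresholds are compared with plain `>=` on the same float64 quantities the
  definitions give (no epsilon slack); the strictly-greater rule applies
  only to the Lift-vs-threshold comparison.
- Quantile convention as above; documented once, fixed everywhere.
- Degenerate inputs: empty mined subset, zero-support rule sides,
  zero permutations, empty null pools and no-offspring lineages raise typed
  errors; contradictory item sets return support 0 by definition.
- Master-seed policy: every stochastic routine takes one seed;
  per-permutation and per-replicate streams are spawned from it.
- Experiment sizes: the FPR experiment uses 100 replicate 405 × 76 cohorts
  with 200 permutations each; the recovery experiment 50 replicates with two
  planted pairs (gaps 0.55 and 0.50, source prevalence ≈ 0.5). These sizes
  give Monte-Carlo standard errors well below the margins being tested while
  completing in minutes on a single core.

## Known limitations

- The FPR guarantee is marginal over candidates, not family-wise; no FDR
  machinery beyond the permutation construction is provided by design.
- Probabilities are plug-in strain fractions; no shrinkage for very rare
  viruses (their rules are instead policed by the support floor and the
  low-support strata thresholds).
- Rules with more than three antecedent viruses, multi-item consequents,
  and quantitative titer information are out of scope.
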