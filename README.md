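# virorules

Association-rule mining of mycovirus co-occurrence in fungal strain panels.

Large surveys of plant-pathogenic fungi such as *Botrytis cinerea* find most
field strains co-infected by several RNA/DNA mycoviruses at once. Given a
binary strains × viruses presence/absence matrix (RT-PCR detection calls),
`virorules` asks which viruses *prefer* or *avoid* each other inside a single
host, expresses the answer as association rules, and checks those rules
against the virus compositions of single-spore offspring, protoplast
regenerants and transfectants derived from parent strains.

## The statistic

Every virus contributes two items, `V=True` (present) and `V=False` (absent).
A rule `{A₁, …, Aₖ} ⇒ {B}` (k ≤ 3: "one-to-one", "two-to-one",
"three-to-one") over distinct viruses is scored on the mined strain subset
(by default the strains carrying at least one virus):

- **Support** = P(A₁ ∩ … ∩ Aₖ ∩ B)
- **Confidence** = Support / P(A₁ ∩ … ∩ Aₖ)
- **Lift** = Support / [P(A₁ ∩ … ∩ Aₖ) · P(B)] — equals 1 under independence

Candidates are enumerated with the Apriori algorithm (minimum Support and
Confidence default to 3/V for V virus species). Because the null spread of
Lift depends strongly on a rule's Support and Confidence, significance uses a
**dynamic threshold**: virus columns are permuted independently across strains
(exactly preserving every prevalence), candidate rules are re-mined on each of
200 permuted matrices, the pooled null Lifts are stratified on a
(Support × Confidence) decile grid, and each stratum's threshold is set to the
empirical upper 95% quantile of its null Lifts. A rule is retained only when
its Lift strictly exceeds its stratum threshold, which holds the expected
false-positive rate among candidates below α = 5%.

Retained one-to-one rules are classified as Type I (`F⇒F`), II (`T⇒T`),
III (`T⇒F`) or IV (`F⇒T`); multi-antecedent rules by their state pattern
(`TT⇒F`, `TFT⇒T`, …). Validation screens the significant rules applicable to
a parent strain (all rule viruses carried by the parent = "predicted") and
confirms a rule only when it holds, as a material implication, in **every**
offspring — the predicted / confirmed / accuracy bookkeeping of a
parent–offspring verification table.

## Worked example

```python
import pandas as pd
from virorules import PresenceAbsenceMatrix, MiningConfig, compute_rule_metrics

# 10 strains; virus A in strains 1-5, virus B in strains 1-4
m = PresenceAbsenceMatrix(pd.DataFrame(
    {"A": [1]*5 + [0]*5, "B": [1]*4 + [0]*6},
    index=[f"s{i}" for i in range(1, 11)]))
cfg = MiningConfig(min_support=0, min_confidence=0, include_virus_free_strains=True)
print(compute_rule_metrics(m, [("A", True)], ("B", True), cfg))
print(compute_rule_metrics(m, [("A", False)], ("B", False), cfg))
```

prints

```
RuleMetrics(support=0.4, confidence=0.8, lift=2.0)
RuleMetrics(support=0.5, confidence=1.0, lift=1.6666666666666667)
```

i.e. strains with A carry B 80% of the time, twice the rate expected if the
two viruses were independent (Lift 2 > 1: co-occurrence, Type II), and the
absence rule `{A=F}⇒{B=F}` holds in every A-free strain (Confidence 1.0).

## Analysis scripts

The `analysis/` drivers run the whole study on a simulated survey-scale
cohort (405 strains × 76 viruses, long-tailed prevalence spectrum, two
planted dependencies):

```bash
python analysis/01_simulate_cohort.py     # matrix + truth + lineages -> results/data/
python analysis/02_cohort_summary.py      # prevalence + co-infection histogram
python analysis/03_mine_calibrate_filter.py  # candidates -> significant rules (+ typing)
python analysis/04_validate_lineages.py   # predicted/confirmed/accuracy per lineage
```

The same stages are available as a library (`virorules.pipeline.run_pipeline`)
and as the `virorules` command-line tool (`simulate`, `summarize`, `mine`,
`calibrate`, `filter`, `classify`, `validate`, `run`).

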