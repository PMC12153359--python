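"""Validation of mined rules against offspring/transfectant virus compositions.

A parent strain carrying a virus set nominates ("predicts") every significant
rule whose viruses are all present in the parent.  Each predicted rule is then
tested on every offspring under material-implication semantics: the rule holds
on an offspring when the antecedent is unsatisfied (vacuously true) or the
consequent is satisfied, and is confirmed only when it holds on all offspring.
This mirrors the single-spore / protoplast-regenerant / transfectant
verification experiment and its predicted / confirmed / accuracy bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class LineageError(ValueError):
    pass


@dataclass(frozen=True)
class Lineage:
    """A parent strain's virus set plus its offspring virus compositions."""

    parent_id: str
    parent_viruses: frozenset
    offspring: tuple  # of (offspring_id, frozenset of virus ids)
    origin: str = "single_spore"  # or protoplast_regenerant / transfectant

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    @property
    def usable(self) -> bool:
        """A lineage with no offspring cannot falsify or confirm any rule."""
        return self.n_offspring >= 1


def _rule_viruses(row) -> set:
    return {v for v, _ in row["lhs_items"]} | {row["rhs_virus"]}


def select_applicable_rules(rules: pd.DataFrame, lineage: Lineage) -> pd.DataFrame:
    """Rules whose full virus set is a subset of the parent's detected viruses.

    These are the "predicted" rules for the strain: only rules about viruses
    the parent actually carries can be followed through conidiation.
    """
    if rules.empty:
        return rules
    keep = [
        _rule_viruses(row) <= lineage.parent_viruses
        for _, row in rules.iterrows()
    ]
    return rules.loc[keep]


def evaluate_rule_on_lineage(rule, lineage: Lineage) -> tuple[int, bool]:
    """Count offspring on which a rule holds; confirmed iff it holds on all.

    ``rule`` is a rules-frame row (or any mapping with ``lhs_items``,
    ``rhs_virus``, ``rhs_state``).  On an offspring with virus set S, an item
    ``(v, state)`` is satisfied iff ``(v in S) == state``; the rule holds iff
    the antecedent is not fully satisfied (vacuous) or the consequent is
    satisfied.
    """
    if not lineage.usable:
        raise LineageError(f"lineage {lineage.parent_id!r} has no offspring")
    lhs = rule["lhs_items"]
    rhs_v, rhs_s = rule["rhs_virus"], rule["rhs_state"]
    holds = 0
    for _, viruses in lineage.offspring:
        lhs_sat = all((v in viruses) == s for v, s in lhs)
        if (not lhs_sat) or ((rhs_v in viruses) == rhs_s):
            holds += 1
    return holds, holds == lineage.n_offspring


def summarize_validation(
    rules: pd.DataFrame, lineages: Sequence[Lineage]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lineage and overall predicted/confirmed/accuracy report.

    Returns ``(per_lineage, overall)``: one row per (lineage, rule_form) with
    columns strain, origin, n_viruses, n_offspring, rule_form, predicted,
    confirmed, accuracy; and the pooled accuracy per rule_form.  Accuracy is
    100 * confirmed / predicted, reported as NaN (undefined) when no rule is
    predicted.  Lineages without offspring are skipped (unusable).
    """
    rows = []
    for lin in lineages:
        if not lin.usable:
            continue
        applicable = select_applicable_rules(rules, lin)
        forms = applicable["rule_form"].unique() if len(applicable) else []
        for form in forms:
            sub = applicable[applicable["rule_form"] == form]
            confirmed = sum(
                evaluate_rule_on_lineage(row, lin)[1] for _, row in sub.iterrows()
            )
            n_pred = len(sub)
            rows.append(
                {
                    "strain": lin.parent_id,
                    "origin": lin.origin,
                    "n_viruses": len(lin.parent_viruses),
                    "n_offspring": lin.n_offspring,
                    "rule_form": form,
                    "predicted": n_pred,
                    "confirmed": int(confirmed),
                    "accuracy": 100.0 * confirmed / n_pred if n_pred else np.nan,
                }
            )
        if not len(forms):
            rows.append(
                {
                    "strain": lin.parent_id,
                    "origin": lin.origin,
                    "n_viruses": len(lin.parent_viruses),
                    "n_offspring": lin.n_offspring,
                    "rule_form": "none",
                    "predicted": 0,
                    "confirmed": 0,
                    "accuracy": np.nan,
                }
            )
    per_lineage = pd.DataFrame(
        rows,
        columns=["strain", "origin", "n_viruses", "n_offspring", "rule_form",
                 "predicted", "confirmed", "accuracy"],
    )
    pooled = per_lineage[per_lineage["rule_form"] != "none"]
    if len(pooled):
        overall = (
            pooled.groupby("rule_form", as_index=False)[["predicted", "confirmed"]]
            .sum()
        )
        overall["accuracy"] = np.where(
            overall["predicted"] > 0,
            100.0 * overall["confirmed"] / overall["predicted"],
            np.nan,
        )
    else:
        overall = pd.DataFrame(columns=["rule_form", "predicted", "confirmed", "accuracy"])
    return per_lineage, overall
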