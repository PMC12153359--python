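"""Rule typology and grouped-matrix summaries.

One-to-one rules fall into four types by the states of their items:

    Type I   {A=F} => {B=F}   absence explains absence (co-exclusion echo)
    Type II  {A=T} => {B=T}   presence explains presence (co-occurrence)
    Type III {A=T} => {B=F}   presence explains absence (incompatibility)
    Type IV  {A=F} => {B=T}   absence explains presence

Multi-antecedent rules are labelled by their state pattern with antecedent
states sorted True-first (set notation is unordered), e.g. ``TT=>F`` or
``TTF=>T``; two antecedents give 8 attainable labels, three give 16.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import pandas as pd

_ONE_TO_ONE_TYPES = {
    (False, False): "I",
    (True, True): "II",
    (True, False): "III",
    (False, True): "IV",
}


def classify_rule(rule) -> str:
    """Deterministic type label from item states only (metrics ignored)."""
    if hasattr(rule, "lhs"):
        lhs_states = [it.state for it in rule.lhs]
        rhs_state = rule.rhs.state
    else:
        lhs_states = [s for _, s in rule["lhs_items"]]
        rhs_state = rule["rhs_state"]
    if len(lhs_states) == 1:
        return _ONE_TO_ONE_TYPES[(lhs_states[0], rhs_state)]
    if len(lhs_states) > 3:
        raise ValueError("rules with more than three antecedent items are unsupported")
    lhs_sorted = sorted(lhs_states, reverse=True)  # True before False
    pattern = "".join("T" if s else "F" for s in lhs_sorted)
    return f"{pattern}=>{'T' if rhs_state else 'F'}"


def classify_rules_frame(rules: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the rules frame with a ``rule_type`` column."""
    out = rules.copy()
    out["rule_type"] = [
        classify_rule(row) for _, row in rules.iterrows()
    ] if len(rules) else pd.Series(dtype=str)
    return out


def type_census(rules: pd.DataFrame) -> dict:
    """Count rules per type; counts partition the rule set."""
    if rules.empty:
        return {}
    labels = (rules["rule_type"] if "rule_type" in rules
              else [classify_rule(row) for _, row in rules.iterrows()])
    return dict(sorted(Counter(labels).items()))


def _itemset_label(items) -> str:
    return ";".join(f"{v}={'T' if s else 'F'}" for v, s in items)


def group_rules(rules: pd.DataFrame) -> pd.DataFrame:
    """Grouped-matrix view: one cell per (antecedent itemset, consequent item).

    Long-format tabular twin of the balloon-plot display: columns
    ``lhs_group``, ``rhs_group``, ``n_rules``, ``max_lift``, ``max_support``.
    Grouping is by item set (virus + state), not by state pattern, so every
    rule contributes to exactly one cell and cell counts sum to the rule
    count.
    """
    if rules.empty:
        return pd.DataFrame(columns=["lhs_group", "rhs_group", "n_rules",
                                     "max_lift", "max_support"])
    df = rules.copy()
    df["lhs_group"] = [_itemset_label(items) for items in df["lhs_items"]]
    df["rhs_group"] = [
        f"{v}={'T' if s else 'F'}" for v, s in zip(df["rhs_virus"], df["rhs_state"])
    ]
    grouped = (
        df.groupby(["lhs_group", "rhs_group"], as_index=False)
        .agg(n_rules=("lift", "size"), max_lift=("lift", "max"),
             max_support=("support", "max"))
    )
    return grouped.sort_values(["lhs_group", "rhs_group"]).reset_index(drop=True)
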