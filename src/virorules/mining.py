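"""Apriori enumeration of virus co-occurrence rules with Support/Confidence/Lift.

Every virus contributes two items, ``Virus = True`` (present) and
``Virus = False`` (absent).  A rule is an antecedent item set of one to three
items over distinct viruses implying a single consequent item over a further
virus.  Probabilities are estimated as strain fractions over the mined strain
subset (by default, strains carrying at least one virus):

    Support(L => R)    = P(L and R)
    Confidence(L => R) = P(L and R) / P(L)
    Lift(L => R)       = P(L and R) / (P(L) * P(R))

Lift equals 1 when antecedent and consequent occur independently.  Candidate
enumeration applies the Apriori anti-monotone pruning (no superset of an
infrequent item set is visited) and emits rules in a canonical order
(lexicographic by antecedent items with True before False, then by
consequent), so output files are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ONE_TO_ONE = "one_to_one"
TWO_TO_ONE = "two_to_one"
THREE_TO_ONE = "three_to_one"
FORM_BY_LHS_SIZE = {1: ONE_TO_ONE, 2: TWO_TO_ONE, 3: THREE_TO_ONE}

RULES_FRAME_COLUMNS = (
    "lhs_items", "rhs_virus", "rhs_state", "rule_form",
    "support", "confidence", "lift",
)


class UndefinedMetricError(ValueError):
    """Antecedent or consequent has zero support; metrics are undefined."""


@dataclass(frozen=True)
class Item:
    virus_id: str
    state: bool

    def __str__(self) -> str:
        return f"{self.virus_id}={'T' if self.state else 'F'}"


def item_sort_key(item) -> tuple:
    """Canonical item order: by virus id, True before False."""
    virus, state = (item.virus_id, item.state) if isinstance(item, Item) else item
    return (virus, 0 if state else 1)


@dataclass(frozen=True)
class RuleMetrics:
    support: float
    confidence: float
    lift: float


@dataclass(frozen=True)
class Rule:
    lhs: tuple  # of Item
    rhs: Item
    metrics: RuleMetrics | None = None

    @property
    def rule_form(self) -> str:
        return FORM_BY_LHS_SIZE[len(self.lhs)]


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and scope of candidate enumeration.

    ``min_support`` and ``min_confidence`` default to 3 / V where V is the
    number of virus species in the matrix (the smallest burden observed in
    nearly every strain of the survey the defaults emulate).
    """

    max_lhs_size: int = 1
    min_support: float | None = None
    min_confidence: float | None = None
    include_virus_free_strains: bool = False

    def resolved(self, n_viruses: int) -> "MiningConfig":
        if not 1 <= self.max_lhs_size <= 3:
            raise ValueError("max_lhs_size must be 1, 2 or 3")
        ms = 3.0 / n_viruses if self.min_support is None else self.min_support
        mc = 3.0 / n_viruses if self.min_confidence is None else self.min_confidence
        for name, v in (("min_support", ms), ("min_confidence", mc)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        return replace(self, min_support=ms, min_confidence=mc)


# ---------------------------------------------------------------------------
# scalar operations (reference path; the enumerator below is vectorized)
# ---------------------------------------------------------------------------

def _coerce_items(items) -> list[tuple[str, bool]]:
    out = []
    for it in items:
        if isinstance(it, Item):
            out.append((it.virus_id, it.state))
        else:
            v, s = it
            out.append((str(v), bool(s)))
    return out


def itemset_support(
    matrix, items: Iterable, config: MiningConfig | None = None
) -> float:
    """Fraction of mined strains satisfying every item of the set.

    A contradictory set (both states of one virus) has support 0 by
    definition.
    """
    cfg = (config or MiningConfig())
    mask = matrix.mined_mask(cfg.include_virus_free_strains)
    vals = matrix.values[mask]
    n = vals.shape[0]
    if n == 0:
        raise ValueError("no strains in the mined subset")
    coerced = _coerce_items(items)
    seen: dict[str, bool] = {}
    for v, s in coerced:
        if v in seen and seen[v] != s:
            return 0.0
        seen[v] = s
    sat = np.ones(n, dtype=bool)
    col = {vid: i for i, vid in enumerate(matrix.virus_ids)}
    for v, s in seen.items():
        if v not in col:
            raise KeyError(f"unknown virus id {v!r}")
        sat &= (vals[:, col[v]] == 1) if s else (vals[:, col[v]] == 0)
    return int(sat.sum()) / n


def compute_rule_metrics(
    matrix, lhs: Iterable, rhs, config: MiningConfig | None = None
) -> RuleMetrics:
    """Support, Confidence and Lift of a single rule ``lhs => rhs``."""
    rhs_v, rhs_s = _coerce_items([rhs])[0]
    lhs_items = _coerce_items(lhs)
    if any(v == rhs_v for v, _ in lhs_items):
        raise ValueError("consequent virus must not appear in the antecedent")
    s_lhs = itemset_support(matrix, lhs_items, config)
    s_rhs = itemset_support(matrix, [(rhs_v, rhs_s)], config)
    if s_lhs == 0.0 or s_rhs == 0.0:
        raise UndefinedMetricError(
            "antecedent or consequent has zero support; metrics undefined"
        )
    s_full = itemset_support(matrix, lhs_items + [(rhs_v, rhs_s)], config)
    return RuleMetrics(
        support=s_full, confidence=s_full / s_lhs, lift=s_full / (s_lhs * s_rhs)
    )


# ---------------------------------------------------------------------------
# vectorized Apriori enumeration
# ---------------------------------------------------------------------------

_TRIPLE_CHUNK = 20_000  # bounds the n x chunk work array for 3-antecedent joins


def _mine_arrays(values01: np.ndarray, ms: float, mc: float, max_lhs: int) -> list[dict]:
    """Enumerate candidate rules as index/metric arrays.

    ``values01`` is the mined (n x V) 0/1 array.  Item index layout: column
    j < V is (virus j, True) and j >= V is (virus j - V, False).  Returns one
    dict per rule form with parallel arrays ``lhs`` (tuple of index arrays),
    ``rhs``, ``support``, ``confidence``, ``lift``.
    """
    n, V = values01.shape
    if n == 0:
        raise ValueError("empty mined strain subset")
    M = np.empty((n, 2 * V), dtype=np.float32)
    M[:, :V] = values01
    M[:, V:] = 1.0 - values01
    c1 = M.sum(axis=0).astype(np.float64)  # exact item counts
    virus = np.concatenate([np.arange(V), np.arange(V)])

    C2 = (M.T @ M).astype(np.float64)
    sup2 = C2 / n
    diffv = virus[:, None] != virus[None, :]
    freq2 = (sup2 >= ms) & diffv

    out: list[dict] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        conf2 = np.where(c1[:, None] > 0, C2 / c1[:, None], 0.0)
        den = np.outer(c1, c1)
        lift2 = np.where(den > 0, C2 * n / den, 0.0)
    keep = freq2 & (conf2 >= mc)
    ai, bi = np.nonzero(keep)
    out.append(
        dict(form=ONE_TO_ONE, lhs=(ai,), rhs=bi,
             support=sup2[ai, bi], confidence=conf2[ai, bi], lift=lift2[ai, bi])
    )
    if max_lhs == 1:
        return out

    iu, ju = np.nonzero(np.triu(freq2, k=1))  # frequent unordered item pairs
    if iu.size == 0:
        for size in range(2, max_lhs + 1):
            out.append(_empty_form(size))
        return out
    A2 = M[:, iu] * M[:, ju]  # n x P indicator of both items
    C3 = (A2.T @ M).astype(np.float64)  # P x 2V
    pc = C2[iu, ju]
    sup3 = C3 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        conf3 = np.where(pc[:, None] > 0, C3 / pc[:, None], 0.0)
        den3 = pc[:, None] * c1[None, :]
        lift3 = np.where(den3 > 0, C3 * n / den3, 0.0)
    okv3 = (virus[iu][:, None] != virus[None, :]) & (virus[ju][:, None] != virus[None, :])
    keep3 = (sup3 >= ms) & (conf3 >= mc) & okv3
    pi, ki = np.nonzero(keep3)
    out.append(
        dict(form=TWO_TO_ONE, lhs=(iu[pi], ju[pi]), rhs=ki,
             support=sup3[pi, ki], confidence=conf3[pi, ki], lift=lift3[pi, ki])
    )
    if max_lhs == 2:
        return out

    # frequent triples {i < j < k}: join frequent pairs (i, j) with items k > j
    cols = np.arange(2 * V)
    ft = (sup3 >= ms) & okv3 & (cols[None, :] > ju[:, None])
    tp, tk = np.nonzero(ft)
    if tp.size == 0:
        out.append(_empty_form(3))
        return out
    ti, tj = iu[tp], ju[tp]
    cnt3 = C3[tp, tk]
    lhs_i, lhs_j, lhs_k, rhs_l = [], [], [], []
    s4s, c4s, l4s = [], [], []
    for lo in range(0, tp.size, _TRIPLE_CHUNK):
        sl = slice(lo, min(lo + _TRIPLE_CHUNK, tp.size))
        A3 = A2[:, tp[sl]] * M[:, tk[sl]]
        C4 = (A3.T @ M).astype(np.float64)
        cnt = cnt3[sl]
        sup4 = C4 / n
        with np.errstate(divide="ignore", invalid="ignore"):
            conf4 = np.where(cnt[:, None] > 0, C4 / cnt[:, None], 0.0)
            den4 = cnt[:, None] * c1[None, :]
            lift4 = np.where(den4 > 0, C4 * n / den4, 0.0)
        okv4 = (
            (virus[ti[sl]][:, None] != virus[None, :])
            & (virus[tj[sl]][:, None] != virus[None, :])
            & (virus[tk[sl]][:, None] != virus[None, :])
        )
        keep4 = (sup4 >= ms) & (conf4 >= mc) & okv4
        qi, li = np.nonzero(keep4)
        lhs_i.append(ti[sl][qi])
        lhs_j.append(tj[sl][qi])
        lhs_k.append(tk[sl][qi])
        rhs_l.append(li)
        s4s.append(sup4[qi, li])
        c4s.append(conf4[qi, li])
        l4s.append(lift4[qi, li])
    out.append(
        dict(form=THREE_TO_ONE,
             lhs=(np.concatenate(lhs_i), np.concatenate(lhs_j), np.concatenate(lhs_k)),
             rhs=np.concatenate(rhs_l),
             support=np.concatenate(s4s),
             confidence=np.concatenate(c4s),
             lift=np.concatenate(l4s))
    )
    return out


def _empty_form(size: int) -> dict:
    e = np.empty(0, dtype=np.intp)
    f = np.empty(0, dtype=np.float64)
    return dict(form=FORM_BY_LHS_SIZE[size], lhs=tuple(e for _ in range(size)),
                rhs=e, support=f, confidence=f, lift=f)


def candidate_rule_stats(
    values01: np.ndarray, n_viruses: int, config: MiningConfig
) -> pd.DataFrame:
    """Metric triples of all candidate rules without item labels.

    Fast path used for permutation nulls and FPR measurement: returns a
    DataFrame with columns rule_form, support, confidence, lift.
    """
    cfg = config.resolved(n_viruses)
    forms = _mine_arrays(values01, cfg.min_support, cfg.min_confidence, cfg.max_lhs_size)
    categories = [f["form"] for f in forms]
    codes = np.repeat(np.arange(len(forms), dtype=np.int8),
                      [len(f["rhs"]) for f in forms])
    return pd.DataFrame(
        {
            "rule_form": pd.Categorical.from_codes(codes, categories=categories),
            "support": np.concatenate([f["support"] for f in forms]),
            "confidence": np.concatenate([f["confidence"] for f in forms]),
            "lift": np.concatenate([f["lift"] for f in forms]),
        }
    )


def enumerate_candidate_rules(
    matrix, config: MiningConfig | None = None, as_frame: bool = True
):
    """Enumerate all candidate rules meeting the support/confidence floors.

    Rules are ordered pairs/tuples: ``{A} => {B}`` and ``{B} => {A}`` are
    distinct candidates.  Returns a canonical-ordered DataFrame with columns
    ``lhs_items`` (tuple of (virus_id, state)), ``rhs_virus``, ``rhs_state``,
    ``rule_form``, ``support``, ``confidence``, ``lift`` — or a list of
    :class:`Rule` when ``as_frame`` is False.
    """
    cfg = (config or MiningConfig()).resolved(matrix.n_viruses)
    mask = matrix.mined_mask(cfg.include_virus_free_strains)
    vals = matrix.values[mask]
    forms = _mine_arrays(vals, cfg.min_support, cfg.min_confidence, cfg.max_lhs_size)

    vids = matrix.virus_ids
    V = len(vids)

    def decode(idx: int) -> tuple[str, bool]:
        return (vids[idx], True) if idx < V else (vids[idx - V], False)

    rows = []
    for f in forms:
        lhs_cols = f["lhs"]
        for r in range(len(f["rhs"])):
            lhs = tuple(
                sorted((decode(int(col[r])) for col in lhs_cols), key=item_sort_key)
            )
            rv, rs = decode(int(f["rhs"][r]))
            rows.append(
                (lhs, rv, rs, f["form"], f["support"][r], f["confidence"][r], f["lift"][r])
            )
    rows.sort(key=lambda t: (len(t[0]),
                             tuple(item_sort_key(it) for it in t[0]),
                             item_sort_key((t[1], t[2]))))
    df = pd.DataFrame(rows, columns=list(RULES_FRAME_COLUMNS))
    if as_frame:
        return df
    return frame_to_rules(df)


def frame_to_rules(df: pd.DataFrame) -> list[Rule]:
    rules = []
    for _, row in df.iterrows():
        rules.append(
            Rule(
                lhs=tuple(Item(v, s) for v, s in row["lhs_items"]),
                rhs=Item(row["rhs_virus"], row["rhs_state"]),
                metrics=RuleMetrics(row["support"], row["confidence"], row["lift"]),
            )
        )
    return rules


def rules_to_frame(rules: Sequence[Rule]) -> pd.DataFrame:
    rows = [
        (
            tuple(sorted(((it.virus_id, it.state) for it in r.lhs), key=item_sort_key)),
            r.rhs.virus_id, r.rhs.state, r.rule_form,
            r.metrics.support, r.metrics.confidence, r.metrics.lift,
        )
        for r in rules
    ]
    return pd.DataFrame(rows, columns=list(RULES_FRAME_COLUMNS))
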