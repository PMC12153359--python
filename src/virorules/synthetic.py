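"""Synthetic presence/absence matrices and lineages with known structure.

The generators emulate the shape of a large field virome survey: ~405
virus-infected strains typed for 76 viruses whose prevalences span a long
tail from a single strain up to ~80% of the panel, with optional planted
pairwise and conditional (two-antecedent) dependencies, and parent ->
offspring lineages in which each parental virus is retained independently
with some probability (offspring never gain viruses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix_io import PresenceAbsenceMatrix
from .validation import Lineage

DEFAULT_N_STRAINS = 405
DEFAULT_N_VIRUSES = 76


def default_prevalences(
    n_viruses: int = DEFAULT_N_VIRUSES,
    n_strains: int = DEFAULT_N_STRAINS,
    high: float = 0.8,
) -> np.ndarray:
    """Log-spaced prevalence spectrum from 1/n_strains up to ``high``.

    Emulates the survey's long-tailed virus frequency distribution (many rare
    viruses, a few near-ubiquitous ones) and deliberately stresses the
    low-support strata of the calibration.
    """
    return np.geomspace(1.0 / n_strains, high, n_viruses)


def virus_names(n_viruses: int) -> list[str]:
    return [f"V{i + 1:02d}" for i in range(n_viruses)]


@dataclass(frozen=True)
class PlantedPair:
    """B | A dependency: P(B=1 | A=1) vs P(B=1 | A=0)."""

    a: str
    b: str
    p_b_given_a: float
    p_b_given_not_a: float

    def expected_lift_tt(self, p_a: float) -> float:
        """Closed-form Lift of {A=T} => {B=T} under the generative model."""
        p_b = p_a * self.p_b_given_a + (1 - p_a) * self.p_b_given_not_a
        return self.p_b_given_a / p_b

    def expected_lift_tf(self, p_a: float) -> float:
        """Closed-form Lift of {A=T} => {B=F}."""
        p_b = p_a * self.p_b_given_a + (1 - p_a) * self.p_b_given_not_a
        return (1 - self.p_b_given_a) / (1 - p_b)


@dataclass(frozen=True)
class PlantedConditional:
    """C | (A, B) dependency with a full 4-row conditional table."""

    a: str
    b: str
    c: str
    table: Mapping  # {(bool, bool): P(C=1 | A, B)}


@dataclass(frozen=True)
class SyntheticConfig:
    n_strains: int = DEFAULT_N_STRAINS
    n_viruses: int = DEFAULT_N_VIRUSES
    prevalences: Sequence[float] | None = None  # None = default spectrum
    planted_pairs: tuple = ()
    planted_conditionals: tuple = ()
    seed: int = 0

    def resolved_prevalences(self) -> np.ndarray:
        prev = (np.asarray(self.prevalences, float) if self.prevalences is not None
                else default_prevalences(self.n_viruses, self.n_strains))
        if prev.size != self.n_viruses:
            raise ValueError("prevalence vector length must equal n_viruses")
        if ((prev < 0) | (prev > 1)).any():
            raise ValueError("prevalences must lie in [0, 1]")
        return prev


@dataclass(frozen=True)
class LineageConfig:
    """Offspring generation: independent per-virus retention, no gains."""

    retention_prob: float = 0.8
    incompatible_pairs: tuple = ()  # pairs never co-retained in one offspring
    n_offspring: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ValueError("retention_prob must lie in [0, 1]")


def _strain_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def generate_null_matrix(config: SyntheticConfig) -> PresenceAbsenceMatrix:
    """Independent Bernoulli cells with column-specific prevalences."""
    prev = config.resolved_prevalences()
    rng = np.random.default_rng(config.seed)
    vals = (rng.random((config.n_strains, config.n_viruses)) < prev[None, :]).astype(np.int8)
    return PresenceAbsenceMatrix(
        pd.DataFrame(vals, index=_strain_ids(config.n_strains),
                     columns=virus_names(config.n_viruses))
    )


def _topo_order(targets: dict, n_names: Sequence[str]) -> list[str]:
    """Kahn's algorithm over planted source -> target edges; cycles error."""
    indeg = {v: 0 for v in n_names}
    children: dict[str, list[str]] = {v: [] for v in n_names}
    for tgt, sources in targets.items():
        for s in sources:
            children[s].append(tgt)
            indeg[tgt] += 1
    queue = [v for v in n_names if indeg[v] == 0]
    order = []
    while queue:
        v = queue.pop()
        order.append(v)
        for ch in children[v]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                queue.append(ch)
    if len(order) != len(n_names):
        raise ValueError("planted dependency graph must be acyclic")
    return order


def generate_planted_matrix(
    config: SyntheticConfig,
) -> tuple[PresenceAbsenceMatrix, list]:
    """Sample a matrix with planted dependencies plus the ground truth.

    Non-target viruses are independent Bernoulli draws at their configured
    prevalence; each planted target is drawn per strain from its conditional
    distribution given the (already sampled) source states, in topological
    order.  Returns (matrix, truth) where truth lists the planted structures.
    """
    prev = config.resolved_prevalences()
    names = virus_names(config.n_viruses)
    col = {v: i for i, v in enumerate(names)}
    targets: dict[str, tuple] = {}
    for p in config.planted_pairs:
        if p.b in targets:
            raise ValueError(f"virus {p.b!r} is the target of more than one planted structure")
        targets[p.b] = (p.a,)
    for c in config.planted_conditionals:
        if c.c in targets:
            raise ValueError(f"virus {c.c!r} is the target of more than one planted structure")
        targets[c.c] = (c.a, c.b)
    for t, sources in targets.items():
        for s in (t, *sources):
            if s not in col:
                raise KeyError(f"unknown virus id {s!r} in planted structure")
    order = _topo_order(targets, names)

    rng = np.random.default_rng(config.seed)
    u = rng.random((config.n_strains, config.n_viruses))
    vals = np.zeros((config.n_strains, config.n_viruses), dtype=np.int8)
    by_target = {p.b: p for p in config.planted_pairs}
    by_target.update({c.c: c for c in config.planted_conditionals})
    for v in order:
        j = col[v]
        if v not in targets:
            vals[:, j] = u[:, j] < prev[j]
            continue
        struct = by_target[v]
        if isinstance(struct, PlantedPair):
            a = vals[:, col[struct.a]].astype(bool)
            p_row = np.where(a, struct.p_b_given_a, struct.p_b_given_not_a)
        else:
            a = vals[:, col[struct.a]].astype(bool)
            b = vals[:, col[struct.b]].astype(bool)
            p_row = np.empty(config.n_strains)
            for sa in (False, True):
                for sb in (False, True):
                    m = (a == sa) & (b == sb)
                    p_row[m] = struct.table[(sa, sb)]
        vals[:, j] = u[:, j] < p_row
    matrix = PresenceAbsenceMatrix(
        pd.DataFrame(vals, index=_strain_ids(config.n_strains), columns=names)
    )
    return matrix, list(config.planted_pairs) + list(config.planted_conditionals)


def generate_lineages(
    parent_id: str,
    parent_viruses,
    config: LineageConfig,
    origin: str = "single_spore",
) -> Lineage:
    """Simulate offspring virus sets: independent retention, subset of parent.

    Each offspring keeps each parental virus with ``retention_prob``; any
    incompatible pair still co-retained loses one member uniformly at random.
    Offspring never acquire viruses the parent lacks.
    """
    parent = sorted(map(str, parent_viruses))
    if not parent:
        raise ValueError("parent virus set must be non-empty")
    rng = np.random.default_rng(config.seed)
    offspring = []
    for k in range(config.n_offspring):
        kept = {v for v in parent if rng.random() < config.retention_prob}
        for a, b in config.incompatible_pairs:
            if a in kept and b in kept:
                kept.discard(a if rng.random() < 0.5 else b)
        offspring.append((f"{parent_id}-o{k + 1}", frozenset(kept)))
    return Lineage(
        parent_id=parent_id, parent_viruses=frozenset(parent),
        offspring=tuple(offspring), origin=origin,
    )
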