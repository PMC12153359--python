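"""Permutation-null calibration of dynamic Lift thresholds at a target FPR.

The null model permutes each virus column independently across strains, which
preserves every per-virus prevalence and the strain count exactly while
destroying cross-virus association.  Candidate rules are mined on each
permuted matrix and their (Support, Confidence, Lift) triples pooled; the
pool is stratified on a (Support x Confidence) grid and each stratum's Lift
threshold is set to the empirical upper (1 - alpha) quantile of its null
lifts, so that a rule retained only when its Lift strictly exceeds its
stratum threshold keeps the expected fraction of null candidates passing at
or below alpha.

Quantile convention: the threshold is the smallest null lift whose empirical
CDF is >= q, i.e. ``sorted(x)[ceil(q * len(x)) - 1]``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix_io import PresenceAbsenceMatrix
from .mining import MiningConfig, candidate_rule_stats


def upper_quantile(x, q: float) -> float:
    """Smallest order statistic with empirical CDF >= q.

    For x = {0.01, ..., 1.00} and q = 0.95 this is 0.95: exactly 5% of the
    sample lies strictly above the returned value.
    """
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty sample")
    k = max(int(math.ceil(q * x.size)) - 1, 0)
    return float(np.partition(x, k)[k])


@dataclass(frozen=True)
class CalibrationConfig:
    """Target FPR, permutation budget and stratification for thresholding."""

    alpha: float = 0.05
    n_permutations: int = 200
    seed: int = 0
    n_support_bins: int = 10
    n_confidence_bins: int = 10
    support_edges: tuple | None = None  # inner bin edges; None = data deciles
    confidence_edges: tuple | None = None
    null_model: str = "permute"  # or "bernoulli" (plug-in prevalence)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.null_model not in {"permute", "bernoulli"}:
            raise ValueError(f"unknown null model {self.null_model!r}")


@dataclass(frozen=True)
class CalibrationTable:
    """Per-(support, confidence) stratum Lift thresholds.

    ``support_edges`` / ``confidence_edges`` are the *inner* bin edges; with
    k inner edges there are k + 1 bins, so the strata always cover [0, 1].
    Strata with no null rules are unusable and fall back to the global upper
    (1 - alpha) null quantile.
    """

    support_edges: np.ndarray
    confidence_edges: np.ndarray
    thresholds: np.ndarray  # (n_support_bins, n_confidence_bins), fallback-filled
    n_null: np.ndarray
    usable: np.ndarray
    global_threshold: float
    alpha: float

    def bin_indices(self, support, confidence) -> tuple[np.ndarray, np.ndarray]:
        si = np.searchsorted(self.support_edges, np.asarray(support, float), side="right")
        ci = np.searchsorted(self.confidence_edges, np.asarray(confidence, float), side="right")
        return si, ci

    def threshold_for(self, support, confidence) -> np.ndarray:
        si, ci = self.bin_indices(support, confidence)
        return self.thresholds[si, ci]

    def pass_mask(
        self, support, confidence, lift,
        min_support: float | None = None, min_lift: float | None = None,
    ) -> np.ndarray:
        """True where lift strictly exceeds the stratum threshold (and floors)."""
        lift = np.asarray(lift, float)
        mask = lift > self.threshold_for(support, confidence)
        if min_support is not None:
            mask &= np.asarray(support, float) >= min_support
        if min_lift is not None:
            mask &= lift >= min_lift
        return mask

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "global_threshold": self.global_threshold,
            "support_edges": self.support_edges.tolist(),
            "confidence_edges": self.confidence_edges.tolist(),
            "thresholds": self.thresholds.tolist(),
            "n_null": self.n_null.tolist(),
            "usable": self.usable.astype(bool).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationTable":
        return cls(
            support_edges=np.asarray(d["support_edges"], float),
            confidence_edges=np.asarray(d["confidence_edges"], float),
            thresholds=np.asarray(d["thresholds"], float),
            n_null=np.asarray(d["n_null"], int),
            usable=np.asarray(d["usable"], bool),
            global_threshold=float(d["global_threshold"]),
            alpha=float(d["alpha"]),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path) -> "CalibrationTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# null generation
# ---------------------------------------------------------------------------

def permute_matrix_columns(matrix: PresenceAbsenceMatrix, seed) -> PresenceAbsenceMatrix:
    """Independently permute each virus column across strains.

    Column sums (prevalences) are preserved exactly; cross-virus association
    is destroyed in expectation.  ``seed`` may be an int or a Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    permuted = rng.permuted(matrix.values, axis=0)
    return PresenceAbsenceMatrix(
        pd.DataFrame(permuted, index=matrix.data.index, columns=matrix.data.columns)
    )


def _null_values(values01: np.ndarray, rng: np.random.Generator, model: str) -> np.ndarray:
    if model == "permute":
        return rng.permuted(values01, axis=0)
    prev = values01.mean(axis=0)
    return (rng.random(values01.shape) < prev[None, :]).astype(np.int8)


def build_null_lift_distribution(
    matrix: PresenceAbsenceMatrix,
    mining_config: MiningConfig | None = None,
    calib_config: CalibrationConfig | None = None,
) -> pd.DataFrame:
    """Pool candidate-rule metric triples over permutation-null matrices.

    Mines ``enumerate_candidate_rules``'s candidate set (metrics only) on each
    of ``n_permutations`` null matrices and concatenates the
    (rule_form, support, confidence, lift) triples.  Per-permutation random
    streams are spawned deterministically from the master seed.
    """
    mcfg = (mining_config or MiningConfig()).resolved(matrix.n_viruses)
    ccfg = calib_config or CalibrationConfig()
    if ccfg.n_permutations <= 0:
        raise ValueError("empty null: n_permutations must be positive")
    vals = matrix.values[matrix.mined_mask(mcfg.include_virus_free_strains)]
    streams = np.random.SeedSequence(ccfg.seed).spawn(ccfg.n_permutations)
    pools = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        null_vals = _null_values(vals, rng, ccfg.null_model)
        pools.append(candidate_rule_stats(null_vals, matrix.n_viruses, mcfg))
    return pd.concat(pools, ignore_index=True)


# ---------------------------------------------------------------------------
# threshold table construction and filtering
# ---------------------------------------------------------------------------

def decile_inner_edges(x, n_bins: int) -> np.ndarray:
    """Inner bin edges at the 1/n .. (n-1)/n quantiles of x (deduplicated)."""
    x = np.asarray(x, float)
    if x.size == 0 or n_bins <= 1:
        return np.empty(0)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    return np.unique(np.quantile(x, qs))


def calibrate_dynamic_thresholds(
    null_pool: pd.DataFrame,
    config: CalibrationConfig | None = None,
    support_edges=None,
    confidence_edges=None,
) -> CalibrationTable:
    """Build the stratified Lift-threshold table from a pooled null.

    Bin edges come from (in order of precedence) the explicit arguments, the
    config, or the deciles of the null pool itself.  Each stratum's threshold
    is the upper (1 - alpha) quantile of its null lifts; empty strata are
    flagged unusable and filled with the global quantile.
    """
    cfg = config or CalibrationConfig()
    if null_pool is None or len(null_pool) == 0:
        raise ValueError("empty null pool")
    sup = null_pool["support"].to_numpy(float)
    conf = null_pool["confidence"].to_numpy(float)
    lift = null_pool["lift"].to_numpy(float)

    if support_edges is None:
        support_edges = cfg.support_edges
    if confidence_edges is None:
        confidence_edges = cfg.confidence_edges
    s_edges = (np.asarray(support_edges, float) if support_edges is not None
               else decile_inner_edges(sup, cfg.n_support_bins))
    c_edges = (np.asarray(confidence_edges, float) if confidence_edges is not None
               else decile_inner_edges(conf, cfg.n_confidence_bins))

    si = np.searchsorted(s_edges, sup, side="right")
    ci = np.searchsorted(c_edges, conf, side="right")
    flat = si * (c_edges.size + 1) + ci
    return _table_from_strata(flat, lift, s_edges, c_edges, cfg.alpha)


def _table_from_strata(
    flat: np.ndarray, lift: np.ndarray,
    s_edges: np.ndarray, c_edges: np.ndarray, alpha: float,
) -> CalibrationTable:
    """Assemble the threshold table from flattened stratum ids and lifts."""
    ns, nc = s_edges.size + 1, c_edges.size + 1
    q = 1.0 - alpha
    global_thr = upper_quantile(lift, q)

    order = np.argsort(flat, kind="stable")
    flat_sorted = flat[order]
    lift_sorted = lift[order]
    boundaries = np.flatnonzero(np.diff(flat_sorted)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [flat.size]])

    thresholds = np.full((ns, nc), global_thr, dtype=float)
    n_null = np.zeros((ns, nc), dtype=int)
    usable = np.zeros((ns, nc), dtype=bool)
    for a, b in zip(starts, stops):
        key = flat_sorted[a]
        r, c = divmod(int(key), nc)
        cell = lift_sorted[a:b]
        thresholds[r, c] = upper_quantile(cell, q)
        n_null[r, c] = b - a
        usable[r, c] = True
    return CalibrationTable(
        support_edges=s_edges, confidence_edges=c_edges, thresholds=thresholds,
        n_null=n_null, usable=usable, global_threshold=global_thr, alpha=alpha,
    )


def calibrate_forms(
    matrix: PresenceAbsenceMatrix,
    mining_config: MiningConfig,
    calib_config: CalibrationConfig,
    candidates_by_form: dict,
) -> dict:
    """Calibrate one threshold table per rule form over a single permutation sweep.

    Memory-lean variant of :func:`calibrate` for large candidate sets: bin
    edges come from each form's observed candidate deciles, and each null
    rule is reduced to its (stratum id, float32 lift) pair as soon as it is
    mined, so the permutation sweep never pools full metric tables.
    """
    mcfg = mining_config.resolved(matrix.n_viruses)
    ccfg = calib_config
    if ccfg.n_permutations <= 0:
        raise ValueError("empty null: n_permutations must be positive")
    edges = {}
    for form, cand in candidates_by_form.items():
        s_edges = (np.asarray(ccfg.support_edges, float) if ccfg.support_edges is not None
                   else decile_inner_edges(cand["support"], ccfg.n_support_bins))
        c_edges = (np.asarray(ccfg.confidence_edges, float)
                   if ccfg.confidence_edges is not None
                   else decile_inner_edges(cand["confidence"], ccfg.n_confidence_bins))
        edges[form] = (s_edges, c_edges)

    from .mining import _mine_arrays  # local import avoids cycle at module load

    vals = matrix.values[matrix.mined_mask(mcfg.include_virus_free_strains)]
    # per form: stratum id -> list of float32 lift chunks (split per permutation,
    # so no pass ever sorts more than one permutation's rules at once)
    accum: dict = {form: {} for form in edges}
    for ss in np.random.SeedSequence(ccfg.seed).spawn(ccfg.n_permutations):
        rng = np.random.default_rng(ss)
        null_vals = _null_values(vals, rng, ccfg.null_model)
        for f in _mine_arrays(null_vals, mcfg.min_support, mcfg.min_confidence,
                              mcfg.max_lhs_size):
            if f["form"] not in edges or f["rhs"].size == 0:
                continue
            s_edges, c_edges = edges[f["form"]]
            si = np.searchsorted(s_edges, f["support"], side="right")
            ci = np.searchsorted(c_edges, f["confidence"], side="right")
            flat = si * (c_edges.size + 1) + ci
            order = np.argsort(flat, kind="stable")
            flat_sorted = flat[order]
            lift_sorted = f["lift"][order].astype(np.float32)
            cuts = np.flatnonzero(np.diff(flat_sorted)) + 1
            strata = accum[f["form"]]
            for a, b in zip(np.concatenate([[0], cuts]),
                            np.concatenate([cuts, [flat.size]])):
                strata.setdefault(int(flat_sorted[a]), []).append(lift_sorted[a:b].copy())
    tables = {}
    q = 1.0 - ccfg.alpha
    for form, strata in accum.items():
        if not strata:
            raise ValueError(f"empty null pool for form {form!r}")
        s_edges, c_edges = edges[form]
        ns, nc = s_edges.size + 1, c_edges.size + 1
        cells = {key: np.concatenate(chunks) for key, chunks in strata.items()}
        global_thr = upper_quantile(np.concatenate(list(cells.values())), q)
        thresholds = np.full((ns, nc), global_thr, dtype=float)
        n_null = np.zeros((ns, nc), dtype=int)
        usable = np.zeros((ns, nc), dtype=bool)
        for key, cell in cells.items():
            r, c = divmod(key, nc)
            thresholds[r, c] = upper_quantile(cell, q)
            n_null[r, c] = cell.size
            usable[r, c] = True
        tables[form] = CalibrationTable(
            support_edges=s_edges, confidence_edges=c_edges, thresholds=thresholds,
            n_null=n_null, usable=usable, global_threshold=global_thr, alpha=ccfg.alpha,
        )
    return tables


def calibrate(
    matrix: PresenceAbsenceMatrix,
    mining_config: MiningConfig | None = None,
    calib_config: CalibrationConfig | None = None,
    candidates: pd.DataFrame | None = None,
) -> CalibrationTable:
    """End-to-end calibration: null pool + thresholds per observed strata.

    Bin edges default to the deciles of the *observed* candidate support and
    confidence distributions (candidates are mined here when not supplied).
    """
    mcfg = (mining_config or MiningConfig()).resolved(matrix.n_viruses)
    ccfg = calib_config or CalibrationConfig()
    if candidates is None:
        vals = matrix.values[matrix.mined_mask(mcfg.include_virus_free_strains)]
        candidates = candidate_rule_stats(vals, matrix.n_viruses, mcfg)
    s_edges = (np.asarray(ccfg.support_edges, float) if ccfg.support_edges is not None
               else decile_inner_edges(candidates["support"], ccfg.n_support_bins))
    c_edges = (np.asarray(ccfg.confidence_edges, float) if ccfg.confidence_edges is not None
               else decile_inner_edges(candidates["confidence"], ccfg.n_confidence_bins))
    null_pool = build_null_lift_distribution(matrix, mcfg, ccfg)
    return calibrate_dynamic_thresholds(
        null_pool, ccfg, support_edges=s_edges, confidence_edges=c_edges
    )


def filter_significant_rules(
    candidates: pd.DataFrame,
    table: CalibrationTable,
    min_support: float | None = None,
    min_lift: float | None = None,
) -> pd.DataFrame:
    """Retain candidates whose Lift strictly exceeds their stratum threshold.

    Optional global floors (``min_support``, ``min_lift``) reproduce the
    published summary cutoffs.  Each retained rule records the threshold it
    beat (``lift_threshold_applied``) and carries ``significant = True``.
    """
    if candidates.empty:
        out = candidates.copy()
        out["significant"] = pd.Series(dtype=bool)
        out["lift_threshold_applied"] = pd.Series(dtype=float)
        return out
    thr = table.threshold_for(
        candidates["support"].to_numpy(float), candidates["confidence"].to_numpy(float)
    )
    mask = table.pass_mask(
        candidates["support"].to_numpy(float),
        candidates["confidence"].to_numpy(float),
        candidates["lift"].to_numpy(float),
        min_support=min_support, min_lift=min_lift,
    )
    out = candidates.loc[mask].copy()
    out["significant"] = True
    out["lift_threshold_applied"] = thr[mask]
    return out.reset_index(drop=True)
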