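"""Presence/absence matrix container, readers/writers and cohort summaries.

The matrix is the single source of truth for every probability downstream:
cell (s, v) is 1 when virus ``v`` was detected (RT-PCR) in strain ``s`` and 0
otherwise.  Wide files carry one column per virus; long files list
``strain_id, virus_id, present`` records with unlisted pairs defaulting to
absent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .validation import Lineage

#: Per-strain virus-count histogram bins used for cohort reporting.
HISTOGRAM_BINS = ("0", "1", "2", "3-5", "6-10", "11-15", "16-20", "21+")
_BIN_EDGES = np.array([-0.5, 0.5, 1.5, 2.5, 5.5, 10.5, 15.5, 20.5, np.inf])


class MatrixValidationError(ValueError):
    """Raised when an input table violates the presence/absence contract."""


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Validated binary strains x viruses occurrence table.

    Parameters
    ----------
    data
        DataFrame indexed by unique strain ids with one 0/1 column per virus.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise MatrixValidationError("matrix must have at least one strain and one virus")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate strain id(s): {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate virus id(s): {dups}")
        vals = df.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"invalid value {vals[r, c]!r} at strain {df.index[r]!r}, "
                f"virus {df.columns[c]!r}: cells must be 0 or 1"
            )
        df = df.astype(np.int8)
        df.index = df.index.rename("strain_id")
        df.columns = df.columns.rename(None)
        object.__setattr__(self, "data", df)

    # -- basic views ------------------------------------------------------
    @property
    def strain_ids(self) -> list:
        return list(self.data.index)

    @property
    def virus_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_strains(self) -> int:
        return self.data.shape[0]

    @property
    def n_viruses(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def prevalence(self) -> pd.Series:
        """Per-virus fraction of strains carrying the virus."""
        return self.data.mean(axis=0)

    def virus_counts(self) -> pd.Series:
        """Per-virus number of strains carrying the virus."""
        return self.data.sum(axis=0)

    def strain_virus_counts(self) -> pd.Series:
        """Per-strain number of detected viruses."""
        return self.data.sum(axis=1)

    def mined_mask(self, include_virus_free: bool = False) -> np.ndarray:
        """Boolean strain mask used for probability estimation.

        Virus-free strains are surveyed but excluded from mining by default
        (probabilities are estimated over infected strains only).
        """
        if include_virus_free:
            return np.ones(self.n_strains, dtype=bool)
        return self.values.sum(axis=1) > 0

    def subset_strains(self, strain_ids: Sequence) -> "PresenceAbsenceMatrix":
        return PresenceAbsenceMatrix(self.data.loc[list(strain_ids)])


@dataclass(frozen=True)
class CohortSummary:
    """Prevalence and co-infection-burden summary of a strain panel."""

    virus_counts: pd.Series
    strain_virus_counts: pd.Series
    histogram: Mapping[str, int]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        viruses = self.virus_counts.rename("n_strains").rename_axis("virus_id").reset_index()
        strains = (
            self.strain_virus_counts.rename("n_viruses").rename_axis("strain_id").reset_index()
        )
        hist = pd.DataFrame(
            {"bin": list(self.histogram.keys()), "n_strains": list(self.histogram.values())}
        )
        return viruses, strains, hist


def cohort_summary(matrix: PresenceAbsenceMatrix) -> CohortSummary:
    """Summarize per-virus prevalence and per-strain co-infection burden.

    The histogram partitions strains by the number of viruses they carry into
    the reporting bins 0, 1, 2, 3-5, 6-10, 11-15, 16-20 and >=21; bin counts
    always sum to the number of strains.
    """
    counts = matrix.strain_virus_counts().to_numpy()
    hist, _ = np.histogram(counts, bins=_BIN_EDGES)
    return CohortSummary(
        virus_counts=matrix.virus_counts(),
        strain_virus_counts=matrix.strain_virus_counts(),
        histogram=dict(zip(HISTOGRAM_BINS, hist.astype(int).tolist())),
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def read_presence_matrix(path, format: str = "wide") -> PresenceAbsenceMatrix:
    """Read a presence/absence matrix from a wide or long delimited file.

    Wide: first column ``strain_id``, remaining columns one per virus, cells
    0/1.  Long: columns ``strain_id, virus_id, present``; duplicate
    (strain, virus) records are an error and unlisted pairs default to 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    if format == "wide":
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.isna().any().any():
            raise MatrixValidationError("missing cells in wide matrix")
        return PresenceAbsenceMatrix(df)
    if format == "long":
        df = pd.read_csv(path, sep=sep, dtype={"strain_id": str, "virus_id": str})
        required = {"strain_id", "virus_id", "present"}
        if not required.issubset(df.columns):
            raise MatrixValidationError(
                f"long format requires columns {sorted(required)}, got {list(df.columns)}"
            )
        dup = df.duplicated(subset=["strain_id", "virus_id"])
        if dup.any():
            pair = df.loc[dup, ["strain_id", "virus_id"]].iloc[0].tolist()
            raise MatrixValidationError(f"duplicate (strain, virus) entry: {pair}")
        bad = ~df["present"].isin((0, 1))
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise MatrixValidationError(
                f"invalid value {row['present']!r} at strain {row['strain_id']!r}, "
                f"virus {row['virus_id']!r}: cells must be 0 or 1"
            )
        wide = (
            df.pivot(index="strain_id", columns="virus_id", values="present")
            .fillna(0)
            .astype(np.int8)
        )
        wide = wide.loc[pd.unique(df["strain_id"]), :]
        return PresenceAbsenceMatrix(wide)
    raise ValueError(f"unknown format {format!r} (expected 'wide' or 'long')")


def write_presence_matrix(matrix: PresenceAbsenceMatrix, path) -> None:
    """Write the matrix in wide format (strain_id + one column per virus)."""
    path = Path(path)
    matrix.data.rename_axis("strain_id").to_csv(path, sep=_sep_for(path))


def read_lineages(path, vocabulary: Iterable | None = None) -> list[Lineage]:
    """Read parent/offspring virus compositions from a lineage CSV.

    Format: ``parent_id,member_id,role,viruses`` with role in
    {parent, offspring} and ``viruses`` a semicolon-separated virus-id list
    (empty for virus-free members).  One :class:`Lineage` is returned per
    parent; when ``vocabulary`` is given every virus id must belong to it.
    """
    path = Path(path)
    vocab = set(map(str, vocabulary)) if vocabulary is not None else None
    parents: dict[str, frozenset] = {}
    offspring: dict[str, list] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            viruses = frozenset(v for v in row["viruses"].split(";") if v)
            if vocab is not None:
                unknown = sorted(viruses - vocab)
                if unknown:
                    raise MatrixValidationError(
                        f"unknown virus id(s) {unknown} in lineage row for "
                        f"{row['member_id']!r}"
                    )
            pid = row["parent_id"]
            if pid not in offspring:
                offspring[pid] = []
                order.append(pid)
            role = row["role"]
            if role == "parent":
                if pid in parents:
                    raise MatrixValidationError(f"duplicate parent row for {pid!r}")
                parents[pid] = viruses
            elif role == "offspring":
                offspring[pid].append((row["member_id"], viruses))
            else:
                raise MatrixValidationError(f"unknown role {role!r} (expected parent/offspring)")
    missing = [p for p in order if p not in parents]
    if missing:
        raise MatrixValidationError(f"lineage(s) without a parent row: {missing}")
    return [
        Lineage(parent_id=p, parent_viruses=parents[p], offspring=tuple(offspring[p]))
        for p in order
    ]


def write_lineages(lineages: Sequence[Lineage], path) -> None:
    rows = []
    for lin in lineages:
        rows.append(
            {"parent_id": lin.parent_id, "member_id": lin.parent_id, "role": "parent",
             "viruses": ";".join(sorted(lin.parent_viruses))}
        )
        for oid, vset in lin.offspring:
            rows.append(
                {"parent_id": lin.parent_id, "member_id": oid, "role": "offspring",
                 "viruses": ";".join(sorted(vset))}
            )
    pd.DataFrame(rows, columns=["parent_id", "member_id", "role", "viruses"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# rules tables
# ---------------------------------------------------------------------------

RULES_TABLE_COLUMNS = (
    "lhs_items",
    "rhs_item",
    "support",
    "confidence",
    "lift",
    "rule_form",
    "rule_type",
    "significant",
    "lift_threshold_applied",
)


def _fmt_item(virus_id: str, state: bool) -> str:
    return f"{virus_id}={'T' if state else 'F'}"


def _parse_item(token: str) -> tuple[str, bool]:
    virus, _, state = token.rpartition("=")
    if state not in {"T", "F"} or not virus:
        raise MatrixValidationError(f"malformed item token {token!r}")
    return virus, state == "T"


def write_rules_table(rules: pd.DataFrame, path) -> None:
    """Write a rules DataFrame as a CSV of serialized items plus metrics.

    ``lhs_items`` is serialized as e.g. ``"V01=T;V07=F"`` and ``rhs_item`` as
    ``"V03=T"``.  Optional columns (rule_type, significant,
    lift_threshold_applied) are emitted empty when absent so the header is
    stable; the file round-trips through :func:`read_rules_table`.
    """
    out = pd.DataFrame(index=rules.index)
    if len(rules):
        out["lhs_items"] = [
            ";".join(_fmt_item(v, s) for v, s in lhs) for lhs in rules["lhs_items"]
        ]
        out["rhs_item"] = [
            _fmt_item(v, s) for v, s in zip(rules["rhs_virus"], rules["rhs_state"])
        ]
        for col in ("support", "confidence", "lift", "rule_form"):
            out[col] = rules[col].to_numpy()
        out["rule_type"] = rules["rule_type"] if "rule_type" in rules else ""
        out["significant"] = rules["significant"] if "significant" in rules else ""
        out["lift_threshold_applied"] = (
            rules["lift_threshold_applied"] if "lift_threshold_applied" in rules else ""
        )
    else:
        out = pd.DataFrame(columns=list(RULES_TABLE_COLUMNS))
    out.to_csv(path, index=False, float_format="%.12g")


def read_rules_table(path) -> pd.DataFrame:
    """Read a rules CSV back into the in-memory rules DataFrame layout."""
    raw = pd.read_csv(path, dtype={"lhs_items": str, "rhs_item": str})
    if raw.empty:
        return pd.DataFrame(
            columns=["lhs_items", "rhs_virus", "rhs_state", "rule_form",
                     "support", "confidence", "lift", "rule_type", "significant",
                     "lift_threshold_applied"]
        )
    lhs = [tuple(_parse_item(tok) for tok in s.split(";")) for s in raw["lhs_items"]]
    rhs = [_parse_item(s) for s in raw["rhs_item"]]
    df = pd.DataFrame(
        {
            "lhs_items": lhs,
            "rhs_virus": [v for v, _ in rhs],
            "rhs_state": [s for _, s in rhs],
            "rule_form": raw["rule_form"],
            "support": raw["support"].astype(float),
            "confidence": raw["confidence"].astype(float),
            "lift": raw["lift"].astype(float),
        }
    )
    for col in ("rule_type", "significant", "lift_threshold_applied"):
        if col in raw:
            df[col] = raw[col]
    return df
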