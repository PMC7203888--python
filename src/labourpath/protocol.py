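"""Intervention protocols, binary intervention paths and path-count tables.

A labour is modelled as a traversal from onset (O) to birth (B) during which a
woman may receive, in a fixed order of increasing invasiveness, any subset of
the interventions in a *sequential protocol*.  With ``n`` interventions there
are exactly ``2**n`` mutually exclusive paths, each encoded as a binary flag
vector (1 = the intervention was received).  The universal data container is
the :class:`PathCountTable`: the number of women observed on each path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ProtocolError",
    "RecordValidationError",
    "DegenerateCohortError",
    "InterventionProtocol",
    "InterventionPath",
    "PathCountTable",
    "DEFAULT_PROTOCOL",
    "ROBSON_CLASSES",
    "enumerate_paths",
    "path_table_from_records",
    "merge_augmentation",
]

#: The fixed vocabulary of Robson classes, including the a/b refinements of
#: groups II and IV commonly used in labour-ward reports.
ROBSON_CLASSES = (
    "I", "IIa", "IIb", "III", "IVa", "IVb", "V", "VI", "VII", "VIII", "IX", "X",
)


class ProtocolError(ValueError):
    """Invalid intervention protocol (empty, duplicated or blank labels)."""


class DegenerateCohortError(ValueError):
    """Raised when a ratio is requested on a cohort with no women (N = 0)."""


class RecordValidationError(ValueError):
    """A per-woman record failed validation; names the offending row/column."""

    def __init__(self, message: str, row: object = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


@dataclass(frozen=True)
class InterventionProtocol:
    """An ordered set of interventions, least to most invasive.

    Parameters
    ----------
    labels
        Unique, non-empty intervention names.  Position ``i < j`` means
        intervention ``i`` is less invasive than ``j`` and, under the
        sequential-protocol assumption, precedes it in time whenever both
        occur.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        labels = tuple(labels)
        if len(labels) < 1:
            raise ProtocolError("a protocol needs at least one intervention")
        if any(not isinstance(l, str) or not l for l in labels):
            raise ProtocolError("intervention labels must be non-empty strings")
        if len(set(labels)) != len(labels):
            raise ProtocolError(f"duplicate intervention labels in {labels!r}")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ProtocolError(
                f"unknown intervention {label!r}; protocol is {self.labels}"
            ) from None

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return self.n


#: Augmentation, ventouse, caesarean — the default three-intervention protocol.
DEFAULT_PROTOCOL = InterventionProtocol(("A", "V", "C"))


@dataclass(frozen=True)
class InterventionPath:
    """One binary intervention path (x, y, z, ...)."""

    flags: tuple[int, ...]

    def __init__(self, flags: Iterable[int]):
        flags = tuple(int(f) for f in flags)
        if any(f not in (0, 1) for f in flags):
            raise ValueError(f"path flags must be 0/1, got {flags}")
        object.__setattr__(self, "flags", flags)

    @property
    def treatments(self) -> int:
        """Number of interventions received on this path (x + y + z)."""
        return sum(self.flags)

    def __iter__(self):
        return iter(self.flags)

    def __len__(self):
        return len(self.flags)


def enumerate_paths(protocol: InterventionProtocol) -> list[InterventionPath]:
    """All ``2**n`` intervention paths in canonical binary-ascending order.

    The leftmost (least invasive) intervention is the most significant bit, so
    for the default protocol the order is (0,0,0), (0,0,1), (0,1,0), (0,1,1),
    (1,0,0), (1,0,1), (1,1,0), (1,1,1).
    """
    if not isinstance(protocol, InterventionProtocol):
        protocol = InterventionProtocol(protocol)
    n = protocol.n
    return [
        InterventionPath(tuple((k >> (n - 1 - i)) & 1 for i in range(n)))
        for k in range(2 ** n)
    ]


def _validate_path(flags: Sequence[int], n: int) -> tuple[int, ...]:
    flags = tuple(int(f) for f in flags)
    if len(flags) != n:
        raise ValueError(f"path {flags} has length {len(flags)}, protocol has n={n}")
    if any(f not in (0, 1) for f in flags):
        raise ValueError(f"path flags must be 0/1, got {flags}")
    return flags


@dataclass
class PathCountTable:
    """Counts of women per binary intervention path.

    ``counts`` maps flag tuples to nonnegative integers; paths absent from the
    mapping count zero.  ``stratum`` optionally labels the subpopulation the
    table refers to (e.g. a Robson class).
    """

    protocol: InterventionProtocol
    counts: dict[tuple[int, ...], int] = field(default_factory=dict)
    stratum: str | None = None

    def __post_init__(self):
        clean: dict[tuple[int, ...], int] = {}
        for path, c in self.counts.items():
            flags = _validate_path(tuple(path), self.protocol.n)
            c = int(c)
            if c < 0:
                raise ValueError(f"negative count {c} for path {flags}")
            clean[flags] = clean.get(flags, 0) + c
        self.counts = clean

    # -- basic accessors -------------------------------------------------
    @property
    def N(self) -> int:
        """Total number of women."""
        return sum(self.counts.values())

    def count(self, path) -> int:
        flags = _validate_path(tuple(path), self.protocol.n)
        return self.counts.get(flags, 0)

    def paths(self) -> list[InterventionPath]:
        return enumerate_paths(self.protocol)

    def require_nonempty(self) -> None:
        if self.N == 0:
            raise DegenerateCohortError(
                "cohort has N = 0 women; ratios are undefined"
            )

    # -- conversions -----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """One row per path (canonical order) with a ``count`` column."""
        rows = [
            dict(zip(self.protocol.labels, p.flags), count=self.count(p))
            for p in self.paths()
        ]
        return pd.DataFrame(rows)

    def to_records(self) -> pd.DataFrame:
        """Expand back to one row per woman (inverse of aggregation)."""
        rows = []
        for p in self.paths():
            rows.extend([dict(zip(self.protocol.labels, p.flags))] * self.count(p))
        return pd.DataFrame(rows, columns=list(self.protocol.labels), dtype=int)

    def scaled(self, k: int) -> "PathCountTable":
        """Multiply every count by a positive integer ``k``."""
        if k <= 0:
            raise ValueError("scale factor must be a positive integer")
        return PathCountTable(
            self.protocol, {p: c * k for p, c in self.counts.items()}, self.stratum
        )

    def __add__(self, other: "PathCountTable") -> "PathCountTable":
        if other.protocol.labels != self.protocol.labels:
            raise ProtocolError("cannot pool tables on different protocols")
        merged = dict(self.counts)
        for p, c in other.counts.items():
            merged[p] = merged.get(p, 0) + c
        return PathCountTable(self.protocol, merged)


def merge_augmentation(
    records: pd.DataFrame,
    components: Sequence[str] = ("amniotomy", "oxytocin"),
    target: str = "A",
) -> pd.DataFrame:
    """OR-merge raw amniotomy/oxytocin flags into a single augmentation flag.

    When both component columns are present they are combined by logical OR
    into ``target`` and dropped; when neither is present the frame is returned
    unchanged.  This makes cohorts with sequential and non-sequential
    augmentation protocols comparable.
    """
    present = [c for c in components if c in records.columns]
    if not present:
        return records
    out = records.copy()
    merged = out[present].astype(int).max(axis=1)
    out = out.drop(columns=present)
    out[target] = merged
    return out


def path_table_from_records(
    records: pd.DataFrame,
    protocol: InterventionProtocol = DEFAULT_PROTOCOL,
    stratify_by: str | None = None,
) -> PathCountTable | dict[str, PathCountTable]:
    """Aggregate per-woman 0/1 intervention records into a path-count table.

    Parameters
    ----------
    records
        One row per woman; must contain one 0/1 column per protocol label.
        Raw ``amniotomy``/``oxytocin`` columns, if present, are OR-merged into
        the augmentation flag first.
    stratify_by
        Optional column (typically ``robson_class``); when given, returns one
        table per stratum.  Robson labels are validated against the fixed
        class vocabulary.
    """
    records = merge_augmentation(records)
    missing = [l for l in protocol.labels if l not in records.columns]
    if missing:
        raise RecordValidationError(
            f"records are missing intervention columns {missing}", column=missing[0]
        )
    for label in protocol.labels:
        col = records[label]
        bad = ~col.isin((0, 1, "0", "1", False, True))
        if bad.any():
            row = records.index[bad][0]
            raise RecordValidationError(
                f"non-binary value {col[row]!r} in column {label!r} at row {row}",
                row=row,
                column=label,
            )

    if stratify_by is not None:
        if stratify_by not in records.columns:
            raise RecordValidationError(
                f"stratification column {stratify_by!r} not present",
                column=stratify_by,
            )
        if stratify_by == "robson_class":
            unknown = set(records[stratify_by].unique()) - set(ROBSON_CLASSES)
            if unknown:
                raise RecordValidationError(
                    f"unknown Robson class labels {sorted(map(str, unknown))}; "
                    f"expected one of {ROBSON_CLASSES}",
                    column=stratify_by,
                )
        return {
            str(value): path_table_from_records(group, protocol)
            for value, group in records.groupby(stratify_by, sort=True)
        }

    counts: dict[tuple[int, ...], int] = {}
    flags_frame = records[list(protocol.labels)].astype(int)
    for path, group in flags_frame.groupby(list(protocol.labels), sort=True):
        key = path if isinstance(path, tuple) else (path,)
        counts[tuple(int(f) for f in key)] = len(group)
    table = PathCountTable(protocol, counts)
    assert table.N == len(records)
    return table
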