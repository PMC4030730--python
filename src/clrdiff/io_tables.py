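"""Reading and writing count tables, condition labels and result tables.

Count tables are plain text, features as rows and samples as columns, the
first column holding feature identifiers and the first row sample
identifiers.  Tab is the default delimiter.  Condition files are two-column
(sample_id, condition) text files.  Result tables are written with a fixed
11-column layout; see :data:`RESULT_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class TableFormatError(ValueError):
    """Raised when an input table fails structural validation."""


class DesignError(ValueError):
    """Raised when condition labels do not form a valid two-group design."""


#: Minimum number of samples per condition required for testing.
MIN_GROUP_SIZE = 3

#: Column order of a written result table.
RESULT_COLUMNS = [
    "feature_id",
    "rab_all",
    "rab_condA",
    "rab_condB",
    "diff_btw",
    "diff_win",
    "effect",
    "we_ep",
    "we_eBH",
    "wi_ep",
    "wi_eBH",
]


@dataclass(frozen=True)
class CountTable:
    """A feature-by-sample matrix of non-negative integer read counts."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # (n_features, n_samples), integer dtype

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise TableFormatError("counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise TableFormatError("counts must be non-negative")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "counts", counts)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        """Per-sample total read counts (column sums)."""
        return self.counts.sum(axis=0)

    def subset_features(self, keep: np.ndarray) -> "CountTable":
        """Return a new table restricted to the given boolean feature mask."""
        keep = np.asarray(keep, dtype=bool)
        ids = tuple(f for f, k in zip(self.feature_ids, keep) if k)
        return CountTable(ids, self.sample_ids, self.counts[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.feature_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class ConditionDesign:
    """A two-level condition assignment for the samples of a count table."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = dict(self.labels)
        levels = sorted(set(labels.values()))
        if len(levels) != 2:
            raise DesignError(
                f"exactly two conditions are required, got {len(levels)}: {levels}"
            )
        for level in levels:
            n = sum(1 for v in labels.values() if v == level)
            if n < MIN_GROUP_SIZE:
                raise DesignError(
                    f"condition {level!r} has {n} samples; at least "
                    f"{MIN_GROUP_SIZE} samples per group are required"
                )
        object.__setattr__(self, "labels", labels)

    @property
    def conditions(self) -> tuple[str, str]:
        return tuple(sorted(set(self.labels.values())))  # type: ignore[return-value]

    def group_indices(
        self, sample_ids: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray, str, str]:
        """Split ``sample_ids`` into the two condition groups.

        Condition "A" is the condition of the first sample in ``sample_ids``
        order; "B" is the other.  Returns (idx_a, idx_b, cond_a, cond_b).
        """
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise DesignError(f"samples without a condition label: {missing}")
        cond_a = self.labels[sample_ids[0]]
        (cond_b,) = [c for c in self.conditions if c != cond_a]
        idx_a = np.array([i for i, s in enumerate(sample_ids) if self.labels[s] == cond_a])
        idx_b = np.array([i for i, s in enumerate(sample_ids) if self.labels[s] == cond_b])
        return idx_a, idx_b, cond_a, cond_b

    def swapped(self) -> "ConditionDesign":
        """Return a design with the two condition labels exchanged."""
        a, b = self.conditions
        flip = {a: b, b: a}
        return ConditionDesign({s: flip[c] for s, c in self.labels.items()})


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise TableFormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


def read_counts(path: str | Path, delimiter: str = "\t") -> CountTable:
    """Read a feature-by-sample count table from a delimited text file.

    The first row holds sample identifiers, the first column feature
    identifiers.  Every body cell must parse as a non-negative integer;
    malformed cells raise :class:`TableFormatError` naming the offending
    row and column.  Lines starting with ``#`` are ignored.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep=delimiter, header=None, dtype=str, comment="#", skip_blank_lines=True
    )
    if raw.shape[0] < 1 or raw.shape[1] < 2:
        raise TableFormatError(f"{path}: not a feature x sample table")
    sample_ids = [str(x) for x in raw.iloc[0, 1:]]
    body = raw.iloc[1:]
    if body.empty:
        raise TableFormatError(f"{path}: table has a header but no feature rows")
    feature_ids = [str(x) for x in body.iloc[:, 0]]
    cells = body.iloc[:, 1:]
    numeric = cells.apply(pd.to_numeric, errors="coerce")
    values = numeric.to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (np.mod(values, 1) != 0) | (values < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise TableFormatError(
            f"{path}: cell at feature {feature_ids[i]!r}, sample "
            f"{sample_ids[j]!r} is not a non-negative integer: {cells.iat[i, j]!r}"
        )
    return CountTable(tuple(feature_ids), tuple(sample_ids), values.astype(np.int64))


def write_counts(table: CountTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write a count table in the layout accepted by :func:`read_counts`."""
    table.to_frame().to_csv(path, sep=delimiter, index_label="feature_id")


def read_conditions(
    source: str | Path | Mapping[str, str], delimiter: str = "\t"
) -> ConditionDesign:
    """Build a :class:`ConditionDesign` from a mapping or a two-column file.

    The file form has one ``sample_id<TAB>condition`` pair per line with no
    header; lines starting with ``#`` are ignored.
    """
    if isinstance(source, Mapping):
        return ConditionDesign(dict(source))
    path = Path(source)
    raw = pd.read_csv(
        path, sep=delimiter, header=None, dtype=str, comment="#", skip_blank_lines=True
    )
    if raw.shape[1] != 2:
        raise DesignError(f"{path}: expected two columns (sample_id, condition)")
    labels: dict[str, str] = {}
    for sample, cond in raw.itertuples(index=False):
        if sample in labels:
            raise DesignError(f"{path}: duplicate sample {sample!r}")
        labels[str(sample)] = str(cond)
    return ConditionDesign(labels)


def conditions_from_labels(
    labels: Sequence[str], sample_ids: Sequence[str]
) -> ConditionDesign:
    """Build a design from a positional label list matching ``sample_ids``."""
    if len(labels) != len(sample_ids):
        raise DesignError(
            f"{len(labels)} labels given for {len(sample_ids)} samples"
        )
    return ConditionDesign(dict(zip(sample_ids, labels)))


def write_results(
    results: pd.DataFrame, path: str | Path, note: str | None = None
) -> None:
    """Write a per-feature result table as tab-separated text.

    Columns are written in :data:`RESULT_COLUMNS` order with at least six
    significant digits.  ``note`` (e.g. the sign convention of diff_btw) is
    emitted as a leading ``#`` comment line.
    """
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise TableFormatError(f"result table is missing columns: {missing}")
    out = results[RESULT_COLUMNS]
    with open(path, "w") as fh:
        if note:
            fh.write(f"# {note}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    """Re-read a result table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing result columns: {missing}")
    return df
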