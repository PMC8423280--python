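"""Domain containers and CSV readers/writers for probability score tables.

The central objects are:

* :class:`ClassCatalog` — the ordered class list plus the designated
  positive class.  The catalog order is the canonical column order of
  score tables and the index order used by argmax prediction.
* :class:`LabelVector` — ground-truth class per sample.
* :class:`ProbabilityTable` — one base learner's per-sample, per-class
  probability rows (softmax-style output), aligned to the catalog.
* :class:`ClassifierBundle` — several tables over identical samples,
  the unit consumed by the fusion and cross-validation machinery.

File dialect: UTF-8 CSV.  Score tables carry a ``sample_id`` column and
one ``prob_<class>`` column per catalog class; label files carry
``sample_id,label``.  Lines starting with ``#`` are comments and are
skipped on read (the CLI uses them for version/seed provenance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParseError, SchemaError, ValidationError

#: Maximum tolerated deviation of a probability row sum from 1.  Rows
#: within tolerance are renormalized (softmax output carries float
#: noise); rows outside it raise, since silently fixing bad data hides
#: upstream bugs.
ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered class names and the positive class of the binary task.

    The ordering is a contract: probability columns, argmax indices and
    tie-breaking all refer to it.  For the pneumonia screening task the
    catalog is ``("Normal", "Pneumonia")`` with positive ``"Pneumonia"``.
    """

    classes: tuple[str, ...]
    positive: str

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValidationError("catalog needs at least 2 classes")
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("class names must be unique")
        if any(not c for c in self.classes):
            raise ValidationError("class names must be non-empty")
        if self.positive not in self.classes:
            raise ValidationError(
                f"positive class {self.positive!r} not in catalog {self.classes}"
            )

    def index(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise ValidationError(f"class {name!r} not in catalog") from None

    @property
    def positive_index(self) -> int:
        return self.classes.index(self.positive)


@dataclass(frozen=True)
class LabelVector:
    """Ground-truth class per sample, in a fixed sample order."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    catalog: ClassCatalog

    def __post_init__(self) -> None:
        if len(self.sample_ids) < 1:
            raise ValidationError("label vector must contain at least one sample")
        if len(self.sample_ids) != len(self.labels):
            raise AlignmentError("sample_ids and labels differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample identifiers must be unique")
        bad = sorted({l for l in self.labels} - set(self.catalog.classes))
        if bad:
            raise ValidationError(f"labels not in catalog: {bad}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_indices(self) -> np.ndarray:
        """Labels as integer indices into the catalog order."""
        lut = {c: i for i, c in enumerate(self.catalog.classes)}
        return np.array([lut[l] for l in self.labels], dtype=np.intp)

    def subset(self, indices: Sequence[int]) -> "LabelVector":
        idx = list(indices)
        return LabelVector(
            tuple(self.sample_ids[i] for i in idx),
            tuple(self.labels[i] for i in idx),
            self.catalog,
        )


@dataclass(eq=False)
class ProbabilityTable:
    """Per-sample per-class probabilities emitted by one classifier.

    ``probabilities`` has shape ``(n_samples, n_classes)`` with columns
    in catalog order.  Rows must sum to 1 within :data:`ROW_SUM_TOL`;
    rows within tolerance are renormalized exactly on construction.
    """

    name: str
    sample_ids: tuple[str, ...]
    probabilities: np.ndarray
    catalog: ClassCatalog

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("classifier name must be non-empty")
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != len(self.catalog.classes):
            raise ValidationError(
                f"probabilities must be (n, {len(self.catalog.classes)}); "
                f"got shape {probs.shape}"
            )
        if probs.shape[0] != len(self.sample_ids):
            raise AlignmentError("row count does not match sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample identifiers must be unique")
        if probs.size:
            if np.any(~np.isfinite(probs)) or probs.min() < 0 or probs.max() > 1:
                raise ValidationError(
                    f"{self.name}: probabilities must lie in [0, 1]"
                )
            sums = probs.sum(axis=1)
            off = np.abs(sums - 1.0)
            if off.max() > ROW_SUM_TOL:
                row = int(np.argmax(off > ROW_SUM_TOL))
                raise ValidationError(
                    f"{self.name}: row {self.sample_ids[row]!r} sums to "
                    f"{sums[row]:.6g}, outside tolerance {ROW_SUM_TOL}"
                )
            probs = probs / sums[:, None]
        self.probabilities = probs

    def __len__(self) -> int:
        return len(self.sample_ids)

    def positive_scores(self) -> np.ndarray:
        """The positive-class probability column."""
        return self.probabilities[:, self.catalog.positive_index]

    def subset(self, indices: Sequence[int]) -> "ProbabilityTable":
        idx = np.asarray(list(indices), dtype=np.intp)
        return ProbabilityTable(
            self.name,
            tuple(self.sample_ids[i] for i in idx),
            self.probabilities[idx],
            self.catalog,
        )

    def equals(self, other: "ProbabilityTable", atol: float = 1e-12) -> bool:
        return (
            self.name == other.name
            and self.sample_ids == other.sample_ids
            and self.catalog == other.catalog
            and self.probabilities.shape == other.probabilities.shape
            and bool(
                np.allclose(self.probabilities, other.probabilities, atol=atol, rtol=0)
            )
        )


@dataclass(eq=False)
class ClassifierBundle:
    """Probability tables from several classifiers over identical samples."""

    tables: list[ProbabilityTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValidationError("bundle must contain at least one table")
        names = [t.name for t in self.tables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate classifier names: {dupes}")
        ref = self.tables[0]
        for t in self.tables[1:]:
            if t.sample_ids != ref.sample_ids:
                raise AlignmentError(
                    f"table {t.name!r} sample order differs from {ref.name!r}"
                )
            if t.catalog != ref.catalog:
                raise AlignmentError(
                    f"table {t.name!r} catalog differs from {ref.name!r}"
                )

    def __len__(self) -> int:
        return len(self.tables)

    def __iter__(self):
        return iter(self.tables)

    @property
    def catalog(self) -> ClassCatalog:
        return self.tables[0].catalog

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.tables[0].sample_ids

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tables]

    def stacked(self) -> np.ndarray:
        """Probabilities stacked to shape (K, n_samples, n_classes)."""
        return np.stack([t.probabilities for t in self.tables])

    def subset(self, indices: Sequence[int]) -> "ClassifierBundle":
        return ClassifierBundle([t.subset(indices) for t in self.tables])


# ---------------------------------------------------------------------------
# CSV I/O


def _prob_columns(catalog: ClassCatalog) -> list[str]:
    return [f"prob_{c}" for c in catalog.classes]


def read_score_table(
    path: str | Path, catalog: ClassCatalog, name: str | None = None
) -> ProbabilityTable:
    """Read one classifier's score table from CSV.

    The header must declare ``sample_id`` and one ``prob_<class>``
    column for every catalog class (any column order); row order is
    preserved.  ``name`` defaults to the file stem.

    Raises :class:`SchemaError` for a missing column, :class:`ParseError`
    for a non-numeric probability cell, and :class:`ValidationError` for
    a row whose probabilities do not sum to 1 within tolerance.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str})
    required = ["sample_id", *_prob_columns(catalog)]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    probs = df[_prob_columns(catalog)]
    numeric = probs.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any() and not probs.isna().values.any():
        bad = numeric.isna().any(axis=1)
        row = df.loc[bad, "sample_id"].iloc[0]
        raise ParseError(f"{path}: non-numeric probability in row {row!r}")
    if numeric.isna().values.any():
        bad = numeric.isna().any(axis=1)
        row = df.loc[bad, "sample_id"].iloc[0]
        raise ParseError(f"{path}: missing probability in row {row!r}")
    return ProbabilityTable(
        name=name or path.stem,
        sample_ids=tuple(df["sample_id"].astype(str)),
        probabilities=numeric.to_numpy(dtype=float),
        catalog=catalog,
    )


def write_score_table(
    table: ProbabilityTable,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a score table as CSV with columns in catalog order.

    Probabilities are serialized with 12 significant digits so the
    read/write round trip is the identity to well below 1e-12.
    """
    path = Path(path)
    cols = _prob_columns(table.catalog)
    df = pd.DataFrame(table.probabilities, columns=cols)
    df.insert(0, "sample_id", list(table.sample_ids))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_labels(path: str | Path, catalog: ClassCatalog) -> LabelVector:
    """Read a ``sample_id,label`` CSV into a :class:`LabelVector`."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return LabelVector(
        tuple(df["sample_id"]), tuple(df["label"]), catalog
    )


def write_labels(
    labels: LabelVector, path: str | Path, header_comment: str | None = None
) -> None:
    df = pd.DataFrame(
        {"sample_id": list(labels.sample_ids), "label": list(labels.labels)}
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def infer_catalog_from_scores(path: str | Path, positive: str) -> ClassCatalog:
    """Build a catalog from a score file's ``prob_<class>`` header order."""
    df = pd.read_csv(path, comment="#", nrows=0)
    classes = tuple(
        c[len("prob_"):] for c in df.columns if c.startswith("prob_")
    )
    if len(classes) < 2:
        raise SchemaError(f"{path}: fewer than two prob_<class> columns")
    return ClassCatalog(classes=classes, positive=positive)


def align_bundle(
    tables: Iterable[ProbabilityTable], labels: LabelVector
) -> ClassifierBundle:
    """Reorder each table to the label vector's sample order and bundle them.

    Raises :class:`AlignmentError` listing the symmetric difference when
    a table's sample set differs from the labels'.
    """
    tables = list(tables)
    if not tables:
        raise ValidationError("no tables to align")
    order = {sid: i for i, sid in enumerate(labels.sample_ids)}
    aligned = []
    for t in tables:
        if set(t.sample_ids) != set(labels.sample_ids):
            missing = sorted(set(labels.sample_ids) - set(t.sample_ids))
            extra = sorted(set(t.sample_ids) - set(labels.sample_ids))
            raise AlignmentError(
                f"table {t.name!r} samples differ from labels; "
                f"missing={missing[:10]} extra={extra[:10]}"
            )
        perm = np.argsort([order[sid] for sid in t.sample_ids], kind="stable")
        aligned.append(
            replace(
                t,
                sample_ids=tuple(t.sample_ids[i] for i in perm),
                probabilities=t.probabilities[perm],
            )
        )
    return ClassifierBundle(aligned)
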