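"""Readers, writers and probe filtering for methylation beta matrices.

Beta matrices are stored probes-as-rows (array-community convention):
column 1 holds the Illumina-style probe IDs, the header row holds sample
IDs, and cells hold beta values in [0, 1] (empty cell = missing).
Reference libraries are serialized as versioned JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .hierarchy import CellHierarchy

LIBRARY_FORMAT_VERSION = "1.0"

EXCLUSION_CATEGORIES = ("cross_reactive", "snp_related", "sex_chromosome", "non_cpg")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    ``values`` is a float array with NaN marking missing entries; every
    non-missing value lies in [0, 1]; probe and sample IDs are unique.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        self._check_range()

    def _check_range(self) -> None:
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {self.values[i, j]!r} outside [0, 1] at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in index]
        if missing:
            raise ValidationError(f"probes not in matrix: {missing[:5]!r}...")
        rows = [index[p] for p in probes]
        return BetaMatrix(list(probes), list(self.sample_ids), self.values[rows, :])

    def select_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]!r}...")
        cols = [index[s] for s in samples]
        return BetaMatrix(list(self.probe_ids), list(samples), self.values[:, cols])


@dataclass(frozen=True)
class ProbeExclusionSet:
    """A named list of probes to remove (cross-reactive, SNP-related, ...)."""

    category: str
    probe_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.category not in EXCLUSION_CATEGORIES:
            raise ValidationError(
                f"unknown exclusion category {self.category!r}; "
                f"expected one of {EXCLUSION_CATEGORIES}"
            )
        object.__setattr__(self, "probe_ids", frozenset(str(p) for p in self.probe_ids))


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} ID {x!r}")
        seen.add(x)


def _dialect_sep(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    if dialect not in ("csv", "tsv"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_beta_matrix(
    path: str | Path, dialect: str | None = None, transpose: bool = False
) -> BetaMatrix:
    """Read a beta matrix CSV/TSV (probe IDs in column 1, sample IDs in row 1).

    Empty cells become missing values. ``transpose`` accepts samples-as-rows
    files. Out-of-range values, duplicate IDs and non-numeric cells raise
    :class:`ValidationError`.
    """
    sep = _dialect_sep(path, dialect)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    # pandas silently mangles duplicate header names, so check the raw header
    _check_unique(header[1:], "sample" if not transpose else "probe")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # malformed header / unreadable file
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if df.columns.isnull().any() or df.index.isnull().any():
        raise ValidationError(f"malformed header or probe column in {path}")
    if transpose:
        df = df.T
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"non-numeric value {cell!r} at probe {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}"
                ) from None
    return BetaMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_beta_matrix(beta: BetaMatrix, path: str | Path, dialect: str | None = None) -> None:
    sep = _dialect_sep(path, dialect)
    beta.to_dataframe().to_csv(path, sep=sep, float_format="%.17g")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table with at least sample_id and cell_type."""
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "cell_type"):
        if col not in df.columns:
            raise ValidationError(f"annotation file {path} lacks column {col!r}")
    _check_unique(list(df["sample_id"]), "sample")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return df


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, index=False)


def read_exclusion_list(path: str | Path, category: str) -> ProbeExclusionSet:
    """Read a plain-text exclusion list (one probe per line, # comments)."""
    probes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            probes.add(line)
    return ProbeExclusionSet(category=category, probe_ids=frozenset(probes))


def filter_probes(
    beta: BetaMatrix,
    exclusions: Iterable[ProbeExclusionSet] = (),
    drop_non_cpg_prefixes: bool = True,
) -> BetaMatrix:
    """Remove excluded probes and, optionally, ``ch.``/``rs`` prefixed probes.

    The union of all exclusion lists is removed; samples and values are
    untouched. Idempotent. Raises if nothing survives.
    """
    drop: set[str] = set()
    for ex in exclusions:
        drop |= set(ex.probe_ids)
    keep = [
        p
        for p in beta.probe_ids
        if p not in drop
        and not (drop_non_cpg_prefixes and (p.startswith("ch.") or p.startswith("rs")))
    ]
    if not keep:
        raise ValidationError("empty matrix after filtering")
    if len(keep) == len(beta.probe_ids):
        return beta
    return beta.select_probes(keep)


def read_proportions(path: str | Path) -> pd.DataFrame:
    """Read a proportions CSV (samples as rows, cell types as columns)."""
    df = pd.read_csv(path, index_col=0)
    return df


def write_proportions(props: pd.DataFrame, path: str | Path) -> None:
    props.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# reference-library serialization


def save_library(lib, path: str | Path) -> None:
    """Serialize a :class:`~hibed.library.ReferenceLibrary` to versioned JSON."""
    doc = {
        "format_version": LIBRARY_FORMAT_VERSION,
        "hierarchy": lib.hierarchy.to_dict(),
        "provenance": lib.provenance,
        "sub_libraries": [
            {
                "node": sub.node_label,
                "cell_types": list(sub.cell_types),
                "probe_ids": list(sub.probe_ids),
                "means": [[float(v) for v in row] for row in sub.means],
                "complement_mean": (
                    None
                    if sub.complement_mean is None
                    else [float(v) for v in sub.complement_mean]
                ),
            }
            for sub in lib.sub_libraries.values()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_library(path: str | Path):
    """Load a reference library, checking format version and completeness."""
    from .library import ReferenceLibrary, SubLibrary  # avoid circular import

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"cannot parse library file {path}: {exc}") from exc
    version = doc.get("format_version")
    if version != LIBRARY_FORMAT_VERSION:
        raise ValidationError(
            f"library format version {version!r} unsupported "
            f"(expected {LIBRARY_FORMAT_VERSION!r})"
        )
    hierarchy = CellHierarchy.from_dict(doc["hierarchy"])
    subs = {}
    for block in doc["sub_libraries"]:
        subs[block["node"]] = SubLibrary(
            node_label=block["node"],
            cell_types=list(block["cell_types"]),
            probe_ids=list(block["probe_ids"]),
            means=np.asarray(block["means"], dtype=float),
            complement_mean=(
                None
                if block.get("complement_mean") is None
                else np.asarray(block["complement_mean"], dtype=float)
            ),
        )
    lib = ReferenceLibrary(
        hierarchy=hierarchy, sub_libraries=subs, provenance=doc.get("provenance", {})
    )
    return lib
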