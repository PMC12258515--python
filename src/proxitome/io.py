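"""Readers, writers and validated containers for intensity matrices,
sample metadata, gene sets (GMT), annotation tables and phosphosite tables.

All intensities are handled in log2 space internally. Raw-scale input can be
converted at read time; in raw space an intensity of 0 is treated as missing
(MaxQuant-style exports use 0 for absent proteins).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("proxitome")

#: controlled vocabulary for annotation labels used across the analyses
DEFAULT_VOCABULARY = frozenset(
    {
        "has_pTyr_site",
        "mitochondrial",
        "matrix",
        "intermembrane_space",
        "inner_membrane",
        "outer_membrane",
        "complex_I_core",
        "complex_I_accessory",
        "complex_I_assembly",
        "complex_II",
        "complex_III",
        "complex_IV",
        "complex_V",
    }
)

#: labels that imply the parent "mitochondrial" label
_SUBMITO_LABELS = frozenset(DEFAULT_VOCABULARY - {"has_pTyr_site", "mitochondrial"})

_MISSING_SENTINELS = {"", "NA", "NaN", "nan", "na"}

_METADATA_COLUMNS = ("variant", "egf", "inhibitor", "replicate")


def _parse_state(value: object, column: str, sample: str) -> str:
    """Normalize a ±condition field ('+'/'-', yes/no, true/false, 0/1) to '+'/'-'."""
    text = str(value).strip().lower()
    if text in {"+", "plus", "yes", "true", "1", "stimulated", "treated"}:
        return "+"
    if text in {"-", "minus", "no", "false", "0", "unstimulated", "untreated"}:
        return "-"
    raise ValueError(
        f"cannot interpret {column}={value!r} for sample {sample!r}; expected +/-"
    )


@dataclass
class IntensityTable:
    """Proteins × samples log2 intensity matrix with metadata and masks.

    Parameters
    ----------
    values : DataFrame
        log2 intensities, index = protein IDs, columns = sample IDs.
        NaN marks a missing (unquantified) cell.
    metadata : DataFrame
        One row per sample (index = sample ID) with columns
        ``variant``, ``egf`` ('+'/'-'), ``inhibitor`` ('+'/'-'), ``replicate``.
    imputed : DataFrame, optional
        Boolean mask, same shape as ``values``; True where the value was
        filled in by imputation rather than observed.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = self.values.index
        if ids.duplicated().any():
            dups = sorted(set(ids[ids.duplicated()]))
            raise ValueError(f"duplicate protein IDs: {dups}")
        samples = list(self.values.columns)
        meta_samples = list(self.metadata.index)
        missing_meta = [s for s in samples if s not in set(meta_samples)]
        if missing_meta:
            raise ValueError(f"samples absent from metadata: {missing_meta}")
        extra_meta = [s for s in meta_samples if s not in set(samples)]
        if extra_meta:
            raise ValueError(f"metadata samples absent from matrix: {extra_meta}")
        for col in _METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata is missing required column {col!r}")
            if self.metadata[col].isna().any():
                bad = list(self.metadata.index[self.metadata[col].isna()])
                raise ValueError(f"metadata column {col!r} incomplete for {bad}")
        # normalize metadata in place: align order, coerce condition fields
        self.metadata = self.metadata.loc[samples].copy()
        for col in ("egf", "inhibitor"):
            self.metadata[col] = [
                _parse_state(v, col, s)
                for s, v in self.metadata[col].items()
            ]
        self.metadata["replicate"] = self.metadata["replicate"].astype(int)
        if (self.metadata["replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        else:
            if not (
                self.imputed.index.equals(self.values.index)
                and self.imputed.columns.equals(self.values.columns)
            ):
                raise ValueError("imputed mask does not align with values")
            self.imputed = self.imputed.astype(bool)

    # ------------------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def observed_mask(self) -> pd.DataFrame:
        """True where a value was actually measured (present and not imputed)."""
        return self.values.notna() & ~self.imputed

    def samples_for(
        self,
        variant: str | None = None,
        egf: str | None = None,
        inhibitor: str | None = None,
    ) -> list[str]:
        """Sample IDs matching the given (sub)condition."""
        sel = pd.Series(True, index=self.metadata.index)
        if variant is not None:
            sel &= self.metadata["variant"] == variant
        if egf is not None:
            sel &= self.metadata["egf"] == _parse_state(egf, "egf", "<query>")
        if inhibitor is not None:
            sel &= self.metadata["inhibitor"] == _parse_state(
                inhibitor, "inhibitor", "<query>"
            )
        return list(self.metadata.index[sel])

    def copy(self) -> "IntensityTable":
        return IntensityTable(
            self.values.copy(), self.metadata.copy(), self.imputed.copy()
        )


def read_intensity_table(
    matrix_path: str | Path,
    metadata_path: str | Path,
    *,
    missing_sentinel: str = "NA",
    log2_input: bool = True,
) -> IntensityTable:
    """Read a proteins × samples TSV plus a sample-metadata TSV.

    The matrix file has the protein ID in the first column and one column per
    sample. Empty cells and the sentinel become missing. With
    ``log2_input=False`` values are raw intensities: zeros become missing and
    the remainder are log2-transformed.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError(f"{matrix_path}: expected protein ID column plus samples")
    id_col = raw.columns[0]
    ids = raw[id_col].astype(str)
    if ids.duplicated().any():
        dups = sorted(set(ids[ids.duplicated()]))
        raise ValueError(f"{matrix_path}: duplicate protein IDs: {dups}")
    sentinels = _MISSING_SENTINELS | {missing_sentinel}
    values = pd.DataFrame(index=pd.Index(ids, name="protein_id"), dtype=float)
    for col in raw.columns[1:]:
        cells = raw[col].str.strip()
        parsed = np.full(len(cells), np.nan)
        for i, cell in enumerate(cells):
            if cell in sentinels:
                continue
            try:
                parsed[i] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{matrix_path}: non-numeric cell {cell!r} at "
                    f"protein {ids.iloc[i]!r}, sample {col!r}"
                ) from None
        values[col] = parsed
    if not log2_input:
        arr = values.to_numpy()
        arr = np.where(arr == 0, np.nan, arr)  # raw 0 means absent
        if np.any(arr < 0):
            raise ValueError(f"{matrix_path}: negative raw intensities")
        values = pd.DataFrame(
            np.log2(arr), index=values.index, columns=values.columns
        )
    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in metadata.columns:
        raise ValueError(f"{metadata_path}: missing 'sample_id' column")
    metadata = metadata.set_index("sample_id")
    return IntensityTable(values, metadata)


def write_intensity_table(
    table: IntensityTable,
    matrix_path: str | Path,
    metadata_path: str | Path,
    *,
    missing_sentinel: str = "NA",
) -> None:
    """Write the table in the same TSV dialect :func:`read_intensity_table` reads.

    Values are serialized with shortest-round-trip precision, so a
    write → read cycle reproduces the matrix bitwise.
    """
    out = table.values.copy()
    with open(matrix_path, "w") as fh:
        fh.write("protein_id\t" + "\t".join(out.columns) + "\n")
        for pid, row in out.iterrows():
            cells = [
                missing_sentinel if pd.isna(v) else repr(float(v)) for v in row
            ]
            fh.write(str(pid) + "\t" + "\t".join(cells) + "\n")
    meta = table.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


# ----------------------------------------------------------------------
# Gene sets (GMT)
# ----------------------------------------------------------------------


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene-set names: {dups}")
        for s in self.sets:
            if not s.members:
                raise ValueError(f"gene set {s.name!r} has no members")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line — name, description, members, tab-separated."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one member ({len(fields)} fields found)"
                )
            sets.append(GeneSet(fields[0], fields[1], list(fields[2:])))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ----------------------------------------------------------------------
# Annotation tables
# ----------------------------------------------------------------------


class AnnotationTable:
    """protein ID → set of labels, against a controlled vocabulary.

    A sub-mitochondrial label (matrix, intermembrane_space, membrane or ETC
    complex labels) implies the parent ``mitochondrial`` label; the parent
    label is added automatically so queries on ``mitochondrial`` are complete.
    Proteins absent from the table simply carry no labels.
    """

    def __init__(
        self,
        labels: Mapping[str, Iterable[str]],
        vocabulary: Iterable[str] = DEFAULT_VOCABULARY,
    ) -> None:
        self.vocabulary = frozenset(vocabulary)
        mapping: dict[str, set[str]] = {}
        for pid, labs in labels.items():
            labs = set(labs)
            unknown = labs - self.vocabulary
            if unknown:
                raise ValueError(
                    f"labels {sorted(unknown)} for {pid!r} are outside the "
                    f"declared vocabulary"
                )
            if labs & _SUBMITO_LABELS and "mitochondrial" in self.vocabulary:
                labs.add("mitochondrial")
            mapping[str(pid)] = labs
        self._labels = mapping

    def labels(self, protein_id: str) -> set[str]:
        return set(self._labels.get(protein_id, set()))

    def has(self, protein_id: str, label: str) -> bool:
        return label in self._labels.get(protein_id, set())

    def with_label(self, label: str) -> set[str]:
        if label not in self.vocabulary:
            raise ValueError(f"label {label!r} not in vocabulary")
        return {pid for pid, labs in self._labels.items() if label in labs}

    def __len__(self) -> int:
        return len(self._labels)

    @classmethod
    def from_gene_sets(
        cls,
        collection: GeneSetCollection,
        vocabulary: Iterable[str] = DEFAULT_VOCABULARY,
    ) -> "AnnotationTable":
        mapping: dict[str, set[str]] = {}
        for s in collection:
            for pid in s.members:
                mapping.setdefault(pid, set()).add(s.name)
        return cls(mapping, vocabulary)

    def to_gene_sets(self) -> GeneSetCollection:
        by_label: dict[str, list[str]] = {}
        for pid, labs in self._labels.items():
            for lab in labs:
                by_label.setdefault(lab, []).append(pid)
        sets = [
            GeneSet(lab, "annotation", sorted(members))
            for lab, members in sorted(by_label.items())
        ]
        return GeneSetCollection(sets)


# ----------------------------------------------------------------------
# Phosphosite tables
# ----------------------------------------------------------------------

PHOSPHOSITE_COLUMNS = ("protein_id", "position", "window")


def read_phosphosites(path: str | Path) -> pd.DataFrame:
    """Read a phosphosite table: protein_id, residue position, flanking window."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "window": str})
    missing = [c for c in PHOSPHOSITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["position"] = df["position"].astype(int)
    return df[list(PHOSPHOSITE_COLUMNS)]


def write_phosphosites(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
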