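"""Core data model and file I/O for expression analysis.

Containers for log2 expression matrices, sample design tables, probeset
annotations, and gene-set collections (GMT), together with the plain-text
readers/writers the rest of the pipeline consumes. Expression values are
assumed to be already normalized and on log2 scale; the loaders validate
structure and finiteness but never impute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("clrnet")

#: decimal places used when serializing expression values; read(write(m)) == m
#: holds exactly because generated values are rounded to this precision first.
FLOAT_PRECISION = 10


class FormatError(ValueError):
    """A file violates the structural contract of its format."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probesets x samples matrix of log2 expression values.

    Rows are probesets (the microarray measurement unit; several probesets
    may interrogate the same gene and are kept as separate rows), columns
    are samples. All values must be finite.
    """

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise FormatError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite value at probe {self.probe_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_ids.index(probe_id)]

    def subset_probes(self, keep: list[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``keep`` (in the given order)."""
        index = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [index[p] for p in keep]
        return ExpressionMatrix(tuple(keep), self.sample_ids, self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.probe_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample metadata: condition, time, replicate, baseline flag.

    ``is_baseline_control`` marks untreated reference samples; fold changes
    are computed against their mean and they are excluded from the
    condition x time ANOVA (they occupy no factorial cell).
    """

    table: pd.DataFrame  # index = sample_id; columns condition, time, replicate, is_baseline_control

    def __post_init__(self) -> None:
        required = {"condition", "time", "replicate", "is_baseline_control"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise FormatError("duplicate sample ids in design")
        if (self.table["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be >= 1")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    @property
    def baseline_samples(self) -> tuple[str, ...]:
        mask = self.table["is_baseline_control"].astype(bool)
        return tuple(self.table.index[mask])

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        """Every sample in the matrix must appear exactly once in the design."""
        design_ids = set(self.table.index)
        matrix_ids = set(matrix.sample_ids)
        if matrix_ids - design_ids:
            raise FormatError(
                f"samples missing from design: {sorted(matrix_ids - design_ids)[:5]}"
            )


@dataclass(frozen=True)
class ProbeAnnotation:
    """probe_id -> gene symbol map. Empty symbol means unannotated.

    Unannotated probes travel through the network stages under their
    probe_id and are dropped only from gene-level operations.
    """

    mapping: Mapping[str, str]

    def gene_of(self, probe_id: str) -> str:
        if probe_id not in self.mapping:
            raise KeyError(f"probe {probe_id!r} has no annotation entry")
        return self.mapping[probe_id]

    def genes_of(self, probe_ids, drop_unannotated: bool = True) -> set[str]:
        """Gene symbols for a probe collection; unannotated dropped with a log line."""
        genes, dropped = set(), 0
        for p in probe_ids:
            g = self.gene_of(p)
            if g:
                genes.add(g)
            else:
                dropped += 1
                if not drop_unannotated:
                    genes.add(p)
        if dropped:
            logger.info("dropped %d unannotated probes from gene mapping", dropped)
        return genes


@dataclass(frozen=True)
class GeneSetCollection:
    """term_id -> (term_name, member gene symbols), as read from GMT."""

    terms: Mapping[str, tuple[str, frozenset]]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise FormatError(f"term {tid!r} has an empty member set")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())

    def members(self, term_id: str) -> frozenset:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    """Read a TSV expression matrix: header = sample ids, first column = probe ids."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path.name}: duplicate probe id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = df.index[coerced.isna()][0]
            raise FormatError(
                f"{path.name}: non-numeric value at probe {row!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path.name}: missing value in probe {row!r}")
    return ExpressionMatrix(
        tuple(str(i) for i in df.index),
        tuple(str(c) for c in df.columns),
        df.to_numpy(dtype=float),
    )


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=f"%.{FLOAT_PRECISION}f")


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str, "time": str})
    if "sample_id" not in df.columns:
        raise FormatError("design table needs a sample_id column")
    df = df.set_index("sample_id")
    df["is_baseline_control"] = df["is_baseline_control"].astype(bool)
    df["replicate"] = df["replicate"].astype(int)
    return SampleDesign(df)


def write_design(design: SampleDesign, path) -> None:
    out = design.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> ProbeAnnotation:
    """Two-column TSV probe_id<TAB>gene_symbol (symbol may be empty)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 1:
                continue
            probe = parts[0]
            gene = parts[1] if len(parts) > 1 else ""
            if probe in mapping:
                raise FormatError(f"line {lineno}: duplicate probe id {probe!r}")
            mapping[probe] = gene
    return ProbeAnnotation(mapping)


def write_annotation(annot: ProbeAnnotation, path) -> None:
    with open(path, "w") as fh:
        for probe, gene in annot.mapping.items():
            fh.write(f"{probe}\t{gene}\n")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: term_id<TAB>description<TAB>member1<TAB>member2..."""
    terms: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"line {lineno}: GMT lines need term, description and >=1 member"
                )
            term_id, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"line {lineno}: term {term_id!r} has no members")
            if term_id in terms:
                raise FormatError(f"line {lineno}: duplicate term id {term_id!r}")
            terms[term_id] = (desc, frozenset(members))
    return GeneSetCollection(terms)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id, (desc, members) in collection:
            fh.write("\t".join([term_id, desc, *sorted(members)]) + "\n")
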