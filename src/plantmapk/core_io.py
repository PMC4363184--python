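"""Readers and writers for the external formats the pipeline touches.

All interval types are 0-based, half-open.  GFF3 (1-based inclusive) is
converted on read.  Sequences are normalised on read: uppercased, internal
whitespace removed, terminal '*' stop symbols stripped.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from skbio import TreeNode

from .constants import AMINO_ACIDS, GAP, UNKNOWN_RESIDUE

_VALID_RESIDUES = frozenset(AMINO_ACIDS + UNKNOWN_RESIDUE)
_VALID_ALIGNED = _VALID_RESIDUES | {GAP}
_WS = re.compile(r"\s+")


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with optional species metadata."""

    id: str
    sequence: str
    species_tag: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record requires a non-empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one mRNA, in transcription order.

    ``exons`` are 0-based half-open intervals on the gene's strand,
    non-overlapping and sorted by start.  ``orf_length_nt`` not divisible
    by three marks an incomplete ORF via ``complete_orf`` rather than an
    error.
    """

    gene_id: str
    mrna_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str
    orf_length_nt: int

    def __post_init__(self) -> None:
        if not self.exons:
            raise FormatError(f"mRNA {self.mrna_id!r} has zero exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise FormatError(f"mRNA {self.mrna_id!r}: empty exon ({start},{end})")
            if prev_end is not None and start < prev_end:
                raise FormatError(f"mRNA {self.mrna_id!r}: overlapping/unsorted exons")
            prev_end = end
        if self.strand not in "+-":
            raise FormatError(f"mRNA {self.mrna_id!r}: bad strand {self.strand!r}")
        if self.orf_length_nt < 3:
            raise FormatError(f"mRNA {self.mrna_id!r}: ORF shorter than one codon")

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def complete_orf(self) -> bool:
        return self.orf_length_nt % 3 == 0

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


class AlignmentMatrix:
    """A rectangular multiple alignment of protein records.

    Rows are gapped sequences of equal length; ``coverage_mask`` gives the
    per-column fraction of rows carrying a real residue (neither gap nor
    'X').
    """

    def __init__(self, records: Sequence[ProteinRecord]):
        records = list(records)
        if not records:
            raise FormatError("alignment requires at least one row")
        n = len(records[0].sequence)
        for rec in records:
            if len(rec.sequence) != n:
                raise FormatError(
                    f"ragged alignment: row {rec.id!r} has length "
                    f"{len(rec.sequence)}, expected {n}"
                )
            bad = set(rec.sequence) - _VALID_ALIGNED
            if bad:
                raise FormatError(f"row {rec.id!r}: invalid characters {sorted(bad)}")
        _check_unique_ids(records)
        self.records = records
        self.n_sites = n

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.id for r in self.records]

    def as_array(self) -> np.ndarray:
        """Alignment as an (m, n_sites) array of single characters."""
        return np.array([list(r.sequence) for r in self.records])

    def coverage_mask(self) -> np.ndarray:
        """Per-column fraction of non-gap, non-'X' residues, in [0, 1]."""
        arr = self.as_array()
        real = (arr != GAP) & (arr != UNKNOWN_RESIDUE)
        return real.mean(axis=0)


def _check_unique_ids(records: Iterable[ProteinRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r}")
        seen.add(rec.id)


def normalize_sequence(raw: str, *, aligned: bool = False) -> str:
    """Uppercase, drop whitespace, strip terminal '*' and validate."""
    seq = _WS.sub("", raw).upper().rstrip("*")
    allowed = _VALID_ALIGNED if aligned else _VALID_RESIDUES
    bad = set(seq) - allowed
    if bad:
        raise FormatError(f"invalid residue characters {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into normalised records."""
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(entry.seq))
        if not seq:
            raise FormatError(f"record {entry.id!r}: empty sequence")
        records.append(
            ProteinRecord(id=entry.id, sequence=seq, description=entry.description)
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_gff3_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon (or CDS) features into GeneModels.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open.  Minus-strand models keep their exons in transcription
    order, i.e. sorted by genomic start (intron counting is
    strand-agnostic).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        exons = list(db.children(mrna, featuretype="exon", order_by="start"))
        if not exons:
            exons = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not exons:
            raise FormatError(f"mRNA {mrna.id!r} has zero exons")
        intervals = tuple((e.start - 1, e.end) for e in exons)
        lo, hi = mrna.start - 1, mrna.end
        for start, end in intervals:
            if start < lo or end > hi:
                raise FormatError(
                    f"mRNA {mrna.id!r}: exon ({start},{end}) outside parent span ({lo},{hi})"
                )
        orf = sum(end - start for start, end in intervals)
        models.append(
            GeneModel(
                gene_id=gene_id,
                mrna_id=mrna.id,
                exons=intervals,
                strand=mrna.strand if mrna.strand in "+-" else "+",
                orf_length_nt=orf,
            )
        )
    if not models:
        raise FormatError(f"no mRNA features in {path}")
    return models


def read_alignment(path: str | Path, format: str = "aligned-fasta") -> AlignmentMatrix:
    """Read an aligned FASTA or Clustal file into an AlignmentMatrix."""
    fmt = {"aligned-fasta": "fasta", "fasta": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    records = [
        ProteinRecord(
            id=row.id,
            sequence=normalize_sequence(str(row.seq), aligned=True),
            description=row.description,
        )
        for row in msa
    ]
    return AlignmentMatrix(records)


def write_alignment_fasta(alignment: AlignmentMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in alignment.records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_newick(source: str | Path) -> TreeNode:
    """Parse a Newick string (or file path) into a tree."""
    text = source if isinstance(source, str) and source.strip().endswith(";") else Path(source).read_text()
    try:
        # keep underscores literal: sequence ids routinely contain them
        return TreeNode.read(io.StringIO(text), format="newick",
                             convert_underscores=False)
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"malformed Newick: {exc}") from exc


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree to a Newick string (branch lengths to 6 decimals)."""
    for node in tree.traverse():
        if node.length is not None:
            node.length = round(float(node.length), 6)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def write_report(tables: dict[str, "object"], out_dir: str | Path) -> list[Path]:
    """Write each named DataFrame as a deterministic TSV under ``out_dir``.

    Rows are sorted by the first column, columns kept in the frame's
    declared order, so identical inputs give byte-identical files.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        frame = pd.DataFrame(frame)
        if len(frame.columns) and len(frame):
            frame = frame.sort_values(frame.columns[0], kind="mergesort")
        dest = out_dir / f"{name}.tsv"
        frame.to_csv(dest, sep="\t", index=False, encoding="utf-8")
        written.append(dest)
    return written
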