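"""Readers/writers for the pipeline's external formats.

Covers protein and in-frame CDS FASTA, the gene-locus and duplicated-block
TSV tables, expression matrices, and the POPTR-style locus-identifier parser
that maps the 4-digit chromosome field to Populus linkage groups I-XIX or to
unassembled scaffolds.

Coordinates are 1-based inclusive throughout, matching the source tables;
conversion to 0-based happens only inside individual computations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard one-letter codes plus X (unknown)
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
#: nucleotide alphabet for in-frame CDS (N tolerated at read time; codons
#: containing N are dropped downstream, never imputed)
CDS_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence: identifier, free-text description, residues."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsRecord:
    """An in-frame coding sequence, frame anchored at position 0."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """Genomic placement of one gene (1-based inclusive coordinates)."""

    gene_id: str
    chrom_label: str
    start: int
    end: int
    strand: str = "+"
    locus_index: int = 0  # 1-based rank along the chromosome, by start

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class DuplicatedBlock:
    """A pair of homologous chromosome segments from whole-genome duplication."""

    block_id: str
    side_a: tuple[str, int, int]
    side_b: tuple[str, int, int]

    def __post_init__(self) -> None:
        for label, s, e in (self.side_a, self.side_b):
            if s > e:
                raise ValueError(f"block {self.block_id}: {label} start {s} > end {e}")

    def contains(self, locus: GeneLocus, side: Literal["a", "b"]) -> bool:
        """True when the gene interval lies fully inside the given side."""
        label, s, e = self.side_a if side == "a" else self.side_b
        return locus.chrom_label == label and s <= locus.start and locus.end <= e


def _validate_sequence(seq: str, alphabet: frozenset[str], rec_id: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"record {rec_id}: illegal residue {ch!r} at position {pos + 1}"
            )


def read_fasta(
    path: str | Path, mode: Literal["protein", "cds"] = "protein"
) -> list[ProteinRecord] | list[CdsRecord]:
    """Read a FASTA file into typed records.

    Sequences are uppercased and whitespace-stripped; record order is
    preserved. In protein mode a single trailing ``*`` (stop) is removed with
    a log line. Empty files, duplicate ids and illegal characters are errors.
    """
    records: list = []
    seen: set[str] = set()
    cls = ProteinRecord if mode == "protein" else CdsRecord
    alphabet = PROTEIN_ALPHABET if mode == "protein" else CDS_ALPHABET
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if mode == "protein" and seq.endswith("*"):
            logger.info("stripping trailing stop '*' from %s", rec.id)
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"record {rec.id}: empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        _validate_sequence(seq, alphabet, rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(cls(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrap), preserving order."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# -- POPTR locus-identifier parsing ------------------------------------------

POPTR_ID_RE = re.compile(r"POPTR_(\d{4})s(\d+)\.(\d+)$")

_ROMAN = [
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def _to_roman(n: int) -> str:
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def parse_poptr_chrom(
    locus_id: str, *, lenient: bool = False
) -> tuple[str, bool]:
    """Map a POPTR_<4 digits>s<digits>.<version> id to a chromosome label.

    A 4-digit field in 0001-0019 denotes a linkage group and yields
    ``("LG_<roman>", True)``; any other value is an unassembled scaffold,
    yielding ``("scaffold_<n>", False)``. Non-matching ids raise, or pass
    through as an opaque label in lenient mode (logged).
    """
    m = POPTR_ID_RE.search(locus_id)
    if m is None:
        if lenient:
            logger.warning("non-POPTR locus id %r passed through", locus_id)
            return locus_id, False
        raise ValueError(f"not a POPTR locus id: {locus_id!r}")
    num = int(m.group(1))
    if 1 <= num <= 19:
        return f"LG_{_to_roman(num)}", True
    return f"scaffold_{num}", False


# -- TSV tables ---------------------------------------------------------------

def read_locus_table(path: str | Path) -> list[GeneLocus]:
    """Read a gene-locus TSV (gene_id, chrom_label, start, end, strand).

    ``locus_index`` is recomputed per chromosome as the rank by start
    coordinate (ties broken by gene_id, logged); an input locus_index column,
    if present, is ignored in favour of the recomputed rank.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom_label", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"locus table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in locus table: {dupes}")
    loci: list[GeneLocus] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric coordinate at line {line_no}") from exc
        loci.append(
            GeneLocus(row.gene_id, row.chrom_label, start, end, row.strand)
        )
    return assign_locus_indices(loci)


def assign_locus_indices(loci: Iterable[GeneLocus]) -> list[GeneLocus]:
    """Rank genes along each chromosome by start (ties by gene_id)."""
    out: list[GeneLocus] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom_label, []).append(locus)
    for chrom, group in by_chrom.items():
        ordered = sorted(group, key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(ordered, start=1):
            if rank > 1 and g.start == ordered[rank - 2].start:
                logger.info("locus tie at %s:%d broken by gene_id", chrom, g.start)
            out.append(
                GeneLocus(g.gene_id, g.chrom_label, g.start, g.end, g.strand, rank)
            )
    return out


def read_block_table(path: str | Path) -> list[DuplicatedBlock]:
    """Read a duplicated-block TSV (block_id, chrom/start/end for each side)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"block_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"block table missing columns: {sorted(missing)}")
    blocks = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            blocks.append(
                DuplicatedBlock(
                    row.block_id,
                    (row.chrom_a, int(row.start_a), int(row.end_a)),
                    (row.chrom_b, int(row.start_b), int(row.end_b)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"bad block row at line {line_no}: {exc}") from exc
    return blocks


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV: first column gene/probe id, remaining columns
    sample values. Returns a DataFrame indexed by id with float values; rows
    with missing entries are dropped with a log line."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric, errors="raise")
    n_bad = int(df.isna().any(axis=1).sum())
    if n_bad:
        logger.warning("dropping %d expression rows with missing values", n_bad)
        df = df.dropna(axis=0)
    return df


def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Read a probe-to-gene map TSV with columns probe_id, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError("probe map needs columns probe_id, gene_id")
    return df
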