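"""Sequence and table I/O for the MIP family pipeline.

Reads and writes plain FASTA (via Biopython), the packaged family table
(the 89-locus soybean MIP roster: 66 full-length genes plus 23 pseudogene
loci), BED-like exon tables for user gene models, and provides the small
locus-name helpers used by the chromosome statistics.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")

_LOCUS_RE = re.compile(r"^Glyma(\d{2})g\d{5}$")


class SeqIOError(ValueError):
    """Raised for malformed sequence or table input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (20 canonical letters plus X)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        bad = [
            (i, c)
            for i, c in enumerate(self.sequence)
            if c not in PROTEIN_ALPHABET
        ]
        if bad:
            i, c = bad[0]
            raise SeqIOError(
                f"record {self.id!r}: illegal residue {c!r} at offset {i}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodingRecord:
    """A CDS paired (by id) with a ProteinRecord.

    ``frame`` is the 0-based offset of the first complete codon.  After
    trimming the offset the length must be divisible by 3.
    """

    id: str
    sequence: str
    frame: int = 0
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        bad = [
            (i, c)
            for i, c in enumerate(self.sequence)
            if c not in NUCLEOTIDE_ALPHABET
        ]
        if bad:
            i, c = bad[0]
            raise SeqIOError(
                f"record {self.id!r}: illegal nucleotide {c!r} at offset {i}"
            )
        if self.frame < 0:
            raise SeqIOError(f"record {self.id!r}: negative frame")
        if (len(self.sequence) - self.frame) % 3 != 0:
            raise SeqIOError(
                f"record {self.id!r}: length {len(self.sequence)} minus frame "
                f"{self.frame} not divisible by 3"
            )

    def codons(self) -> list[str]:
        s = self.sequence[self.frame:]
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def translate(self) -> str:
        aa = str(Seq(self.sequence[self.frame:]).translate())
        return aa[:-1] if aa.endswith("*") else aa

    def matches_protein(self, protein: ProteinRecord) -> bool:
        return self.translate() == protein.sequence

    def __len__(self) -> int:
        return len(self.sequence)


EstState = Literal["yes", "no", "unknown"]
KaKsNote = Literal["<1", "1", ">1", "?", ""]


@dataclass(frozen=True)
class FamilyTableRow:
    """One transcribed row of the printed family table.

    Coordinates are kept 1-based inclusive exactly as printed.  ``?``
    entries become the explicit "unknown" state (EST) or are preserved
    verbatim (ka/ks note); blanks stay blank, they are distinct from "?".
    """

    gene_name: str
    locus_name: str
    genome_location: tuple[int, int]
    est: EstState
    ntm: int
    pl: int
    rse: int
    psl: str
    kaks_note: KaKsNote
    comment: str = ""

    def __post_init__(self):
        if self.pl <= 0:
            raise SeqIOError(f"{self.gene_name}: PL must be positive")
        if self.rse < 0:
            raise SeqIOError(f"{self.gene_name}: RSE must be >= 0")
        if not 0 <= self.ntm <= 7:
            raise SeqIOError(f"{self.gene_name}: NTM {self.ntm} out of [0, 7]")
        if not _LOCUS_RE.match(self.locus_name):
            raise SeqIOError(
                f"{self.gene_name}: locus name {self.locus_name!r} does not "
                "match GlymaNNgNNNNN"
            )

    @property
    def subfamily_prefix(self) -> str:
        """PIP/TIP/NIP/SIP/XIP parsed from the gene name, for both Gm* and
        Pseudo* rows."""
        m = re.match(r"^(?:Gm|Pseudo)(PIP|TIP|NIP|SIP|XIP)", self.gene_name)
        if not m:
            raise SeqIOError(f"unrecognized gene name {self.gene_name!r}")
        return m.group(1)

    @property
    def is_pseudo(self) -> bool:
        return self.gene_name.startswith("Pseudo")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene on one sequence, 1-based inclusive."""

    id: str
    exons: tuple[tuple[int, int], ...]
    strand: Literal["+", "-", "?"] = "?"

    def __post_init__(self):
        if not self.exons:
            raise SeqIOError(f"gene model {self.id!r}: no exons")
        prev_end = -math.inf
        for start, end in self.exons:
            if start > end:
                raise SeqIOError(
                    f"gene model {self.id!r}: exon {start}..{end} inverted"
                )
            if start <= prev_end:
                raise SeqIOError(
                    f"gene model {self.id!r}: exons overlap or are unsorted"
                )
            prev_end = end


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, kind: str = "protein") -> list:
    """Read a FASTA file into ProteinRecord or CodingRecord objects.

    ``kind`` is "protein" or "nucleotide".  Sequences are uppercased and
    validated against the record alphabet; duplicate ids are an error.
    """
    cls = {"protein": ProteinRecord, "nucleotide": CodingRecord}[kind]
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(cls(id=rec.id, sequence=str(rec.seq).upper(), description=desc))
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Family table

_TABLE_COLUMNS = [
    "gene_name", "locus_name", "genome_location", "est", "ntm",
    "pl", "rse", "psl", "kaks", "comment",
]


def _parse_row(i: int, row: dict) -> FamilyTableRow:
    loc = str(row["genome_location"])
    m = re.match(r"^(\d+)\.\.(\d+)$", loc)
    if not m:
        raise SeqIOError(f"row {i}: malformed genome location {loc!r}")
    est_raw = str(row["est"]).strip()
    est = {"yes": "yes", "no": "no", "?": "unknown"}.get(est_raw.lower())
    if est is None:
        raise SeqIOError(f"row {i}: unrecognized EST flag {est_raw!r}")
    try:
        ntm = int(row["ntm"])
        pl = int(row["pl"])
        rse = int(row["rse"])
    except (TypeError, ValueError) as exc:
        raise SeqIOError(f"row {i}: non-integer NTM/PL/RSE field: {exc}") from exc
    kaks = "" if pd.isna(row["kaks"]) else str(row["kaks"]).strip()
    if kaks not in ("<1", "1", ">1", "?", ""):
        raise SeqIOError(f"row {i}: unrecognized ka/ks note {kaks!r}")
    psl = "" if pd.isna(row["psl"]) else str(row["psl"]).strip()
    comment = "" if pd.isna(row["comment"]) else str(row["comment"]).strip()
    return FamilyTableRow(
        gene_name=str(row["gene_name"]).strip(),
        locus_name=str(row["locus_name"]).strip(),
        genome_location=(int(m.group(1)), int(m.group(2))),
        est=est,
        ntm=ntm,
        pl=pl,
        rse=rse,
        psl=psl,
        kaks_note=kaks,
        comment=comment,
    )


def load_family_table(path) -> list[FamilyTableRow]:
    """Load a 10-column TSV family table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    if df.empty:
        raise SeqIOError(f"family table {path} has no rows")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SeqIOError(f"family table missing columns: {sorted(missing)}")
    return [_parse_row(i + 2, row) for i, row in enumerate(df.to_dict("records"))]


def packaged_family_table() -> list[FamilyTableRow]:
    """The family table shipped with the package (66 full-length + 23 pseudo)."""
    ref = resources.files("mipscan") / "data" / "family_table.tsv"
    with resources.as_file(ref) as path:
        return load_family_table(path)


def chromosome_of(locus_name: str) -> int:
    """Chromosome number encoded in a Glyma locus name (GlymaNNg... -> NN)."""
    m = _LOCUS_RE.match(locus_name)
    if not m:
        raise SeqIOError(f"locus name {locus_name!r} does not match GlymaNNgNNNNN")
    chrom = int(m.group(1))
    if not 1 <= chrom <= 20:
        raise SeqIOError(f"locus {locus_name!r}: chromosome {chrom} out of [1, 20]")
    return chrom


def count_introns(model: GeneModel) -> int:
    return len(model.exons) - 1


def read_gene_models(path) -> list[GeneModel]:
    """Read BED-like exon rows (0-based half-open) into GeneModels.

    Expected TSV columns: id, start, end[, strand].  Coordinates are
    converted to the package's 1-based inclusive convention.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
    if df.shape[1] < 3:
        raise SeqIOError("gene model table needs at least id, start, end columns")
    models: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    for i, row in df.iterrows():
        try:
            start, end = int(row[1]), int(row[2])
        except ValueError as exc:
            raise SeqIOError(f"gene model row {i + 1}: {exc}") from exc
        if end <= start:
            raise SeqIOError(f"gene model row {i + 1}: empty interval")
        gid = str(row[0])
        models.setdefault(gid, []).append((start + 1, end))
        if df.shape[1] > 3 and str(row[3]) in ("+", "-"):
            strands[gid] = str(row[3])
    return [
        GeneModel(id=gid, exons=tuple(sorted(exons)), strand=strands.get(gid, "?"))
        for gid, exons in models.items()
    ]
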