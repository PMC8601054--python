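"""Readers and writers for the external formats the pipeline touches.

All other modules consume only the record types defined here: protein and
CDS FASTA (possibly gapped alignments that are degapped on read), tab
separated domain-annotation tables, and tab separated paralog pair lists.
Every coordinate that crosses a file boundary is 1-based inclusive.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X", "*"}
NUCLEOTIDES = set("ACGTN")
GAP_CHARS = "-."

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; gaps stripped if the source was an alignment."""

    id: str
    sequence: str
    raw_had_gaps: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: residues outside the 20+X alphabet: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedRecord:
    """One row of a multiple alignment: gap characters are retained."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"aligned record {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET - set(GAP_CHARS)
        if bad:
            raise ValueError(
                f"aligned record {self.id!r}: unexpected characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def degapped(self) -> ProteinRecord:
        return ProteinRecord(
            self.id, degap(self.sequence),
            raw_had_gaps=any(c in self.sequence for c in GAP_CHARS),
            description=self.description,
        )


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence; length divisible by 3 after stop trimming."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"CDS {self.id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise ValueError(
                f"CDS {self.id!r}: non-ACGTN characters: {sorted(bad)}"
            )
        if len(trim_terminal_stop(self.sequence)) % 3 != 0:
            raise ValueError(
                f"CDS {self.id!r}: length {len(self.sequence)} not divisible "
                "by 3 after trimming a terminal stop"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRow:
    """One domain annotation (InterProScan-style TSV row)."""

    protein_id: str
    domain_name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"annotation {self.protein_id}/{self.domain_name}: "
                f"bad coordinates {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class GenePairRow:
    """One paralog pair with its duplication class and optional Ks/Ka."""

    gene_a: str
    gene_b: str
    dup_class: str = "unknown"  # segmental | tandem | unknown
    ks_given: Optional[float] = None
    ka_given: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"gene pair with identical members: {self.gene_a}")
        if self.dup_class not in ("segmental", "tandem", "unknown"):
            raise ValueError(f"unknown duplication class {self.dup_class!r}")
        for name, v in (("ks", self.ks_given), ("ka", self.ka_given)):
            if v is not None and v < 0:
                raise ValueError(f"negative {name} for {self.gene_a}/{self.gene_b}")


def degap(sequence: str) -> str:
    """Remove alignment gap characters ('-' and '.'). Idempotent."""
    return sequence.translate({ord(c): None for c in GAP_CHARS})


def trim_terminal_stop(cds: str) -> str:
    """Drop one trailing stop codon if the in-frame sequence ends with one."""
    if len(cds) % 3 == 0 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def _check_unique_ids(records: Sequence) -> None:
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(
    path: str | Path,
    *,
    degap_records: bool = False,
    kind: str = "protein",
) -> list[ProteinRecord] | list[CdsRecord]:
    """Read a FASTA file into protein or CDS records, in file order.

    The record id is the header token before the first whitespace; the
    remainder is kept as a free-text description.  With ``degap_records``
    gap characters are removed and ``raw_had_gaps`` is set on proteins.
    Lower-case letters are upper-cased.  An empty file and duplicate ids
    are hard errors, as is any residue outside the permitted alphabet.
    """
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise ValueError(f"{path}: no FASTA records found")
    records: list = []
    for rec in raw:
        seq = str(rec.seq).upper()
        had_gaps = any(c in seq for c in GAP_CHARS)
        if degap_records:
            seq = degap(seq)
        elif had_gaps and kind == "cds":
            raise ValueError(f"CDS {rec.id!r}: gapped input; pass degap_records=True")
        desc = rec.description[len(rec.id):].strip()
        if kind == "protein":
            records.append(
                ProteinRecord(rec.id, seq, raw_had_gaps=had_gaps and degap_records,
                              description=desc)
            )
        elif kind == "cds":
            records.append(CdsRecord(rec.id, seq, description=desc))
        elif kind == "aligned":
            records.append(AlignedRecord(rec.id, seq, description=desc))
        else:
            raise ValueError(f"unknown record kind {kind!r}")
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, preserving ids and descriptions."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


_ANNOTATION_COLUMNS = ("protein_id", "domain_name", "start", "end")


def read_annotation_table(path: str | Path) -> list[AnnotationRow]:
    """Read a tab-separated domain annotation table.

    Expects a header naming protein_id, domain_name, start, end (any
    order); coordinates stay 1-based inclusive.  Malformed coordinates
    raise with the offending line number.
    """
    rows: list[AnnotationRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_ANNOTATION_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    AnnotationRow(
                        protein_id=row["protein_id"].strip(),
                        domain_name=row["domain_name"].strip(),
                        start=int(row["start"]),
                        end=int(row["end"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return rows


_PAIR_DEFAULT_COLMAP = {
    "gene_a": "gene_a",
    "gene_b": "gene_b",
    "dup_class": "dup_class",
    "ks": "ks",
    "ka": "ka",
}


def read_gene_pairs(
    path: str | Path,
    colmap: Optional[dict[str, str]] = None,
) -> list[GenePairRow]:
    """Read a tab-separated paralog pair list.

    ``colmap`` maps the logical fields (gene_a, gene_b, dup_class, ks, ka)
    to the actual column headers, so tables with arbitrary layouts can be
    consumed; dup_class, ks and ka are optional columns.
    """
    cm = dict(_PAIR_DEFAULT_COLMAP)
    if colmap:
        cm.update(colmap)
    rows: list[GenePairRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = set(reader.fieldnames or ())
        for required in ("gene_a", "gene_b"):
            if cm[required] not in fields:
                raise ValueError(f"{path}: missing column {cm[required]!r}")
        for lineno, row in enumerate(reader, start=2):
            def _opt_float(key: str) -> Optional[float]:
                col = cm[key]
                if col not in row or row[col] in (None, "", "NA", "NaN"):
                    return None
                return float(row[col])

            try:
                dup = "unknown"
                if cm["dup_class"] in fields and row[cm["dup_class"]]:
                    dup = row[cm["dup_class"]].strip().lower()
                rows.append(
                    GenePairRow(
                        gene_a=row[cm["gene_a"]].strip(),
                        gene_b=row[cm["gene_b"]].strip(),
                        dup_class=dup,
                        ks_given=_opt_float("ks"),
                        ka_given=_opt_float("ka"),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_tsv_report(rows: Sequence, path: str | Path,
                     columns: Optional[Sequence[str]] = None) -> None:
    """Write homogeneous rows (dataclasses or dicts) as a TSV report.

    Column order is the dataclass field order (or the dict key order of
    the first row) unless ``columns`` overrides it; a header line is
    always written, so an empty row list yields a header-only file.
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("cannot infer columns from an empty row list")
        first = rows[0]
        if dataclasses.is_dataclass(first):
            columns = [f.name for f in dataclasses.fields(first)]
        else:
            columns = list(first.keys())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            if dataclasses.is_dataclass(row):
                d = dataclasses.asdict(row)
            else:
                d = dict(row)
            writer.writerow(["" if d.get(c) is None else d[c] for c in columns])
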