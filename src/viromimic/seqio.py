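"""Sequence and tabular-hit I/O.

FASTA and FASTQ parsing is delegated to Biopython and normalised into the
lightweight :class:`SeqRecord` container used throughout the package.
Alignment results travel as :class:`HitTable` objects and are serialised in
the 12-column BLAST ``outfmt 6`` tabular convention (the ``.m6`` files most
downstream tooling expects).

Conventions
-----------
* Residues are uppercased on read and ``U`` is mapped to ``T`` for
  nucleotide records (tolerant ingestion of RNA-style input).
* Internal coordinates everywhere in the package are 0-based half-open on
  the forward strand; the tabular output uses BLAST's 1-based inclusive
  coordinates with ``start > end`` on the minus strand.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

from Bio import SeqIO as _BioSeqIO

__all__ = [
    "SeqRecord",
    "HitTable",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_hit_table",
    "parse_hit_table",
]

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class SeqRecord:
    """A named sequence, optionally with per-residue Phred qualities.

    ``residues`` is a plain uppercase string over {A,C,G,T,N} for nucleotide
    records or the 20 amino acids plus X for proteins.  ``qualities`` is only
    meaningful for nucleotide reads.
    """

    id: str
    residues: str
    description: str = ""
    qualities: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if len(self.residues) == 0:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} quality scores for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HitTable:
    """An ordered collection of alignment hits (see ``align_core.AlignmentHit``)."""

    rows: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def sorted(self) -> "HitTable":
        """Rows sorted by (query id, ascending E-value, subject id)."""
        return HitTable(
            sorted(self.rows, key=lambda h: (h.query_id, h.evalue, h.subject_id))
        )


def _open_source(path_or_text: Union[str, os.PathLike]) -> io.TextIOBase:
    """Accept either a filesystem path or raw FASTA text."""
    text = str(path_or_text)
    if "\n" in text or text.lstrip().startswith(">"):
        return io.StringIO(text)
    return open(path_or_text, "r")


def _validate_alphabet(record: SeqRecord, alphabet: frozenset, kind: str) -> None:
    for ch in record.residues:
        if ch not in alphabet:
            raise ValueError(
                f"record {record.id!r} contains character {ch!r} outside the "
                f"{kind} alphabet"
            )


def read_fasta(
    path_or_text: Union[str, os.PathLike],
    alphabet: str = "nucleotide",
) -> List[SeqRecord]:
    """Read a FASTA file (or raw FASTA text) into a list of records.

    Wrapped sequence lines are concatenated, residues are uppercased, and for
    nucleotide input ``U`` is mapped to ``T``.  Record order is preserved.

    Raises
    ------
    ValueError
        If the source contains no records, a duplicate id, or a residue
        outside the declared alphabet (the error names the record and the
        offending character).
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: List[SeqRecord] = []
    seen = set()
    with _open_source(path_or_text) as handle:
        text = handle.read()
    if ">" not in text:
        raise ValueError("no records found in FASTA input")
    with io.StringIO(text) as handle:
        for rec in _BioSeqIO.parse(handle, "fasta"):
            residues = str(rec.seq).upper()
            if alphabet == "nucleotide":
                residues = residues.replace("U", "T")
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            out = SeqRecord(id=rec.id, residues=residues, description=desc)
            _validate_alphabet(
                out,
                NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET,
                alphabet,
            )
            if out.id in seen:
                raise ValueError(f"duplicate record id {out.id!r} in FASTA input")
            seen.add(out.id)
            records.append(out)
    if not records:
        raise ValueError("no records found in FASTA input")
    return records


def write_fasta(records: Iterable[SeqRecord], path: Union[str, os.PathLike],
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_fastq(path: Union[str, os.PathLike]) -> List[SeqRecord]:
    """Read 4-line FASTQ records with Phred+33 qualities.

    Raises
    ------
    ValueError
        On a truncated record or a sequence/quality length mismatch; the
        error reports the (0-based) index of the offending record.
    """
    records: List[SeqRecord] = []
    with _open_source(path) as handle:
        parser = _BioSeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"FASTQ parse error at record {index}: {exc}") from exc
            residues = str(rec.seq).upper().replace("U", "T")
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            out = SeqRecord(
                id=rec.id,
                residues=residues,
                description=desc,
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
            _validate_alphabet(out, NUCLEOTIDE_ALPHABET, "nucleotide")
            records.append(out)
            index += 1
    if not records:
        raise ValueError("no records found in FASTQ input")
    return records


def write_fastq(records: Iterable[SeqRecord], path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f"@{header}\n{rec.residues}\n+\n{qual}\n")


# --- BLAST outfmt-6 compatible tabular hits ("m6") -------------------------

def format_evalue(evalue: float) -> str:
    if evalue == 0.0:
        return "0.0"
    return f"{evalue:.3g}"


def _hit_line(hit) -> str:
    return "\t".join(
        [
            hit.query_id,
            hit.subject_id,
            f"{hit.pct_identity:.2f}",
            str(hit.aln_len),
            str(hit.mismatches),
            str(hit.gap_openings),
            str(hit.q_start),
            str(hit.q_end),
            str(hit.s_start),
            str(hit.s_end),
            format_evalue(hit.evalue),
            f"{hit.bit_score:.1f}",
        ]
    )


def write_hit_table(hits: HitTable, path: Union[str, os.PathLike]) -> None:
    """Write hits as 12 tab-separated BLAST outfmt-6 columns per row."""
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(_hit_line(hit) + "\n")


def hit_table_text(hits: HitTable) -> str:
    return "".join(_hit_line(h) + "\n" for h in hits)


def parse_hit_table(path_or_text: Union[str, os.PathLike]) -> HitTable:
    """Parse a 12-column tabular hit file back into a :class:`HitTable`.

    Fields that are not part of the tabular format (reading frame, raw
    score) are not recoverable and default to 0 / None.
    """
    from .align_core import AlignmentHit  # local import to avoid a cycle

    text_like = str(path_or_text)
    if "\n" in text_like or "\t" in text_like:
        lines = text_like.splitlines()
    else:
        with open(path_or_text) as fh:
            lines = fh.read().splitlines()
    rows = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise ValueError(
                f"hit table line {lineno}: expected 12 tab-separated columns, "
                f"got {len(parts)}"
            )
        rows.append(
            AlignmentHit(
                query_id=parts[0],
                subject_id=parts[1],
                frame=0,
                pct_identity=float(parts[2]),
                aln_len=int(parts[3]),
                mismatches=int(parts[4]),
                gap_openings=int(parts[5]),
                q_start=int(parts[6]),
                q_end=int(parts[7]),
                s_start=int(parts[8]),
                s_end=int(parts[9]),
                evalue=float(parts[10]),
                bit_score=float(parts[11]),
                raw_score=None,
            )
        )
    return HitTable(rows)
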