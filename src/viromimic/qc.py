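"""Read quality control for virome FASTQ data.

A read is removed when it is shorter than ``min_len``, its arithmetic mean
Phred score is below ``min_mean_q``, or its fraction of N calls exceeds
``max_n_frac``.  All three comparisons are strict, so a 100 nt read, a read
with mean quality exactly 25, and a read with exactly 10% N's are all kept.
Each removed read is attributed to the first rule it fails, in the order
length -> quality -> N content, so the report counts partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .seqio import SeqRecord

__all__ = ["QCReport", "qc_filter"]


@dataclass
class QCReport:
    n_input: int
    n_removed_length: int
    n_removed_quality: int
    n_removed_n_content: int
    n_kept: int

    def __post_init__(self) -> None:
        removed = (self.n_removed_length + self.n_removed_quality
                   + self.n_removed_n_content)
        if removed + self.n_kept != self.n_input:
            raise ValueError("QC report counts do not partition the input")

    def to_tsv(self) -> str:
        lines = [
            f"n_input\t{self.n_input}",
            f"n_removed_length\t{self.n_removed_length}",
            f"n_removed_quality\t{self.n_removed_quality}",
            f"n_removed_n_content\t{self.n_removed_n_content}",
            f"n_kept\t{self.n_kept}",
        ]
        return "\n".join(lines) + "\n"


def qc_filter(
    reads: Sequence[SeqRecord],
    min_len: int = 100,
    min_mean_q: float = 25.0,
    max_n_frac: float = 0.10,
) -> Tuple[List[SeqRecord], QCReport]:
    """Apply the three read filters; returns (kept reads, report).

    Mean quality is the arithmetic mean of the Phred scores (the PRINSEQ
    convention), not a probability-domain average.
    """
    kept: List[SeqRecord] = []
    n_len = n_qual = n_ncontent = 0
    for read in reads:
        if read.qualities is None:
            raise ValueError(f"read {read.id!r} has no quality scores")
        L = len(read.residues)
        if L < min_len:
            n_len += 1
            continue
        if sum(read.qualities) / L < min_mean_q:
            n_qual += 1
            continue
        if read.residues.count("N") / L > max_n_frac:
            n_ncontent += 1
            continue
        kept.append(read)
    report = QCReport(
        n_input=len(reads),
        n_removed_length=n_len,
        n_removed_quality=n_qual,
        n_removed_n_content=n_ncontent,
        n_kept=len(kept),
    )
    return kept, report
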