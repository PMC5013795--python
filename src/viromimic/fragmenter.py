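"""Mock-virome construction: tile genomes into fixed-length segments.

A viral genome is cut, without overlap, into consecutive ``frag_len``
segments starting at position 0.  The trailing remainder is kept as a final
shorter fragment only when it is at least ``min_keep`` long, so the number
of fragments per genome is the closed form::

    count = floor(L / frag_len) + (1 if 0 < L mod frag_len and
                                        L mod frag_len >= min_keep else 0)

Fragments carry provenance (parent genome id and coordinates), which the
simulator's ground-truth scoring relies on.  Only the forward strand is
stored; reverse-strand homology is recovered downstream by six-frame
translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

from .seqio import SeqRecord

__all__ = ["Fragment", "fragment_genome", "fragment_set"]

DEFAULT_FRAG_LEN = 200
DEFAULT_MIN_KEEP = 100


@dataclass
class Fragment:
    """One genome segment: ``residues == genome[start:end]`` (0-based half-open)."""

    fragment_id: str
    parent_id: str
    start: int
    end: int
    residues: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.residues):
            raise ValueError(
                f"fragment {self.fragment_id}: coordinates span "
                f"{self.end - self.start} nt but sequence is {len(self.residues)} nt"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def to_record(self) -> SeqRecord:
        return SeqRecord(id=self.fragment_id, residues=self.residues,
                         description=f"{self.parent_id}:{self.start}-{self.end}")


def fragment_genome(
    genome: SeqRecord,
    frag_len: int = DEFAULT_FRAG_LEN,
    min_keep: int = DEFAULT_MIN_KEEP,
) -> List[Fragment]:
    """Tile one genome into non-overlapping fragments of ``frag_len``.

    The remainder shorter than ``min_keep`` is dropped.  An empty genome
    sequence is not representable (records are non-empty), but a genome
    shorter than ``min_keep`` yields an empty list.
    """
    if frag_len < 1:
        raise ValueError(f"frag_len must be >= 1, got {frag_len}")
    if not (1 <= min_keep <= frag_len):
        raise ValueError(f"min_keep must be in [1, frag_len], got {min_keep}")
    fragments: List[Fragment] = []
    L = len(genome.residues)
    for start in range(0, L, frag_len):
        end = min(start + frag_len, L)
        if end - start < frag_len and end - start < min_keep:
            break
        fragments.append(
            Fragment(
                fragment_id=f"{genome.id}_{start}",
                parent_id=genome.id,
                start=start,
                end=end,
                residues=genome.residues[start:end],
            )
        )
    return fragments


def fragment_set(
    genomes: Sequence[SeqRecord],
    frag_len: int = DEFAULT_FRAG_LEN,
    min_keep: int = DEFAULT_MIN_KEEP,
) -> List[Fragment]:
    """Fragment a collection of genomes, preserving genome order."""
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate genome ids: {dupes}")
    out: List[Fragment] = []
    for genome in genomes:
        out.extend(fragment_genome(genome, frag_len=frag_len, min_keep=min_keep))
    return out
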