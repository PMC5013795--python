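"""Per-protein aggregation of virome evidence and the annotation cascade.

A host protein becomes a candidate ("qualifies") when at least
``min_fragments`` distinct virome fragments align to it below the virome
E-value cutoff.  Candidates are then pushed through a strictly ordered
annotation cascade:

1. homology to a reference proteome (BLASTp-style, E < 1e-5)   -> reference_homolog
2. otherwise, a significant non-viral domain hit                -> domain_annotated
3. otherwise, a significant viral-tagged domain hit             -> viral_like
4. otherwise                                                    -> novel

The cascade short-circuits: a protein with both reference homology and
domain hits is classified by the reference step only, and the four classes
partition the qualifying set.

Domain models are position-specific scoring matrices (PSSMs) tagged with a
category.  Significance of the best-window score is assessed against an
empirical null of residue-shuffled copies of the protein, Bonferroni
corrected across models, preserving the 0.01 E-value decision threshold of
conserved-domain searches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .align_core import (
    AA20,
    KAParams,
    SearchParams,
    SubstitutionMatrix,
    seeded_search,
)
from .seqio import HitTable, SeqRecord

__all__ = [
    "ProteinHitSummary",
    "DomainModel",
    "DomainHit",
    "TriageRecord",
    "CATEGORIES",
    "aggregate_hits",
    "reference_homology",
    "scan_domains",
    "triage_classify",
    "count_categories",
    "read_domain_models",
    "write_domain_models",
]

CATEGORIES = ("PAMP", "apoptosis", "viral", "other")
TRIAGE_CLASSES = ("reference_homolog", "domain_annotated", "viral_like", "novel")

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


@dataclass
class ProteinHitSummary:
    """Virome evidence aggregated over one host protein."""

    protein_id: str
    n_unique_fragments: int
    n_hsps: int
    best_evalue: float

    def __post_init__(self) -> None:
        if self.n_unique_fragments > self.n_hsps:
            raise ValueError("unique fragments cannot exceed HSP count")


@dataclass
class DomainModel:
    """An integer-scaled per-position log-odds profile with a category tag."""

    name: str
    category: str
    pssm: np.ndarray  # (length, 20) int, columns in alphabetical aa order

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=np.int32)
        if self.pssm.ndim != 2 or self.pssm.shape[1] != 20:
            raise ValueError(f"model {self.name}: PSSM must be (length, 20)")
        if self.pssm.shape[0] < 5:
            raise ValueError(f"model {self.name}: length must be >= 5")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"model {self.name}: category {self.category!r} not in {CATEGORIES}"
            )

    @property
    def length(self) -> int:
        return int(self.pssm.shape[0])

    def consensus(self) -> str:
        return "".join(AA20[j] for j in self.pssm.argmax(axis=1))

    def max_score(self) -> int:
        return int(self.pssm.max(axis=1).sum())


@dataclass
class DomainHit:
    protein_id: str
    domain_name: str
    start: int  # 0-based half-open protein coordinates of the best window
    end: int
    score: int
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


@dataclass
class TriageRecord:
    protein_id: str
    n_unique_fragments: int
    category: str
    best_reference_hit: Optional[Tuple[str, float]] = None
    domain_hits: List[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in TRIAGE_CLASSES:
            raise ValueError(f"unknown triage class {self.category!r}")


def aggregate_hits(
    hits: HitTable,
    evalue_virome: float = 1e-4,
    min_fragments: int = 5,
) -> List[ProteinHitSummary]:
    """Summarise tblastn hits per protein and keep qualifying proteins.

    HSPs at or above ``evalue_virome`` are discarded (the cutoff is a strict
    "less than"); each fragment counts once per protein no matter how many
    HSPs it produced.  Results are sorted by unique-fragment count
    descending, ties broken by protein id.
    """
    frag_sets: Dict[str, set] = {}
    hsp_counts: Dict[str, int] = {}
    best: Dict[str, float] = {}
    for hit in hits:
        if hit.evalue >= evalue_virome:
            continue
        frag_sets.setdefault(hit.query_id, set()).add(hit.subject_id)
        hsp_counts[hit.query_id] = hsp_counts.get(hit.query_id, 0) + 1
        if hit.evalue < best.get(hit.query_id, math.inf):
            best[hit.query_id] = hit.evalue
    summaries = [
        ProteinHitSummary(
            protein_id=pid,
            n_unique_fragments=len(frags),
            n_hsps=hsp_counts[pid],
            best_evalue=best[pid],
        )
        for pid, frags in frag_sets.items()
        if len(frags) >= min_fragments
    ]
    summaries.sort(key=lambda s: (-s.n_unique_fragments, s.protein_id))
    return summaries


def reference_homology(
    candidates: Sequence[SeqRecord],
    reference: Sequence[SeqRecord],
    evalue_ref: float = 1e-5,
    params: SearchParams = SearchParams(),
    matrix: Optional[SubstitutionMatrix] = None,
    ka: Optional[KAParams] = None,
) -> Dict[str, Tuple[str, float]]:
    """Best reference-proteome homolog per candidate, below ``evalue_ref``.

    Proteins absent from the returned map had no reference hit below the
    cutoff.  An empty reference set is an error (distinct from "searched and
    found nothing").
    """
    if not reference:
        raise ValueError("reference proteome is empty")
    hits = seeded_search(candidates, reference, params=params, matrix=matrix,
                         mode="blastp", ka=ka)
    best: Dict[str, Tuple[str, float]] = {}
    for hit in hits:
        if hit.evalue >= evalue_ref:
            continue
        cur = best.get(hit.query_id)
        if cur is None or hit.evalue < cur[1]:
            best[hit.query_id] = (hit.subject_id, hit.evalue)
    return best


def _window_scores(seqs: np.ndarray, pssm: np.ndarray) -> np.ndarray:
    """Best sliding-window PSSM score per row of an encoded sequence matrix.

    ``seqs`` is (n_rows, L) with codes 0..19 for the standard amino acids
    and 20 for anything else (scores 0).
    """
    m = pssm.shape[0]
    L = seqs.shape[1]
    n_win = L - m + 1
    padded = np.zeros((m, 21), dtype=np.int32)
    padded[:, :20] = pssm
    scores = np.zeros((seqs.shape[0], n_win), dtype=np.int32)
    for j in range(m):
        scores += padded[j, seqs[:, j:j + n_win]]
    return scores


def _encode20(protein: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, 20) for c in protein], dtype=np.int16)


def scan_domains(
    protein: Union[SeqRecord, str],
    models: Sequence[DomainModel],
    evalue_dom: float = 0.01,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> List[DomainHit]:
    """Scan a protein against a PSSM collection with a shuffle null.

    For each model the observed statistic is the best window score; its
    empirical p-value is ``(1 + #{shuffled maxima >= observed}) /
    (n_shuffles + 1)`` over residue-shuffled copies of the protein, and the
    reported E-value is Bonferroni corrected by the number of models.  Only
    hits with E-value strictly below ``evalue_dom`` are returned.

    Residues outside the 20-letter alphabet contribute score 0 at every
    model position.  Models longer than the protein are skipped; if every
    model is longer the result is empty.
    """
    pid = protein.id if hasattr(protein, "id") else ""
    residues = protein.residues if hasattr(protein, "residues") else protein
    codes = _encode20(residues)
    L = codes.shape[0]
    usable = [mdl for mdl in models if mdl.length <= L]
    if not usable:
        return []
    n_models = len(models)

    rng = np.random.default_rng(seed)
    shuffles = rng.permuted(np.tile(codes, (n_shuffles, 1)), axis=1)

    observed = {}
    for mdl in usable:
        w = _window_scores(codes[None, :], mdl.pssm)
        best_idx = int(w[0].argmax())
        observed[mdl.name] = (int(w[0, best_idx]), best_idx)

    # Exceedance counting with early exit: once a model's exceedance count is
    # high enough that its Bonferroni E-value can no longer fall below the
    # cutoff, it needs no further shuffles; identical hit set and p-values.
    exceed = {mdl.name: 0 for mdl in usable}
    alive = list(usable)
    block = 64
    done = 0
    while alive and done < n_shuffles:
        chunk = shuffles[done:done + block]
        done += chunk.shape[0]
        still = []
        for mdl in alive:
            maxima = _window_scores(chunk, mdl.pssm).max(axis=1)
            exceed[mdl.name] += int((maxima >= observed[mdl.name][0]).sum())
            min_possible = (1 + exceed[mdl.name]) / (n_shuffles + 1) * n_models
            if min_possible < evalue_dom:
                still.append(mdl)
        alive = still
        block = min(block * 4, 1024)

    hits: List[DomainHit] = []
    for mdl in usable:
        e = (1 + exceed[mdl.name]) / (n_shuffles + 1) * n_models
        if e < evalue_dom:
            score, idx = observed[mdl.name]
            hits.append(
                DomainHit(
                    protein_id=pid,
                    domain_name=mdl.name,
                    start=idx,
                    end=idx + mdl.length,
                    score=score,
                    evalue=e,
                )
            )
    hits.sort(key=lambda h: (h.evalue, h.domain_name))
    return hits


def triage_classify(
    summaries: Sequence[ProteinHitSummary],
    ref_map: Mapping[str, Tuple[str, float]],
    domain_hits: Mapping[str, Sequence[DomainHit]],
    categories: Mapping[str, str],
) -> List[TriageRecord]:
    """Assign each qualifying protein to exactly one cascade class.

    ``categories`` maps domain name -> category (from the model collection).
    The cascade order is fixed: reference homology preempts any domain
    annotation; non-viral domains preempt viral-tagged ones.
    """
    records: List[TriageRecord] = []
    for summ in summaries:
        pid = summ.protein_id
        dhits = list(domain_hits.get(pid, ()))
        if pid in ref_map:
            cls = "reference_homolog"
        else:
            cats = {categories.get(h.domain_name, "other") for h in dhits}
            if cats - {"viral"}:
                cls = "domain_annotated"
            elif "viral" in cats:
                cls = "viral_like"
            else:
                cls = "novel"
        records.append(
            TriageRecord(
                protein_id=pid,
                n_unique_fragments=summ.n_unique_fragments,
                category=cls,
                best_reference_hit=ref_map.get(pid),
                domain_hits=dhits,
            )
        )
    return records


def count_categories(records: Sequence[TriageRecord]) -> Dict[str, int]:
    counts = {cls: 0 for cls in TRIAGE_CLASSES}
    for rec in records:
        counts[rec.category] += 1
    return counts


# --- domain-model text format ------------------------------------------------
# One block per model: a header line ">name category length" followed by
# `length` rows of 20 tab-separated integer scores (alphabetical aa columns).

def write_domain_models(models: Sequence[DomainModel], path) -> None:
    with open(path, "w") as fh:
        for mdl in models:
            fh.write(f">{mdl.name} {mdl.category} {mdl.length}\n")
            for row in mdl.pssm:
                fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_domain_models(path) -> List[DomainModel]:
    models: List[DomainModel] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"expected model header at line {i + 1}, got {header!r}")
        parts = header[1:].split()
        if len(parts) != 3:
            raise ValueError(f"malformed model header: {header!r}")
        name, category, length = parts[0], parts[1], int(parts[2])
        rows = []
        for k in range(length):
            rows.append([int(v) for v in lines[i + 1 + k].split("\t")])
        models.append(DomainModel(name=name, category=category,
                                  pssm=np.array(rows, dtype=np.int32)))
        i += 1 + length
    return models
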