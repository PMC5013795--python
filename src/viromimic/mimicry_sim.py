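"""Synthetic viral-mimicry data with ground truth.

The simulator emulates the study design the pipeline is built for: a host
proteome in which a designated "immune" subset is targeted by viruses, viral
genomes that embed reverse-translated, point-mutated copies of segments of
those immune proteins (mimics) at a controlled amino-acid identity on both
strands, a diverged reference proteome covering only part of the host
proteome, and a small PSSM domain collection with PAMP / apoptosis / viral /
other category tags.  Everything is driven by a single integer seed and is
byte-reproducible.

Layout of an immune protein: its assigned domain consensus is planted near
the N-terminus (offset 5) and mimic source windows are drawn strictly
downstream of it, so that planted mimics never contain the shared domain
consensus — otherwise fragments of one protein's mimic would accumulate
spurious virome evidence on every other protein carrying the same domain
and blur the ground truth.

A single ``mimic_len``-residue mimic spans only ceil(3*mimic_len/frag_len)
fragments, so ``copies_per_target`` exists to push each planted target over
the >= ``min_fragments`` aggregation rule; this mirrors the assumption that
genuine immune targets attract many independent viral segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .align_core import AA20, ROBINSON_BACKGROUND, translate, reverse_complement
from .seqio import SeqRecord
from .triage import DomainModel

__all__ = [
    "SimParams",
    "SimTruth",
    "SimBundle",
    "generate_domain_models",
    "generate_proteome",
    "reverse_translate",
    "mutate_to_identity",
    "generate_virome",
    "generate_reference_proteome",
    "simulate",
]

_DOMAIN_OFFSET = 5  # domain consensus is planted at this protein offset

_CANONICAL_NAMES = {
    "PAMP": ["NACHT", "LRR_1", "Lectin_C", "TIR", "MASP_R"],
    "apoptosis": ["TNF", "TNFR", "DED", "CARD", "Pep_C14"],
}

# standard-scenario category layout: 4 PAMP + 4 apoptosis + 1 viral + 1 other
_STANDARD_CATEGORIES = (
    "PAMP", "apoptosis", "PAMP", "apoptosis", "PAMP", "apoptosis",
    "PAMP", "apoptosis", "viral", "other",
)


def _rng(seed: Union[int, np.random.Generator, np.random.SeedSequence]):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimParams:
    """Simulation parameters; the defaults are the standard scenario."""

    n_proteins: int = 500
    protein_len_range: Tuple[int, int] = (150, 600)
    n_immune: int = 50
    mimic_identity: float = 0.7
    mimic_len: int = 100
    copies_per_target: int = 4
    n_genomes: int = 10
    genome_len: int = 50_000
    frag_len: int = 200
    min_fragments: int = 5
    ref_coverage: float = 0.6
    ref_identity: float = 0.5
    n_models: int = 10
    domain_len: int = 30
    model_categories: Tuple[str, ...] = _STANDARD_CATEGORIES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_immune <= self.n_proteins):
            raise ValueError("n_immune must be in [0, n_proteins]")
        if not (0.0 < self.mimic_identity <= 1.0):
            raise ValueError("mimic_identity must be in (0, 1]")
        if self.mimic_len * 3 > self.genome_len:
            raise ValueError("mimic_len*3 must fit in a genome")
        if self.n_immune > 0 and (self.copies_per_target * self.mimic_len * 3
                                  < self.min_fragments * self.frag_len):
            raise ValueError(
                "copies_per_target * mimic_len * 3 must cover at least "
                "min_fragments * frag_len so planted targets can qualify"
            )
        lo, hi = self.protein_len_range
        if lo < self.mimic_len + _DOMAIN_OFFSET + self.domain_len + 5:
            raise ValueError(
                "proteins must be long enough to hold a domain plus a "
                "disjoint mimic window"
            )
        if not (0.0 <= self.ref_coverage <= 1.0):
            raise ValueError("ref_coverage must be in [0, 1]")
        if not (0.0 < self.ref_identity <= 1.0):
            raise ValueError("ref_identity must be in (0, 1]")


@dataclass
class SimTruth:
    """Ground truth: which proteins were targeted and where mimics landed."""

    target_proteins: Set[str] = field(default_factory=set)
    # (genome_id, start, end, protein_id, protein_start, protein_end, strand)
    mimic_placements: List[Tuple[str, int, int, str, int, int, str]] = field(
        default_factory=list
    )
    immune_domain_assignments: Dict[str, Optional[str]] = field(default_factory=dict)


@dataclass
class SimBundle:
    """Everything one simulation run produces."""

    params: SimParams
    proteome: List[SeqRecord]
    reference: List[SeqRecord]
    genomes: List[SeqRecord]
    models: List[DomainModel]
    truth: SimTruth

    @property
    def category_map(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for mdl in self.models:
            if mdl.category in ("PAMP", "apoptosis"):
                out.setdefault(mdl.category, set()).add(mdl.name)
        return out

    @property
    def domain_categories(self) -> Dict[str, str]:
        return {mdl.name: mdl.category for mdl in self.models}


_BACKGROUND = np.array([ROBINSON_BACKGROUND[a] for a in AA20])
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()


def generate_domain_models(
    n_models: int,
    length: int,
    categories: Sequence[str],
    seed: Union[int, np.random.Generator] = 0,
) -> List[DomainModel]:
    """Random-consensus PSSMs: +4 on the consensus residue, -2 elsewhere.

    Categories are assigned by cycling over ``categories``; canonical
    immune-domain names (NACHT, TIR, TNF, ...) are used while the per-category
    pools last, then generic names.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = _rng(seed)
    used: Dict[str, int] = {}
    models: List[DomainModel] = []
    for i in range(n_models):
        cat = categories[i % len(categories)]
        k = used.get(cat, 0)
        used[cat] = k + 1
        pool = _CANONICAL_NAMES.get(cat, [])
        name = pool[k] if k < len(pool) else f"{cat.capitalize()}_{k + 1}"
        consensus = rng.choice(20, size=length, p=_BACKGROUND)
        pssm = np.full((length, 20), -2, dtype=np.int32)
        pssm[np.arange(length), consensus] = 4
        models.append(DomainModel(name=name, category=cat, pssm=pssm))
    return models


def generate_proteome(
    params: SimParams,
    models: Optional[Sequence[DomainModel]] = None,
    seed: Union[int, np.random.Generator, None] = None,
) -> Tuple[List[SeqRecord], Dict[str, Optional[str]]]:
    """Host proteome with an immune subset carrying planted domain consensi.

    Residues are i.i.d. from the scoring background; lengths are uniform in
    ``protein_len_range``.  Immune proteins are assigned, cycling, one of
    the non-"other" domain models or no domain at all (the future novel
    class); the assigned consensus replaces the residues at a fixed
    N-terminal offset.  Returns (records, assignments) where assignments
    maps immune protein id -> domain name or None.
    """
    rng = _rng(params.seed if seed is None else seed)
    if models is None:
        models = generate_domain_models(params.n_models, params.domain_len,
                                        params.model_categories, rng)
    lo, hi = params.protein_len_range
    lengths = rng.integers(lo, hi + 1, size=params.n_proteins)
    aa = np.frombuffer(AA20.encode(), dtype=np.uint8)
    total = int(lengths.sum())
    flat = rng.choice(aa, size=total, p=_BACKGROUND)
    records: List[SeqRecord] = []
    pos = 0
    for i, L in enumerate(lengths):
        residues = flat[pos:pos + L].tobytes().decode()
        records.append(SeqRecord(id=f"prot{i:04d}", residues=residues))
        pos += int(L)

    immune_idx = np.sort(rng.choice(params.n_proteins, size=params.n_immune,
                                    replace=False))
    # One of each assignable domain (and one unassigned / future-novel slot)
    # is guaranteed; the remaining targets draw uniformly, so per-domain
    # counts vary across seeds instead of being artificially balanced.
    pattern: List[Optional[str]] = [m.name for m in models
                                    if m.category != "other"] + [None]
    draws = [pattern[j] if j < len(pattern)
             else pattern[int(rng.integers(len(pattern)))]
             for j in range(params.n_immune)]
    assignments: Dict[str, Optional[str]] = {}
    by_name = {m.name: m for m in models}
    for j, idx in enumerate(immune_idx):
        rec = records[idx]
        domain = draws[j]
        assignments[rec.id] = domain
        if domain is not None:
            cons = by_name[domain].consensus()
            res = rec.residues
            rec.residues = (res[:_DOMAIN_OFFSET] + cons
                            + res[_DOMAIN_OFFSET + len(cons):])
    return records, assignments


def _codons_by_aa() -> Dict[str, List[str]]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    out: Dict[str, List[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


_CODONS_BY_AA = _codons_by_aa()


def reverse_translate(
    protein_segment: str,
    codon_table: Optional[Mapping[str, List[str]]] = None,
    seed: Union[int, np.random.Generator] = 0,
) -> str:
    """Random reverse translation, uniform over synonymous codons.

    ``translate(result, +1)`` reproduces the input exactly.  Residues
    without a codon (X) are an error.
    """
    table = codon_table or _CODONS_BY_AA
    rng = _rng(seed)
    codons = []
    for aa in protein_segment:
        options = table.get(aa)
        if not options:
            raise ValueError(f"residue {aa!r} has no codon")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def mutate_to_identity(
    nuc: str,
    target_identity: float,
    seed: Union[int, np.random.Generator] = 0,
) -> str:
    """Apply amino-acid-changing codon substitutions to an exact identity.

    Exactly ``len - round(target_identity * len)`` codons (len in amino
    acids) are replaced by codons of a different, non-stop amino acid, so
    the translated identity to the original segment is
    ``round(target_identity * len) / len``.  No indels are introduced.
    """
    if len(nuc) % 3 != 0:
        raise ValueError("mimic region length must be a multiple of 3")
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    n_aa = len(nuc) // 3
    n_keep = int(round(target_identity * n_aa))
    if n_keep < 1:
        raise ValueError(
            f"target identity {target_identity} is unreachable for {n_aa} residues"
        )
    n_mut = n_aa - n_keep
    rng = _rng(seed)
    codons = [nuc[3 * i:3 * i + 3] for i in range(n_aa)]
    sites = rng.choice(n_aa, size=n_mut, replace=False)
    aa_list = list(AA20)
    for site in sites:
        old_aa = translate(codons[site], 1)
        choices = [a for a in aa_list if a != old_aa]
        new_aa = choices[rng.integers(len(choices))]
        options = _CODONS_BY_AA[new_aa]
        codons[site] = options[rng.integers(len(options))]
    return "".join(codons)


def generate_virome(
    proteome: Sequence[SeqRecord],
    assignments: Mapping[str, Optional[str]],
    params: SimParams,
    seed: Union[int, np.random.Generator, None] = None,
) -> Tuple[List[SeqRecord], SimTruth]:
    """Random viral genomes with planted mimic regions and their ground truth.

    Each immune target contributes ``copies_per_target`` independently
    reverse-translated, identity-mutated copies of a protein segment drawn
    downstream of its planted domain; alternate copies go on the minus
    strand.  Placements never overlap within a genome.
    """
    rng = _rng(params.seed if seed is None else seed)
    by_id = {rec.id: rec for rec in proteome}
    nt = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome_arrays = [
        rng.choice(nt, size=params.genome_len) for _ in range(params.n_genomes)
    ]
    occupied: List[List[Tuple[int, int]]] = [[] for _ in range(params.n_genomes)]
    truth = SimTruth(immune_domain_assignments=dict(assignments))

    region_nt = params.mimic_len * 3
    window_floor = _DOMAIN_OFFSET + params.domain_len + 5
    for pid in sorted(assignments):
        rec = by_id[pid]
        truth.target_proteins.add(pid)
        L = len(rec.residues)
        for copy in range(params.copies_per_target):
            w0 = int(rng.integers(window_floor, L - params.mimic_len + 1))
            segment = rec.residues[w0:w0 + params.mimic_len]
            nuc = reverse_translate(segment, seed=rng)
            nuc = mutate_to_identity(nuc, params.mimic_identity, seed=rng)
            strand = "+" if copy % 2 == 0 else "-"
            insert = nuc if strand == "+" else reverse_complement(nuc)
            placed = False
            for _attempt in range(1000):
                g = int(rng.integers(params.n_genomes))
                start = int(rng.integers(0, params.genome_len - region_nt + 1))
                end = start + region_nt
                if all(end <= s or start >= e for s, e in occupied[g]):
                    occupied[g].append((start, end))
                    genome_arrays[g][start:end] = np.frombuffer(
                        insert.encode(), dtype=np.uint8
                    )
                    truth.mimic_placements.append(
                        (f"virus{g:02d}", start, end, pid, w0,
                         w0 + params.mimic_len, strand)
                    )
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    "could not place a mimic region without overlap; "
                    "genomes are too small for the requested load"
                )
    genomes = [
        SeqRecord(id=f"virus{g:02d}", residues=arr.tobytes().decode())
        for g, arr in enumerate(genome_arrays)
    ]
    return genomes, truth


def generate_reference_proteome(
    host_proteome: Sequence[SeqRecord],
    ref_coverage: float,
    ref_identity: float,
    seed: Union[int, np.random.Generator] = 0,
    groups: Optional[Mapping[str, str]] = None,
) -> List[SeqRecord]:
    """A diverged reference proteome covering part of the host proteome.

    A ``ref_coverage`` fraction of host proteins is copied with residue
    substitutions down to ``ref_identity``; the rest have no reference
    homolog.  When ``groups`` maps protein ids to strata (the simulator
    passes the immune-domain assignment groups), coverage is applied within
    each stratum, which guarantees every stratum retains uncovered members
    whenever its size allows — so the triage cascade can produce all four
    classes.
    """
    rng = _rng(seed)
    if ref_coverage == 0.0:
        return []
    strata: Dict[str, List[int]] = {}
    for i, rec in enumerate(host_proteome):
        key = groups.get(rec.id, "__background__") if groups else "__all__"
        strata.setdefault(key, []).append(i)
    covered: List[int] = []
    for key in sorted(strata):
        members = strata[key]
        k = int(np.floor(ref_coverage * len(members)))
        if k > 0:
            picked = rng.choice(len(members), size=k, replace=False)
            covered.extend(members[j] for j in np.sort(picked))
    covered.sort()
    aa_list = list(AA20)
    reference: List[SeqRecord] = []
    for out_idx, host_idx in enumerate(covered):
        res = list(host_proteome[host_idx].residues)
        L = len(res)
        n_keep = int(round(ref_identity * L))
        n_mut = L - n_keep
        sites = rng.choice(L, size=n_mut, replace=False)
        for site in sites:
            choices = [a for a in aa_list if a != res[site]]
            res[site] = choices[rng.integers(len(choices))]
        reference.append(
            SeqRecord(
                id=f"ref{out_idx:04d}",
                residues="".join(res),
                description=f"homolog_of={host_proteome[host_idx].id}",
            )
        )
    return reference


def simulate(params: SimParams) -> SimBundle:
    """Run the full generator: models, proteome, reference, virome, truth."""
    root = np.random.SeedSequence(params.seed)
    s_models, s_prot, s_ref, s_vir = root.spawn(4)
    models = generate_domain_models(params.n_models, params.domain_len,
                                    params.model_categories,
                                    np.random.default_rng(s_models))
    proteome, assignments = generate_proteome(
        params, models, np.random.default_rng(s_prot)
    )
    groups = {pid: (dom if dom is not None else "__none__")
              for pid, dom in assignments.items()}
    reference = generate_reference_proteome(
        proteome, params.ref_coverage, params.ref_identity,
        np.random.default_rng(s_ref), groups=groups,
    )
    genomes, truth = generate_virome(proteome, assignments, params,
                                     np.random.default_rng(s_vir))
    return SimBundle(params=params, proteome=proteome, reference=reference,
                     genomes=genomes, models=models, truth=truth)
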