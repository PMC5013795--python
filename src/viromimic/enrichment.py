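"""Domain-category enrichment of the candidate set against the proteome.

For each immune-domain category (PAMP sensing, apoptosis) the per-domain
frequency — the proportion of proteins carrying at least one hit to that
domain — is computed in the virome-derived candidate set and in the whole
proteome (the proteome baseline includes the candidates, which are a
subset of it).  The two frequency vectors are compared with a paired
two-tailed t-test across the domains of the category, one pair per domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .triage import DomainHit

__all__ = [
    "DEFAULT_CATEGORY_MAP",
    "EnrichmentResult",
    "DegenerateVarianceError",
    "domain_frequencies",
    "paired_t_test",
    "enrichment_test",
]

# Canonical immune-domain vocabulary: NACHT-family NTPase, leucine-rich
# repeat, C-type lectin, Toll/interleukin-1 receptor homology, MBL-associated
# serine protease (pathogen sensing); TNF ligand/receptor, death-effector,
# caspase recruitment, and peptidase C14 (caspase) domains (apoptosis).
DEFAULT_CATEGORY_MAP: Dict[str, Set[str]] = {
    "PAMP": {"NACHT", "LRR_1", "Lectin_C", "TIR", "MASP_R"},
    "apoptosis": {"TNF", "TNFR", "DED", "CARD", "Pep_C14"},
}


class DegenerateVarianceError(ValueError):
    """All paired differences are identical: the t statistic is undefined."""


@dataclass
class EnrichmentResult:
    category: str
    domains: List[str]
    freq_candidates: List[float]
    freq_proteome: List[float]
    t_stat: float
    df: int
    p_two_tailed: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("degrees of freedom must be >= 1")
        if not (0.0 < self.p_two_tailed <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


def _validate_category_map(category_map: Mapping[str, Set[str]]) -> None:
    seen: Dict[str, str] = {}
    for cat, names in category_map.items():
        for name in names:
            if name in seen:
                raise ValueError(
                    f"domain {name!r} appears in both {seen[name]!r} and {cat!r}"
                )
            seen[name] = cat


def domain_frequencies(
    protein_ids: Set[str],
    domain_hits: Iterable[DomainHit],
    category_map: Mapping[str, Set[str]] = None,
) -> Dict[str, float]:
    """Proportion of proteins in the set with >= 1 hit to each mapped domain.

    Presence/absence semantics: a protein with four hits to the same domain
    counts once.  Domains with no hits anywhere get frequency 0.
    """
    if not protein_ids:
        raise ValueError("protein set is empty")
    category_map = category_map or DEFAULT_CATEGORY_MAP
    _validate_category_map(category_map)
    wanted = {name for names in category_map.values() for name in names}
    carriers: Dict[str, Set[str]] = {name: set() for name in wanted}
    for hit in domain_hits:
        if hit.domain_name in wanted and hit.protein_id in protein_ids:
            carriers[hit.domain_name].add(hit.protein_id)
    n = len(protein_ids)
    return {name: len(members) / n for name, members in carriers.items()}


def paired_t_test(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, int, float]:
    """Two-tailed paired t-test; returns (t, df, p).

    ``t = mean(d) / (sd(d)/sqrt(n))`` with the sample (n-1) standard
    deviation of the differences ``d = x - y`` and ``df = n - 1``.

    Raises
    ------
    DegenerateVarianceError
        If all differences are identical to machine precision — a p-value
        would be 0 or undefined, and silently returning one would be wrong.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.shape[0]
    if n < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError(
            "all paired differences are identical; t statistic undefined"
        )
    t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def enrichment_test(
    candidate_ids: Set[str],
    all_protein_ids: Set[str],
    domain_hits: Iterable[DomainHit],
    category_map: Mapping[str, Set[str]] = None,
) -> List[EnrichmentResult]:
    """Per-category paired t-test of candidate vs whole-proteome frequencies."""
    category_map = category_map or DEFAULT_CATEGORY_MAP
    if not candidate_ids <= all_protein_ids:
        raise ValueError("candidates must be a subset of the proteome")
    for cat, names in category_map.items():
        if len(names) < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 domains")
    hits = list(domain_hits)
    freq_cand = domain_frequencies(candidate_ids, hits, category_map)
    freq_all = domain_frequencies(all_protein_ids, hits, category_map)
    results: List[EnrichmentResult] = []
    for cat in sorted(category_map):
        domains = sorted(category_map[cat])
        x = [freq_cand[d] for d in domains]
        y = [freq_all[d] for d in domains]
        t, df, p = paired_t_test(x, y)
        results.append(
            EnrichmentResult(
                category=cat,
                domains=domains,
                freq_candidates=x,
                freq_proteome=y,
                t_stat=t,
                df=df,
                p_two_tailed=p,
            )
        )
    return results
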