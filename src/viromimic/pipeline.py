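"""End-to-end orchestration: virome -> search -> triage -> enrichment -> TM.

``run_pipeline`` wires the stages together under one flat configuration and
writes a deterministic report bundle (no timestamps, fixed ordering), so
identical inputs and config produce byte-identical outputs.  Reference
proteome and domain models are optional; when absent the corresponding
cascade stage is skipped and logged, and every candidate that reaches that
stage falls through to the next one.

Transmembrane prediction is applied to the novel class only by default —
the unannotated candidates are the ones whose cellular localisation cannot
be looked up — with a switch to run it on all candidates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import yaml

from . import __version__
from .align_core import SearchParams, blosum62, compute_ka_params, seeded_search
from .enrichment import DegenerateVarianceError, enrichment_test
from .fragmenter import fragment_set
from .qc import qc_filter
from .seqio import (
    HitTable,
    SeqRecord,
    format_evalue,
    read_fasta,
    read_fastq,
    write_fasta,
    write_hit_table,
)
from .tm_predict import predict_tm_segments
from .triage import (
    DomainModel,
    aggregate_hits,
    count_categories,
    read_domain_models,
    reference_homology,
    scan_domains,
    triage_classify,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("viromimic")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults match the published thresholds."""

    frag_len: int = 200
    min_keep: int = 100
    qc_min_len: int = 100
    qc_min_mean_q: float = 25.0
    qc_max_n_frac: float = 0.10
    evalue_virome: float = 1e-4
    min_fragments: int = 5
    evalue_ref: float = 1e-5
    evalue_dom: float = 0.01
    dom_n_shuffles: int = 1000
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_all_candidates: bool = False
    fragment_input: bool = True
    run_enrichment: bool = True
    # seeded-search parameters
    word_size: int = 3
    neighbor_thresh: int = 11
    x_drop: int = 20
    gap_open: int = 11
    gap_extend: int = 1
    evalue_report_max: float = 10.0
    mask_window: int = 12
    mask_entropy: float = 2.0
    gap_trigger_evalue: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frag_len", "min_keep", "qc_min_len", "qc_min_mean_q",
                     "evalue_virome", "min_fragments", "evalue_ref",
                     "evalue_dom", "dom_n_shuffles", "tm_window",
                     "tm_threshold", "qc_max_n_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config key {name!r} must be positive")

    def search_params(self) -> SearchParams:
        return SearchParams(
            word_size=self.word_size,
            neighbor_thresh=self.neighbor_thresh,
            x_drop=self.x_drop,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            evalue_report_max=self.evalue_report_max,
            mask_window=self.mask_window,
            mask_entropy=self.mask_entropy,
            gap_trigger_evalue=self.gap_trigger_evalue,
        )

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        field_types = {f.name: f.type for f in fields(cls)}
        unknown = set(data) - set(field_types)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        coerced = {}
        for key, value in data.items():
            target = field_types[key]
            try:
                if target == "int":
                    coerced[key] = int(value)
                elif target == "float":
                    coerced[key] = float(value)
                elif target == "bool":
                    coerced[key] = (value.strip().lower() in ("true", "yes", "1")
                                    if isinstance(value, str) else bool(value))
                else:
                    coerced[key] = value
            except (TypeError, ValueError) as exc:
                raise ValueError(f"config key {key!r}: {exc}") from exc
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path: Union[str, os.PathLike]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a flat key: value mapping")
        return cls.from_dict(data)

    def to_yaml_text(self) -> str:
        items = dataclasses.asdict(self)
        return "".join(f"{k}: {items[k]}\n" for k in sorted(items))

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml_text().encode()).hexdigest()


@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: Path
    qc_report: Optional[object]
    hits: HitTable
    summaries: list
    triage_records: list
    category_counts: Dict[str, int]
    enrichment: list
    tm_records: list


def _load_proteins(source) -> List[SeqRecord]:
    if isinstance(source, (str, os.PathLike)):
        return read_fasta(source, alphabet="protein")
    return list(source)


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _domain_seed(base_seed: int, index: int) -> int:
    # stable per-protein shuffle seed, independent of scan order
    return (base_seed * 1_000_003 + index) % (2 ** 31)


def run_pipeline(
    config: PipelineConfig,
    virome,
    host_proteome,
    reference=None,
    domain_models: Optional[Union[str, os.PathLike, Sequence[DomainModel]]] = None,
    category_map: Optional[Mapping[str, Set[str]]] = None,
    outdir: Union[str, os.PathLike] = "viromimic_out",
) -> PipelineResult:
    """Run the full prediction pipeline and write the report bundle.

    ``virome`` is a FASTQ path (reads are quality filtered and used as
    subjects), a FASTA path, or a sequence of records; FASTA/record input is
    fragmented into ``frag_len`` segments unless ``fragment_input`` is off.
    ``host_proteome`` is required; ``reference`` and ``domain_models`` are
    optional and their cascade stages are skipped when absent.
    """
    if host_proteome is None:
        raise ValueError("a host proteome is required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = blosum62()
    ka = compute_ka_params(matrix)
    params = config.search_params()

    # --- virome input ------------------------------------------------------
    qc_report = None
    if isinstance(virome, (str, os.PathLike)) and str(virome).endswith(
            (".fastq", ".fq")):
        reads = read_fastq(virome)
        kept, qc_report = qc_filter(
            reads, min_len=config.qc_min_len, min_mean_q=config.qc_min_mean_q,
            max_n_frac=config.qc_max_n_frac,
        )
        (outdir / "qc_report.tsv").write_text(qc_report.to_tsv())
        subjects = kept
        logger.info("QC kept %d of %d reads", qc_report.n_kept, qc_report.n_input)
    else:
        records = (read_fasta(virome, alphabet="nucleotide")
                   if isinstance(virome, (str, os.PathLike)) else list(virome))
        if config.fragment_input:
            subjects = fragment_set(records, config.frag_len, config.min_keep)
            write_fasta([f.to_record() for f in subjects],
                        outdir / "fragments.fasta")
        else:
            subjects = records

    proteome = _load_proteins(host_proteome)

    # --- translated search and aggregation ---------------------------------
    hits = seeded_search(proteome, subjects, params=params, matrix=matrix,
                         mode="tblastn", ka=ka)
    write_hit_table(hits, outdir / "hits.m6")
    summaries = aggregate_hits(hits, evalue_virome=config.evalue_virome,
                               min_fragments=config.min_fragments)
    _write_tsv(
        outdir / "protein_summaries.tsv",
        ["protein_id", "n_unique_fragments", "n_hsps", "best_evalue"],
        [(s.protein_id, s.n_unique_fragments, s.n_hsps,
          format_evalue(s.best_evalue)) for s in summaries],
    )
    candidate_ids = [s.protein_id for s in summaries]
    by_id = {rec.id: rec for rec in proteome}
    candidates = [by_id[pid] for pid in candidate_ids]

    # --- reference homology -------------------------------------------------
    if reference is not None:
        ref_records = _load_proteins(reference)
        ref_map = reference_homology(candidates, ref_records,
                                     evalue_ref=config.evalue_ref,
                                     params=params, matrix=matrix, ka=ka)
    else:
        logger.warning("no reference proteome given; homology stage skipped")
        ref_map = {}

    # --- domain scanning ----------------------------------------------------
    if domain_models is not None:
        models = (read_domain_models(domain_models)
                  if isinstance(domain_models, (str, os.PathLike))
                  else list(domain_models))
    else:
        logger.warning("no domain models given; domain stage skipped")
        models = []
    categories = {m.name: m.category for m in models}
    protein_index = {rec.id: i for i, rec in enumerate(proteome)}

    domain_hits: Dict[str, list] = {}

    def _scan(pid: str) -> list:
        if pid not in domain_hits:
            rec = by_id[pid]
            domain_hits[pid] = scan_domains(
                rec, models, evalue_dom=config.evalue_dom,
                n_shuffles=config.dom_n_shuffles,
                seed=_domain_seed(config.seed, protein_index[pid]),
            ) if models else []
        return domain_hits[pid]

    for pid in candidate_ids:
        if pid not in ref_map:
            _scan(pid)

    records = triage_classify(summaries, ref_map, domain_hits, categories)
    _write_tsv(
        outdir / "triage.tsv",
        ["protein_id", "n_unique_fragments", "category", "reference_hit",
         "reference_evalue", "domains"],
        [
            (
                r.protein_id,
                r.n_unique_fragments,
                r.category,
                r.best_reference_hit[0] if r.best_reference_hit else ".",
                format_evalue(r.best_reference_hit[1])
                if r.best_reference_hit else ".",
                ",".join(h.domain_name for h in r.domain_hits) or ".",
            )
            for r in records
        ],
    )
    counts = count_categories(records)
    _write_tsv(outdir / "category_counts.tsv", ["category", "count"],
               sorted(counts.items()))

    # --- enrichment ---------------------------------------------------------
    enrichment_results = []
    if models and config.run_enrichment:
        if category_map is None:
            category_map = {}
            for m in models:
                if m.category in ("PAMP", "apoptosis"):
                    category_map.setdefault(m.category, set()).add(m.name)
            category_map = {c: n for c, n in category_map.items() if len(n) >= 2}
        if category_map and candidate_ids:
            for rec in proteome:
                _scan(rec.id)
            all_hits = [h for hits_ in domain_hits.values() for h in hits_]
            try:
                enrichment_results = enrichment_test(
                    set(candidate_ids), set(by_id), all_hits, category_map
                )
            except DegenerateVarianceError:
                logger.warning("enrichment skipped: degenerate variance")
            _write_tsv(
                outdir / "domain_frequencies.tsv",
                ["category", "domain", "freq_candidates", "freq_proteome"],
                [
                    (res.category, d, f"{fc:.6f}", f"{fp:.6f}")
                    for res in enrichment_results
                    for d, fc, fp in zip(res.domains, res.freq_candidates,
                                         res.freq_proteome)
                ],
            )
            _write_tsv(
                outdir / "enrichment.tsv",
                ["category", "t_stat", "df", "p_two_tailed"],
                [(r.category, f"{r.t_stat:.4f}", r.df, f"{r.p_two_tailed:.3g}")
                 for r in enrichment_results],
            )
        else:
            logger.warning("enrichment skipped: no usable category map")

    # --- transmembrane prediction -------------------------------------------
    tm_targets = (candidate_ids if config.tm_all_candidates
                  else [r.protein_id for r in records if r.category == "novel"])
    tm_records = [
        predict_tm_segments(by_id[pid], window=config.tm_window,
                            threshold=config.tm_threshold)
        for pid in tm_targets
    ]
    _write_tsv(
        outdir / "tm_records.tsv",
        ["protein_id", "n_segments", "segments"],
        [
            (t.protein_id, t.n_segments,
             ",".join(f"{s}-{e}" for s, e in t.segments) or ".")
            for t in tm_records
        ],
    )

    # --- manifest ------------------------------------------------------------
    (outdir / "config.yaml").write_text(config.to_yaml_text())
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "n_subjects": len(subjects),
        "n_proteins": len(proteome),
        "n_hits": len(hits),
        "n_candidates": len(candidate_ids),
        "category_counts": counts,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )

    return PipelineResult(
        config=config,
        outdir=outdir,
        qc_report=qc_report,
        hits=hits,
        summaries=summaries,
        triage_records=records,
        category_counts=counts,
        enrichment=enrichment_results,
        tm_records=tm_records,
    )
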