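"""Identify H3-related (HTR) candidate genes in a proteome.

The search is an iterative local-alignment scan: H3.1/H3.3/CenH3 query
proteins are aligned against every proteome entry (Smith-Waterman, BLOSUM62,
affine gaps), hits passing the e-value threshold join the query set, and the
scan repeats until no new sequence is found. Karlin-Altschul statistics
turn raw scores into e-values. The post-scan filters mirror the curation a
genome survey applies: collapse nucleotide-identical CDSs, collapse
alternative transcripts of one locus, and drop incomplete fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._pairwise import _local_kernel, encode_protein, score_grid
from .genome_io import GeneModel, SequenceRecord


@dataclass
class ScanConfig:
    """Scan thresholds and alignment-statistics constants.

    The gapped-BLAST defaults are used for the substitution model (BLOSUM62,
    gap open 11 / extend 1) and for the Karlin-Altschul parameters
    (lambda = 0.267, K = 0.041).
    """

    evalue_threshold: float = 1e-10
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    min_core_coverage: float = 0.8
    # histone-fold core on mature query coordinates, 0-based half-open
    # (canonical positions 45..135); clipped to the query length
    core_span: tuple[int, int] = (44, 135)

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")


@dataclass
class HomologyHit:
    query_id: str
    subject_id: str
    sw_score: float
    aligned_span_on_subject: tuple[int, int]  # 0-based half-open
    aligned_span_on_query: tuple[int, int]
    query_length: int | None = None
    evalue: float | None = None


@dataclass
class HtrCandidate:
    gene_id: str
    protein: SequenceRecord
    best_hit: HomologyHit
    cds: SequenceRecord | None = None
    gene_model: GeneModel | None = None
    filter_status: str = "kept"  # kept | redundant | isoform | incomplete


def smith_waterman(query: str, subject: str, config: ScanConfig | None = None) -> HomologyHit:
    """Optimal local alignment of query vs subject.

    Returns the score and the aligned half-open spans on both sequences.
    Traceback ties are broken diagonal > up > left, so the reported span is
    deterministic.
    """
    config = config or ScanConfig()
    grid = score_grid(encode_protein(query), encode_protein(subject))
    score, q0, q1, s0, s1 = _local_kernel(grid, float(config.gap_open), float(config.gap_extend))
    return HomologyHit(
        query_id="",
        subject_id="",
        sw_score=float(score),
        aligned_span_on_subject=(int(s0), int(s1)),
        aligned_span_on_query=(int(q0), int(q1)),
        query_length=len(query),
    )


def estimate_evalue(hit: HomologyHit, query_len: int, db_residues: int, config: ScanConfig) -> float:
    """Karlin-Altschul expected number of chance hits at this score:
    E = K * m * n * exp(-lambda * S)."""
    return config.karlin_k * query_len * db_residues * math.exp(-config.karlin_lambda * hit.sw_score)


def scan_proteome(
    proteome: list[SequenceRecord],
    queries: list[SequenceRecord],
    gene_models: dict[str, GeneModel] | None = None,
    cds_map: dict[str, SequenceRecord] | None = None,
    config: ScanConfig | None = None,
) -> list[HtrCandidate]:
    """Iterative homology scan of a proteome.

    Hits passing the e-value threshold join the query set; rounds repeat
    until a fixpoint (every matching sequence was itself used to search).
    The reported best_hit for each subject is its highest-scoring alignment
    against any query available up to and including its discovery round.
    The output is independent of proteome record order.
    """
    config = config or ScanConfig()
    gene_models = gene_models or {}
    cds_map = cds_map or {}
    if not queries:
        raise ValueError("empty query set")
    if not proteome:
        return []

    db_residues = sum(len(r.seq) for r in proteome)
    encoded = {r.id: encode_protein(r.seq) for r in proteome}
    subjects = {r.id: r for r in proteome}

    best: dict[str, HomologyHit] = {}
    pool: list[SequenceRecord] = list(queries)
    pending = [r.id for r in proteome]
    go, ge = float(config.gap_open), float(config.gap_extend)

    while pool:
        new_hits: list[str] = []
        for sid in pending:
            s_idx = encoded[sid]
            for q in pool:
                grid = score_grid(encode_protein(q.seq), s_idx)
                score, q0, q1, s0, s1 = _local_kernel(grid, go, ge)
                hit = HomologyHit(
                    q.id, sid, float(score), (int(s0), int(s1)), (int(q0), int(q1)), len(q.seq)
                )
                hit.evalue = estimate_evalue(hit, len(q.seq), db_residues, config)
                prev = best.get(sid)
                if prev is None or hit.sw_score > prev.sw_score:
                    best[sid] = hit
            if best[sid].evalue < config.evalue_threshold:
                new_hits.append(sid)
        pending = [sid for sid in pending if sid not in set(new_hits)]
        pool = [subjects[sid] for sid in sorted(new_hits)]

    out = []
    for sid in sorted(best):
        if best[sid].evalue >= config.evalue_threshold:
            continue
        out.append(
            HtrCandidate(
                gene_id=sid,
                protein=subjects[sid],
                best_hit=best[sid],
                cds=cds_map.get(sid),
                gene_model=gene_models.get(sid),
            )
        )
    return out


def filter_candidates(candidates: list[HtrCandidate], config: ScanConfig | None = None) -> list[HtrCandidate]:
    """Apply the redundancy / isoform / incompleteness filters.

    (a) byte-identical CDS nucleotide sequences collapse to the
    lexicographically smallest gene_id (others -> ``redundant``);
    (b) transcripts of one gene locus collapse to the longest-CDS
    representative (others -> ``isoform``);
    (c) alignments covering less than ``min_core_coverage`` of the query
    are marked ``incomplete``.

    Statuses are (re)assigned on every call, so the operation is idempotent.
    Only candidates whose final status is ``kept`` pass downstream.
    """
    config = config or ScanConfig()
    for c in candidates:
        c.filter_status = "kept"

    # (c) incompleteness first: fragments should not shadow full-length genes
    # in the redundancy groups.
    for c in candidates:
        q0, q1 = c.best_hit.aligned_span_on_query
        qlen = c.best_hit.query_length
        if not qlen:
            continue
        core0, core1 = config.core_span
        core1 = min(core1, qlen)
        core0 = min(core0, core1)
        width = core1 - core0
        if width <= 0:
            continue
        overlap = max(0, min(q1, core1) - max(q0, core0))
        if overlap / width < config.min_core_coverage:
            c.filter_status = "incomplete"

    # (a) CDS redundancy
    by_cds: dict[str, list[HtrCandidate]] = {}
    for c in candidates:
        if c.filter_status != "kept" or c.cds is None:
            continue
        by_cds.setdefault(c.cds.seq, []).append(c)
    for group in by_cds.values():
        group.sort(key=lambda c: c.gene_id)
        for c in group[1:]:
            c.filter_status = "redundant"

    # (b) isoforms of one locus
    by_locus: dict[str, list[HtrCandidate]] = {}
    for c in candidates:
        if c.filter_status != "kept" or c.gene_model is None:
            continue
        by_locus.setdefault(c.gene_model.gene_id, []).append(c)
    for group in by_locus.values():
        group.sort(key=lambda c: (-(len(c.cds.seq) if c.cds else len(c.protein.seq)), c.gene_id))
        for c in group[1:]:
            c.filter_status = "isoform"

    return candidates
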