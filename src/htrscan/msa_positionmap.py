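"""Alignment of HTR candidates and mapping onto canonical H3 numbering.

Signature positions (31/41/87/90) and the methylatable lysines (4/9/27/36)
are defined in canonical mature-H3 coordinates: 1-based, position 1 being
the first residue after the initiator methionine. Every candidate protein
is therefore aligned globally to a canonical reference and its residue
indices translated into that frame before any classification rule looks at
it. A progressive multiple aligner (neighbor-joining guide tree on
p-distances, profile-profile merges with sum-of-pairs BLOSUM62 scoring)
replaces external MSA tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._pairwise import (
    PROTEIN_ALPHABET,
    blosum62_matrix,
    encode_protein,
    nw_align,
    nw_align_grid,
)
from .genome_io import SequenceRecord

_GAP_OPEN = 11.0
_GAP_EXT = 1.0


def default_reference() -> SequenceRecord:
    """The bundled canonical mature-H3 reference.

    A synthetic stand-in occupying the coordinate frame of a mature plant
    H3.3 (135 residues, initiator Met excluded); any analysis of real data
    should override it with the organism's own mature H3.3 sequence.
    """
    from importlib.resources import files

    from .genome_io import read_fasta

    path = files("htrscan").joinpath("data/h3_reference_synthetic.fasta")
    return read_fasta(str(path), "protein")[0]


@dataclass
class Alignment:
    """A multiple alignment: equal-length gapped rows keyed by seq_ids."""

    seq_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.rows):
            raise ValueError("seq_ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, seq_id: str) -> str:
        return self.rows[self.seq_ids.index(seq_id)].replace("-", "")


@dataclass
class PositionMap:
    """Candidate residue indices keyed by canonical H3 position.

    ``mapping[p]`` is the 0-based index into the candidate protein aligned
    with canonical position p (1-based, mature numbering), or None where the
    candidate has a gap. ``n_terminal_overhang`` counts candidate residues
    aligned before canonical position 1, excluding a trimmed initiator Met.
    """

    candidate_id: str
    candidate_seq: str
    reference_seq: str
    mapping: dict[int, int | None]
    n_terminal_overhang: int
    met_trimmed: bool = False

    def residue_at(self, position: int) -> str:
        idx = self.mapping.get(position)
        return self.candidate_seq[idx] if idx is not None else "-"

    def identity_over(self, start: int, end: int) -> float:
        """Fraction of canonical positions in [start, end] (inclusive) where
        the candidate carries the reference residue; gaps count as
        mismatches."""
        end = min(end, len(self.reference_seq))
        positions = range(start, end + 1)
        if not positions:
            raise ValueError("empty canonical range")
        matches = sum(
            1 for p in positions if self.residue_at(p) == self.reference_seq[p - 1]
        )
        return matches / len(list(positions))


def global_align_pair(a: SequenceRecord | str, b: SequenceRecord | str) -> Alignment:
    """Optimal global (Needleman-Wunsch) alignment of two proteins.

    BLOSUM62, affine gaps (open 11 / extend 1), end gaps penalized,
    deterministic traceback (diagonal > up > left).
    """
    ida, sa = _as_pair(a, "seq_a")
    idb, sb = _as_pair(b, "seq_b")
    aln = nw_align(sa, sb, _GAP_OPEN, _GAP_EXT)
    ga, gb = aln.gapped(sa, sb)
    return Alignment([ida, idb], [ga, gb])


def _as_pair(x, default_id: str) -> tuple[str, str]:
    if isinstance(x, SequenceRecord):
        return x.id, x.seq
    return default_id, str(x)


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Residue count matrix (columns x alphabet); gaps contribute nothing."""
    n_alpha = len(PROTEIN_ALPHABET)
    ncol = len(rows[0])
    counts = np.zeros((ncol, n_alpha))
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                counts[j, encode_protein(c)[0]] += 1
    return counts


def _merge_profiles(a: Alignment, b: Alignment) -> Alignment:
    """Profile-profile global alignment with average sum-of-pairs scoring."""
    ca = _profile_counts(a.rows)
    cb = _profile_counts(b.rows)
    S = blosum62_matrix()
    grid = (ca @ S @ cb.T) / (len(a.rows) * len(b.rows))
    path = nw_align_grid(grid, _GAP_OPEN, _GAP_EXT)
    na, nb = len(a.rows), len(b.rows)
    rows_a = [[] for _ in range(na)]
    rows_b = [[] for _ in range(nb)]
    for i, j in zip(path.a_idx, path.b_idx):
        for r in range(na):
            rows_a[r].append(a.rows[r][i] if i >= 0 else "-")
        for r in range(nb):
            rows_b[r].append(b.rows[r][j] if j >= 0 else "-")
    return Alignment(
        a.seq_ids + b.seq_ids,
        ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b],
    )


def _pairwise_p_distance(sa: str, sb: str) -> float:
    aln = nw_align(sa, sb, _GAP_OPEN, _GAP_EXT)
    paired = [(i, j) for i, j in zip(aln.a_idx, aln.b_idx) if i >= 0 and j >= 0]
    if not paired:
        return 1.0
    matches = sum(1 for i, j in paired if sa[i] == sb[j])
    return 1.0 - matches / len(paired)


def progressive_msa(seqs: list[SequenceRecord]) -> Alignment:
    """Progressive multiple alignment.

    Guide tree: neighbor joining on pairwise p-distances (midpoint of the
    NJ star for <= 3 sequences is implicit); merges follow the guide tree
    bottom-up with profile-profile global alignment. Each row ungaps back
    to its input sequence exactly.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in MSA input")
    profiles = {s.id: Alignment([s.id], [s.seq]) for s in seqs}
    if len(seqs) == 2:
        return global_align_pair(seqs[0], seqs[1])

    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _pairwise_p_distance(seqs[i].seq, seqs[j].seq)

    from .phylo import DistanceMatrix, neighbor_joining

    tree = neighbor_joining(DistanceMatrix(ids, dm))

    def build(node) -> Alignment:
        if node.is_leaf():
            return profiles[node.taxon.label]
        child_alns = [build(ch) for ch in node.child_nodes()]
        merged = child_alns[0]
        for nxt in child_alns[1:]:
            merged = _merge_profiles(merged, nxt)
        return merged

    return build(tree.seed_node)


def map_to_reference(candidate: SequenceRecord | str, reference: SequenceRecord | str) -> PositionMap:
    """Map a candidate protein onto canonical mature-H3 numbering.

    The reference must be a mature H3 (position 1 = first residue after the
    initiator Met). A candidate that retains its initiator Met has it
    excluded from the N-terminal overhang count. Raises ``unmappable`` when
    fewer than 20 reference positions align.
    """
    cid, cseq = _as_pair(candidate, "candidate")
    _, rseq = _as_pair(reference, "reference")
    aln = nw_align(cseq, rseq, _GAP_OPEN, _GAP_EXT)

    mapping: dict[int, int | None] = {p: None for p in range(1, len(rseq) + 1)}
    first_ref_col = None
    for col, (ci, rj) in enumerate(zip(aln.a_idx, aln.b_idx)):
        if rj >= 0:
            if first_ref_col is None:
                first_ref_col = col
            mapping[rj + 1] = int(ci) if ci >= 0 else None

    mapped = sum(1 for v in mapping.values() if v is not None)
    if mapped < 20:
        raise ValueError(f"unmappable: candidate {cid!r} aligns {mapped} reference positions (< 20)")

    # N-terminal overhang: the candidate's length excess ahead of the
    # histone-fold core (canonical 45) - candidate residues preceding the
    # first mapped core position, minus the canonical tail span they could
    # account for. Counting against the core anchor keeps the measure
    # robust to where the aligner happens to place extension gaps within a
    # divergent tail.
    core_anchor = next(
        (p for p in range(45, len(rseq) + 1) if mapping[p] is not None), None
    )
    if core_anchor is not None:
        overhang = max(0, mapping[core_anchor] - (core_anchor - 1))
    else:
        overhang = sum(1 for col in range(first_ref_col) if aln.a_idx[col] >= 0)
    met_trimmed = False
    if cseq[0] == "M" and overhang >= 1:
        overhang -= 1
        met_trimmed = True
    return PositionMap(cid, cseq, rseq, mapping, overhang, met_trimmed)
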