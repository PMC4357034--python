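"""Variant classification of HTR candidates.

Plant H3 variants are discriminated by four signature residues in mature-H3
numbering — 31, 41, 87 and 90 — together with gene structure: H3.3 genes
carry T31 Y41 H87 L90 and contain introns, H3.1 genes carry A31 F41 S87 A90
and are intronless, and the intronless A31 Y41 (S/Q)87 L90 form of
nonflowering plants is H3.1A. CenH3 is recognised by phylogenetic affinity
to a known CenH3 anchor and/or by its long divergent N-terminal tail, and
takes priority over the signature rules. Everything else — degenerate
tails, off-consensus signatures, signature/intron contradictions — is the
heterogeneous H3-like class. The conserved lysines K4/K9/K27/K36 are
audited per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .msa_positionmap import PositionMap

logger = logging.getLogger(__name__)

CLASSES = ("CENH3", "H3_1", "H3_1A", "H3_3", "H3_LIKE")

LYSINE_POSITIONS = (4, 9, 27, 36)

# N-terminal tail = canonical 1..44; histone-fold core starts near 45.
TAIL_RANGE = (1, 44)
CORE_RANGE = (45, 135)


@dataclass(frozen=True)
class RuleSet:
    """A signature rule set: which canonical positions discriminate the
    variants and which residue tuples define each class."""

    name: str
    positions: tuple[int, ...]
    h3_1: tuple[tuple[str, ...], ...]
    h3_3: tuple[tuple[str, ...], ...]
    h3_1a: tuple[tuple[str, ...], ...] = ()


PLANT_RULES = RuleSet(
    name="plant",
    positions=(31, 41, 87, 90),
    h3_1=(("A", "F", "S", "A"),),
    h3_3=(("T", "Y", "H", "L"),),
    h3_1a=(("A", "Y", "S", "L"), ("A", "Y", "Q", "L")),
)

# Metazoan H3.1 vs H3.3 discriminate at 31/87/89/90 and use different
# residues; no H3.1A class. Off by default.
ANIMAL_RULES = RuleSet(
    name="animal",
    positions=(31, 87, 89, 90),
    h3_1=(("A", "S", "V", "M"),),
    h3_3=(("S", "A", "I", "G"),),
)


@dataclass
class SignatureProfile:
    """Residues at the rule set's signature positions plus lysine states."""

    positions: tuple[int, ...]
    residues: tuple[str, ...]  # aligned with positions; '-' = gap
    k4: str = "-"
    k9: str = "-"
    k27: str = "-"
    k36: str = "-"
    n_terminal_overhang: int = 0
    tail_deleted: bool = False

    def signature_residues(self) -> tuple[str, ...]:
        return self.residues

    def lysine_states(self) -> dict[int, str]:
        return {4: self.k4, 9: self.k9, 27: self.k27, 36: self.k36}


@dataclass
class VariantCall:
    gene_id: str
    variant_class: str
    signature: SignatureProfile
    intron_count: int | None  # None = unknown
    evidence: set[str] = field(default_factory=set)
    confidence: str = "low"
    species: str = "synthetic"


@dataclass
class CenH3Params:
    min_support: float = 70.0
    min_overhang: int = 15
    max_core_identity: float = 0.75
    core_range: tuple[int, int] = CORE_RANGE


def extract_signature(
    pmap: PositionMap, rules: RuleSet = PLANT_RULES
) -> SignatureProfile:
    """Read signature residues and lysine states through a position map.

    Unmapped positions record a gap; a tail is called deleted when at least
    10 N-terminal canonical positions (1-44) map to gap.
    """
    residues = tuple(pmap.residue_at(p) for p in rules.positions)
    lysines = {p: pmap.residue_at(p) for p in LYSINE_POSITIONS}
    tail_gaps = sum(
        1 for p in range(TAIL_RANGE[0], TAIL_RANGE[1] + 1) if pmap.residue_at(p) == "-"
    )
    return SignatureProfile(
        positions=rules.positions,
        residues=residues,
        k4=lysines[4],
        k9=lysines[9],
        k27=lysines[27],
        k36=lysines[36],
        n_terminal_overhang=pmap.n_terminal_overhang,
        tail_deleted=tail_gaps >= 10,
    )


def _signature_class(sig: SignatureProfile, rules: RuleSet) -> str | None:
    r = sig.residues
    if r in rules.h3_1:
        return "H3_1"
    if r in rules.h3_3:
        return "H3_3"
    if r in rules.h3_1a:
        return "H3_1A"
    return None


def classify_variant(
    sig: SignatureProfile,
    intron_count: int | None,
    cenh3_evidence: set[str] | None = None,
    gene_id: str = "",
    rules: RuleSet = PLANT_RULES,
    species: str = "synthetic",
) -> VariantCall:
    """Assign the variant class for one candidate.

    Decision order: (1) any CenH3 evidence wins; (2-4) a matching signature
    with agreeing intron evidence gives H3.1 / H3.3 / H3.1A; with unknown
    introns the signature decides alone (flag ``signature_only``, medium
    confidence); a matching signature contradicted by the intron evidence
    is a conflict and falls to H3-like; (5) everything else is H3-like.
    """
    cenh3_evidence = set(cenh3_evidence or ())
    if cenh3_evidence:
        confidence = "high" if "cenh3_clade" in cenh3_evidence else "medium"
        return VariantCall(gene_id, "CENH3", sig, intron_count, cenh3_evidence, confidence, species)

    sig_class = _signature_class(sig, rules)
    if sig_class is None:
        return VariantCall(gene_id, "H3_LIKE", sig, intron_count, {"no_signature_match"}, "low", species)

    wants_introns = sig_class == "H3_3"
    if intron_count is None:
        return VariantCall(
            gene_id, sig_class, sig, None, {"signature_match", "signature_only"}, "medium", species
        )
    intron_agrees = (intron_count >= 1) if wants_introns else (intron_count == 0)
    if intron_agrees:
        return VariantCall(
            gene_id, sig_class, sig, intron_count, {"signature_match", "intron_match"}, "high", species
        )
    return VariantCall(
        gene_id,
        "H3_LIKE",
        sig,
        intron_count,
        {"signature_match", "signature_intron_conflict"},
        "low",
        species,
    )


def detect_cenh3(
    pmap: PositionMap,
    tree=None,
    anchors: list[str] | None = None,
    params: CenH3Params | None = None,
    known_non_cenh3: set[str] | None = None,
) -> set[str]:
    """Collect CenH3 evidence flags for one candidate.

    ``cenh3_tail``: N-terminal overhang of at least ``min_overhang``
    residues AND core identity to the reference (canonical 45-135) below
    ``max_core_identity``. ``cenh3_clade``: the candidate sits in a
    supported bipartition (>= ``min_support``) with an anchor, excluding
    all known non-CenH3 ids. Without tree and anchors only the tail
    heuristic runs.
    """
    params = params or CenH3Params()
    known_non_cenh3 = known_non_cenh3 or set()
    flags: set[str] = set()

    lo, hi = params.core_range
    if (
        pmap.n_terminal_overhang >= params.min_overhang
        and pmap.identity_over(lo, hi) < params.max_core_identity
    ):
        flags.add("cenh3_tail")

    if tree is not None and anchors:
        from .phylo import supported_clades

        leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        anchor_set = set(anchors) & leaves
        target = {pmap.candidate_id} | anchor_set
        if anchor_set and pmap.candidate_id in leaves:
            for side, support in supported_clades(tree):
                if support < params.min_support:
                    continue
                if target <= side and not (side & known_non_cenh3):
                    flags.add("cenh3_clade")
                    break
    elif tree is None and not anchors:
        logger.warning(
            "no CenH3 anchors and no tree for %s: tail heuristic only", pmap.candidate_id
        )
    return flags


def audit_lysines(calls: list[VariantCall]) -> pd.DataFrame:
    """Per-class conservation of K4/K9/K27/K36.

    One row per class: gene count, fraction of genes carrying K at each
    site (gaps count as non-K), and the observed substitutions as
    ``gene:K<pos><aa>`` flags.
    """
    if not calls:
        return pd.DataFrame(
            columns=["class", "n", "k4_fraction", "k9_fraction", "k27_fraction", "k36_fraction", "substitutions"]
        )
    rows = []
    for cls in sorted({c.variant_class for c in calls}):
        members = [c for c in calls if c.variant_class == cls]
        fracs = {}
        subs = []
        for pos in LYSINE_POSITIONS:
            states = [c.signature.lysine_states()[pos] for c in members]
            fracs[pos] = sum(1 for s in states if s == "K") / len(members)
            subs.extend(
                f"{c.gene_id}:K{pos}{s}"
                for c, s in zip(members, states)
                if s not in ("K", "-")
            )
        rows.append(
            {
                "class": cls,
                "n": len(members),
                "k4_fraction": fracs[4],
                "k9_fraction": fracs[9],
                "k27_fraction": fracs[27],
                "k36_fraction": fracs[36],
                "substitutions": ";".join(sorted(subs)) or ".",
            }
        )
    return pd.DataFrame(rows)
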