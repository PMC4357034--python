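"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* ``synth_genome`` — a labelled proteome/CDS/GFF3 triple: H3.1, H3.3,
  H3.1A, CenH3 and H3-like genes built from a synthetic canonical mature
  H3 reference with the class-defining signature residues and intron
  structures, plus random decoy proteins that must fail the homology
  threshold. CenH3 genes descend from a common diverged, tail-extended
  CenH3 ancestor so they form a clade.
* ``evolve_codons`` — a continuous-time (Gillespie) codon substitution
  simulator with transition/transversion ratio kappa and nonsynonymous
  scaling omega, normalized to one expected substitution per codon site
  per unit time at the ancestor composition.
* ``synth_expression`` — tissue expression matrices with planted profile
  archetypes (constitutive, dividing-high, single-tissue heterogeneous,
  not-detected).

All randomness flows through one seeded generator per call; outputs are
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .genome_io import ExpressionMatrix, GeneModel, SequenceRecord
from .selection import SENSE_CODONS, STOP_CODONS, _AA, is_sense

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# canonical mature-H3 coordinates (1-based)
SIGNATURE_POSITIONS = (31, 41, 87, 90)
LYSINE_POSITIONS = (4, 9, 27, 36)
PROTECTED = SIGNATURE_POSITIONS + LYSINE_POSITIONS

H3_1_SIG = ("A", "F", "S", "A")
H3_3_SIG = ("T", "Y", "H", "L")
H3_1A_87 = ("S", "Q")

# residues that must NOT appear at a signature position for an H3-like gene,
# so the elimination rule is guaranteed to fire
_SIG_FORBIDDEN = {31: {"T", "A"}, 41: {"Y", "F"}, 87: {"H", "S", "Q"}, 90: {"L", "A"}}

_CODONS_FOR = {}
for _c in SENSE_CODONS:
    _CODONS_FOR.setdefault(_AA[_c], []).append(_c)


@dataclass
class ExpressionPlan:
    """Planted expression archetypes over a two-group tissue panel."""

    tissue_groups: dict[str, str] = field(
        default_factory=lambda: {
            "root_young": "dividing",
            "root_mature": "dividing",
            "stem": "dividing",
            "seed": "dividing",
            "embryo": "dividing",
            "shoot_apex": "dividing",
            "leaf_young": "differentiated",
            "leaf_mature": "differentiated",
            "leaf_senescent": "differentiated",
            "endosperm": "differentiated",
        }
    )
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "constitutive": 4,
            "dividing_high": 4,
            "heterogeneous": 4,
            "not_detected": 2,
        }
    )
    delta: float = 2.0  # log2 group effect
    noise_sd: float = 0.2  # log2 noise
    base_log2: float = 6.0
    detection_floor: float = 1.0


@dataclass
class SynthesisSpec:
    """Study conditions for one synthetic genome."""

    seed: int = 42
    n_h3_1: int = 4
    n_h3_3: int = 4
    n_h3_1a: int = 4
    n_cenh3: int = 4
    n_h3_like: int = 4
    n_decoys: int = 20
    reference_length: int = 135
    mutation_rate: float = 0.02  # outside protected positions
    cenh3_tail_length: int = 25
    cenh3_ancestor_divergence: float = 0.35  # core fraction mutated in the CenH3 ancestor
    cenh3_within_rate: float = 0.08  # extra per-gene divergence within the CenH3 clade
    h3_like_truncated: int = 1  # how many H3-like genes lose the N-terminal tail
    k27m_in_h3_like: int = 0
    synonymous_swap_rate: float = 0.1  # per-codon silent divergence from the reference CDS
    # codon-simulation defaults
    omega: float = 0.2
    kappa: float = 1.0
    divergence: float = 0.3  # expected substitutions per codon site
    n_codons: int = 200
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)

    def __post_init__(self) -> None:
        for name in ("n_h3_1", "n_h3_3", "n_h3_1a", "n_cenh3", "n_h3_like", "n_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cenh3 > 0 and self.cenh3_tail_length < 1:
            raise ValueError("cenh3_tail_length must be >= 1 when CenH3 genes are requested")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


@dataclass
class TruthLabel:
    variant_class: str  # CENH3 | H3_1 | H3_1A | H3_3 | H3_LIKE | NONE
    signature: tuple[str, str, str, str] | None
    intron_count: int


@dataclass
class TruthLabels:
    labels: dict[str, TruthLabel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def class_of(self, gene_id: str) -> str:
        return self.labels[gene_id].variant_class


@dataclass
class SyntheticGenome:
    proteome: list[SequenceRecord]
    cds: dict[str, SequenceRecord]
    gene_models: dict[str, GeneModel]
    truth: TruthLabels
    reference: SequenceRecord
    queries: list[SequenceRecord]
    cenh3_anchor_ids: list[str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .genome_io import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "proteome.faa",
            "cds": outdir / "cds.fna",
            "gff3": outdir / "genes.gff3",
            "reference": outdir / "reference.faa",
            "queries": outdir / "queries.faa",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.proteome, paths["proteome"])
        write_fasta([self.cds[r.id] for r in self.proteome if r.id in self.cds], paths["cds"])
        write_gff3(self.gene_models, paths["gff3"])
        write_fasta([self.reference], paths["reference"])
        write_fasta(self.queries, paths["queries"])
        with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_id\tclass\tsignature\tintron_count\n")
            for gid in sorted(self.truth.labels):
                lab = self.truth.labels[gid]
                sig = "".join(lab.signature) if lab.signature else "."
                fh.write(f"{gid}\t{lab.variant_class}\t{sig}\t{lab.intron_count}\n")
        return paths


def make_reference(seed: int, length: int = 135) -> SequenceRecord:
    """A synthetic canonical mature H3 reference.

    Random protein with the conserved lysines fixed at 4/9/27/36 and the
    H3.3 signature (T31 Y41 H87 L90); deterministic per seed. This is a
    synthetic stand-in occupying the coordinate frame of the real
    Arabidopsis H3.3, not a biological sequence.
    """
    if length < 100:
        raise ValueError("reference length must be >= 100")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(AA20), size=length))
    for p in LYSINE_POSITIONS:
        seq[p - 1] = "K"
    for p, res in zip(SIGNATURE_POSITIONS, H3_3_SIG):
        seq[p - 1] = res
    return SequenceRecord(f"h3ref_s{seed}", "".join(seq), "protein")


def _mutate(seq: list[str], rate: float, protected0: set[int], rng) -> list[str]:
    out = list(seq)
    for i in range(len(out)):
        if i in protected0:
            continue
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return out


def _mutate_exact(seq: list[str], n_positions: int, candidates0: list[int], rng) -> list[str]:
    out = list(seq)
    picked = rng.choice(candidates0, size=min(n_positions, len(candidates0)), replace=False)
    for i in picked:
        choices = [a for a in AA20 if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def _random_codon(aa: str, rng) -> str:
    opts = _CODONS_FOR[aa]
    return opts[rng.integers(len(opts))]


def _backtranslate_protein(
    protein: str,
    rng,
    sources: list[str | None] | None = None,
    swap_rate: float = 0.0,
) -> str:
    """Back-generate a CDS for ``protein`` (leading Met gets ATG, random stop).

    ``sources`` optionally gives, per residue, the codon the gene inherits
    (by descent from the reference CDS); the inherited codon is kept when it
    still encodes the residue, replaced by a random synonymous codon with
    probability ``swap_rate`` (silent divergence) or whenever the amino
    acid changed. Without sources every codon is uniformly random.
    """
    codons = []
    for i, aa in enumerate(protein):
        src = sources[i] if sources is not None else None
        if src is not None and _AA[src] == aa and rng.random() >= swap_rate:
            codons.append(src)
        else:
            codons.append(_random_codon(aa, rng))
    stops = sorted(STOP_CODONS)
    codons.append(stops[rng.integers(len(stops))])
    return "".join(codons)


def _gene_model(gid: str, strand: str, cds_nt_len: int, n_introns: int, cursor: int, rng) -> tuple[GeneModel, int]:
    tid = f"{gid}.1"
    if n_introns > 0:
        cuts = sorted(rng.choice(np.arange(3, cds_nt_len - 2), size=n_introns, replace=False))
        lengths = np.diff([0, *cuts, cds_nt_len]).tolist()
    else:
        lengths = [cds_nt_len]
    segments = []
    pos = cursor
    for k, ln in enumerate(lengths):
        segments.append((pos, pos + ln - 1))
        pos += ln
        if k < len(lengths) - 1:
            pos += int(rng.integers(60, 201))  # intron
    gm = GeneModel(gene_id=gid, transcript_ids=[tid], strand=strand, cds_segments={tid: segments})
    return gm, pos + 500


def write_gff3(gene_models: dict[str, GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(gene_models):
            gm = gene_models[gid]
            segs = [s for segs in gm.cds_segments.values() for s in segs]
            if segs:
                lo = min(s for s, _ in segs)
                hi = max(e for _, e in segs)
            else:
                lo, hi = 1, 1
            fh.write(f"chr1\thtrscan\tgene\t{lo}\t{hi}\t.\t{gm.strand}\t.\tID={gid}\n")
            for tid in gm.transcript_ids:
                fh.write(f"chr1\thtrscan\tmRNA\t{lo}\t{hi}\t.\t{gm.strand}\t.\tID={tid};Parent={gid}\n")
                for s, e in sorted(gm.cds_segments.get(tid, [])):
                    fh.write(f"chr1\thtrscan\tCDS\t{s}\t{e}\t.\t{gm.strand}\t0\tID=cds_{tid};Parent={tid}\n")


def synth_genome(spec: SynthesisSpec) -> SyntheticGenome:
    """Generate a labelled synthetic genome (proteome + CDS + GFF3 + truth).

    Mature proteins are built from the seed reference; every gene is then
    emitted with an initiator Met, a back-generated CDS with uniformly
    random synonymous codons, and a gene model realizing its intron plan.
    """
    rng = np.random.default_rng(spec.seed)
    ref = make_reference(spec.seed, spec.reference_length)
    refseq = list(ref.seq)
    protected0 = {p - 1 for p in PROTECTED}
    core0 = list(range(44, min(135, len(refseq))))  # canonical 45..135, 0-based
    tail0 = list(range(0, 44))

    # CenH3 ancestor: extended tail + strongly diverged core
    cen_tail = list(rng.choice(list(AA20), size=spec.cenh3_tail_length))
    cen_core = _mutate_exact(refseq, round(spec.cenh3_ancestor_divergence * len(core0)), core0, rng)
    cen_core = _mutate(cen_core, spec.cenh3_ancestor_divergence, set(core0), rng)  # tail region drift
    cen_ancestor = cen_tail + cen_core

    # reference codon assignment: genes inherit codons by descent so that
    # synonymous divergence within the genome stays realistic (unsaturated)
    ref_codons = [_random_codon(aa, rng) for aa in refseq]
    cen_anc_codons = [_random_codon(aa, rng) for aa in cen_tail] + [
        rc if _AA[rc] == aa else _random_codon(aa, rng)
        for rc, aa in zip(ref_codons, cen_core)
    ]

    plan: list[tuple[str, int]] = (
        [("H3_1", i) for i in range(spec.n_h3_1)]
        + [("H3_3", i) for i in range(spec.n_h3_3)]
        + [("H3_1A", i) for i in range(spec.n_h3_1a)]
        + [("CENH3", i) for i in range(spec.n_cenh3)]
        + [("H3_LIKE", i) for i in range(spec.n_h3_like)]
        + [("NONE", i) for i in range(spec.n_decoys)]
    )
    order = rng.permutation(len(plan))

    proteome: list[SequenceRecord] = []
    cds: dict[str, SequenceRecord] = {}
    gene_models: dict[str, GeneModel] = {}
    truth = TruthLabels()
    cursor = 1000

    for gnum, idx in enumerate(order, start=1):
        cls, within = plan[idx]
        gid = f"g{gnum:03d}"
        signature: tuple[str, str, str, str] | None = None
        sources: list[str | None] | None = list(ref_codons)
        if cls == "H3_1":
            mature = list(refseq)
            for p, res in zip(SIGNATURE_POSITIONS, H3_1_SIG):
                mature[p - 1] = res
            mature = _mutate(mature, spec.mutation_rate, protected0, rng)
            introns = 0
            signature = H3_1_SIG
        elif cls == "H3_3":
            mature = _mutate(list(refseq), spec.mutation_rate, protected0, rng)
            introns = int(rng.integers(1, 3))
            signature = H3_3_SIG
        elif cls == "H3_1A":
            mature = list(refseq)
            sig = ("A", "Y", H3_1A_87[rng.integers(2)], "L")
            for p, res in zip(SIGNATURE_POSITIONS, sig):
                mature[p - 1] = res
            mature = _mutate(mature, spec.mutation_rate, protected0, rng)
            introns = 0
            signature = sig
        elif cls == "CENH3":
            mature = _mutate(list(cen_ancestor), spec.cenh3_within_rate, set(), rng)
            sources = list(cen_anc_codons)
            introns = int(rng.integers(0, 3))
        elif cls == "H3_LIKE":
            mature = list(refseq)
            n_perturb = int(rng.integers(1, 4))
            for p in rng.choice(SIGNATURE_POSITIONS, size=n_perturb, replace=False):
                choices = [a for a in AA20 if a not in _SIG_FORBIDDEN[int(p)]]
                mature[int(p) - 1] = choices[rng.integers(len(choices))]
            if within < spec.k27m_in_h3_like:
                mature[27 - 1] = "M"
            mature = _mutate(mature, spec.mutation_rate, protected0, rng)
            if within < spec.h3_like_truncated:
                mature = mature[44:]  # tail degeneration
                sources = sources[44:]
            introns = int(rng.integers(0, 3))
        else:  # decoy
            length = int(rng.integers(90, 181))
            mature = list(rng.choice(list(AA20), size=length))
            sources = None
            introns = int(rng.integers(0, 3))

        protein = "M" + "".join(mature)
        full_sources = ["ATG"] + sources if sources is not None else None
        cds_nt = _backtranslate_protein(protein, rng, full_sources, spec.synonymous_swap_rate)
        proteome.append(SequenceRecord(gid, protein, "protein"))
        cds[gid] = SequenceRecord(gid, cds_nt, "dna")
        strand = "+" if rng.random() < 0.5 else "-"
        gm, cursor = _gene_model(gid, strand, len(cds_nt), introns, cursor, rng)
        gene_models[gid] = gm
        truth.labels[gid] = TruthLabel(cls, signature, introns)

    # clean queries: one of each seeded type; CenH3 query is an anchor
    q_h31 = list(refseq)
    for p, res in zip(SIGNATURE_POSITIONS, H3_1_SIG):
        q_h31[p - 1] = res
    queries = [
        SequenceRecord("query_H3_1", "".join(q_h31), "protein"),
        SequenceRecord("query_H3_3", "".join(refseq), "protein"),
        SequenceRecord(
            "query_CenH3", "".join(_mutate(list(cen_ancestor), spec.cenh3_within_rate, set(), rng)), "protein"
        ),
    ]
    return SyntheticGenome(
        proteome, cds, gene_models, truth, ref, queries, cenh3_anchor_ids=["query_CenH3"]
    )


# ---------------------------------------------------------------------------
# codon evolution


def _codon_moves(kappa: float, omega: float) -> dict[str, list[tuple[str, float]]]:
    ts = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    moves: dict[str, list[tuple[str, float]]] = {}
    for c in SENSE_CODONS:
        out = []
        for k in range(3):
            for b in "ACGT":
                if b == c[k]:
                    continue
                target = c[:k] + b + c[k + 1 :]
                if target in STOP_CODONS:
                    continue
                rate = kappa if (c[k], b) in ts else 1.0
                if _AA[target] != _AA[c]:
                    rate *= omega
                if rate > 0:
                    out.append((target, rate))
        moves[c] = out
    return moves


def evolve_codons(
    ancestor_codons: list[str],
    tree_or_divergence,
    omega: float,
    kappa: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, list[str]]:
    """Evolve an ancestral codon sequence along a tree or a pairwise split.

    Continuous-time simulation: only single-nucleotide changes, rate kappa
    for transitions and 1 for transversions, scaled by omega when
    nonsynonymous, zero into stop codons. The rate matrix is normalized so
    the mean substitution rate per codon site is 1 at the ancestor
    composition, so branch lengths are expected substitutions per codon
    site. A float divergence d is treated as an unrooted two-leaf tree
    ('A', 'B') with d/2 on each branch.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    for c in ancestor_codons:
        if not is_sense(c):
            raise ValueError(f"ancestor codon {c!r} is not a sense codon")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    moves = _codon_moves(kappa, omega)
    exit_rate = {c: sum(r for _, r in moves[c]) for c in SENSE_CODONS}
    mu = float(np.mean([exit_rate[c] for c in ancestor_codons]))
    if mu == 0.0:
        mu = 1.0  # omega = 0 with no synonymous moves anywhere (degenerate)

    def evolve_branch(seq: list[str], t: float) -> list[str]:
        seq = list(seq)
        rates = np.array([exit_rate[c] for c in seq]) / mu
        elapsed = 0.0
        while True:
            total = rates.sum()
            if total <= 0:
                return seq
            elapsed += rng.exponential(1.0 / total)
            if elapsed > t:
                return seq
            i = rng.choice(len(seq), p=rates / total)
            opts = moves[seq[i]]
            weights = np.array([r for _, r in opts]) / exit_rate[seq[i]]
            j = rng.choice(len(opts), p=weights)
            seq[i] = opts[j][0]
            rates[i] = exit_rate[seq[i]] / mu

    if isinstance(tree_or_divergence, (int, float)):
        half = float(tree_or_divergence) / 2.0
        return {"A": evolve_branch(ancestor_codons, half), "B": evolve_branch(ancestor_codons, half)}

    tree = tree_or_divergence
    out: dict[str, list[str]] = {}

    def walk(node, seq):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_seq = evolve_branch(seq, bl)
            if child.is_leaf():
                out[child.taxon.label] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.seed_node, list(ancestor_codons))
    return out


def random_ancestor_codons(n_codons: int, seed: int | np.random.Generator) -> list[str]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]


def random_tree(n_taxa: int, seed: int | np.random.Generator, mean_branch: float = 0.5) -> dendropy.Tree:
    """Random topology by successive pair joins; exponential branch lengths.

    The default mean branch length (0.5 expected substitutions per codon
    site) emulates an anciently diverged gene family sampled across a deep
    species range, giving per-site substitution counts informative for
    counting-based site tests.
    """
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [f"t{i + 1:02d}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.exponential(mean_branch))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    for child in nodes:
        tree.seed_node.add_child(child)
        child.edge.length = float(rng.exponential(mean_branch))
    tree.is_rooted = False
    return tree


def synth_two_clade_alignment(
    seed: int | np.random.Generator,
    n_cols: int = 100,
    n_diagnostic: int = 20,
):
    """Protein alignment with a planted CenH3-like clade for bootstrap tests.

    Two four-taxon clades: the ordinary-H3 clade carries ``n_diagnostic``
    shared diagnostic substitutions; the CenH3 clade has deliberate nested
    structure (synapomorphies for {cen1,cen2,cen3} and {cen2,cen3}) with
    the anchor (``anchor_cenh3``) basal, plus two private substitutions per
    taxon. With the anchor basal, the smallest supported clade containing
    it is the whole CenH3 clade. Returns (alignment, cenh3_leaf_set).
    """
    from .msa_positionmap import Alignment

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aa = list(AA20)

    def mutate(row, cols):
        for c in cols:
            choices = [a for a in aa if a != row[c]]
            row[c] = choices[rng.integers(len(choices))]

    base = rng.choice(aa, size=n_cols)
    cols = rng.permutation(n_cols)
    diag = cols[:n_diagnostic]
    syn3 = cols[n_diagnostic : n_diagnostic + 6]
    syn2 = cols[n_diagnostic + 6 : n_diagnostic + 12]
    priv = cols[n_diagnostic + 12 : n_diagnostic + 28]

    ids, rows = [], []
    h3_base = base.copy()
    mutate(h3_base, diag)
    for k in range(4):
        row = h3_base.copy()
        mutate(row, priv[2 * k : 2 * k + 2])
        ids.append(f"h3_{k}")
        rows.append("".join(row))
    grp3 = base.copy()
    mutate(grp3, syn3)
    grp2 = grp3.copy()
    mutate(grp2, syn2)
    for k, src in enumerate((base, grp3, grp2, grp2)):
        row = src.copy()
        mutate(row, priv[8 + 2 * k : 10 + 2 * k])
        ids.append("anchor_cenh3" if k == 0 else f"cen{k}")
        rows.append("".join(row))
    cen = {"anchor_cenh3", "cen1", "cen2", "cen3"}
    return Alignment(ids, rows), cen


# ---------------------------------------------------------------------------
# expression


def synth_expression(
    plan: ExpressionPlan | SynthesisSpec, seed: int = 0
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Planted-archetype expression matrix and its truth labels.

    Constitutive genes are flat; dividing-high genes gain +delta log2 in
    dividing tissues; heterogeneous genes spike in a single differentiated
    tissue (so they are neither flat nor dividing-high); not-detected genes
    sit below the detection floor. Truth maps gene -> archetype (the spike
    pattern is labelled 'heterogeneous', 'not_detected' genes are excluded
    by preprocessing).
    """
    if isinstance(plan, SynthesisSpec):
        seed = plan.seed if seed == 0 else seed
        plan = plan.expression
    rng = np.random.default_rng(seed)
    tissues = list(plan.tissue_groups)
    div = [i for i, t in enumerate(tissues) if plan.tissue_groups[t] == "dividing"]
    dif = [i for i, t in enumerate(tissues) if plan.tissue_groups[t] == "differentiated"]
    if not div or not dif:
        raise ValueError("expression plan needs both tissue groups")
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth: dict[str, str] = {}
    gnum = 1
    for archetype in ("constitutive", "dividing_high", "heterogeneous", "not_detected"):
        for _ in range(plan.counts.get(archetype, 0)):
            gid = f"e{gnum:03d}"
            gnum += 1
            log2 = np.full(len(tissues), plan.base_log2)
            if archetype == "dividing_high":
                log2[div] += plan.delta
            elif archetype == "heterogeneous":
                spike = dif[rng.integers(len(dif))]
                log2[spike] += plan.delta + 1.0
            if archetype == "not_detected":
                row = rng.uniform(0.0, 0.5 * plan.detection_floor, size=len(tissues))
            else:
                log2 = log2 + rng.normal(0.0, plan.noise_sd, size=len(tissues))
                row = np.power(2.0, log2)
            gene_ids.append(gid)
            rows.append(row)
            truth[gid] = archetype
    return ExpressionMatrix(gene_ids, tissues, np.vstack(rows)), truth
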