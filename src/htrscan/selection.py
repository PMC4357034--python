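"""Selective-pressure analysis of HTR coding sequences.

Global selection is quantified with Nei-Gojobori (1986) counting: fractional
synonymous/nonsynonymous site counts averaged over the two sequences of a
pair, substitution counts averaged over all mutational pathways between
differing codons (pathways through stop codons excluded, weights
renormalized), and a Jukes-Cantor correction of the proportions. Site-wise
selection follows the SLAC counting approach: ancestral codons by Fitch
parsimony on a tree, per-site synonymous/nonsynonymous change counts summed
over branches, and one-sided binomial tests of the synonymous share against
the site's compositional expectation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.special import betainc

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)
_NT = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

GAP_CODON = "---"


def is_sense(codon: str) -> bool:
    return codon in _AA


@dataclass
class CodonAlignment:
    """Aligned coding sequences as rows of codon triplets ('---' = gap)."""

    ids: list[str]
    rows: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        ncols = {len(r) for r in self.rows}
        if len(ncols) > 1:
            raise ValueError("codon rows have unequal lengths")
        for rid, row in zip(self.ids, self.rows):
            for k, codon in enumerate(row):
                if codon == GAP_CODON:
                    continue
                if codon not in _AA:
                    raise ValueError(f"{rid}: codon {codon!r} at site {k} is not a sense codon")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class SiteResult:
    site_index: int
    nd: float
    sd: float
    expected_syn_fraction: float
    p_negative: float
    p_positive: float
    site_class: str  # negative | positive | ns
    q_negative: float = 1.0
    q_positive: float = 1.0


@dataclass
class SelectionResult:
    group: str
    dn: float | None = None
    ds: float | None = None
    ratio: float | None = None  # undefined iff ds == 0
    n_pairs: int = 0
    n_saturated: int = 0
    per_site: list[SiteResult] = field(default_factory=list)


def backtranslate(protein_alignment, cds_map: dict[str, str]) -> CodonAlignment:
    """Expand a gapped protein alignment into its codon alignment.

    Each CDS must translate exactly to its (ungapped) protein row; a single
    terminal stop codon is stripped. Mismatches raise with the sequence id
    and the first differing position.
    """
    rows: list[list[str]] = []
    for sid, row in zip(protein_alignment.seq_ids, protein_alignment.rows):
        cds = _cds_str(cds_map[sid]).upper().replace("U", "T")
        protein = row.replace("-", "")
        if len(cds) == 3 * len(protein) + 3 and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"{sid}: CDS length {len(cds)} does not match protein length {len(protein)} (x3, +/- stop)"
            )
        translated = str(Seq(cds).translate())
        for pos, (a, b) in enumerate(zip(translated, protein), start=1):
            if a != b:
                raise ValueError(
                    f"{sid}: translation mismatch at protein position {pos} ({a!r} != {b!r})"
                )
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        it = iter(codons)
        rows.append([next(it) if c != "-" else GAP_CODON for c in row])
    return CodonAlignment(list(protein_alignment.seq_ids), rows)


def _cds_str(x) -> str:
    return x.seq if hasattr(x, "seq") else str(x)


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """NG86 fractional (synonymous, nonsynonymous) site counts of a codon.

    At each position, each of the three alternative nucleotides counts 1/3
    of a site; a change to a stop codon counts as nonsynonymous, keeping
    s + n = 3 exactly.
    """
    if codon not in _AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0.0
    for k in range(3):
        for b in _NT:
            if b == codon[k]:
                continue
            alt = codon[:k] + b + codon[k + 1 :]
            if alt not in STOP_CODONS and _AA[alt] == _AA[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pathway_changes(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) changes between codons.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are excluded and the remaining pathways
    reweighted uniformly. If every pathway is blocked (possible only for
    rare codon pairs), all pathways are used with steps into or out of a
    stop codon counted as nonsynonymous.
    """
    if codon_a not in _AA or codon_b not in _AA:
        raise ValueError("pathway_changes needs sense codons")
    diff = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = codon_a
        sd = nd = 0.0
        for k in order:
            nxt = cur[:k] + codon_b[k] + cur[k + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                nd += 1.0
            elif _AA[cur] == _AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [r for order in permutations(diff) if (r := walk(order, False)) is not None]
    if not results:
        results = [walk(order, True) for order in permutations(diff)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"saturated: p = {p:.4f} >= 3/4")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(codons_a: list[str], codons_b: list[str]):
    """Nei-Gojobori counts and corrected rates for one sequence pair.

    Returns (Sd, Nd, S_sites, N_sites, dS, dN). Columns gapped in either
    sequence are dropped pairwise. Raises on empty overlap or saturation.
    """
    if len(codons_a) != len(codons_b):
        raise ValueError("codon lists differ in length")
    pairs = [
        (a, b)
        for a, b in zip(codons_a, codons_b)
        if a != GAP_CODON and b != GAP_CODON and "-" not in a and "-" not in b
    ]
    if not pairs:
        raise ValueError("empty overlap: no comparable codons")
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    for a, b in pairs:
        sa, na = codon_site_counts(a)
        sb, nb = codon_site_counts(b)
        s_sites += 0.5 * (sa + sb)
        n_sites += 0.5 * (na + nb)
        psd, pnd = pathway_changes(a, b)
        sd += psd
        nd += pnd
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return sd, nd, s_sites, n_sites, _jukes_cantor(ps), _jukes_cantor(pn)


def group_dnds(ca: CodonAlignment, group: str = "group") -> SelectionResult:
    """Global dN, dS and their ratio for a codon alignment.

    dN and dS are means over all unordered sequence pairs; saturated pairs
    are skipped with a warning and counted. The ratio is undefined (None)
    when dS = 0.
    """
    if len(ca.rows) < 2:
        raise ValueError("group_dnds needs >= 2 sequences")
    dns, dss = [], []
    saturated = 0
    for i, j in combinations(range(len(ca.rows)), 2):
        try:
            _, _, _, _, ds, dn = ng86_pair(ca.rows[i], ca.rows[j])
        except ValueError as exc:
            if "saturated" in str(exc):
                saturated += 1
                continue
            raise
        dns.append(dn)
        dss.append(ds)
    if not dns:
        raise ValueError("all pairs saturated")
    if saturated:
        warnings.warn(f"{group}: {saturated} saturated pair(s) skipped")
    dn = float(np.mean(dns))
    ds = float(np.mean(dss))
    return SelectionResult(
        group=group,
        dn=dn,
        ds=ds,
        ratio=(dn / ds) if ds > 0 else None,
        n_pairs=len(dns),
        n_saturated=saturated,
    )


def _binom_sf_geq(s: float, n: float, p: float) -> float:
    """P(X >= s) for X ~ Binomial(n, p), continuous extension via the
    regularized incomplete beta so fractional pathway-averaged counts are
    handled; exact for integer s, n."""
    if n <= 0 or s <= 0:
        return 1.0
    if s > n:
        return 0.0
    if p <= 0:
        return 0.0 if s > 0 else 1.0
    if p >= 1:
        return 1.0
    return float(betainc(s, n - s + 1.0, p)) if s < n else float(p**n)


def _binom_cdf_leq(s: float, n: float, p: float) -> float:
    """P(X <= s), continuous extension (see _binom_sf_geq)."""
    if n <= 0 or s >= n:
        return 1.0
    if s < 0:
        return 0.0
    if p >= 1:
        return 0.0 if s < n else 1.0
    if p <= 0:
        return 1.0
    return float(betainc(n - s, s + 1.0, 1.0 - p)) if s > 0 else float((1.0 - p) ** n)


def _fitch_site(tree, leaf_codons: dict[str, str | None]) -> list[tuple[str, str]]:
    """Parsimony codon assignment for one site; returns (parent, child)
    codon pairs for every branch whose endpoints are both assigned.

    Leaves with a gap are wildcards (None state set). Ties in the Fitch
    sets are resolved by codon lexicographic order.
    """
    down: dict[int, frozenset | None] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            codon = leaf_codons[node.taxon.label]
            down[id(node)] = frozenset([codon]) if codon is not None else None
        else:
            sets = [down[id(c)] for c in node.child_nodes()]
            concrete = [s for s in sets if s is not None]
            if not concrete:
                down[id(node)] = None
                continue
            inter = frozenset.intersection(*concrete)
            down[id(node)] = inter if inter else frozenset.union(*concrete)

    changes: list[tuple[str, str]] = []
    assign: dict[int, str | None] = {}
    for node in tree.preorder_node_iter():
        sset = down[id(node)]
        if node.parent_node is None:
            assign[id(node)] = min(sset) if sset else None
            continue
        parent_codon = assign[id(node.parent_node)]
        if sset is None:
            assign[id(node)] = parent_codon
            continue
        if parent_codon is not None and parent_codon in sset:
            assign[id(node)] = parent_codon
        else:
            assign[id(node)] = min(sset)
        child_codon = assign[id(node)]
        if parent_codon is not None and child_codon is not None and parent_codon != child_codon:
            changes.append((parent_codon, child_codon))
    return changes


def site_selection(
    ca: CodonAlignment, tree, alpha: float = 0.05, group: str = "group"
) -> SelectionResult:
    """SLAC-style per-site selection calls.

    Per site: ancestral codons by Fitch parsimony, Nd/Sd summed over
    branches via pathway averaging, expected synonymous fraction from the
    site's observed codons, and two one-sided binomial tests. Raw p-values
    drive the call (negative if p_negative < alpha, else positive if
    p_positive < alpha); Benjamini-Hochberg q-values are reported alongside.
    """
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_names != set(ca.ids):
        raise ValueError("tree leaves do not match alignment ids")
    row_of = dict(zip(ca.ids, ca.rows))
    sites: list[SiteResult] = []
    for k in range(ca.column_count):
        leaf_codons = {
            name: (row_of[name][k] if row_of[name][k] != GAP_CODON else None)
            for name in ca.ids
        }
        observed = sorted({c for c in leaf_codons.values() if c is not None})
        if not observed:
            sites.append(SiteResult(k, 0.0, 0.0, 0.0, 1.0, 1.0, "ns"))
            continue
        s_site = float(np.mean([codon_site_counts(c)[0] for c in observed]))
        frac = s_site / 3.0
        sd = nd = 0.0
        for pa, ch in _fitch_site(tree, leaf_codons):
            psd, pnd = pathway_changes(pa, ch)
            sd += psd
            nd += pnd
        total = sd + nd
        if total == 0:
            sites.append(SiteResult(k, 0.0, 0.0, frac, 1.0, 1.0, "ns"))
            continue
        p_neg = _binom_sf_geq(sd, total, frac)
        p_pos = _binom_cdf_leq(sd, total, frac)
        if p_neg < alpha:
            cls = "negative"
        elif p_pos < alpha:
            cls = "positive"
        else:
            cls = "ns"
        sites.append(SiteResult(k, nd, sd, frac, p_neg, p_pos, cls))

    _attach_qvalues(sites)
    return SelectionResult(group=group, per_site=sites)


def _attach_qvalues(sites: list[SiteResult]) -> None:
    from statsmodels.stats.multitest import multipletests

    variable = [s for s in sites if (s.sd + s.nd) > 0]
    if not variable:
        return
    for attr, qattr in (("p_negative", "q_negative"), ("p_positive", "q_positive")):
        _, qvals, _, _ = multipletests([getattr(s, attr) for s in variable], method="fdr_bh")
        for s, q in zip(variable, qvals):
            setattr(s, qattr, float(q))
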