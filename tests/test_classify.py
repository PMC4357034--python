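import dendropy
import numpy as np
import pytest

from htrscan.classify import (
    ANIMAL_RULES,
    PLANT_RULES,
    CenH3Params,
    SignatureProfile,
    audit_lysines,
    classify_variant,
    detect_cenh3,
    extract_signature,
)
from htrscan.msa_positionmap import map_to_reference
from htrscan.synthetic_data import make_reference

AA = "ACDEFGHIKLMNPQRSTVWY"


def _sig(residues, **kw):
    return SignatureProfile((31, 41, 87, 90), tuple(residues), **kw)


H3_1 = ("A", "F", "S", "A")
H3_3 = ("T", "Y", "H", "L")
H3_1A_S = ("A", "Y", "S", "L")
H3_1A_Q = ("A", "Y", "Q", "L")


def _perturbed_signatures(n=20, seed=123):
    """Signature tuples matching none of the plant classes."""
    rng = np.random.default_rng(seed)
    known = {H3_1, H3_3, H3_1A_S, H3_1A_Q}
    out = []
    while len(out) < n:
        cand = tuple(rng.choice(list(AA), size=4))
        if cand not in known:
            out.append(cand)
    return out


class TestDecisionTable:
    def test_table_total_deterministic_and_consistent(self):
        """Every (signature, introns, cenh3-evidence) combination yields
        exactly one class; conflicts land in H3-like; CenH3 evidence wins."""
        signatures = [H3_1, H3_3, H3_1A_S, H3_1A_Q] + _perturbed_signatures()
        for residues in signatures:
            for introns in (0, 1, None):
                for evidence in (set(), {"cenh3_tail"}, {"cenh3_clade"}):
                    call = classify_variant(_sig(residues), introns, evidence)
                    repeat = classify_variant(_sig(residues), introns, set(evidence))
                    assert call.variant_class == repeat.variant_class
                    assert call.variant_class in ("CENH3", "H3_1", "H3_1A", "H3_3", "H3_LIKE")
                    if evidence:
                        assert call.variant_class == "CENH3"
                    if "signature_intron_conflict" in call.evidence:
                        assert call.variant_class == "H3_LIKE"

    @pytest.mark.parametrize(
        "residues,introns,expected,confidence",
        [
            (H3_3, 1, "H3_3", "high"),
            (H3_3, 2, "H3_3", "high"),
            (H3_1, 0, "H3_1", "high"),
            (H3_1A_S, 0, "H3_1A", "high"),
            (H3_1A_Q, 0, "H3_1A", "high"),
            (H3_3, None, "H3_3", "medium"),
            (H3_1, None, "H3_1", "medium"),
            (("G", "G", "G", "G"), 1, "H3_LIKE", "low"),
        ],
    )
    def test_expected_assignments(self, residues, introns, expected, confidence):
        call = classify_variant(_sig(residues), introns)
        assert call.variant_class == expected
        assert call.confidence == confidence
        if introns is None and expected != "H3_LIKE":
            assert "signature_only" in call.evidence

    @pytest.mark.parametrize(
        "residues,introns",
        [(H3_3, 0), (H3_1, 1), (H3_1A_S, 2)],
    )
    def test_signature_intron_conflicts_fall_to_h3_like(self, residues, introns):
        call = classify_variant(_sig(residues), introns)
        assert call.variant_class == "H3_LIKE"
        assert "signature_intron_conflict" in call.evidence

    def test_cenh3_evidence_overrides_clean_signature(self):
        call = classify_variant(_sig(H3_1), 0, {"cenh3_tail", "cenh3_clade"})
        assert call.variant_class == "CENH3"
        assert call.confidence == "high"

    def test_animal_rule_set(self):
        sig = SignatureProfile((31, 87, 89, 90), ("A", "S", "V", "M"))
        assert classify_variant(sig, 0, rules=ANIMAL_RULES).variant_class == "H3_1"
        sig33 = SignatureProfile((31, 87, 89, 90), ("S", "A", "I", "G"))
        assert classify_variant(sig33, 1, rules=ANIMAL_RULES).variant_class == "H3_3"


class TestExtractSignature:
    def test_clean_h3_1_profile(self):
        ref = make_reference(42)
        cand = list(ref.seq)
        for p, r in zip((31, 41, 87, 90), H3_1):
            cand[p - 1] = r
        pmap = map_to_reference("".join(cand), ref)
        sig = extract_signature(pmap)
        assert sig.residues == H3_1
        assert (sig.k4, sig.k9, sig.k27, sig.k36) == ("K",) * 4
        assert not sig.tail_deleted

    def test_k27m_recorded(self):
        ref = make_reference(42)
        cand = list(ref.seq)
        cand[27 - 1] = "M"
        sig = extract_signature(map_to_reference("".join(cand), ref))
        assert sig.k27 == "M"

    def test_truncated_tail_gaps_and_flag(self):
        ref = make_reference(42)
        sig = extract_signature(map_to_reference(ref.seq[44:], ref))
        assert (sig.k4, sig.k9, sig.k27) == ("-",) * 3
        assert sig.tail_deleted


class TestDetectCenh3:
    def test_tail_heuristic_fires_on_divergent_extended_candidate(self):
        ref = make_reference(10)
        rng = np.random.default_rng(0)
        core = list(ref.seq)
        for i in rng.choice(np.arange(44, len(core)), size=36, replace=False):
            core[i] = "W" if core[i] != "W" else "Y"
        tail = "".join(rng.choice(list(AA), size=25))
        pmap = map_to_reference(tail + "".join(core), ref)
        assert pmap.n_terminal_overhang >= 15
        flags = detect_cenh3(pmap, tree=None, anchors=["a"])
        assert flags == {"cenh3_tail"}

    def test_clade_evidence_from_supported_tree(self):
        ref = make_reference(10)
        nwk = "((cand:0.1,anchor:0.1)98:0.3,(h1:0.1,h2:0.1)99:0.3,h3:0.4);"
        tree = dendropy.Tree.get(data=nwk, schema="newick", suppress_internal_node_taxa=True)
        pmap = map_to_reference(ref.seq, ref)
        pmap.candidate_id = "cand"
        flags = detect_cenh3(
            pmap, tree=tree, anchors=["anchor"], known_non_cenh3={"h1", "h2", "h3"}
        )
        assert flags == {"cenh3_clade"}

    def test_ordinary_h3_gets_no_flags(self):
        ref = make_reference(10)
        pmap = map_to_reference(ref.seq, ref)
        assert detect_cenh3(pmap, tree=None, anchors=["a"]) == set()

    def test_low_support_clade_not_flagged(self):
        ref = make_reference(10)
        nwk = "((cand:0.1,anchor:0.1)50:0.3,(h1:0.1,h2:0.1)99:0.3,h3:0.4);"
        tree = dendropy.Tree.get(data=nwk, schema="newick", suppress_internal_node_taxa=True)
        pmap = map_to_reference(ref.seq, ref)
        pmap.candidate_id = "cand"
        assert detect_cenh3(pmap, tree=tree, anchors=["anchor"], params=CenH3Params()) == set()


class TestAuditLysines:
    def test_clean_set_fully_conserved(self):
        calls = [
            classify_variant(_sig(H3_1, k4="K", k9="K", k27="K", k36="K"), 0, gene_id=f"g{i}")
            for i in range(3)
        ]
        table = audit_lysines(calls)
        row = table[table["class"] == "H3_1"].iloc[0]
        assert all(row[f"k{p}_fraction"] == 1.0 for p in (4, 9, 27, 36))
        assert row["substitutions"] == "."

    def test_planted_k27m_listed(self):
        good = classify_variant(_sig(H3_3, k27="K"), 1, gene_id="g1")
        mutant = classify_variant(_sig(("G", "G", "G", "G"), k27="M"), 0, gene_id="g2")
        table = audit_lysines([good, mutant])
        row = table[table["class"] == "H3_LIKE"].iloc[0]
        assert "g2:K27M" in row["substitutions"]
        assert row["k27_fraction"] == 0.0

    def test_empty_calls_give_empty_table(self):
        assert audit_lysines([]).empty


def test_classification_invariant_to_candidate_order(genome42):
    from htrscan import homology_scan as hs

    g = genome42
    cands = hs.filter_candidates(hs.scan_proteome(g.proteome, g.queries, g.gene_models, g.cds))
    kept = [c for c in cands if c.filter_status == "kept"]

    def classes(order):
        out = {}
        for c in order:
            pmap = map_to_reference(c.protein, g.reference)
            sig = extract_signature(pmap)
            ev = detect_cenh3(pmap, tree=None, anchors=["query_CenH3"])
            out[c.gene_id] = classify_variant(
                sig, g.gene_models[c.gene_id].representative_intron_count, ev
            ).variant_class
        return out

    assert classes(kept) == classes(list(reversed(kept)))
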