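import numpy as np
import pytest

from htrscan.msa_positionmap import Alignment
from htrscan.selection import (
    CodonAlignment,
    SENSE_CODONS,
    _binom_cdf_leq,
    _binom_sf_geq,
    backtranslate,
    codon_site_counts,
    group_dnds,
    ng86_pair,
    pathway_changes,
    site_selection,
)
from htrscan.synthetic_data import evolve_codons, random_ancestor_codons, random_tree
from oracles import (
    binom_tail_geq,
    binom_tail_leq,
    ng86_changes_oracle,
    ng86_pair_oracle,
    ng86_sites_oracle,
)


def _codons(s):
    return [s[i : i + 3] for i in range(0, len(s), 3)]


class TestBacktranslate:
    def test_identical_cds_pair_chunks_into_triplets(self):
        aln = Alignment(["a", "b"], ["MKV", "MKV"])
        cds = {"a": "ATGAAAGTT", "b": "ATGAAAGTT"}
        ca = backtranslate(aln, cds)
        assert ca.rows == [["ATG", "AAA", "GTT"]] * 2

    def test_terminal_stop_stripped(self):
        aln = Alignment(["a", "b"], ["MKV", "MKV"])
        ca = backtranslate(aln, {"a": "ATGAAAGTTTAA", "b": "ATGAAAGTT"})
        assert ca.rows[0] == ["ATG", "AAA", "GTT"]

    def test_gap_becomes_triple_gap(self):
        aln = Alignment(["a", "b"], ["MKV", "M-V"])
        ca = backtranslate(aln, {"a": "ATGAAAGTT", "b": "ATGGTT"})
        assert ca.rows[1] == ["ATG", "---", "GTT"]

    def test_translation_mismatch_names_sequence_and_position(self):
        aln = Alignment(["a"], ["MKV"])
        with pytest.raises(ValueError, match="a.*position 2"):
            backtranslate(aln, {"a": "ATGCCCGTT"})  # CCC = Pro, not Lys

    def test_length_mismatch_rejected(self):
        aln = Alignment(["a"], ["MKV"])
        with pytest.raises(ValueError, match="length"):
            backtranslate(aln, {"a": "ATGAAA"})


class TestNg86Pair:
    def test_identical_sequences_have_zero_counts(self):
        row = _codons("ATGAAAGTT")
        sd, nd, s, n, ds, dn = ng86_pair(row, row)
        assert (sd, nd, ds, dn) == (0.0, 0.0, 0.0, 0.0)

    def test_synonymous_single_change(self):
        assert pathway_changes("TTT", "TTC") == (1.0, 0.0)  # Phe -> Phe
        pad = ["GGG"] * 9
        sd, nd, *_ = ng86_pair(pad + ["TTT"], pad + ["TTC"])
        assert (sd, nd) == (1.0, 0.0)

    def test_nonsynonymous_single_change(self):
        assert pathway_changes("TTT", "TAT") == (0.0, 1.0)  # Phe -> Tyr
        pad = ["GGG"] * 9
        sd, nd, *_ = ng86_pair(pad + ["TTT"], pad + ["TAT"])
        assert (sd, nd) == (0.0, 1.0)

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(12)
        a = random_ancestor_codons(50, rng)
        b = evolve_codons(a, 0.4, 0.5, 1.0, rng)["A"]
        _, _, s, n, _, _ = ng86_pair(a, b)
        assert s + n == pytest.approx(150.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        a = random_ancestor_codons(30, rng)
        b = evolve_codons(a, 0.4, 0.5, 1.0, rng)["A"]
        assert ng86_pair(a, b) == ng86_pair(b, a)

    def test_random_pairs_match_pathway_enumeration_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(120):
            a = random_ancestor_codons(20, rng)
            b = evolve_codons(a, 0.5, 0.7, 2.0, rng)["A"]
            sd, nd, s, n, _, _ = ng86_pair(a, b)
            osd, ond, os_, on_ = ng86_pair_oracle(a, b)
            assert sd == pytest.approx(osd, abs=1e-9)
            assert nd == pytest.approx(ond, abs=1e-9)
            assert s == pytest.approx(os_, abs=1e-9)
            assert n == pytest.approx(on_, abs=1e-9)

    def test_every_codon_pair_change_counts_match_oracle(self):
        for a in SENSE_CODONS[::7]:
            for b in SENSE_CODONS[::5]:
                assert pathway_changes(a, b) == pytest.approx(ng86_changes_oracle(a, b), abs=1e-12)
            assert codon_site_counts(a)[0] == pytest.approx(ng86_sites_oracle(a), abs=1e-12)

    def test_saturation_rejected(self):
        a = ["AAA"] * 5
        b = ["GGG"] * 5
        with pytest.raises(ValueError, match="saturated"):
            ng86_pair(a, b)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ng86_pair(["---"], ["ATG"])


class TestGroupDnds:
    def test_identical_pair_ratio_undefined(self):
        row = _codons("ATGAAAGTTCCA")
        res = group_dnds(CodonAlignment(["a", "b"], [row, list(row)]))
        assert res.dn == 0.0 and res.ds == 0.0
        assert res.ratio is None

    def test_omega_point_two_pair_recovered(self):
        """A 200-codon pair at divergence 0.3, omega = 0.2, seed 5."""
        rng = np.random.default_rng(5)
        anc = random_ancestor_codons(200, rng)
        leaves = evolve_codons(anc, 0.3, 0.2, 1.0, rng)
        res = group_dnds(CodonAlignment(["A", "B"], [leaves["A"], leaves["B"]]))
        assert 0.12 < res.ratio < 0.28

    def test_neutral_pair_near_one(self):
        rng = np.random.default_rng(6)
        ratios = []
        for _ in range(20):
            anc = random_ancestor_codons(200, rng)
            leaves = evolve_codons(anc, 0.3, 1.0, 1.0, rng)
            ratios.append(group_dnds(CodonAlignment(["A", "B"], [leaves["A"], leaves["B"]])).ratio)
        assert 0.8 < np.mean(ratios) < 1.25


class TestBinomialTails:
    def test_matches_exact_binomial_on_integers(self):
        for n in (1, 4, 6, 11):
            for k in range(n + 1):
                for p in (0.1, 0.25, 0.5, 0.8):
                    assert _binom_sf_geq(k, n, p) == pytest.approx(binom_tail_geq(k, n, p), abs=1e-12)
                    assert _binom_cdf_leq(k, n, p) == pytest.approx(binom_tail_leq(k, n, p), abs=1e-12)

    def test_all_synonymous_site_example(self):
        # 6 changes, all synonymous, expected synonymous fraction 0.25
        assert _binom_sf_geq(6.0, 6.0, 0.25) == pytest.approx(0.25**6, abs=1e-15)


class TestSiteSelection:
    def test_invariant_sites_not_significant(self):
        rng = np.random.default_rng(1)
        tree = random_tree(5, rng, mean_branch=0.1)
        row = _codons("ATGAAAGTT")
        ca = CodonAlignment(
            [f"t{i + 1:02d}" for i in range(5)], [list(row) for _ in range(5)]
        )
        res = site_selection(ca, tree)
        assert all(s.site_class == "ns" and s.p_negative == 1.0 for s in res.per_site)

    def test_leaf_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        tree = random_tree(4, rng)
        ca = CodonAlignment(["x1", "x2", "x3", "x4"], [[c] for c in ("ATG",) * 4])
        with pytest.raises(ValueError, match="leaves"):
            site_selection(ca, tree)

    def test_strong_purifying_simulation_flags_negative_sites(self):
        rng = np.random.default_rng(9)
        tree = random_tree(10, rng)
        anc = random_ancestor_codons(135, rng)
        leaves = evolve_codons(anc, tree, 0.05, 1.0, rng)
        ca = CodonAlignment(list(leaves), [leaves[k] for k in leaves])
        res = site_selection(ca, tree, alpha=0.05)
        variable = [s for s in res.per_site if s.sd + s.nd > 0]
        negative = [s for s in variable if s.site_class == "negative"]
        assert len(negative) / len(variable) > 0.5
        # q-values attached and in range
        assert all(0 <= s.q_negative <= 1 for s in variable)

    def test_fitch_deterministic(self):
        rng = np.random.default_rng(14)
        tree = random_tree(6, rng, mean_branch=0.3)
        anc = random_ancestor_codons(40, rng)
        leaves = evolve_codons(anc, tree, 0.5, 1.0, rng)
        ca = CodonAlignment(list(leaves), [leaves[k] for k in leaves])
        r1 = site_selection(ca, tree)
        r2 = site_selection(ca, tree)
        assert [(s.sd, s.nd, s.p_negative) for s in r1.per_site] == [
            (s.sd, s.nd, s.p_negative) for s in r2.per_site
        ]
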