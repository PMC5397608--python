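import numpy as np
import pytest

from solubis.annotation import AntibodyChain, annotate_chain, net_charge
from solubis.design import (GATEKEEPERS, MutationCandidate, apply_mutations,
                            compose_variant, mass_scan, select_mass_candidates,
                            supercharge_scan)
from solubis.fixtures import make_toy_fv
from solubis.io import MutationSpec
from solubis.profile import APR, detect_aprs, propensity_profile
from solubis.scoring import Antibody, score_antibody


def _antibody(fx):
    return Antibody("toy", {"H": annotate_chain(fx.heavy, "H"),
                            "L": annotate_chain(fx.light, "L")})


def _detected_apr(fx):
    aprs = detect_aprs(propensity_profile(fx.light), fx.light)
    assert len(aprs) == 1
    return aprs[0]


class TestMassScan:
    @pytest.mark.parametrize("apr_length,expected", [(6, 30), (11, 55), (13, 65)])
    def test_candidate_counts_without_gatekeepers(self, apr_length, expected):
        fx = make_toy_fv(1, apr_in_cdr=False, apr_length=apr_length)
        ab = _antibody(fx)
        apr = _detected_apr(fx)
        assert not any(aa in GATEKEEPERS for aa in apr.sequence)
        cands = mass_scan(ab, "L", apr)
        assert len(cands) == expected

    def test_identity_skip_when_wild_type_is_gatekeeper(self):
        fx = make_toy_fv(1, apr_in_cdr=False, apr_length=6)
        ab = _antibody(fx)
        a, _ = fx.apr_interval
        # hand-built APR interval that includes the planted Asp flank
        seq = fx.light[a - 2 : a + 3]
        assert seq[0] == "D"
        apr = APR(a - 1, a + 3, seq, 0.0)
        cands = mass_scan(ab, "L", apr)
        assert len(cands) == 5 * 5 - 1

    def test_count_formula_property(self):
        for seed, length in [(2, 7), (3, 9)]:
            fx = make_toy_fv(seed, apr_in_cdr=False, apr_length=length)
            apr = _detected_apr(fx)
            n_gk = sum(aa in GATEKEEPERS for aa in apr.sequence)
            assert len(mass_scan(_antibody(fx), "L", apr)) == 5 * len(apr) - n_gk

    def test_sorted_most_suppressing_first(self):
        fx = make_toy_fv(1, apr_in_cdr=True)
        cands = mass_scan(_antibody(fx), "L", _detected_apr(fx))
        d = [c.d_tango for c in cands]
        assert d == sorted(d)
        assert all(c.d_tango <= 0 for c in cands)

    def test_empty_apr_rejected(self):
        fx = make_toy_fv(1, True)
        with pytest.raises(ValueError):
            mass_scan(_antibody(fx), "L", APR(10, 9, "", 0.0))


class TestSelect:
    def _cand(self, d_tango, ddg, pos=1, mut="D"):
        return MutationCandidate(MutationSpec("I", "L", pos, "", mut),
                                 d_tango, ddg, 0, "mass_scan")

    def test_stability_filter(self):
        cands = [self._cand(-90.0, 2.0), self._cand(-60.0, 0.2)]
        kept = select_mass_candidates(cands, max_ddg=0.5)
        assert len(kept) == 1 and kept[0].d_tango == -60.0

    def test_tie_broken_by_ddg(self):
        cands = [self._cand(-50.0, 0.4, mut="K"), self._cand(-50.0, 0.1, mut="E")]
        kept = select_mass_candidates(cands)
        assert kept[0].mutation.mutant == "E"

    def test_top_n(self):
        cands = [self._cand(-float(i), 0.0, pos=i) for i in range(1, 56)]
        assert len(select_mass_candidates(cands, top_n=2)) == 2

    def test_all_filtered_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="max_ddg"):
            assert select_mass_candidates([self._cand(-10, 3.0)]) == []

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_mass_candidates([])


class TestSupercharge:
    def test_toy_framework_segment_enumeration(self):
        chain = AntibodyChain("H", "ASD", [(i + 1, "") for i in range(3)], ["FR1"] * 3)
        cands = supercharge_scan(Antibody("t", {"H": chain}))
        got = {(c.mutation.wild_type, c.mutation.mutant) for c in cands}
        assert got == {("A", "K"), ("A", "R"), ("S", "K"), ("S", "R"),
                       ("D", "K"), ("D", "R"), ("D", "N"), ("D", "Q")}

    def test_cdr_positions_excluded(self, toy_cdr_fixture):
        ab = _antibody(toy_cdr_fixture)
        chain = ab.chains["H"]
        cdr_positions = {chain.numbering[i] for i, r in enumerate(chain.regions)
                         if r.startswith("CDR")}
        cands = supercharge_scan(ab)
        assert all((c.mutation.position, c.mutation.icode) not in cdr_positions
                   for c in cands)

    def test_all_lysine_segment_yields_nothing(self):
        chain = AntibodyChain("H", "KKKKK", [(i + 1, "") for i in range(5)], ["FR1"] * 5)
        assert supercharge_scan(Antibody("t", {"H": chain})) == []

    def test_every_candidate_increases_fr_net_charge(self, toy_cdr_fixture):
        ab = _antibody(toy_cdr_fixture)
        before = net_charge(ab.chains["H"], "fr").value
        for cand in supercharge_scan(ab)[:20]:
            mutated = apply_mutations(ab, [cand.mutation])
            after = net_charge(mutated.chains["H"], "fr").value
            assert after - before == cand.d_charge >= 1


class TestComposeVariant:
    def test_empty_mutation_list_is_identity(self, toy_cdr_fixture):
        ab = _antibody(toy_cdr_fixture)
        wt = score_antibody(ab)
        var = compose_variant(ab, [])
        assert var.report.solubis_score == wt.solubis_score
        assert var.d_charge == 0

    def test_gatekeeper_mutation_lowers_score(self, toy_cdr_fixture):
        fx = toy_cdr_fixture
        ab = _antibody(fx)
        wt = score_antibody(ab)
        apr = _detected_apr(fx)
        site = (apr.start + apr.end) // 2
        num, icode = ab.chains["L"].numbering[site - 1]
        mut = MutationSpec(fx.light[site - 1], "L", num, icode, "D")
        var = compose_variant(ab, [mut])
        assert var.report.solubis_score < wt.solubis_score

    def test_order_independent(self, toy_cdr_fixture):
        fx = toy_cdr_fixture
        ab = _antibody(fx)
        apr = _detected_apr(fx)
        m1 = MutationSpec(fx.light[apr.start - 1], "L", *ab.chains["L"].numbering[apr.start - 1], "P")
        m2 = MutationSpec(fx.light[apr.end - 1], "L", *ab.chains["L"].numbering[apr.end - 1], "K")
        a = compose_variant(ab, [m1, m2])
        b = compose_variant(ab, [m2, m1])
        assert a.report.solubis_score == b.report.solubis_score
        assert a.report.antibody == b.report.antibody

    def test_wild_type_mismatch_names_position(self, toy_cdr_fixture):
        ab = _antibody(toy_cdr_fixture)
        seq = ab.chains["L"].sequence
        wrong = "W" if seq[49] != "W" else "Y"
        with pytest.raises(ValueError, match="mismatch at L50"):
            compose_variant(ab, [MutationSpec(wrong, "L", *ab.chains["L"].numbering[49], "K")])

    def test_duplicate_position_rejected(self, toy_cdr_fixture):
        ab = _antibody(toy_cdr_fixture)
        num, icode = ab.chains["L"].numbering[0]
        wt = ab.chains["L"].sequence[0]
        muts = [MutationSpec(wt, "L", num, icode, "K"),
                MutationSpec(wt, "L", num, icode, "R")]
        with pytest.raises(ValueError, match="duplicated"):
            compose_variant(ab, muts)
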