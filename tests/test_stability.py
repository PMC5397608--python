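import numpy as np
import pytest

from solubis._scales import HYDRO_NORM, MAX_ASA
from solubis.io import read_pdb_chains
from solubis.profile import APR, detect_aprs, propensity_profile
from solubis.scoring import Antibody, score_antibody
from solubis.annotation import annotate_chain
from solubis.stability import (DEFAULT_STABILITY_PARAMS, StabilityProfile,
                               apr_dg_contrib, ddg_of_mutation,
                               relative_accessibility, stability_profile)

# Shrake-Rupley radii used by the implementation (Biopython defaults)
_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def brute_force_sasa(structure, chain_id, n_points=2000, probe=1.4):
    """Independent SASA oracle: dense golden-spiral sampling per atom."""
    atoms = []
    for chain in structure.chains.values():
        for res in chain.residues:
            for a in res.atoms:
                atoms.append((a.coord, _RADII.get(a.element, 1.7)))
    coords = np.array([c for c, _ in atoms])
    radii = np.array([r for _, r in atoms]) + probe
    k = np.arange(n_points)
    phi = np.arccos(1 - 2 * (k + 0.5) / n_points)
    theta = np.pi * (1 + 5**0.5) * k
    sphere = np.stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
                       np.cos(phi)], axis=1)
    per_atom = {}
    for idx in range(len(atoms)):
        pts = coords[idx] + radii[idx] * sphere
        free = np.ones(n_points, dtype=bool)
        for jdx in range(len(atoms)):
            if jdx == idx:
                continue
            d2 = np.sum((pts - coords[jdx]) ** 2, axis=1)
            free &= d2 > radii[jdx] ** 2
        per_atom[idx] = 4 * np.pi * radii[idx] ** 2 * free.mean()
    out = []
    i = 0
    for cid, chain in structure.chains.items():
        for res in chain.residues:
            area = sum(per_atom[i + j] for j in range(len(res.atoms)))
            i += len(res.atoms)
            if cid == chain_id:
                out.append(min(1.0, area / MAX_ASA.get(res.aa, 197.0)))
    return np.array(out)


def _straight_chain_pdb(sequence):
    from solubis.fixtures import _backbone_atoms, _pdb_line
    lines, serial = [], 1
    for i, aa in enumerate(sequence):
        from solubis._scales import ONE_TO_THREE
        for name, elem, xyz in _backbone_atoms(i, 0.0):
            lines.append(_pdb_line(serial, name, ONE_TO_THREE[aa], "A", i + 1, xyz, elem))
            serial += 1
    return "\n".join(lines) + "\nEND\n"


class TestRelativeAccessibility:
    def test_isolated_residue_fully_exposed(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(_straight_chain_pdb("G"))
        st = read_pdb_chains(p)
        assert relative_accessibility(st, "A")[0] == pytest.approx(1.0)

    def test_buried_fixture_residues_occluded(self, toy_cdr_fixture, toy_structures):
        _, st, _ = toy_structures["buried"]
        a, b = toy_cdr_fixture.apr_interval
        rsa = relative_accessibility(st, "L")[a - 1 : b]
        assert np.all(rsa < 0.25)

    def test_deterministic(self, toy_structures):
        _, st, _ = toy_structures["exposed"]
        assert np.array_equal(relative_accessibility(st, "L"),
                              relative_accessibility(st, "L"))

    def test_agrees_with_dense_sampling_oracle(self, tmp_path):
        p = tmp_path / "ten.pdb"
        p.write_text(_straight_chain_pdb("IVIVGSTQLM"))
        st = read_pdb_chains(p)
        rsa = relative_accessibility(st, "A")
        oracle = brute_force_sasa(st, "A")
        assert np.all(np.abs(rsa - oracle) < 0.05)


class TestStabilityProfile:
    def test_exposed_unbonded_residues_near_zero(self, tmp_path):
        p = tmp_path / "g.pdb"
        p.write_text(_straight_chain_pdb("G"))
        st = read_pdb_chains(p)
        prof = stability_profile(st, "A")
        assert prof.delta_g[0] == pytest.approx(0.0)

    def test_buried_apr_energy_matches_term_arithmetic(self, toy_cdr_fixture, toy_structures):
        """ΔG_i = -(alpha*(1-RSA)*H + beta*HB) with no clashes in the fixture."""
        _, st, _ = toy_structures["buried"]
        prof = stability_profile(st, "L")
        a, b = toy_cdr_fixture.apr_interval
        params = DEFAULT_STABILITY_PARAMS
        for i in range(a - 1, b):
            aa = st["L"].residues[i].aa
            hb = prof.hb_backbone[i] + prof.hb_sidechain[i]
            assert hb == 2  # construction plants two partners per APR residue
            expected = -(params.alpha * (1 - prof.rsa[i]) * HYDRO_NORM[aa]
                         + params.beta * hb)
            assert prof.delta_g[i] == pytest.approx(expected)

    def test_no_clashes_in_fixture_geometry(self, toy_structures):
        for key in ("buried", "exposed"):
            _, st, _ = toy_structures[key]
            prof = stability_profile(st, "L")
            # all contributions stabilising or zero: the kappa term never fires
            assert np.all(prof.delta_g <= 1e-9)

    def test_burial_monotonicity_for_hydrophobics(self, toy_cdr_fixture, toy_structures):
        """Burying a hydrophobic APR makes its ΔG strictly more stabilising."""
        _, buried, _ = toy_structures["buried"]
        _, exposed, _ = toy_structures["exposed"]
        a, b = toy_cdr_fixture.apr_interval
        dg_b = stability_profile(buried, "L").delta_g[a - 1 : b]
        dg_e = stability_profile(exposed, "L").delta_g[a - 1 : b]
        assert np.all(dg_b < dg_e)


class TestAprDgContrib:
    def test_uniform_values(self):
        prof = StabilityProfile(np.full(10, -1.0), "external_table")
        assert apr_dg_contrib(prof, APR(3, 7, "IIIII", 100)).dg_contrib == -5.0

    def test_mixed_values(self):
        prof = StabilityProfile(np.array([0, -2, 0, 1, -1, 0, 0]), "external_table")
        assert apr_dg_contrib(prof, APR(2, 6, "AAAAA", 0)).dg_contrib == -2.0

    def test_linearity_over_subintervals(self):
        rng = np.random.default_rng(2)
        prof = StabilityProfile(rng.normal(size=30), "surrogate")
        whole = apr_dg_contrib(prof, APR(5, 20, "", 0)).dg_contrib
        left = apr_dg_contrib(prof, APR(5, 12, "", 0)).dg_contrib
        right = apr_dg_contrib(prof, APR(13, 20, "", 0)).dg_contrib
        assert whole == pytest.approx(left + right)

    def test_interval_outside_profile_rejected(self):
        prof = StabilityProfile(np.zeros(5), "surrogate")
        with pytest.raises(ValueError):
            apr_dg_contrib(prof, APR(3, 9, "", 0))


class TestDdg:
    def test_exposed_residue_identity_independent(self, tmp_path):
        p = tmp_path / "s.pdb"
        p.write_text(_straight_chain_pdb("S"))
        st = read_pdb_chains(p)
        assert ddg_of_mutation(st, "A", 1, "R") == pytest.approx(0.0)

    def test_buried_hydrophobic_to_charged_destabilises(self, toy_cdr_fixture, toy_structures):
        _, st, _ = toy_structures["buried"]
        a, _ = toy_cdr_fixture.apr_interval
        prof = stability_profile(st, "L")
        aa = st["L"].residues[a - 1].aa
        ddg = ddg_of_mutation(st, "L", a, "D", _profile=prof)
        expected = DEFAULT_STABILITY_PARAMS.alpha * (1 - prof.rsa[a - 1]) * (
            HYDRO_NORM[aa] - HYDRO_NORM["D"])
        assert ddg == pytest.approx(expected) and ddg > 0

    def test_polar_to_apolar_loses_sidechain_bonds(self, toy_structures):
        _, st, _ = toy_structures["exposed"]
        idx = next(i for i, r in enumerate(st["L"].residues) if r.aa == "S")
        prof = stability_profile(st, "L")
        fake = StabilityProfile(prof.delta_g, "surrogate",
                                prof.hb_backbone, prof.hb_sidechain.copy(), prof.rsa)
        fake.hb_sidechain[idx] = 2.0
        ddg_apolar = ddg_of_mutation(st, "L", idx + 1, "A", _profile=fake)
        ddg_polar = ddg_of_mutation(st, "L", idx + 1, "T", _profile=fake)
        # alanine loses both side-chain bonds on top of its hydrophobicity change
        beta = DEFAULT_STABILITY_PARAMS.beta
        alpha_term = DEFAULT_STABILITY_PARAMS.alpha * (1 - prof.rsa[idx])
        assert ddg_apolar == pytest.approx(
            alpha_term * (HYDRO_NORM["S"] - HYDRO_NORM["A"]) + beta * 2)
        assert ddg_polar == pytest.approx(alpha_term * (HYDRO_NORM["S"] - HYDRO_NORM["T"]))

    def test_identity_mutation_rejected(self, toy_structures):
        _, st, _ = toy_structures["exposed"]
        aa = st["L"].residues[0].aa
        with pytest.raises(ValueError, match="identity"):
            ddg_of_mutation(st, "L", 1, aa)


def test_external_table_overrides_coordinates(toy_cdr_fixture, toy_structures):
    """With an energy table supplied, scores ignore the coordinates entirely."""
    fx = toy_cdr_fixture
    _, buried_st, table = toy_structures["buried"]
    _, exposed_st, _ = toy_structures["exposed"]
    chains = {"H": annotate_chain(fx.heavy, "H"), "L": annotate_chain(fx.light, "L")}
    r1 = score_antibody(Antibody("a", chains, buried_st, table))
    r2 = score_antibody(Antibody("a", chains, exposed_st, table))
    assert r1.solubis_score == r2.solubis_score
    assert [p.dg_contrib for p in r1.points] == [p.dg_contrib for p in r2.points]
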