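"""Structure-derived local thermodynamic stability (per-residue ΔG, kcal/mol).

Each residue's contribution to the free energy of folding is estimated from
three structural terms:

    ΔG_i = -(alpha * (1 - RSA_i) * H_i  +  beta * HB_i)  +  kappa * C_i

* burial of hydrophobic surface: ``RSA`` is the relative solvent
  accessibility (Shrake-Rupley accessible area over the residue type's
  Gly-X-Gly maximum) and ``H`` the normalised hydrophobic transfer scale;
* hydrogen bonding: ``HB`` counts N/O donor-acceptor pairs below 3.5 Å
  between non-adjacent residues (with a coarse angular check);
* strain: ``C`` counts non-bonded heavy-atom contacts below 2.5 Å.

Negative values are stabilising (FoldX sign convention).  The surrogate is a
ranking potential, not a force field: per-residue ΔG tables computed by real
FoldX (SequenceDetail) are the preferred input and flow through downstream
scoring unchanged.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import cKDTree

from ._scales import HYDRO_NORM, MAX_ASA, POLAR_SIDECHAIN
from .io import ResidueEnergyTable, Structure
from .profile import APR

_BACKBONE_NO = ("N", "O", "OXT")


@dataclasses.dataclass(frozen=True)
class StabilityParams:
    alpha: float = 0.8   # kcal/mol per fully buried, fully hydrophobic residue
    beta: float = 0.5    # kcal/mol per hydrogen bond
    kappa: float = 1.0   # kcal/mol per steric clash
    hb_cutoff: float = 3.5     # Å, donor-acceptor distance
    clash_cutoff: float = 2.5  # Å, non-bonded heavy-atom distance
    probe_radius: float = 1.4  # Å, solvent probe
    n_points: int = 960        # sphere points for Shrake-Rupley


DEFAULT_STABILITY_PARAMS = StabilityParams()


@dataclasses.dataclass
class StabilityProfile:
    delta_g: np.ndarray  # kcal/mol, aligned to chain residues
    provenance: str      # 'surrogate' or 'external_table'
    hb_backbone: np.ndarray | None = None
    hb_sidechain: np.ndarray | None = None
    rsa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_g = np.asarray(self.delta_g, dtype=float)
        if not np.all(np.isfinite(self.delta_g)):
            raise ValueError("stability profile contains non-finite values")


@dataclasses.dataclass(frozen=True)
class APRStability:
    apr: APR
    dg_contrib: float  # kcal/mol, exact sum over the APR interval


def relative_accessibility(
    structure: Structure,
    chain_id: str,
    params: StabilityParams = DEFAULT_STABILITY_PARAMS,
) -> np.ndarray:
    """Per-residue relative solvent accessibility in [0, 1].

    Accessible surface is computed with the Shrake-Rupley rolling-probe
    algorithm over *all* chains of the structure (inter-chain burial counts),
    then normalised by the residue type's Gly-X-Gly maximum area.
    """
    from Bio.PDB.SASA import ShrakeRupley

    if structure.bio_model is None:
        raise ValueError("structure carries no coordinate model")
    sr = ShrakeRupley(probe_radius=params.probe_radius, n_points=params.n_points)
    sr.compute(structure.bio_model, level="R")
    chain = structure[chain_id]
    bio_chain = structure.bio_model[chain_id]
    rsa = np.empty(len(chain.residues))
    for i, res in enumerate(chain.residues):
        if len(res.atoms) < 3:
            warnings.warn(
                f"residue {chain_id}{res.number}{res.icode} has <3 atoms; RSA set to 1"
            )
            rsa[i] = 1.0
            continue
        bio_res = bio_chain[(" ", res.number, res.icode or " ")]
        max_asa = MAX_ASA.get(res.aa, np.mean(list(MAX_ASA.values())))
        rsa[i] = min(1.0, max(0.0, bio_res.sasa / max_asa))
    return rsa


def _atom_catalog(structure: Structure):
    """Flat arrays of every heavy atom with (chain, residue index, name)."""
    coords, meta = [], []
    for cid, chain in structure.chains.items():
        for ri, res in enumerate(chain.residues):
            for atom in res.atoms:
                coords.append(atom.coord)
                meta.append((cid, ri, atom.name, res.aa))
    return np.asarray(coords, dtype=float), meta


def _bonded_neighbor(coords: np.ndarray, meta, idx: int, tree: cKDTree) -> int | None:
    """Nearest same-residue heavy atom within covalent range, or None."""
    cid, ri, _, _ = meta[idx]
    best, best_d = None, 1.9
    for j in tree.query_ball_point(coords[idx], 1.9):
        if j == idx or meta[j][0] != cid or meta[j][1] != ri:
            continue
        d = float(np.linalg.norm(coords[j] - coords[idx]))
        if d < best_d:
            best, best_d = j, d
    return best


def _count_contacts(structure: Structure, chain_id: str, params: StabilityParams):
    """Per-residue hydrogen-bond (backbone/side-chain) and clash counts."""
    coords, meta = _atom_catalog(structure)
    tree = cKDTree(coords)
    chain = structure.chains[chain_id]
    n = len(chain.residues)
    hb_bb = np.zeros(n)
    hb_sc = np.zeros(n)
    clashes = np.zeros(n)

    pairs = tree.query_pairs(params.hb_cutoff)
    for i, j in pairs:
        ci, ri, ni, _ = meta[i]
        cj, rj, nj, _ = meta[j]
        if ci == cj and abs(ri - rj) < 2:
            continue  # same or sequence-adjacent residue: covalent context
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= params.clash_cutoff:
            if ci == chain_id:
                clashes[ri] += 1
            if cj == chain_id:
                clashes[rj] += 1
            continue
        if not (ni[0] in "NO" and nj[0] in "NO"):
            continue
        # angle proxy: the partner must lie on the far side of the covalent bond
        ok = True
        for a, b in ((i, j), (j, i)):
            nb = _bonded_neighbor(coords, meta, a, tree)
            if nb is not None:
                v1 = coords[nb] - coords[a]
                v2 = coords[b] - coords[a]
                cosang = float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
                if cosang > 0:  # angle < 90 degrees
                    ok = False
                    break
        if not ok:
            continue
        for a in (i, j):
            ca, ra, na, _ = meta[a]
            if ca != chain_id:
                continue
            if na in _BACKBONE_NO:
                hb_bb[ra] += 1
            else:
                hb_sc[ra] += 1
    return hb_bb, hb_sc, clashes


def stability_profile(
    structure: Structure,
    chain_id: str,
    params: StabilityParams = DEFAULT_STABILITY_PARAMS,
) -> StabilityProfile:
    """Per-residue folding free-energy contribution of one chain (kcal/mol)."""
    chain = structure[chain_id]
    rsa = relative_accessibility(structure, chain_id, params)
    hb_bb, hb_sc, clashes = _count_contacts(structure, chain_id, params)
    n = len(chain.residues)
    dg = np.zeros(n)
    for i, res in enumerate(chain.residues):
        if not res.atoms:
            warnings.warn(f"residue {chain_id}{res.number} has no coordinates; ΔG set to 0")
            continue
        h = HYDRO_NORM.get(res.aa, 0.0)
        dg[i] = -(params.alpha * (1.0 - rsa[i]) * h + params.beta * (hb_bb[i] + hb_sc[i]))
        dg[i] += params.kappa * clashes[i]
    return StabilityProfile(dg, "surrogate", hb_bb, hb_sc, rsa)


def profile_from_energy_table(
    table: ResidueEnergyTable,
    chain_id: str,
    numbering: list[tuple[int, str]],
) -> StabilityProfile:
    """Align an external per-residue ΔG table (e.g. FoldX) to a chain numbering."""
    dg = np.zeros(len(numbering))
    for i, (num, icode) in enumerate(numbering):
        entry = table.get(chain_id, num, icode)
        if entry is not None:
            dg[i] = entry.delta_g
    return StabilityProfile(dg, "external_table")


def apr_dg_contrib(stability: StabilityProfile, apr: APR) -> APRStability:
    """Exact sum of the per-residue ΔG over the APR's closed interval."""
    if apr.start < 1 or apr.end > len(stability.delta_g):
        raise ValueError(f"APR [{apr.start},{apr.end}] outside stability profile")
    return APRStability(apr, float(stability.delta_g[apr.start - 1 : apr.end].sum()))


def ddg_of_mutation(
    structure: Structure,
    chain_id: str,
    site: int,
    mutant: str,
    params: StabilityParams = DEFAULT_STABILITY_PARAMS,
    _profile: StabilityProfile | None = None,
) -> float:
    """Predicted ΔΔG (kcal/mol, positive = destabilising) of a point mutation.

    The mutant keeps the wild type's burial and backbone hydrogen bonds; its
    hydrophobicity term uses the mutant residue, and side-chain hydrogen bonds
    are lost when a polar side chain is replaced by an apolar one.  ``site``
    is the 1-based index into the chain's residue list.

    This is a ranking heuristic for mutation scans — no side-chain repacking
    or backbone relaxation is attempted.
    """
    chain = structure[chain_id]
    if not (1 <= site <= len(chain.residues)):
        raise ValueError(f"site {site} outside chain {chain_id}")
    res = chain.residues[site - 1]
    if not res.atoms:
        raise ValueError(f"residue {chain_id}{res.number} has no coordinates")
    if res.aa == mutant:
        raise ValueError(f"identity mutation at {chain_id}{res.number}")
    prof = _profile if _profile is not None else stability_profile(structure, chain_id, params)
    i = site - 1
    rsa = prof.rsa[i]
    h_wt = HYDRO_NORM.get(res.aa, 0.0)
    h_mut = HYDRO_NORM.get(mutant, 0.0)
    hb_sc_mut = prof.hb_sidechain[i]
    if res.aa in POLAR_SIDECHAIN and mutant not in POLAR_SIDECHAIN:
        hb_sc_mut = 0.0
    dg_wt = -(params.alpha * (1 - rsa) * h_wt
              + params.beta * (prof.hb_backbone[i] + prof.hb_sidechain[i]))
    dg_mut = -(params.alpha * (1 - rsa) * h_mut
               + params.beta * (prof.hb_backbone[i] + hb_sc_mut))
    return float(dg_mut - dg_wt)
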