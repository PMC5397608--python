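"""Synthetic test inputs: toy Fv sequences, toy structures, printed tables.

``make_toy_fv`` builds ~110-residue heavy and light chains carrying the
conserved anchor motifs the annotation module expects (framework cysteines,
post-CDR1 tryptophan, FG-x-G / WG-x-G J segments), a polar framework
background, and one contiguous hydrophobic APR flanked by aspartate
gatekeepers, planted either inside CDR-L1 or in FR3 of the light chain.  The
fixture records its own ground truth (planted CDR and APR intervals), so
annotation and APR detection can be tested against construction rather than
against an external numbering service.

``make_toy_structure`` places the chains on a deterministic extended-chain
lattice.  In ``buried`` mode the planted APR is wrapped in a packed occluding
shell (pseudo-atom chain Z) plus hydrogen-bond partner atoms, driving its
relative accessibility below 0.25 and its summed ΔG below -5 kcal/mol; in
``exposed`` mode the APR sits on the open chain (RSA > 0.5, ΔG near 0).  The
two modes differ *only* in coordinates, so any downstream score difference is
attributable to the local-stability weight.

``table_fixture_paper`` hard-codes the published evaluation table for nine
wild-type antibodies (aggregation score, Solubis score, APR count, Tm-Tagg
gap, class); "less than 1 degree" gaps are encoded as 0.5 °C.

Every fixture is reproducible from (seed, flags) alone; structures are
topological stand-ins for burial, not immunoglobulin folds.
"""

from __future__ import annotations

import dataclasses
import io as _io

import numpy as np

from .evaluation import EvalRecord
from .io import EnergyEntry, ResidueEnergyTable, Structure, read_pdb_chains
from .stability import DEFAULT_STABILITY_PARAMS, StabilityParams, stability_profile

_BACKGROUND = "STGNQ"       # polar framework alphabet (no C/W/F confounders)
_CHARGED_BG = "KE"          # scattered charges
_APR_ALPHABET = "IVLFY"     # hydrophobic, beta-prone
_FLANK = "D"                # gatekeeper flanking every planted APR


@dataclasses.dataclass
class PlantedFixture:
    seed: int
    apr_in_cdr: bool
    apr_length: int
    heavy: str
    light: str
    apr_chain: str                      # chain carrying the planted APR
    apr_interval: tuple[int, int]       # 1-based closed, on apr_chain
    cdrs: dict[tuple[str, str], tuple[int, int]]  # (chain, label) -> interval


def _background(rng: np.random.Generator, n: int) -> str:
    out = []
    for _ in range(n):
        if rng.random() < 0.12:
            out.append(_CHARGED_BG[rng.integers(len(_CHARGED_BG))])
        else:
            out.append(_BACKGROUND[rng.integers(len(_BACKGROUND))])
    return "".join(out)


def _apr_segment(rng: np.random.Generator, n: int) -> str:
    # at most one Tyr per 5-residue window keeps every window callable
    out: list[str] = []
    for i in range(n):
        aa = _APR_ALPHABET[rng.choice(len(_APR_ALPHABET), p=[0.3, 0.3, 0.2, 0.1, 0.1])]
        if aa == "Y" and "Y" in out[max(0, i - 4) :]:
            aa = "IVL"[rng.integers(3)]
        out.append(aa)
    return "".join(out)


def make_toy_fv(seed: int, apr_in_cdr: bool, apr_length: int = 6) -> PlantedFixture:
    """Build a toy Fv with one gatekeeper-flanked hydrophobic APR planted."""
    if apr_length < 5:
        raise ValueError("apr_length must be >= 5")
    rng = np.random.default_rng(seed)
    cdrs: dict[tuple[str, str], tuple[int, int]] = {}

    # ---- light chain --------------------------------------------------
    if apr_in_cdr and apr_length > 13:
        raise ValueError("APR too long for the host CDR")
    if not apr_in_cdr and apr_length > 24:
        raise ValueError("APR too long for the host framework region")
    apr_seg = _apr_segment(rng, apr_length)

    fr1 = _background(rng, 22) + "C"                     # Cys23
    if apr_in_cdr:
        cdr1 = _background(rng, 1) + _FLANK + apr_seg + _FLANK + _background(rng, 1)
    else:
        cdr1 = _background(rng, 11)
    fr2 = "W" + _background(rng, 14)
    cdr2 = _background(rng, 7)
    if apr_in_cdr:
        fr3 = _background(rng, 31) + "C"
    else:
        pad = 31 - apr_length - 2
        left = pad // 2
        fr3 = (_background(rng, left) + _FLANK + apr_seg + _FLANK
               + _background(rng, pad - left) + "C")
    cdr3 = _background(rng, 9)
    fr4 = "FG" + "QG" + _background(rng, 6)
    const = _background(rng, 5)
    light = fr1 + cdr1 + fr2 + cdr2 + fr3 + cdr3 + fr4 + const

    o = len(fr1)
    cdrs[("L", "CDR1")] = (o + 1, o + len(cdr1))
    o += len(cdr1) + len(fr2)
    cdrs[("L", "CDR2")] = (o + 1, o + len(cdr2))
    o += len(cdr2) + len(fr3)
    cdrs[("L", "CDR3")] = (o + 1, o + len(cdr3))
    if apr_in_cdr:
        apr_start = len(fr1) + 1 + len(_FLANK) + 1  # bg + flank inside CDR1
    else:
        apr_start = len(fr1) + len(cdr1) + len(fr2) + len(cdr2) + (31 - apr_length - 2) // 2 + 2
    apr_interval = (apr_start, apr_start + apr_length - 1)
    assert light[apr_start - 1 : apr_start - 1 + apr_length] == apr_seg

    # ---- heavy chain (no APR) -----------------------------------------
    h_fr1 = _background(rng, 21) + "C" + _background(rng, 3)  # Cys22, H1 at 26
    h_cdr1 = _background(rng, 7)
    h_fr2 = _background(rng, 3) + "W" + _background(rng, 10)
    h_cdr2 = _background(rng, 6)
    h_fr3 = _background(rng, 29) + "C" + _background(rng, 2)
    h_cdr3 = _background(rng, 9)
    h_fr4 = "WG" + "QG" + _background(rng, 6)
    h_const = _background(rng, 4)
    heavy = h_fr1 + h_cdr1 + h_fr2 + h_cdr2 + h_fr3 + h_cdr3 + h_fr4 + h_const

    o = len(h_fr1)
    cdrs[("H", "CDR1")] = (o + 1, o + len(h_cdr1))
    o += len(h_cdr1) + len(h_fr2)
    cdrs[("H", "CDR2")] = (o + 1, o + len(h_cdr2))
    o += len(h_cdr2) + len(h_fr3)
    cdrs[("H", "CDR3")] = (o + 1, o + len(h_cdr3))

    return PlantedFixture(
        seed=seed,
        apr_in_cdr=apr_in_cdr,
        apr_length=apr_length,
        heavy=heavy,
        light=light,
        apr_chain="L",
        apr_interval=apr_interval,
        cdrs=cdrs,
    )


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

_CA_SPACING = 3.8
_SHELL_RADIUS = 6.5
_SHELL_SPACING = 2.6


def _pdb_line(serial: int, name: str, resname: str, chain: str, resseq: int,
              xyz, element: str) -> str:
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {name_field}{'':1s}{resname:>3s} {chain}{resseq:>4d}"
        f"{'':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def _backbone_atoms(i: int, y0: float):
    x = i * _CA_SPACING
    return [
        ("N", "N", (x - 1.2, y0 + 1.0, 0.0)),
        ("CA", "C", (x, y0, 0.0)),
        ("C", "C", (x + 1.2, y0 + 1.0, 0.0)),
        ("O", "O", (x + 1.2, y0 + 2.4, 0.0)),
    ]


def _chain_lines(sequence: str, chain_id: str, y0: float, serial: int):
    from ._scales import ONE_TO_THREE

    lines = []
    for i, aa in enumerate(sequence):
        resname = ONE_TO_THREE.get(aa, "GLY")
        for name, elem, xyz in _backbone_atoms(i, y0):
            lines.append(_pdb_line(serial, name, resname, chain_id, i + 1, xyz, elem))
            serial += 1
    return lines, serial


def _shell_points(x_lo: float, x_hi: float, y_axis: float, z_axis: float):
    """Cylindrical cage (with end caps) around the APR segment."""
    pts = []
    xs = np.arange(x_lo, x_hi + 1e-6, _SHELL_SPACING)
    n_ang = int(np.ceil(2 * np.pi * _SHELL_RADIUS / _SHELL_SPACING))
    for x in xs:
        for k in range(n_ang):
            a = 2 * np.pi * k / n_ang
            pts.append((x, y_axis + _SHELL_RADIUS * np.cos(a), z_axis + _SHELL_RADIUS * np.sin(a)))
    for x in (x_lo, x_hi):  # end caps: concentric rings
        for r in (2.6, 4.5):
            n_r = max(4, int(np.ceil(2 * np.pi * r / _SHELL_SPACING)))
            for k in range(n_r):
                a = 2 * np.pi * k / n_r
                pts.append((x, y_axis + r * np.cos(a), z_axis + r * np.sin(a)))
    return pts


def make_toy_structure(
    fixture: PlantedFixture,
    burial: str,
    stab_params: StabilityParams = DEFAULT_STABILITY_PARAMS,
) -> tuple[str, Structure, ResidueEnergyTable]:
    """Deterministic PDB text for the fixture, parsed structure, matched ΔG table.

    ``burial='buried'`` cages the planted APR (low RSA, 2 hydrogen-bond
    partners per APR residue); ``burial='exposed'`` leaves the chain open.
    """
    if burial not in ("buried", "exposed"):
        raise ValueError(f"unknown burial flag {burial!r}")
    y_l, y_h = 0.0, 60.0
    lines, serial = _chain_lines(fixture.light, "L", y_l, 1)
    more, serial = _chain_lines(fixture.heavy, "H", y_h, serial)
    lines += more

    if burial == "buried":
        a, b = fixture.apr_interval
        extras = []
        for i in range(a - 1, b):
            x = i * _CA_SPACING
            # hydrogen-bond partners for backbone N and O (see stability module
            # geometry: distance < 3.5 A, partner behind the covalent bond)
            extras.append((x - 1.7, y_l + 1.0, 3.0))
            extras.append((x + 1.2, y_l + 3.0, 2.8))
        shell = _shell_points(
            (a - 1) * _CA_SPACING - 5.0,
            (b - 1) * _CA_SPACING + 5.0,
            y_l + 1.2,
            0.4,
        )
        # drop cage points that would collide with chain or partner atoms
        chain_xyz = np.array(
            [xyz for i in range(len(fixture.light)) for _, _, xyz in _backbone_atoms(i, y_l)]
            + extras
        )
        kept = [
            p for p in shell
            if np.min(np.linalg.norm(chain_xyz - np.asarray(p), axis=1)) > 2.8
        ]
        resseq = 1
        for x, y, z in extras:
            lines.append(_pdb_line(serial, "O", "GLY", "Z", resseq, (x, y, z), "O"))
            serial += 1
            resseq += 1
        for x, y, z in kept:
            lines.append(_pdb_line(serial, "CA", "GLY", "Z", resseq, (x, y, z), "C"))
            serial += 1
            resseq += 1

    pdb_text = "\n".join(lines) + "\nEND\n"
    structure = read_pdb_chains(_io.StringIO(pdb_text))
    entries = []
    for cid in ("H", "L"):
        prof = stability_profile(structure, cid, stab_params)
        chain = structure[cid]
        for res, dg in zip(chain.residues, prof.delta_g):
            entries.append(EnergyEntry(cid, res.number, res.icode, res.aa, round(float(dg), 4)))
    return pdb_text, structure, ResidueEnergyTable(entries)


# ---------------------------------------------------------------------------
# published evaluation tables
# ---------------------------------------------------------------------------

# antibody: (total aggregation score, Solubis score, n APRs, Tm-Tagg gap °C, forced label)
_TABLE_WT = {
    "mAb2": (1908, 377, 8, 18.9, None),
    "mAb3": (1131, 71, 7, 4.6, None),
    "mAb4": (1621, 51, 6, 0.5, None),   # printed as "less than 1 degree"
    "mAb5": (2269, 321, 10, 8.5, None),
    "mAb7": (2042, 681, 7, None, 1),    # aggregated prior to analysis
    "mAb8": (1639, 50, 7, 2.8, None),
    "mAb9": (680, 93, 5, 7.6, None),
    "mAb10": (695, 71, 5, 0.5, None),
    "mAb11": (771, 4, 3, 0.5, None),
}


def table_fixture_paper() -> tuple[list[EvalRecord], dict[str, int]]:
    """The nine wild-type validation antibodies and their forced-label overrides."""
    records = []
    forced = {}
    for name, (tango, solubis, n_aprs, gap, force) in _TABLE_WT.items():
        records.append(
            EvalRecord(
                antibody=name,
                solubis_score=float(solubis),
                total_tango=float(tango),
                n_aprs=n_aprs,
                gap=gap,
            )
        )
        if force is not None:
            forced[name] = force
    return records, forced
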