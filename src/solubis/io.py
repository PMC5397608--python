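"""Readers and writers for every external representation the pipeline touches.

Formats: FASTA (sequences), PDB (structures), per-residue free-energy tables
(FoldX SequenceDetail or a generic 4-column TSV), mutation strings such as
``SL50K``, and CSV/JSON result reports.

Conventions: residue positions are 1-based; intervals are closed
``[start, end]``; free energies are in kcal/mol with negative = stabilising.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

from ._scales import CANONICAL, THREE_TO_ONE


class SolubisIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EnergyEntry:
    chain: str
    position: int
    icode: str  # insertion code, '' if none
    aa: str     # one-letter code
    delta_g: float  # kcal/mol

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.position, self.icode)


@dataclasses.dataclass
class ResidueEnergyTable:
    """Per-residue contributions to the free energy of folding (kcal/mol)."""

    entries: list[EnergyEntry]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for e in self.entries:
            if e.key in seen:
                raise SolubisIOError(f"duplicate residue key {e.key}")
            seen.add(e.key)
            if e.aa not in CANONICAL and e.aa != "X":
                raise SolubisIOError(f"non-canonical amino acid {e.aa!r} at {e.key}")
        self._index = {e.key: e for e in self.entries}

    def get(self, chain: str, position: int, icode: str = "") -> EnergyEntry | None:
        return self._index.get((chain, position, icode))

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResidueEnergyTable):
            return NotImplemented
        return self.entries == other.entries


@dataclasses.dataclass(frozen=True)
class MutationSpec:
    """A point substitution in the paper-style ``<wt><chain><pos><mut>`` nomenclature."""

    wild_type: str
    chain: str
    position: int
    icode: str
    mutant: str

    def __post_init__(self) -> None:
        if self.wild_type == self.mutant:
            raise SolubisIOError(f"identity substitution {self}")
        if self.chain not in ("H", "L"):
            raise SolubisIOError(f"chain must be H or L, got {self.chain!r}")

    def __str__(self) -> str:
        return f"{self.wild_type}{self.chain}{self.position}{self.icode}{self.mutant}"


_MUTATION_RE = re.compile(r"^([A-Z])([A-Z])(\d+)([A-Z]?)([A-Z])$")


def parse_mutation_string(text: str) -> MutationSpec:
    """Parse e.g. ``'SL50K'`` -> Ser, light chain, position 50, to Lys."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise SolubisIOError(f"cannot parse mutation string {text!r}")
    wt, chain, pos, icode, mut = m.groups()
    return MutationSpec(wt, chain, int(pos), icode, mut)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(identifier, upper-cased sequence), ...]``.

    Order is preserved. Duplicate identifiers and empty files are errors;
    letters outside the canonical 20 (+X) are kept but warned about.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SolubisIOError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise SolubisIOError(f"duplicate FASTA identifiers: {', '.join(dupes)}")
    out = []
    for r in records:
        seq = str(r.seq).upper()
        odd = sorted(set(seq) - set(CANONICAL) - {"X"})
        if odd:
            warnings.warn(f"record {r.id}: non-standard letters {''.join(odd)}")
        out.append((r.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,)


@dataclasses.dataclass
class StructResidue:
    number: int
    icode: str
    aa: str  # one-letter
    atoms: list[Atom]

    def coord_array(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclasses.dataclass
class ChainStructure:
    chain_id: str
    residues: list[StructResidue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def numbering(self) -> list[tuple[int, str]]:
        return [(r.number, r.icode) for r in self.residues]


class Structure:
    """Heavy-atom coordinates of one PDB model, waters/HETATM/hydrogens removed.

    Keeps the underlying Biopython model so that solvent accessibility can be
    computed in the context of *all* chains (inter-chain occlusion matters).
    """

    def __init__(self, chains: dict[str, ChainStructure], bio_model=None):
        self.chains = chains
        self.bio_model = bio_model

    def __getitem__(self, chain_id: str) -> ChainStructure:
        return self.chains[chain_id]

    def __contains__(self, chain_id: str) -> bool:
        return chain_id in self.chains


def _residue_one_letter(resname: str) -> str:
    one = THREE_TO_ONE.get(resname.strip().upper())
    if one is None:
        warnings.warn(f"unknown residue {resname!r} mapped to X")
        return "X"
    return one


def read_pdb_chains(path: str | Path) -> Structure:
    """Read ATOM records of the first model of a PDB file.

    Waters and HETATM are excluded, hydrogens dropped, alternate locations
    resolved to the highest-occupancy conformer (ties: first encountered).
    Chains with no standard residues are omitted with a warning.
    """
    parser = PDBParser(QUIET=True)
    try:
        source = path if hasattr(path, "read") else str(path)
        bio = parser.get_structure("s", source)
    except Exception as exc:  # Biopython raises various types
        raise SolubisIOError(f"cannot read PDB file {path}: {exc}") from exc
    try:
        model = next(bio.get_models())
    except StopIteration:
        raise SolubisIOError(f"no models in PDB file {path}")

    chains: dict[str, ChainStructure] = {}
    for bio_chain in model:
        residues = []
        for res in list(bio_chain):
            het, num, icode = res.id
            if het.strip():  # water or other heteroatom record
                bio_chain.detach_child(res.id)
                continue
            # res.get_atoms() yields, for disordered atoms, the conformer
            # Biopython selected: the highest occupancy (ties: first seen)
            atoms = [
                Atom(a.get_name(), a.element, np.asarray(a.get_coord(), dtype=float))
                for a in res.get_atoms()
                if a.element not in ("H", "D")
            ]
            residues.append(
                StructResidue(num, icode.strip(), _residue_one_letter(res.get_resname()), atoms)
            )
        if not residues:
            warnings.warn(f"chain {bio_chain.id!r} has no standard residues; omitted")
            model.detach_child(bio_chain.id)
            continue
        chains[bio_chain.id] = ChainStructure(bio_chain.id, residues)
    if not chains:
        raise SolubisIOError(f"no standard protein chains in {path}")
    return Structure(chains, bio_model=model)


# ---------------------------------------------------------------------------
# per-residue energy tables
# ---------------------------------------------------------------------------

def _split_position(token: str) -> tuple[int, str]:
    m = re.match(r"^(-?\d+)([A-Za-z]?)$", token)
    if not m:
        raise ValueError(f"bad residue position {token!r}")
    return int(m.group(1)), m.group(2).upper()


def read_residue_energy_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    energy_column: int = 4,
) -> ResidueEnergyTable:
    """Read per-residue folding free energies (kcal/mol).

    ``generic_tsv``
        Header ``chain<TAB>position<TAB>aa<TAB>delta_g`` then one row per residue.
    ``sequence_detail``
        Whitespace-separated FoldX SequenceDetail layout: each row starts with
        the three-letter amino acid, chain and residue number, followed by
        energy columns.  ``energy_column`` selects the 1-based whitespace-token
        index holding the total per-residue energy (default 4, the first
        energy column); FoldX layouts vary by version, so this reader is
        best-effort.
    """
    if dialect not in ("generic_tsv", "sequence_detail"):
        raise SolubisIOError(f"unknown dialect {dialect!r}")
    entries: list[EnergyEntry] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "generic_tsv":
        if not lines or [c.strip() for c in lines[0].split("\t")] != ["chain", "position", "aa", "delta_g"]:
            raise SolubisIOError(f"{path}: missing generic_tsv header 'chain position aa delta_g'")
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            try:
                chain, pos_tok, aa, dg = (p.strip() for p in parts)
                pos, icode = _split_position(pos_tok)
                entries.append(EnergyEntry(chain, pos, icode, aa.upper(), float(dg)))
            except (ValueError, SolubisIOError) as exc:
                raise SolubisIOError(f"{path}:{ln}: malformed row ({exc})") from exc
    else:
        for ln, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            toks = line.split()
            if toks[0].upper() not in THREE_TO_ONE:
                continue  # header / footer lines
            try:
                aa = THREE_TO_ONE[toks[0].upper()]
                chain = toks[1]
                pos, icode = _split_position(toks[2])
                dg = float(toks[energy_column - 1])
                entries.append(EnergyEntry(chain, pos, icode, aa, dg))
            except (IndexError, ValueError) as exc:
                raise SolubisIOError(f"{path}:{ln}: malformed SequenceDetail row ({exc})") from exc
    try:
        return ResidueEnergyTable(entries)
    except SolubisIOError as exc:
        raise SolubisIOError(f"{path}: {exc}") from exc


def write_energy_table(
    table: ResidueEnergyTable, path: str | Path, dialect: str = "generic_tsv"
) -> None:
    """Write a table in either dialect (SequenceDetail written as aa3 chain pos dg)."""
    from ._scales import ONE_TO_THREE

    with open(path, "w") as fh:
        if dialect == "generic_tsv":
            fh.write("chain\tposition\taa\tdelta_g\n")
            for e in table.entries:
                fh.write(f"{e.chain}\t{e.position}{e.icode}\t{e.aa}\t{_fmt(e.delta_g)}\n")
        elif dialect == "sequence_detail":
            for e in table.entries:
                fh.write(f"{ONE_TO_THREE[e.aa]} {e.chain} {e.position}{e.icode} {_fmt(e.delta_g)}\n")
        else:
            raise SolubisIOError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float) or isinstance(x, np.floating):
        return f"{float(x):.6g}"
    return str(x)


STRETCH_COLUMNS = [
    "antibody", "chain", "region", "start", "end", "sequence",
    "tango_sum", "dg_contrib", "weight", "corrected_score", "critical",
]


def write_report(report, path: str | Path, format: str = "csv") -> None:
    """Serialise a pipeline result deterministically.

    Stretch-point lists go to the fixed CSV schema; any object exposing
    ``to_dict()`` (or a plain dict/list) goes to JSON with sorted keys and
    6-significant-digit floats.
    """
    if format == "csv":
        rows = report if isinstance(report, list) else [report]
        with open(path, "w") as fh:
            fh.write(",".join(STRETCH_COLUMNS) + "\n")
            for r in rows:
                d = r.to_row() if hasattr(r, "to_row") else r
                fh.write(",".join(_fmt(d[c]) for c in STRETCH_COLUMNS) + "\n")
    elif format == "json":
        obj = report.to_dict() if hasattr(report, "to_dict") else report
        with open(path, "w") as fh:
            json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise SolubisIOError(f"unknown report format {format!r}")


def _round_floats(obj):
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj
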