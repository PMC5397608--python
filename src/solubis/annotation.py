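"""Antibody variable-domain annotation: CDR/FR region labels and net charge.

CDRs are located with the conserved anchor residues of the Chothia convention
(the two cysteines of the intradomain disulfide, the Trp following CDR1, the
FG-x-G / WG-x-G J-segment motifs) rather than a full numbering-scheme
alignment; an external numbering sidecar can override the anchor search for
non-standard domains.

Region labels per residue: FR1, CDR1, FR2, CDR2, FR3, CDR3, FR4 for the
variable domain, CONST for anything C-terminal of FR4.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

from ._scales import CHARGE
from .io import SolubisIOError

REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4", "CONST")

# Chothia canonical CDR length bounds (used to pick among candidate anchors).
_L1_LEN = (7, 17)
_H1_LEN = (5, 9)

# Canonical position of the first framework cysteine, used to anchor numbering.
_CYS1_NUMBER = {"L": 23, "H": 22}


class AnnotationError(ValueError):
    """Raised when a required anchor motif cannot be located."""


@dataclasses.dataclass
class AntibodyChain:
    """An annotated antibody chain.

    ``numbering`` holds per-residue scheme positions as (number, insertion
    code); ``regions`` holds one label from ``REGIONS`` per residue.
    """

    chain_type: str  # 'H' or 'L'
    sequence: str
    numbering: list[tuple[int, str]]
    regions: list[str]

    def __post_init__(self) -> None:
        if self.chain_type not in ("H", "L"):
            raise ValueError(f"chain_type must be H or L, got {self.chain_type!r}")
        n = len(self.sequence)
        if len(self.numbering) != n or len(self.regions) != n:
            raise ValueError("numbering/regions must align with the sequence")

    def region_interval(self, label: str) -> tuple[int, int] | None:
        """1-based closed interval of a region label, or None if absent."""
        idx = [i for i, r in enumerate(self.regions) if r == label]
        if not idx:
            return None
        return (idx[0] + 1, idx[-1] + 1)

    def index_of_position(self, number: int, icode: str = "") -> int:
        """0-based sequence index of a scheme position."""
        try:
            return self.numbering.index((number, icode))
        except ValueError:
            raise KeyError(f"position {number}{icode} not in chain numbering") from None


def _find_cys(seq: str, start: int = 0) -> int:
    i = seq.find("C", start)
    if i < 0:
        raise AnnotationError("conserved cysteine not found")
    return i


def _light_intervals(seq: str) -> dict[str, tuple[int, int]]:
    """0-based half-open CDR intervals for a light chain."""
    c1 = _find_cys(seq)
    l1_start = c1 + 1
    # conserved Trp terminates CDR-L1; accept the first Trp giving a canonical length
    w = None
    for m in re.finditer("W", seq[l1_start:]):
        length = m.start()
        if _L1_LEN[0] <= length <= _L1_LEN[1]:
            w = l1_start + m.start()
            break
    if w is None:
        raise AnnotationError("post-CDR-L1 tryptophan anchor not found")
    l1 = (l1_start, w)
    l2_start = (w - 1) + 16  # CDR-L2 begins 16 residues after the L1 end
    l2 = (l2_start, l2_start + 7)
    c2 = _find_cys(seq, l2[1])
    l3_start = c2 + 1
    m = re.search("FG.G", seq[l3_start + 6 :])
    if m is None:
        raise AnnotationError("FG-x-G J-segment anchor not found")
    f = l3_start + 6 + m.start()
    l3 = (l3_start, f)
    return {"CDR1": l1, "CDR2": l2, "CDR3": l3}


def _heavy_intervals(seq: str) -> dict[str, tuple[int, int]]:
    """0-based half-open CDR intervals for a heavy chain."""
    c1 = _find_cys(seq)
    h1_start = c1 + 4
    w = None
    for m in re.finditer("W", seq[h1_start:]):
        length = m.start() - 3  # H1 ends 4 before the conserved Trp
        if _H1_LEN[0] <= length <= _H1_LEN[1]:
            w = h1_start + m.start()
            break
    if w is None:
        raise AnnotationError("post-CDR-H1 tryptophan anchor not found")
    h1 = (h1_start, w - 3)
    h2_start = (h1[1] - 1) + 15  # CDR-H2 begins 15 residues after the H1 end
    h2 = (h2_start, h2_start + 6)
    c2 = _find_cys(seq, h2[1])
    h3_start = c2 + 3
    m = re.search("WG.G", seq[h3_start + 4 :])
    if m is None:
        raise AnnotationError("WG-x-G J-segment anchor not found")
    w2 = h3_start + 4 + m.start()
    h3 = (h3_start, w2)
    return {"CDR1": h1, "CDR2": h2, "CDR3": h3}


def _regions_from_cdrs(n: int, cdrs: dict[str, tuple[int, int]]) -> list[str]:
    fr4_end = min(cdrs["CDR3"][1] + 10, n)  # J segment: ~10 residues of FR4
    regions = ["CONST"] * n
    bounds = [
        ("FR1", 0, cdrs["CDR1"][0]),
        ("CDR1", *cdrs["CDR1"]),
        ("FR2", cdrs["CDR1"][1], cdrs["CDR2"][0]),
        ("CDR2", *cdrs["CDR2"]),
        ("FR3", cdrs["CDR2"][1], cdrs["CDR3"][0]),
        ("CDR3", *cdrs["CDR3"]),
        ("FR4", cdrs["CDR3"][1], fr4_end),
    ]
    prev_end = 0
    for label, a, b in bounds:
        if a != prev_end or b > n or b < a:
            raise AnnotationError(f"inconsistent region bounds at {label}")
        for i in range(a, b):
            regions[i] = label
        prev_end = b
    return regions


def read_numbering_sidecar(path: str | Path) -> list[tuple[str, int, str, str, str]]:
    """Read an external numbering TSV: header ``chain position insertion aa region``."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != ["chain", "position", "insertion", "aa", "region"]:
        raise SolubisIOError(f"{path}: missing sidecar header")
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5 or parts[4] not in REGIONS:
            raise SolubisIOError(f"{path}:{ln}: malformed sidecar row")
        rows.append((parts[0], int(parts[1]), parts[2].strip(), parts[3], parts[4]))
    return rows


def annotate_chain(
    sequence: str,
    chain_type: str,
    external_numbering: list[tuple[str, int, str, str, str]] | None = None,
) -> AntibodyChain:
    """Assign numbering and FR/CDR labels to a variable-domain sequence.

    With ``external_numbering`` (sidecar rows for this chain, one per residue,
    in order) the annotation is taken verbatim. Otherwise CDRs are located by
    the conserved-anchor rules and numbering is assigned by counting from the
    first framework cysteine (Cys23 light / Cys22 heavy).
    """
    sequence = sequence.upper()
    if external_numbering is not None:
        rows = [r for r in external_numbering if r[0] == chain_type]
        if len(rows) != len(sequence):
            raise AnnotationError(
                f"sidecar covers {len(rows)} residues, chain has {len(sequence)}"
            )
        for (_, _, _, aa, _), s in zip(rows, sequence):
            if aa.upper() != s:
                raise AnnotationError("sidecar sequence mismatch")
        return AntibodyChain(
            chain_type,
            sequence,
            [(r[1], r[2]) for r in rows],
            [r[4] for r in rows],
        )
    if len(sequence) < 70:
        raise AnnotationError(
            f"sequence of length {len(sequence)} is shorter than a variable domain "
            "(supply external numbering for fragments)"
        )
    cdrs = (_heavy_intervals if chain_type == "H" else _light_intervals)(sequence)
    regions = _regions_from_cdrs(len(sequence), cdrs)
    c1 = _find_cys(sequence)
    offset = _CYS1_NUMBER[chain_type] - (c1 + 1)
    if offset + 1 < 1:
        offset = 0  # long N-terminal extensions: fall back to sequential numbering
    numbering = [(i + 1 + offset, "") for i in range(len(sequence))]
    return AntibodyChain(chain_type, sequence, numbering, regions)


@dataclasses.dataclass(frozen=True)
class NetCharge:
    value: int
    region_scope: str


_SCOPES = {
    "whole": None,
    "fr": {"FR1", "FR2", "FR3", "FR4", "CONST"},
    "cdr": {"CDR1", "CDR2", "CDR3"},
}


def net_charge(chain: AntibodyChain, scope: str = "whole") -> NetCharge:
    """Formal net charge over a region scope: +1 per K/R, -1 per D/E, His neutral.

    Scopes: ``whole``, ``fr`` (framework + constant, i.e. outside the CDRs),
    ``cdr``. Termini are ignored.
    """
    if scope not in _SCOPES:
        raise ValueError(f"unknown scope {scope!r}; use one of {sorted(_SCOPES)}")
    labels = _SCOPES[scope]
    total = sum(
        CHARGE.get(aa, 0)
        for aa, region in zip(chain.sequence, chain.regions)
        if labels is None or region in labels
    )
    return NetCharge(total, scope)


def apr_region_label(chain: AntibodyChain, interval: tuple[int, int]) -> str:
    """Label a 1-based closed interval: CDRk if it overlaps CDR k, FR otherwise.

    Overlap with two different CDRs yields ``mixed``.
    """
    start, end = interval
    if start > end or start < 1 or end > len(chain.sequence):
        raise ValueError(f"invalid interval {interval} on chain of length {len(chain.sequence)}")
    hit = {r for r in chain.regions[start - 1 : end] if r.startswith("CDR")}
    if not hit:
        return "FR"
    if len(hit) > 1:
        return "mixed"
    return hit.pop()
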