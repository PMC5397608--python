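"""Design of aggregation-suppressing antibody variants.

Two complementary scans:

* **MASS scan** (mutant aggregation and stability spectrum): every residue of
  a critical APR is mutated to each gatekeeper (Asp, Glu, Lys, Arg, Pro) and
  scored for the change in the APR's aggregation score (``d_tango``) and the
  predicted stability cost (``ddg``).  Good candidates maximally reduce
  aggregation at minimal stability cost.
* **Supercharge scan**: every framework/constant-region position of the heavy
  chain is mutated so as to increase the formal net charge (X→K, X→R, and
  acid→amide D→N/Q, E→N/Q), improving colloidal stability without touching
  the CDRs.

``compose_variant`` applies a set of substitutions and re-runs the whole
scoring pipeline on the variant.
"""

from __future__ import annotations

import dataclasses
import warnings

from ._scales import CHARGE
from .annotation import AntibodyChain
from .io import MutationSpec
from .profile import APR, DEFAULT_PARAMS, SurrogateParams, mutant_profile_delta
from .scoring import (Antibody, DEFAULT_CRITICAL_THRESHOLD, SolubisReport,
                      chain_stability, score_antibody)
from .stability import DEFAULT_STABILITY_PARAMS, StabilityParams, ddg_of_mutation

GATEKEEPERS = "DEKRP"
DEFAULT_MAX_DDG = 0.5  # kcal/mol


@dataclasses.dataclass(frozen=True)
class MutationCandidate:
    mutation: MutationSpec
    d_tango: float   # change in the affected APR's summed aggregation score
    ddg: float       # kcal/mol, positive = destabilising
    d_charge: int
    source: str      # 'mass_scan' or 'supercharge'

    def to_row(self) -> dict:
        m = self.mutation
        return {
            "chain": m.chain,
            "position": f"{m.position}{m.icode}",
            "wt": m.wild_type,
            "mut": m.mutant,
            "d_tango": self.d_tango,
            "ddg": self.ddg,
            "d_charge": self.d_charge,
            "source": self.source,
        }


def _site_ddg(
    antibody: Antibody,
    chain_id: str,
    site: int,
    mutant: str,
    stab_params: StabilityParams,
    stab_profile,
) -> float:
    """ΔΔG for a substitution, 0 when no structural source is available."""
    if antibody.structure is not None and chain_id in antibody.structure:
        return ddg_of_mutation(
            antibody.structure, chain_id, site, mutant, stab_params, _profile=stab_profile
        )
    return 0.0


def mass_scan(
    antibody: Antibody,
    chain_id: str,
    apr: APR,
    params: SurrogateParams = DEFAULT_PARAMS,
    stab_params: StabilityParams = DEFAULT_STABILITY_PARAMS,
) -> list[MutationCandidate]:
    """Gatekeeper scan over one APR: 5 substitutions per position, identity skipped.

    Candidates are sorted by (d_tango ascending, ddg ascending): most
    aggregation-suppressing first.
    """
    if apr.end < apr.start:
        raise ValueError("empty APR")
    chain = antibody.chains[chain_id]
    stab_profile = None
    if antibody.structure is not None and chain_id in antibody.structure:
        from .stability import stability_profile
        stab_profile = stability_profile(antibody.structure, chain_id, stab_params)
    out = []
    for site in range(apr.start, apr.end + 1):
        wt = chain.sequence[site - 1]
        num, icode = chain.numbering[site - 1]
        for gk in GATEKEEPERS:
            if gk == wt:
                continue  # wild type already a gatekeeper at this letter
            _, deltas = mutant_profile_delta(chain.sequence, site, gk, params, aprs=[apr])
            ddg = _site_ddg(antibody, chain_id, site, gk, stab_params, stab_profile)
            out.append(
                MutationCandidate(
                    MutationSpec(wt, chain.chain_type, num, icode, gk),
                    d_tango=deltas[apr],
                    ddg=ddg,
                    d_charge=CHARGE.get(gk, 0) - CHARGE.get(wt, 0),
                    source="mass_scan",
                )
            )
    out.sort(key=lambda c: (c.d_tango, c.ddg, c.mutation.position, c.mutation.icode,
                            c.mutation.mutant))
    return out


def select_mass_candidates(
    candidates: list[MutationCandidate],
    max_ddg: float = DEFAULT_MAX_DDG,
    top_n: int | None = None,
) -> list[MutationCandidate]:
    """Shortlist: keep ddg ≤ max_ddg, rank by d_tango, ties by ddg/position/mutant."""
    if not candidates:
        raise ValueError("no candidates to select from")
    kept = [c for c in candidates if c.ddg <= max_ddg]
    if not kept:
        warnings.warn(f"all candidates exceed max_ddg={max_ddg}; empty shortlist")
        return []
    kept.sort(key=lambda c: (c.d_tango, c.ddg, c.mutation.position, c.mutation.icode,
                             c.mutation.mutant))
    return kept[:top_n] if top_n is not None else kept


def supercharge_scan(
    antibody: Antibody,
    chain_id: str = "H",
    stab_params: StabilityParams = DEFAULT_STABILITY_PARAMS,
) -> list[MutationCandidate]:
    """Net-charge-increasing scan outside the CDRs of the heavy chain.

    At every FR/CONST position: X→K and X→R for X not already K/R, plus the
    acid→amide pair D→N/Q, E→N/Q.  Sorted by ddg ascending.
    """
    chain = antibody.chains[chain_id]
    if not chain.regions:
        raise ValueError("chain has no region labels")
    stab_profile = None
    if antibody.structure is not None and chain_id in antibody.structure:
        from .stability import stability_profile
        stab_profile = stability_profile(antibody.structure, chain_id, stab_params)
    out = []
    for i, (wt, region) in enumerate(zip(chain.sequence, chain.regions)):
        if region.startswith("CDR"):
            continue
        num, icode = chain.numbering[i]
        muts = []
        if wt not in ("K", "R"):
            muts += ["K", "R"]
        if wt in ("D", "E"):
            muts += ["N", "Q"]
        for mut in muts:
            d_charge = CHARGE.get(mut, 0) - CHARGE.get(wt, 0)
            assert d_charge >= 1
            ddg = _site_ddg(antibody, chain_id, i + 1, mut, stab_params, stab_profile)
            out.append(
                MutationCandidate(
                    MutationSpec(wt, chain.chain_type, num, icode, mut),
                    d_tango=0.0,
                    ddg=ddg,
                    d_charge=d_charge,
                    source="supercharge",
                )
            )
    out.sort(key=lambda c: (c.ddg, c.mutation.position, c.mutation.icode, c.mutation.mutant))
    return out


@dataclasses.dataclass
class VariantDesign:
    mutations: list[MutationSpec]
    report: SolubisReport
    d_charge: int

    def to_dict(self) -> dict:
        return {
            "mutations": [str(m) for m in self.mutations],
            "d_charge": self.d_charge,
            **self.report.to_dict(),
        }


def apply_mutations(antibody: Antibody, mutations: list[MutationSpec]) -> Antibody:
    """Return a copy of the antibody with all substitutions applied.

    Wild-type letters are checked against the sequence at the stated
    numbering; duplicated positions are an error.  The structure and any
    external energy table are carried over unchanged (the scan heuristics
    treat the backbone as fixed).
    """
    seen = set()
    new_chains = {cid: c for cid, c in antibody.chains.items()}
    seqs = {cid: list(c.sequence) for cid, c in antibody.chains.items()}
    for m in mutations:
        key = (m.chain, m.position, m.icode)
        if key in seen:
            raise ValueError(f"duplicated mutation position {m.chain}{m.position}{m.icode}")
        seen.add(key)
        chain = antibody.chains[m.chain]
        idx = chain.index_of_position(m.position, m.icode)
        if chain.sequence[idx] != m.wild_type:
            raise ValueError(
                f"wild-type mismatch at {m.chain}{m.position}{m.icode}: "
                f"expected {chain.sequence[idx]}, mutation says {m.wild_type}"
            )
        seqs[m.chain][idx] = m.mutant
    for cid in seqs:
        c = antibody.chains[cid]
        new_chains[cid] = AntibodyChain(
            c.chain_type, "".join(seqs[cid]), list(c.numbering), list(c.regions)
        )
    return Antibody(
        antibody.name, new_chains, antibody.structure, antibody.energy_table
    )


def compose_variant(
    antibody: Antibody,
    mutations: list[MutationSpec],
    params: SurrogateParams = DEFAULT_PARAMS,
    stab_params: StabilityParams = DEFAULT_STABILITY_PARAMS,
    critical_threshold: float = DEFAULT_CRITICAL_THRESHOLD,
) -> VariantDesign:
    """Apply mutations and re-run the full scoring pipeline on the variant."""
    variant = apply_mutations(antibody, mutations)
    name = antibody.name + "".join(f"_{m}" for m in sorted(mutations, key=str))
    variant.name = name
    report = score_antibody(
        variant, params, stab_params, critical_threshold=critical_threshold
    )
    d_charge = sum(
        CHARGE.get(m.mutant, 0) - CHARGE.get(m.wild_type, 0) for m in mutations
    )
    return VariantDesign(list(mutations), report, d_charge)
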