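"""The Solubis score: aggregation propensity corrected by local stability.

Each APR becomes a *stretch point*: its summed per-residue aggregation score
(``tango_sum``) paired with the summed ΔG of its residues (``dg_contrib``,
kcal/mol).  The ΔG is clipped to [-5, +5] kcal/mol and rescaled to a weight

    weight = clip((dg_contrib + 5) / 10, 0, 1)

so an APR buried in a strongly stabilising environment (ΔG ≤ -5) is
thermodynamically protected and contributes nothing, while an APR in an
unstable environment (ΔG ≥ +5) contributes its full aggregation score.  The
Solubis score of an antibody is the sum of ``tango_sum × weight`` over all
its APRs; APRs whose corrected score passes a threshold (default 50) are
flagged *critical*.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .annotation import AntibodyChain, apr_region_label
from .io import ResidueEnergyTable, Structure
from .profile import (APR, DEFAULT_PARAMS, PropensityProfile, SurrogateParams,
                      detect_aprs, propensity_profile)
from .stability import (DEFAULT_STABILITY_PARAMS, APRStability, StabilityParams,
                        StabilityProfile, apr_dg_contrib,
                        profile_from_energy_table, stability_profile)

DEFAULT_CRITICAL_THRESHOLD = 50.0


def stability_weight(dg_contrib: float) -> float:
    """Map an APR's summed ΔG (kcal/mol) to [0, 1]: clip((ΔG + 5) / 10, 0, 1)."""
    if not math.isfinite(dg_contrib):
        raise ValueError(f"non-finite dg_contrib {dg_contrib}")
    return min(1.0, max(0.0, (dg_contrib + 5.0) / 10.0))


@dataclasses.dataclass(frozen=True)
class StretchPoint:
    """One APR with its stability weighting — one point of the stretch-plot."""

    antibody: str
    chain: str
    region: str
    apr: APR
    dg_contrib: float
    weight: float
    corrected_score: float
    critical: bool

    @property
    def tango_sum(self) -> float:
        return self.apr.tango_sum

    def to_row(self) -> dict:
        return {
            "antibody": self.antibody,
            "chain": self.chain,
            "region": self.region,
            "start": self.apr.start,
            "end": self.apr.end,
            "sequence": self.apr.sequence,
            "tango_sum": self.apr.tango_sum,
            "dg_contrib": self.dg_contrib,
            "weight": self.weight,
            "corrected_score": self.corrected_score,
            "critical": self.critical,
        }


def make_stretch_points(
    apr_stabilities: list[APRStability],
    chain: AntibodyChain,
    chain_id: str = "",
    antibody: str = "",
    critical_threshold: float = DEFAULT_CRITICAL_THRESHOLD,
) -> list[StretchPoint]:
    """Combine APRs with their ΔG contributions into stretch points."""
    points = []
    for st in apr_stabilities:
        w = stability_weight(st.dg_contrib)
        corrected = st.apr.tango_sum * w
        region = apr_region_label(chain, (st.apr.start, st.apr.end))
        points.append(
            StretchPoint(
                antibody=antibody,
                chain=chain_id or chain.chain_type,
                region=region,
                apr=st.apr,
                dg_contrib=st.dg_contrib,
                weight=w,
                corrected_score=corrected,
                critical=corrected >= critical_threshold,
            )
        )
    return points


@dataclasses.dataclass
class SolubisReport:
    antibody: str
    points: list[StretchPoint]
    critical_threshold: float = DEFAULT_CRITICAL_THRESHOLD
    sequence_only: bool = False

    @property
    def solubis_score(self) -> float:
        return float(sum(p.corrected_score for p in self.points))

    @property
    def total_tango(self) -> float:
        return float(sum(p.tango_sum for p in self.points))

    @property
    def n_aprs(self) -> int:
        return len(self.points)

    @property
    def n_critical(self) -> int:
        return sum(p.critical for p in self.points)

    def to_dict(self) -> dict:
        return {
            "antibody": self.antibody,
            "solubis_score": self.solubis_score,
            "total_tango": self.total_tango,
            "n_aprs": self.n_aprs,
            "n_critical": self.n_critical,
            "critical_threshold": self.critical_threshold,
            "sequence_only": self.sequence_only,
            "stretch_points": [p.to_row() for p in self.points],
        }


def solubis_score(points: list[StretchPoint], antibody: str = "") -> SolubisReport:
    """Total Solubis score of one antibody (empty APR list scores 0)."""
    return SolubisReport(antibody, list(points))


def stretch_density(
    points: list[StretchPoint],
    dg_edges=None,
    tango_edges=None,
    normalize: bool = False,
):
    """2-D histogram of stretch points over (ΔG_contrib, tango_sum) bins.

    Returns ``(counts, dg_edges, tango_edges)``; with ``normalize`` the counts
    are fractions of the total.
    """
    if not points:
        raise ValueError("stretch_density requires at least one point")
    dg = np.array([p.dg_contrib for p in points])
    ts = np.array([p.tango_sum for p in points])
    if dg_edges is None:
        dg_edges = np.linspace(min(dg.min(), -10.0), max(dg.max(), 10.0), 21)
    if tango_edges is None:
        tango_edges = np.linspace(0.0, max(ts.max(), 100.0), 21)
    counts, xe, ye = np.histogram2d(dg, ts, bins=[dg_edges, tango_edges])
    if normalize:
        counts = counts / counts.sum()
    return counts, xe, ye


# ---------------------------------------------------------------------------
# whole-antibody orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Antibody:
    """Sequences (+ optional structure / external ΔG table) of one antibody."""

    name: str
    chains: dict[str, AntibodyChain]  # keyed 'H' / 'L'
    structure: Structure | None = None
    energy_table: ResidueEnergyTable | None = None


def chain_stability(
    antibody: Antibody, chain_id: str, stab_params: StabilityParams
) -> StabilityProfile | None:
    """Resolve the ΔG source for one chain: external table > structure > none."""
    chain = antibody.chains[chain_id]
    if antibody.energy_table is not None:
        return profile_from_energy_table(antibody.energy_table, chain_id, chain.numbering)
    if antibody.structure is not None and chain_id in antibody.structure:
        return stability_profile(antibody.structure, chain_id, stab_params)
    return None


def score_antibody(
    antibody: Antibody,
    params: SurrogateParams = DEFAULT_PARAMS,
    stab_params: StabilityParams = DEFAULT_STABILITY_PARAMS,
    min_len: int = 5,
    threshold: float = 5.0,
    critical_threshold: float = DEFAULT_CRITICAL_THRESHOLD,
    external_profiles: dict[str, PropensityProfile] | None = None,
) -> SolubisReport:
    """Run the full pipeline on one antibody: profile → APRs → ΔG → score.

    Without a structure or energy table the ΔG of every APR defaults to 0
    (weight 0.5) and the report is flagged ``sequence_only``.
    """
    all_points: list[StretchPoint] = []
    sequence_only = antibody.structure is None and antibody.energy_table is None
    for chain_id in sorted(antibody.chains):
        chain = antibody.chains[chain_id]
        if external_profiles and chain_id in external_profiles:
            prof = external_profiles[chain_id]
        else:
            prof = propensity_profile(chain.sequence, params)
        aprs = detect_aprs(prof, chain.sequence, min_len=min_len, threshold=threshold)
        stab = chain_stability(antibody, chain_id, stab_params)
        stabilities = [
            apr_dg_contrib(stab, apr) if stab is not None else APRStability(apr, 0.0)
            for apr in aprs
        ]
        all_points.extend(
            make_stretch_points(
                stabilities, chain, chain_id, antibody.name, critical_threshold
            )
        )
    report = solubis_score(all_points, antibody.name)
    report.critical_threshold = critical_threshold
    report.sequence_only = sequence_only
    return report
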