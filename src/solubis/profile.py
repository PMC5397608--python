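"""Intrinsic beta-aggregation propensity profiles and APR calling.

The per-residue score (0-100) comes from a windowed sequence potential that
captures the established determinants of beta-aggregation: hydrophobicity and
beta-sheet preference promote it, net charge and proline suppress it.  For a
window ``w`` of 5 residues,

    E_w = sum_{j in w} (h_j + b_j) - lambda * |q_w| - gamma * nP_w

with ``h`` the min-max-normalised Kyte-Doolittle hydropathy, ``b`` the
normalised Chou-Fasman beta propensity, ``q_w`` the window formal charge
(K/R +1, D/E -1) and ``nP_w`` the window proline count.  Each residue is
assigned its best (maximum-energy) covering window and scored

    score_i = 100 * sigma((E_{w*} - E0) / s)

with a logistic sigma.  The defaults are a fixed calibration chosen so that
hydrophobic hexapeptides (STVIIE-like) in a polar context are called as APRs
while poly-charged and proline-containing controls are not.

An APR is a maximal run of >= ``min_len`` residues scoring >= ``threshold``
(defaults 5 and 5, matching the 5-100 per-residue convention of TANGO
output).  External per-residue scores (e.g. real TANGO output) can be
substituted via ``profile_from_scores`` and flow through all downstream
stages unchanged.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from ._scales import BETA_NORM, CHARGE, HYDRO_NORM


@dataclasses.dataclass(frozen=True)
class SurrogateParams:
    """Calibrated constants of the windowed aggregation potential."""

    e0: float = 8.5      # logistic midpoint (window-energy units)
    s: float = 0.4       # logistic slope
    lam: float = 3.0     # charge penalty per unit |window charge|
    gamma: float = 3.5   # proline penalty per proline in window
    window: int = 5


DEFAULT_PARAMS = SurrogateParams()


@dataclasses.dataclass
class PropensityProfile:
    per_residue: np.ndarray  # scores in [0, 100], one per residue
    params: SurrogateParams | None

    def __post_init__(self) -> None:
        self.per_residue = np.asarray(self.per_residue, dtype=float)
        if self.per_residue.ndim != 1:
            raise ValueError("profile must be one-dimensional")
        if np.any((self.per_residue < 0) | (self.per_residue > 100)):
            raise ValueError("per-residue scores must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.per_residue)


@dataclasses.dataclass(frozen=True)
class APR:
    """A contiguous aggregation-prone region, 1-based closed interval."""

    start: int
    end: int
    sequence: str
    tango_sum: float

    def __len__(self) -> int:
        return self.end - self.start + 1


def _window_energies(sequence: str, params: SurrogateParams) -> np.ndarray:
    """Energy of every length-``window`` window; -inf for windows containing X."""
    n = len(sequence)
    w = params.window
    if n < w:
        return np.empty(0)
    hb = np.array([HYDRO_NORM.get(a, np.nan) + BETA_NORM.get(a, np.nan) for a in sequence])
    q = np.array([CHARGE.get(a, 0) for a in sequence], dtype=float)
    p = np.array([1.0 if a == "P" else 0.0 for a in sequence])
    x = np.array([a not in HYDRO_NORM for a in sequence], dtype=float)  # X or unknown
    kern = np.ones(w)
    hb_sum = np.convolve(np.nan_to_num(hb), kern, mode="valid")
    q_sum = np.convolve(q, kern, mode="valid")
    p_sum = np.convolve(p, kern, mode="valid")
    x_sum = np.convolve(x, kern, mode="valid")
    e = hb_sum - params.lam * np.abs(q_sum) - params.gamma * p_sum
    e[x_sum > 0] = -np.inf
    return e


def propensity_profile(sequence: str, params: SurrogateParams = DEFAULT_PARAMS) -> PropensityProfile:
    """Per-residue aggregation propensity (0-100) of a sequence.

    Residues are scored from their best covering window; 'X' residues score
    exactly 0 and exclude every window that contains them.
    """
    sequence = sequence.upper()
    n = len(sequence)
    w = params.window
    if n < w:
        warnings.warn(f"sequence of length {n} shorter than window {w}; all-zero profile")
        return PropensityProfile(np.zeros(n), params)
    e = _window_energies(sequence, params)
    best = np.full(n, -np.inf)
    for i in range(n):
        lo = max(0, i - w + 1)
        hi = min(i, n - w)
        if hi >= lo:
            best[i] = e[lo : hi + 1].max()
    with np.errstate(over="ignore"):
        scores = 100.0 / (1.0 + np.exp(-(best - params.e0) / params.s))
    scores[~np.isfinite(best)] = 0.0
    scores[[a not in HYDRO_NORM for a in sequence]] = 0.0
    return PropensityProfile(scores, params)


def profile_from_scores(scores) -> PropensityProfile:
    """Wrap externally computed per-residue scores (e.g. real TANGO output)."""
    return PropensityProfile(np.asarray(scores, dtype=float), None)


def detect_aprs(
    profile: PropensityProfile,
    sequence: str | None = None,
    min_len: int = 5,
    threshold: float = 5.0,
) -> list[APR]:
    """Call APRs: maximal runs of >= ``min_len`` residues scoring >= ``threshold``."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    scores = profile.per_residue
    if sequence is not None and len(sequence) != len(scores):
        raise ValueError("sequence/profile length mismatch")
    aprs: list[APR] = []
    i = 0
    n = len(scores)
    while i < n:
        if scores[i] >= threshold:
            j = i
            while j + 1 < n and scores[j + 1] >= threshold:
                j += 1
            if j - i + 1 >= min_len:
                seg = sequence[i : j + 1] if sequence is not None else ""
                aprs.append(APR(i + 1, j + 1, seg, float(scores[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return aprs


def mutant_profile_delta(
    sequence: str,
    site: int,
    mutant: str,
    params: SurrogateParams = DEFAULT_PARAMS,
    aprs: list[APR] | None = None,
) -> tuple[PropensityProfile, dict[APR, float]]:
    """Recompute the profile after a point substitution at 1-based ``site``.

    Returns the mutant profile and, per wild-type APR, the change in its
    summed score over the *same* interval (negative = aggregation-suppressing).
    """
    sequence = sequence.upper()
    if not (1 <= site <= len(sequence)):
        raise ValueError(f"site {site} outside sequence of length {len(sequence)}")
    if sequence[site - 1] == mutant.upper():
        raise ValueError(f"identity mutation {mutant} at site {site}")
    wt_profile = propensity_profile(sequence, params)
    if aprs is None:
        aprs = detect_aprs(wt_profile, sequence)
    mut_seq = sequence[: site - 1] + mutant.upper() + sequence[site:]
    mut_profile = propensity_profile(mut_seq, params)
    deltas = {
        apr: float(
            mut_profile.per_residue[apr.start - 1 : apr.end].sum()
            - wt_profile.per_residue[apr.start - 1 : apr.end].sum()
        )
        for apr in aprs
    }
    return mut_profile, deltas
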