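"""Chlorine/bromine inference from MS1 isotopologue envelopes.

A feature's observed envelope is compared against theoretical isotope
patterns for a grid of (nCl, nBr) candidates; the cosine similarity over
aligned isotopologue slots picks the best call, with the gap to the
runner-up serving as a confidence margin.  Iodine is monoisotopic and is
therefore never called from envelopes.

The 13C contribution is always modelled: at 19-23 carbons the M+1 peak
(~21-25% of M) rivals the Cl M+2 signal, so naive M+2-only rules misread
halogen-free features.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .chem import (
    ELECTRON_MASS,
    FormulaError,
    IsotopePattern,
    MolecularFormula,
    isotope_pattern,
    parse_formula,
    substitute_halogens,
)
from .spectra import Feature, FeatureTable

__all__ = [
    "DEFAULT_GRID",
    "HalogenCall",
    "classify_halogens",
    "classify_table",
    "envelope_similarity",
    "ion_pattern",
    "write_call_report",
]

Status = Literal["confident", "ambiguous", "no_envelope"]

# candidate (nCl, nBr) grid: Cl 0-3, Br 0-2
DEFAULT_GRID: tuple[tuple[int, int], ...] = tuple(
    (n_cl, n_br) for n_cl in range(4) for n_br in range(3)
)

C13_RATIO = 0.0107 / 0.9893  # M+1/M contribution per carbon


@dataclass(frozen=True)
class HalogenCall:
    """Inferred halogen content for one feature."""

    feature_id: str
    n_cl: int
    n_br: int
    score: float
    margin: float
    status: Status

    def __post_init__(self):
        if self.n_cl < 0 or self.n_br < 0:
            raise ValueError("halogen counts must be non-negative")
        if self.status != "no_envelope" and not 0.0 <= self.score <= 1.0 + 1e-9:
            raise ValueError(f"score out of [0,1]: {self.score}")


@lru_cache(maxsize=4096)
def _cached_pattern(hill: str) -> IsotopePattern:
    return isotope_pattern(parse_formula(hill))


def ion_pattern(neutral: MolecularFormula) -> IsotopePattern:
    """Isotope pattern of the protonated ion ([M+H]+) of a neutral formula."""
    protonated = neutral + MolecularFormula({"H": 1})
    return _cached_pattern(protonated.hill()).shifted(-ELECTRON_MASS)


def envelope_similarity(
    observed: Sequence[tuple[float, float]],
    theoretical: IsotopePattern,
    align_tol: float = 0.01,
) -> float:
    """Cosine between observed and theoretical envelopes over aligned slots.

    Alignment anchors the theoretical base (most intense) peak on an
    observed peak — every observed anchor is tried and the best-scoring
    alignment wins, which tolerates a mispicked monoisotopic peak upstream
    and the near-equal M/M+2 doublet of bromine, where intensity noise can
    swap which peak is the observed base.  Theoretical peaks then claim the
    nearest observed peak within ``align_tol``; unmatched peaks on either
    side contribute a zero on the missing side.  Invariant to uniform
    intensity scaling.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        raise ValueError("observed envelope is empty")
    obs_mz, obs_int = obs[:, 0], obs[:, 1]
    theo_mass = np.asarray(theoretical.masses)
    theo_ab = np.asarray(theoretical.abundances)
    theo_base = theo_mass[int(np.argmax(theo_ab))]
    # anchors: only observed peaks that could plausibly be the base peak
    # (>= half the observed maximum), so wrong candidates cannot shop for a
    # flattering alignment against minor peaks
    anchors = obs_mz[obs_int >= 0.5 * obs_int.max()]
    best = 0.0
    for anchor in anchors:
        best = max(
            best,
            _aligned_cosine(
                obs_mz, obs_int, theo_mass + (anchor - theo_base), theo_ab, align_tol
            ),
        )
    return best


def _aligned_cosine(
    obs_mz: np.ndarray,
    obs_int: np.ndarray,
    aligned: np.ndarray,
    theo_ab: np.ndarray,
    align_tol: float,
) -> float:
    matched_obs = np.full(aligned.size, -1, dtype=int)
    claimed: set[int] = set()
    for k in np.argsort(-theo_ab, kind="stable"):
        dist = np.abs(obs_mz - aligned[k])
        order = np.argsort(dist, kind="stable")
        for j in order:
            if dist[j] > align_tol:
                break
            if j not in claimed:
                matched_obs[k] = j
                claimed.add(j)
                break

    theo_vec = list(theo_ab)
    obs_vec = [obs_int[j] if j >= 0 else 0.0 for j in matched_obs]
    for j in range(obs_mz.size):
        if j not in claimed:
            theo_vec.append(0.0)
            obs_vec.append(obs_int[j])
    tv, ov = np.asarray(theo_vec), np.asarray(obs_vec)
    denom = np.linalg.norm(tv) * np.linalg.norm(ov)
    if denom == 0:
        return 0.0
    return float(np.dot(tv, ov) / denom)


def _estimate_carbon_count(observed: Sequence[tuple[float, float]]) -> int:
    """Carbon count from the M+1/M intensity ratio (13C at 1.07% per C)."""
    obs = sorted(observed)
    if len(obs) < 2 or obs[0][1] <= 0:
        return 20  # fall back to a mid-size metabolite skeleton
    # M+1 is the peak ~1 Da above the first (monoisotopic) envelope peak
    m0_mz, m0_int = obs[0]
    m1 = [i for m, i in obs[1:] if 0.5 < m - m0_mz < 1.5]
    if not m1:
        return 20
    ratio = m1[0] / m0_int
    return max(1, round(ratio / C13_RATIO))


def _candidate_formula(
    base: MolecularFormula | None,
    n_cl: int,
    n_br: int,
    observed: Sequence[tuple[float, float]],
) -> MolecularFormula | None:
    if base is not None:
        try:
            return substitute_halogens(base, n_cl=n_cl, n_br=n_br)
        except FormulaError:
            return None
    n_c = _estimate_carbon_count(observed)
    # formula-free mode: a CnHm stand-in skeleton; H count only needs to be
    # large enough to allow substitution, its isotopes are negligible
    skeleton = MolecularFormula({"C": n_c, "H": max(2 * n_c, n_cl + n_br + 1)})
    return substitute_halogens(skeleton, n_cl=n_cl, n_br=n_br)


def classify_halogens(
    f: Feature,
    mode: Literal["formula_given", "formula_free"] = "formula_free",
    base_formula: MolecularFormula | str | None = None,
    grid: Iterable[tuple[int, int]] = DEFAULT_GRID,
    margin_threshold: float = 0.02,
    align_tol: float = 0.2,
) -> HalogenCall:
    """Best (nCl, nBr) over the candidate grid by envelope similarity.

    ``formula_given`` substitutes halogens onto ``base_formula``;
    ``formula_free`` estimates the carbon count from the M+1/M ratio and
    uses a CnHm stand-in.  ``align_tol`` is generous by default because the
    stand-in skeleton's absolute envelope masses are only approximate; only
    the ~1 Da isotopologue spacing matters after base-peak alignment.
    """
    if mode == "formula_given":
        if base_formula is None:
            raise ValueError("formula_given mode requires base_formula")
        if isinstance(base_formula, str):
            base_formula = parse_formula(base_formula)
    elif base_formula is not None:
        raise ValueError("base_formula only applies in formula_given mode")
    if not f.envelope:
        return HalogenCall(f.id, 0, 0, 0.0, 0.0, "no_envelope")

    scores: list[tuple[float, int, int]] = []
    for n_cl, n_br in grid:
        candidate = _candidate_formula(base_formula, n_cl, n_br, f.envelope)
        if candidate is None:
            continue
        sim = envelope_similarity(f.envelope, ion_pattern(candidate), align_tol)
        scores.append((sim, n_cl, n_br))
    scores.sort(key=lambda t: (-t[0], t[1], t[2]))
    best, runner = scores[0], scores[1] if len(scores) > 1 else (0.0, 0, 0)
    margin = best[0] - runner[0]
    status: Status = "confident" if margin >= margin_threshold else "ambiguous"
    return HalogenCall(f.id, best[1], best[2], best[0], margin, status)


def classify_table(
    features: FeatureTable,
    margin_threshold: float = 0.02,
    grid: Iterable[tuple[int, int]] = DEFAULT_GRID,
) -> dict[str, HalogenCall]:
    """Formula-free halogen calls for every feature in the table."""
    return {
        f.id: classify_halogens(
            f, mode="formula_free", grid=grid, margin_threshold=margin_threshold
        )
        for f in features
    }


def write_call_report(calls: Iterable[HalogenCall], path: str | Path) -> None:
    rows = [
        {
            "id": c.feature_id,
            "n_cl": c.n_cl,
            "n_br": c.n_br,
            "score": f"{c.score:.6f}",
            "margin": f"{c.margin:.6f}",
            "status": c.status,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["id", "n_cl", "n_br", "score", "margin", "status"]
    ).to_csv(path, index=False)
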