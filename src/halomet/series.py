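"""Halogen substitution-series detection (OSMAC H/Cl/Br/I analog sets).

A series groups features interpreted as one scaffold bearing H, Cl, Br or
I at a single position.  Members are linked by the fixed mass shifts of
replacing one H with a halogen, supported by isotope-envelope calls
(Cl/Br), culture-condition evidence (Br from KBr, I from KI — iodine being
monoisotopic leaves no envelope signature), MS/MS similarity to the series
reference member, and the qualitative retention-time ordering
H < Cl < Br < I.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import halogen_shift, ppm_error
from .halogens import HalogenCall, classify_table
from .network import MolecularNetwork, modified_cosine
from .spectra import Feature, FeatureTable, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "HALOGEN_ORDER",
    "MemberEvidence",
    "SubstitutionSeries",
    "find_series",
    "series_report",
    "write_series_csv",
]

HALOGEN_ORDER = ("H", "Cl", "Br", "I")
RtRule = Literal["strict", "warn", "off"]

# condition in which each halogen donor salt is supplied
_EXPECTED_CONDITION = {"Br": "KBr", "I": "KI"}


@dataclass(frozen=True)
class MemberEvidence:
    """Per-member support for its assignment within a series."""

    feature_id: str
    halogen: str
    shift_ppm_error: float
    envelope_call: HalogenCall | None
    msms_cosine: float | None
    condition: str


@dataclass
class SubstitutionSeries:
    """One scaffold's halogen analog set with per-member evidence."""

    series_id: str
    members: dict[str, str]  # halogen -> feature id
    evidence: dict[str, MemberEvidence] = field(default_factory=dict)
    rt_ordered: bool = True

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a series needs at least 2 members")
        unknown = set(self.members) - set(HALOGEN_ORDER)
        if unknown:
            raise ValueError(f"unknown halogen labels: {unknown}")

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(self.members[h] for h in HALOGEN_ORDER if h in self.members)

    def member_set(self) -> frozenset[tuple[str, str]]:
        return frozenset((h, fid) for h, fid in self.members.items())


def _rt_ordered(members: Mapping[str, str], table: FeatureTable) -> bool:
    rts = [table[members[h]].rt for h in HALOGEN_ORDER if h in members]
    return all(b > a for a, b in zip(rts, rts[1:]))


def _envelope_compatible(call: HalogenCall | None, halogen: str) -> bool:
    """Cl/Br members need a supporting envelope call when an envelope exists."""
    if call is None or call.status == "no_envelope":
        return True  # no envelope -> nothing to contradict
    if halogen == "Cl":
        return call.n_cl >= 1
    if halogen == "Br":
        return call.n_br >= 1
    return True  # H and I carry no Cl/Br envelope requirement


def find_series(
    features: FeatureTable,
    ppm_tol: float = 5.0,
    rt_rule: RtRule = "warn",
    min_msms_cosine: float = 0.5,
    require_condition: bool = True,
    frag_tol: float = 0.02,
    calls: Mapping[str, HalogenCall] | None = None,
) -> list[SubstitutionSeries]:
    """Assemble maximal H/Cl/Br/I substitution series from a feature table.

    Every feature seeds a hypothesis for each halogen role it could play;
    partners are sought at the implied H-scaffold m/z plus each halogen
    shift within ``ppm_tol``.  Gates: Cl/Br members must have a compatible
    envelope call; Br/I members must come from the matching salt condition
    when ``require_condition``; members with MS/MS must reach
    ``min_msms_cosine`` against the series reference member.  Series whose
    member maps are subsets of another reported series are dropped, and
    ``rt_rule='strict'`` discards series violating the RT ordering.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if calls is None:
        calls = classify_table(features)

    feats = sorted(features, key=lambda f: (f.mz, f.id))
    mzs = np.array([f.mz for f in feats])
    processed = {
        f.id: preprocess(f.msms) for f in feats if f.msms is not None and len(f.msms)
    }
    shifts = {h: halogen_shift(h) for h in HALOGEN_ORDER}

    def partners(target_mz: float) -> list[Feature]:
        tol = target_mz * ppm_tol * 1e-6
        lo = np.searchsorted(mzs, target_mz - tol, side="left")
        hi = np.searchsorted(mzs, target_mz + tol, side="right")
        return [feats[k] for k in range(lo, hi)]

    candidate_maps: set[frozenset[tuple[str, str]]] = set()
    member_maps: list[dict[str, str]] = []
    for seed, seed_role in itertools.product(feats, HALOGEN_ORDER):
        scaffold_mz = seed.mz - shifts[seed_role]
        if scaffold_mz <= 0:
            continue
        members: dict[str, str] = {}
        for halogen in HALOGEN_ORDER:
            target = scaffold_mz + shifts[halogen]
            best: tuple[float, str] | None = None
            for cand in partners(target):
                if halogen == seed_role and cand.id != seed.id:
                    continue
                if require_condition and halogen in _EXPECTED_CONDITION:
                    if cand.condition != _EXPECTED_CONDITION[halogen]:
                        continue
                if not _envelope_compatible(calls.get(cand.id), halogen):
                    continue
                err = abs(ppm_error(cand.mz, target))
                if best is None or err < best[0]:
                    best = (err, cand.id)
            if best is not None:
                members[halogen] = best[1]
        if seed_role not in members or members[seed_role] != seed.id:
            continue
        if len(members) < 2:
            continue
        key = frozenset(members.items())
        if key not in candidate_maps:
            candidate_maps.add(key)
            member_maps.append(members)

    series_list: list[SubstitutionSeries] = []
    for members in member_maps:
        members = _apply_msms_gate(
            members, processed, min_msms_cosine, frag_tol
        )
        if len(members) < 2:
            continue
        series_list.append(_assemble(members, features, processed, calls, frag_tol))

    # dedupe (msms gating may collapse distinct hypotheses) and drop subsets
    unique: dict[frozenset, SubstitutionSeries] = {}
    for s in series_list:
        unique.setdefault(s.member_set(), s)
    kept = [
        s
        for key, s in unique.items()
        if not any(key < other for other in unique if other != key)
    ]
    if rt_rule == "strict":
        kept = [s for s in kept if s.rt_ordered]
    kept.sort(key=lambda s: (features[s.member_ids[0]].mz, s.member_ids))
    for k, s in enumerate(kept):
        s.series_id = f"S{k:03d}"
    return kept


def _reference_halogen(members: Mapping[str, str]) -> str:
    return next(h for h in HALOGEN_ORDER if h in members)


def _apply_msms_gate(
    members: dict[str, str],
    processed: Mapping[str, object],
    min_msms_cosine: float,
    frag_tol: float,
) -> dict[str, str]:
    ref = _reference_halogen(members)
    ref_spec = processed.get(members[ref])
    if ref_spec is None:
        return members
    kept = {}
    for h, fid in members.items():
        if h == ref:
            kept[h] = fid
            continue
        spec = processed.get(fid)
        if spec is None:
            kept[h] = fid  # no spectrum -> cosine gate not applicable
            continue
        score, _ = modified_cosine(ref_spec, spec, frag_tol=frag_tol)
        if score >= min_msms_cosine:
            kept[h] = fid
    return kept


def _assemble(
    members: dict[str, str],
    features: FeatureTable,
    processed: Mapping[str, object],
    calls: Mapping[str, HalogenCall],
    frag_tol: float,
) -> SubstitutionSeries:
    ref = _reference_halogen(members)
    ref_feat = features[members[ref]]
    ref_spec = processed.get(ref_feat.id)
    evidence: dict[str, MemberEvidence] = {}
    for h, fid in members.items():
        feat = features[fid]
        expected = ref_feat.mz + (halogen_shift(h) - halogen_shift(ref))
        cosine = None
        spec = processed.get(fid)
        if h != ref and ref_spec is not None and spec is not None:
            cosine, _ = modified_cosine(ref_spec, spec, frag_tol=frag_tol)
        evidence[h] = MemberEvidence(
            feature_id=fid,
            halogen=h,
            shift_ppm_error=ppm_error(feat.mz, expected),
            envelope_call=calls.get(fid),
            msms_cosine=cosine,
            condition=feat.condition,
        )
    return SubstitutionSeries(
        series_id="S???",
        members=dict(members),
        evidence=evidence,
        rt_ordered=_rt_ordered(members, features),
    )


def series_report(
    series: Sequence[SubstitutionSeries],
    network: MolecularNetwork | None = None,
    features: FeatureTable | None = None,
) -> pd.DataFrame:
    """One row per member: shifts, ppm errors, RT flag, network component.

    A series whose members land in different network components is marked
    ``split``; members absent from the network are labelled accordingly.
    """
    comp_of = network.component_ids() if network is not None else {}
    rows = []
    for s in series:
        comps = {
            comp_of[fid] for fid in s.member_ids if fid in comp_of
        }
        if network is None:
            comp_label = ""
        elif not comps:
            comp_label = "absent"
        elif len(comps) == 1:
            comp_label = f"component {comps.pop()}"
        else:
            comp_label = "split"
        for h in HALOGEN_ORDER:
            if h not in s.members:
                continue
            ev = s.evidence[h]
            if features is not None and ev.feature_id not in features:
                raise KeyError(f"series {s.series_id}: unknown feature {ev.feature_id}")
            rows.append(
                {
                    "series_id": s.series_id,
                    "halogen": h,
                    "feature_id": ev.feature_id,
                    "shift_da": round(halogen_shift(h), 4),
                    "shift_ppm_error": round(ev.shift_ppm_error, 3),
                    "msms_cosine": (
                        round(ev.msms_cosine, 4) if ev.msms_cosine is not None else ""
                    ),
                    "condition": ev.condition,
                    "rt_ordered": s.rt_ordered,
                    "network_component": comp_label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "series_id",
            "halogen",
            "feature_id",
            "shift_da",
            "shift_ppm_error",
            "msms_cosine",
            "condition",
            "rt_ordered",
            "network_component",
        ],
    )


def write_series_csv(
    series: Sequence[SubstitutionSeries],
    path: str | Path,
    network: MolecularNetwork | None = None,
    features: FeatureTable | None = None,
) -> None:
    series_report(series, network=network, features=features).to_csv(path, index=False)
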