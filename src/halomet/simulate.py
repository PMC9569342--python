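"""Synthetic LC-MS/MS dataset generator with ground truth.

Stands in for the unavailable raw data: protonated scaffold ions with
halogen-substitution analog series (H/Cl/Br/I) at the exact substitution
mass shifts, realistic chlorine/bromine MS1 isotope envelopes, retention
times increasing with halogen size, scaffold-family MS/MS fragments with
shared and halogen-shifted peaks, multiplicative intensity noise,
ppm-scale mass jitter, and unrelated decoy features.  Every distributional
choice here is plumbing; the chemistry (masses, shifts, envelopes) comes
from the element table via :mod:`halomet.chem`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem import (
    MolecularFormula,
    adduct_mz,
    halogen_shift,
    strip_halogens,
    substitute_halogens,
)
from .halogens import HalogenCall, ion_pattern
from .library import load_reference_library
from .series import HALOGEN_ORDER, SubstitutionSeries
from .spectra import (
    Feature,
    FeatureTable,
    MsmsSpectrum,
    write_feature_csv,
    write_mgf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "TruthRecord",
    "generate",
    "generate_dataset",
    "truth_compare",
    "write_truth_tsv",
    "read_truth_tsv",
]

_CONDITION_FOR = {"H": "PDA", "Cl": "NaCl", "Br": "KBr", "I": "KI"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic dataset; defaults give the benchmark set."""

    seed: int = 42
    n_scaffolds: int = 20
    n_full_series: int = 12  # H/Cl/Br/I; the rest are H/Cl/Br (no iodide)
    n_decoys: int = 200
    mass_jitter_ppm: float = 2.0
    envelope_noise: float = 0.05
    n_fragments: int = 10
    shared_fraction: float = 0.6
    shifted_fraction: float = 0.25
    noise_fragments: int = 1
    fragment_intensity_noise: float = 0.1
    fragment_mz_jitter: float = 0.002
    rt_base_range_s: tuple[float, float] = (180.0, 900.0)
    rt_increments_s: Mapping[str, float] = field(
        default_factory=lambda: {"H": 0.0, "Cl": 18.0, "Br": 36.0, "I": 60.0}
    )
    rt_noise_s: float = 4.0
    conditions: tuple[str, ...] = ("PDA", "NaCl", "KBr", "KI")
    envelope_prune: float = 1e-3
    envelope_max_peaks: int = 6

    def __post_init__(self):
        if self.n_full_series > self.n_scaffolds:
            raise ValueError("n_full_series cannot exceed n_scaffolds")
        if self.n_full_series > 0 and "KI" not in self.conditions:
            raise ValueError(
                "iodinated members designed but the KI condition is not enabled"
            )
        if "KBr" not in self.conditions and self.n_scaffolds > 0:
            raise ValueError(
                "brominated members designed but the KBr condition is not enabled"
            )

    def noiseless(self) -> "GeneratorConfig":
        return replace(
            self,
            mass_jitter_ppm=0.0,
            envelope_noise=0.0,
            rt_noise_s=0.0,
            noise_fragments=0,
            fragment_intensity_noise=0.0,
            fragment_mz_jitter=0.0,
        )


@dataclass(frozen=True)
class TruthRecord:
    feature_id: str
    kind: str  # "member" or "decoy"
    scaffold: str
    halogen: str
    formula: str
    condition: str
    series_id: str


@dataclass
class GroundTruth:
    """Per-feature generating facts plus the designed series memberships."""

    records: list[TruthRecord]
    series: dict[str, dict[str, str]]  # series id -> halogen -> feature id

    def by_feature(self) -> dict[str, TruthRecord]:
        return {r.feature_id: r for r in self.records}

    def member_pairs(self) -> set[tuple[str, str]]:
        return {
            (fid, h) for members in self.series.values() for h, fid in members.items()
        }

    def true_halogen_counts(self) -> dict[str, tuple[int, int]]:
        from .chem import parse_formula

        out = {}
        for r in self.records:
            f = parse_formula(r.formula)
            out[r.feature_id] = (f["Cl"], f["Br"])
        return out


def _scaffold_formulas(n: int) -> list[MolecularFormula]:
    """Halogen-free scaffolds drawn from the reference library, extended by
    CH2 homologation when more are requested than the library provides."""
    bases: list[MolecularFormula] = []
    seen: set[str] = set()
    for compound in load_reference_library():
        if compound.formula is None:
            continue
        scaffold = strip_halogens(compound.formula)
        if scaffold.hill() not in seen:
            seen.add(scaffold.hill())
            bases.append(scaffold)
    ch2 = MolecularFormula({"C": 1, "H": 2})
    out: list[MolecularFormula] = []
    k = 0
    while len(out) < n:
        base = bases[k % len(bases)]
        extra = k // len(bases)
        formula = base
        for _ in range(extra):
            formula = formula + ch2
        if formula.hill() not in {f.hill() for f in out}:
            out.append(formula)
        k += 1
    return out


def _member_feature(
    fid: str,
    formula: MolecularFormula,
    rt: float,
    condition: str,
    fragments: Sequence[tuple[float, float, bool]],
    halogen: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> Feature:
    jitter = 1.0 + rng.normal(0.0, cfg.mass_jitter_ppm) * 1e-6
    pattern = ion_pattern(formula)
    keep = min(cfg.envelope_max_peaks, len(pattern.masses))
    ab = np.asarray(pattern.abundances[:keep])
    mask = ab >= cfg.envelope_prune * ab.max()
    masses = np.asarray(pattern.masses[:keep])[mask]
    ab = ab[mask]
    feature_intensity = float(rng.lognormal(mean=np.log(1e5), sigma=0.5))
    env_int = ab * feature_intensity
    if cfg.envelope_noise > 0:
        env_int = env_int * rng.lognormal(0.0, cfg.envelope_noise, size=ab.size)
    envelope = tuple(zip((masses * jitter).tolist(), env_int.tolist()))
    mz = float(masses[0] * jitter)

    shift = halogen_shift(halogen)
    frag_mz, frag_int = [], []
    for fmz, finten, carries_halogen in fragments:
        m = fmz + (shift if carries_halogen else 0.0)
        if cfg.fragment_mz_jitter > 0:
            m += rng.normal(0.0, cfg.fragment_mz_jitter)
        inten = finten
        if cfg.fragment_intensity_noise > 0:
            inten *= float(rng.lognormal(0.0, cfg.fragment_intensity_noise))
        frag_mz.append(m)
        frag_int.append(inten)
    for _ in range(cfg.noise_fragments):
        frag_mz.append(float(rng.uniform(80.0, mz - 30.0)))
        frag_int.append(float(rng.uniform(0.05, 0.3)) * max(frag_int, default=1.0))
    order = np.argsort(frag_mz)
    msms = MsmsSpectrum(
        precursor_mz=mz,
        mz=np.asarray(frag_mz)[order],
        intensity=np.asarray(frag_int)[order],
        rt=rt,
        id=fid,
    )
    return Feature(
        id=fid,
        mz=mz,
        rt=rt,
        intensity=feature_intensity,
        envelope=envelope,
        msms=msms,
        condition=condition,
    )


def _random_decoy_formula(rng: np.random.Generator) -> MolecularFormula:
    counts = {"C": int(rng.integers(12, 30))}
    counts["H"] = int(rng.integers(counts["C"], 2 * counts["C"] + 2))
    counts["O"] = int(rng.integers(0, 9))
    if rng.random() < 0.3:
        counts["N"] = int(rng.integers(1, 3))
    if rng.random() < 0.2:
        counts["Cl"] = 1
    elif rng.random() < 0.1:
        counts["Br"] = 1
    return MolecularFormula({el: n for el, n in counts.items() if n > 0})


def generate(cfg: GeneratorConfig) -> tuple[FeatureTable, GroundTruth]:
    """Build the synthetic feature table and its ground truth in memory."""
    rng = np.random.default_rng(cfg.seed)
    scaffolds = _scaffold_formulas(cfg.n_scaffolds)
    features: list[Feature] = []
    records: list[TruthRecord] = []
    series: dict[str, dict[str, str]] = {}

    for idx, scaffold in enumerate(scaffolds):
        halogens = (
            HALOGEN_ORDER if idx < cfg.n_full_series else tuple(
                h for h in HALOGEN_ORDER if h != "I"
            )
        )
        scaffold_id = f"scaffold{idx:02d}"
        series_id = f"T{idx:03d}"
        base_rt = float(rng.uniform(*cfg.rt_base_range_s))
        n_shared = round(cfg.n_fragments * cfg.shared_fraction)
        n_shifted = round(cfg.n_fragments * cfg.shifted_fraction)
        base_mz = adduct_mz(scaffold)
        frag_positions = np.sort(
            rng.uniform(100.0, max(200.0, base_mz - 40.0), size=cfg.n_fragments)
        )
        frag_intensities = rng.lognormal(mean=0.0, sigma=0.6, size=cfg.n_fragments)
        carries = np.zeros(cfg.n_fragments, dtype=bool)
        carries[n_shared : n_shared + n_shifted] = True
        fragments = list(
            zip(frag_positions.tolist(), frag_intensities.tolist(), carries.tolist())
        )
        members: dict[str, str] = {}
        for halogen in halogens:
            fid = f"F{idx:02d}{halogen}"
            formula = (
                scaffold
                if halogen == "H"
                else substitute_halogens(
                    scaffold,
                    n_cl=int(halogen == "Cl"),
                    n_br=int(halogen == "Br"),
                    n_i=int(halogen == "I"),
                )
            )
            rt = base_rt + cfg.rt_increments_s[halogen]
            if cfg.rt_noise_s > 0:
                rt += float(rng.normal(0.0, cfg.rt_noise_s))
            condition = _CONDITION_FOR[halogen]
            feat = _member_feature(
                fid, formula, rt, condition, fragments, halogen, cfg, rng
            )
            features.append(feat)
            members[halogen] = fid
            records.append(
                TruthRecord(
                    fid, "member", scaffold_id, halogen, formula.hill(), condition,
                    series_id,
                )
            )
        series[series_id] = members

    for d in range(cfg.n_decoys):
        fid = f"D{d:03d}"
        formula = _random_decoy_formula(rng)
        rt = float(rng.uniform(*cfg.rt_base_range_s))
        condition = str(rng.choice(list(cfg.conditions)))
        n_frag = int(rng.integers(6, 14))
        mz0 = adduct_mz(formula)
        frag_positions = np.sort(rng.uniform(80.0, max(150.0, mz0 - 40.0), size=n_frag))
        frag_intensities = rng.lognormal(0.0, 0.6, size=n_frag)
        fragments = [
            (float(m), float(i), False)
            for m, i in zip(frag_positions, frag_intensities)
        ]
        feat = _member_feature(fid, formula, rt, condition, fragments, "H", cfg, rng)
        features.append(feat)
        records.append(
            TruthRecord(fid, "decoy", "", "", formula.hill(), condition, "")
        )

    table = FeatureTable(features, provenance={"generator_seed": cfg.seed})
    return table, GroundTruth(records, series)


def write_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "feature_id\tkind\tscaffold\thalogen\tformula\tcondition\tseries_id\n"
        )
        for r in truth.records:
            handle.write(
                f"{r.feature_id}\t{r.kind}\t{r.scaffold}\t{r.halogen}\t"
                f"{r.formula}\t{r.condition}\t{r.series_id}\n"
            )


def read_truth_tsv(path: str | Path) -> GroundTruth:
    records: list[TruthRecord] = []
    series: dict[str, dict[str, str]] = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("feature_id"):
            raise ValueError("not a truth TSV: bad header")
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            r = TruthRecord(*fields)
            records.append(r)
            if r.kind == "member":
                series.setdefault(r.series_id, {})[r.halogen] = r.feature_id
    return GroundTruth(records, series)


def generate_dataset(
    cfg: GeneratorConfig, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Write the feature CSV, MGF and truth TSV; returns the three paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = generate(cfg)
    csv_path = outdir / "features.csv"
    mgf_path = outdir / "spectra.mgf"
    truth_path = outdir / "truth.tsv"
    write_feature_csv(table, csv_path)
    write_mgf([f.msms for f in table if f.msms is not None], mgf_path)
    write_truth_tsv(truth, truth_path)
    return csv_path, mgf_path, truth_path


def truth_compare(
    truth: GroundTruth,
    series: Sequence[SubstitutionSeries] | None = None,
    calls: Mapping[str, HalogenCall] | None = None,
) -> dict:
    """Precision/recall of predicted series and a halogen-call confusion map.

    Member-level counts compare (feature id, halogen) assignments; the
    series level requires exact member-set equality.  With zero predictions
    precision is reported as 1.0 (zero support), so recall carries the
    signal.
    """
    known = {r.feature_id for r in truth.records}
    summary: dict = {}
    if series is not None:
        pred_pairs: set[tuple[str, str]] = set()
        for s in series:
            for h, fid in s.members.items():
                if fid not in known:
                    raise KeyError(f"predicted feature id not in truth: {fid}")
                pred_pairs.add((fid, h))
        true_pairs = truth.member_pairs()
        tp = len(pred_pairs & true_pairs)
        member_precision = tp / len(pred_pairs) if pred_pairs else 1.0
        if not pred_pairs:
            logger.info("no predicted members; precision reported as 1.0 (no support)")
        member_recall = tp / len(true_pairs) if true_pairs else 1.0
        pred_sets = {frozenset(s.members.items()) for s in series}
        true_sets = {frozenset(m.items()) for m in truth.series.values()}
        stp = len(pred_sets & true_sets)
        summary.update(
            member_precision=member_precision,
            member_recall=member_recall,
            member_tp=tp,
            n_predicted_members=len(pred_pairs),
            n_true_members=len(true_pairs),
            series_precision=stp / len(pred_sets) if pred_sets else 1.0,
            series_recall=stp / len(true_sets) if true_sets else 1.0,
        )
    if calls is not None:
        truth_counts = truth.true_halogen_counts()
        confusion: dict[str, int] = {}
        n_correct = n_total = 0
        for fid, call in calls.items():
            if fid not in truth_counts:
                raise KeyError(f"called feature id not in truth: {fid}")
            true_cl, true_br = truth_counts[fid]
            key = f"true={true_cl}Cl{true_br}Br|called={call.n_cl}Cl{call.n_br}Br"
            confusion[key] = confusion.get(key, 0) + 1
            n_total += 1
            if (call.n_cl, call.n_br) == (true_cl, true_br):
                n_correct += 1
        summary["call_accuracy"] = n_correct / n_total if n_total else 1.0
        summary["call_confusion"] = dict(sorted(confusion.items()))
    return summary
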