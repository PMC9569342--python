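"""Dereplication against the packaged reference-compound table.

The library transcribes the main-text compound list (numbers 1-22).
Entries whose molecular formula was never printed are carried name-only
and excluded from exact-mass matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import MolecularFormula, adduct_mz, parse_formula, ppm_error
from .network import modified_cosine
from .spectra import Feature, FeatureTable, MsmsSpectrum, preprocess

__all__ = [
    "Annotation",
    "ReferenceCompound",
    "annotate_table",
    "load_reference_library",
    "match_library",
    "write_annotation_csv",
]


@dataclass(frozen=True)
class ReferenceCompound:
    name: str
    number: int
    formula: MolecularFormula | None
    family: str
    halogens: str
    note: str = ""

    @property
    def mz(self) -> float | None:
        """Theoretical protonated m/z, or None for name-only entries."""
        return adduct_mz(self.formula) if self.formula is not None else None


@dataclass(frozen=True)
class Annotation:
    feature_id: str
    compound: ReferenceCompound
    ppm: float
    cosine: float | None = None


@lru_cache(maxsize=1)
def load_reference_library() -> tuple[ReferenceCompound, ...]:
    text = (
        resources.files("halomet.data")
        .joinpath("reference_compounds.tsv")
        .read_text()
    )
    compounds = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        number, name, formula, family, halogens, note = line.split("\t")
        compounds.append(
            ReferenceCompound(
                name=name,
                number=int(number),
                formula=parse_formula(formula) if formula else None,
                family=family,
                halogens=halogens,
                note=note,
            )
        )
    return tuple(compounds)


def match_library(
    f: Feature,
    lib: Sequence[ReferenceCompound] | None = None,
    ppm_tol: float = 5.0,
    min_cosine: float = 0.0,
    reference_spectra: dict[int, MsmsSpectrum] | None = None,
) -> list[Annotation]:
    """Rank library candidates for one feature by |ppm error| then cosine.

    All isobaric candidates within ``ppm_tol`` are reported.  When both a
    reference spectrum and the feature's MS/MS exist, candidates below
    ``min_cosine`` are dropped.
    """
    if lib is None:
        lib = load_reference_library()
    if not lib:
        raise ValueError("reference library is empty")
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    hits = []
    for compound in lib:
        theo = compound.mz
        if theo is None:
            continue
        ppm = ppm_error(f.mz, theo)
        if abs(ppm) > ppm_tol:
            continue
        cosine = None
        if (
            reference_spectra is not None
            and compound.number in reference_spectra
            and f.msms is not None
            and len(f.msms)
        ):
            cosine, _ = modified_cosine(
                preprocess(f.msms), preprocess(reference_spectra[compound.number])
            )
            if cosine < min_cosine:
                continue
        hits.append(Annotation(f.id, compound, ppm, cosine))
    hits.sort(
        key=lambda a: (
            abs(a.ppm),
            -(a.cosine if a.cosine is not None else 0.0),
            a.compound.number,
        )
    )
    return hits


def annotate_table(
    features: FeatureTable,
    lib: Sequence[ReferenceCompound] | None = None,
    ppm_tol: float = 5.0,
) -> list[Annotation]:
    out: list[Annotation] = []
    for f in features:
        out.extend(match_library(f, lib=lib, ppm_tol=ppm_tol))
    return out


def write_annotation_csv(annotations: Iterable[Annotation], path: str | Path) -> None:
    rows = [
        {
            "feature_id": a.feature_id,
            "compound_number": a.compound.number,
            "compound_name": a.compound.name,
            "formula": a.compound.formula.hill() if a.compound.formula else "",
            "family": a.compound.family,
            "ppm_error": f"{a.ppm:.3f}",
            "cosine": f"{a.cosine:.4f}" if a.cosine is not None else "",
        }
        for a in annotations
    ]
    pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "compound_number",
            "compound_name",
            "formula",
            "family",
            "ppm_error",
            "cosine",
        ],
    ).to_csv(path, index=False)
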