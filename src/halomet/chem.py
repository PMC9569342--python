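"""Molecular formulas, exact masses, isotopologue patterns, formula search.

All mass arithmetic in the package flows through the packaged element
isotope table (``data/isotopes.tsv``), so results are reproducible and do
not drift with external library versions.  Protonated ions use the proton
mass (hydrogen atom minus electron), i.e. electron correction is applied.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "AdductSpec",
    "ElementIsotopeTable",
    "FormulaError",
    "IsotopePattern",
    "MolecularFormula",
    "adduct_mz",
    "enumerate_formulas",
    "halogen_shift",
    "isotope_pattern",
    "isotope_pattern_brute_force",
    "monoisotopic_mass",
    "parse_formula",
    "ppm_error",
    "rdbe",
    "strip_halogens",
    "substitute_halogens",
]

ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.0078250319 - ELECTRON_MASS

_HILL_FIRST = ("C", "H")


class FormulaError(ValueError):
    """Raised for unparsable or chemically unsupported formulas."""


class ElementIsotopeTable:
    """Per-element isotope masses and abundances from the packaged table."""

    def __init__(self, entries: Mapping[str, Sequence[tuple[float, float]]]):
        self._entries = {el: tuple(iso) for el, iso in entries.items()}
        for el, isotopes in self._entries.items():
            total = sum(ab for _, ab in isotopes)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances for {el} sum to {total}, not 1")

    @classmethod
    def from_package(cls) -> "ElementIsotopeTable":
        text = (
            resources.files("halomet.data").joinpath("isotopes.tsv").read_text()
        )
        entries: dict[str, list[tuple[float, float]]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            el, mass, ab = line.split("\t")
            entries.setdefault(el, []).append((float(mass), float(ab)))
        return cls(entries)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def isotopes(self, element: str) -> tuple[tuple[float, float], ...]:
        try:
            return self._entries[element]
        except KeyError:
            raise FormulaError(f"unsupported element symbol: {element!r}") from None

    def monoisotopic(self, element: str) -> float:
        return self.isotopes(element)[0][0]


ISOTOPES = ElementIsotopeTable.from_package()

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Immutable element → count map restricted to the supported elements."""

    counts: Mapping[str, int]

    def __post_init__(self):
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in ISOTOPES.elements:
                raise FormulaError(f"unsupported element symbol: {el!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer")
            if n > 0:
                clean[el] = int(n)
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def replace(self, **changes: int) -> "MolecularFormula":
        merged = dict(self.counts)
        merged.update(changes)
        return MolecularFormula(merged)

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        parts = []
        rest = sorted(el for el in self.counts if el not in _HILL_FIRST)
        order = [el for el in _HILL_FIRST if el in self.counts] + rest
        if "C" not in self.counts:
            order = sorted(self.counts)
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C21H23ClO5"``."""
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN_RE.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"unparsable formula segment: {text[pos:]!r}")
        if not match.group(0):
            break
        el, digits = match.groups()
        if el not in ISOTOPES.elements:
            raise FormulaError(f"unsupported element symbol: {el!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"count for {el} must be positive, got {n}")
        counts[el] = counts.get(el, 0) + n
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"unparsable formula segment: {text[pos:]!r}")
    return MolecularFormula(counts)


@dataclass(frozen=True)
class AdductSpec:
    """Positive-mode adduct description; only protonation is required."""

    name: str = "[M+H]+"
    proton_delta: int = 1
    charge: int = 1

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


ADDUCTS = {"[M+H]+": AdductSpec("[M+H]+", proton_delta=1, charge=1)}


def get_adduct(name: str) -> AdductSpec:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise ValueError(f"unsupported adduct: {name!r}") from None


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass: sum of lightest-isotope masses."""
    return sum(n * ISOTOPES.monoisotopic(el) for el, n in f.counts.items())


def adduct_mz(f: MolecularFormula, adduct: AdductSpec | str = "[M+H]+") -> float:
    """m/z of the adduct ion, electron-corrected via the proton mass."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return (monoisotopic_mass(f) + adduct.proton_delta * PROTON_MASS) / adduct.charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million, (obs - theo) / theo."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue envelope: (mass, abundance) pairs, ascending mass."""

    masses: tuple[float, ...]
    abundances: tuple[float, ...]
    provenance: str = ""
    prune_threshold: float = 0.0

    def __post_init__(self):
        if len(self.masses) != len(self.abundances):
            raise ValueError("masses and abundances differ in length")
        if any(b <= a for a, b in zip(self.masses, self.masses[1:])):
            raise ValueError("masses must be strictly increasing")
        if any(not (0.0 < ab <= 1.0) for ab in self.abundances):
            raise ValueError("abundances must lie in (0, 1]")

    @property
    def peaks(self) -> tuple[tuple[float, float], ...]:
        return tuple(zip(self.masses, self.abundances))

    @property
    def base_index(self) -> int:
        return int(np.argmax(self.abundances))

    def shifted(self, delta: float) -> "IsotopePattern":
        return IsotopePattern(
            tuple(m + delta for m in self.masses),
            self.abundances,
            provenance=self.provenance,
            prune_threshold=self.prune_threshold,
        )


def _merge_sorted(masses: np.ndarray, abundances: np.ndarray, tol: float):
    """Cluster mass-sorted peaks where consecutive gaps <= tol; weighted mean."""
    if masses.size == 0:
        return masses, abundances
    order = np.argsort(masses, kind="stable")
    masses, abundances = masses[order], abundances[order]
    boundaries = np.nonzero(np.diff(masses) > tol)[0] + 1
    groups = np.concatenate([[0], boundaries, [masses.size]])
    out_m = np.empty(groups.size - 1)
    out_a = np.empty(groups.size - 1)
    for k in range(groups.size - 1):
        sl = slice(groups[k], groups[k + 1])
        a = abundances[sl]
        out_a[k] = a.sum()
        out_m[k] = float(np.average(masses[sl], weights=a))
    return out_m, out_a


def _convolve(da, db, fine_tol=1e-9, floor=1e-14):
    masses = (da[0][:, None] + db[0][None, :]).ravel()
    ab = (da[1][:, None] * db[1][None, :]).ravel()
    masses, ab = _merge_sorted(masses, ab, fine_tol)
    keep = ab >= floor
    # keep the floor loss far below the 1e-9 normalization budget
    return masses[keep], ab[keep]


def _atom_distribution(element: str, n: int):
    isotopes = ISOTOPES.isotopes(element)
    single = (
        np.array([m for m, _ in isotopes]),
        np.array([a for _, a in isotopes]),
    )
    result = (np.zeros(1), np.ones(1))
    power = single
    while n:
        if n & 1:
            result = _convolve(result, power)
        n >>= 1
        if n:
            power = _convolve(power, power)
    return result


def isotope_pattern(
    f: MolecularFormula,
    prune: float = 1e-4,
    merge_tol: float = 0.05,
) -> IsotopePattern:
    """Full isotopologue distribution of ``f`` by per-element convolution.

    Isotopologues closer than ``merge_tol`` are merged at abundance-weighted
    mass; peaks below ``prune`` times the base-peak abundance are dropped.
    With ``prune=0`` abundances sum to 1 within 1e-9.
    """
    if not 0.0 <= prune < 1.0:
        raise ValueError("prune must lie in [0, 1)")
    if merge_tol <= 0:
        raise ValueError("merge_tol must be positive")
    dist = (np.zeros(1), np.ones(1))
    for el, n in sorted(f.counts.items()):
        dist = _convolve(dist, _atom_distribution(el, n))
    masses, ab = _merge_sorted(dist[0], dist[1], merge_tol)
    if prune > 0:
        keep = ab >= prune * ab.max()
        masses, ab = masses[keep], ab[keep]
    return IsotopePattern(
        tuple(masses), tuple(ab), provenance=f.hill(), prune_threshold=prune
    )


def isotope_pattern_brute_force(
    f: MolecularFormula, prune: float = 0.0, merge_tol: float = 0.05
) -> IsotopePattern:
    """Reference implementation: explicit enumeration over every atom.

    Exponential in the number of polyisotopic atoms; intended as a test
    oracle for small formulas only.
    """
    atoms: list[tuple[tuple[float, float], ...]] = []
    for el, n in sorted(f.counts.items()):
        atoms.extend([ISOTOPES.isotopes(el)] * n)
    masses, abundances = [], []
    for combo in itertools.product(*atoms):
        masses.append(sum(m for m, _ in combo))
        ab = 1.0
        for _, a in combo:
            ab *= a
        abundances.append(ab)
    m, a = _merge_sorted(np.array(masses), np.array(abundances), 1e-9)
    m, a = _merge_sorted(m, a, merge_tol)
    if prune > 0:
        keep = a >= prune * a.max()
        m, a = m[keep], a[keep]
    return IsotopePattern(tuple(m), tuple(a), provenance=f.hill() + " (brute force)")


def rdbe(f: MolecularFormula) -> float:
    """Ring and double bond equivalents for CHNOPS + halogen chemistry."""
    monovalent = f["H"] + f["Cl"] + f["Br"] + f["I"]
    return f["C"] + 1 - monovalent / 2 + f["N"] / 2


DEFAULT_BOUNDS: dict[str, int] = {
    "C": 40, "H": 60, "N": 3, "O": 12, "S": 1, "Cl": 3, "Br": 2, "I": 2,
}
DEFAULT_RDBE_RANGE = (0.0, 25.0)


def enumerate_formulas(
    target_mz: float,
    adduct: AdductSpec | str = "[M+H]+",
    tol_ppm: float = 5.0,
    bounds: Mapping[str, int] | None = None,
    rdbe_range: tuple[float, float] = DEFAULT_RDBE_RANGE,
) -> list[tuple[MolecularFormula, float]]:
    """All formulas within ``bounds`` whose adduct ion matches ``target_mz``.

    Returns (formula, ppm error) pairs sorted by absolute ppm error.
    Depth-first search over element counts with mass-bound pruning; the
    RDBE window filters chemically implausible candidates.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    if not bounds or all(v <= 0 for v in bounds.values()):
        raise ValueError("bounds must allow at least one atom")
    for el in bounds:
        ISOTOPES.isotopes(el)  # raises FormulaError on unknown symbols

    neutral_target = target_mz * adduct.charge - adduct.proton_delta * PROTON_MASS
    tol_da = target_mz * tol_ppm * 1e-6 * adduct.charge
    elements = sorted(bounds, key=lambda el: -ISOTOPES.monoisotopic(el))
    masses = [ISOTOPES.monoisotopic(el) for el in elements]
    results: list[tuple[MolecularFormula, float]] = []

    def descend(idx: int, acc_mass: float, acc: dict[str, int]) -> None:
        if idx == len(elements):
            if abs(acc_mass - neutral_target) <= tol_da and acc:
                candidate = MolecularFormula(dict(acc))
                if rdbe_range[0] <= rdbe(candidate) <= rdbe_range[1]:
                    results.append(
                        (candidate, ppm_error(adduct_mz(candidate, adduct), target_mz))
                    )
            return
        el, m = elements[idx], masses[idx]
        # remaining elements can only add mass, so prune on the lower edge
        max_n = min(bounds[el], int((neutral_target + tol_da - acc_mass) / m))
        for n in range(max_n + 1):
            if n:
                acc[el] = n
            descend(idx + 1, acc_mass + n * m, acc)
        acc.pop(el, None)

    descend(0, 0.0, {})
    results.sort(key=lambda item: (abs(item[1]), item[0].hill()))
    return results


_HALOGENS = ("Cl", "Br", "I")


def halogen_shift(halogen: str) -> float:
    """Mass added when one H of a scaffold is replaced by ``halogen``."""
    if halogen == "H":
        return 0.0
    if halogen not in _HALOGENS:
        raise ValueError(f"not a supported halogen: {halogen!r}")
    return ISOTOPES.monoisotopic(halogen) - ISOTOPES.monoisotopic("H")


def strip_halogens(f: MolecularFormula) -> MolecularFormula:
    """Replace every Cl/Br/I atom with H, giving the halogen-free scaffold."""
    n_hal = sum(f[x] for x in _HALOGENS)
    if n_hal == 0:
        return f
    counts = {el: n for el, n in f.counts.items() if el not in _HALOGENS}
    counts["H"] = counts.get("H", 0) + n_hal
    return MolecularFormula(counts)


def substitute_halogens(
    base: MolecularFormula, n_cl: int = 0, n_br: int = 0, n_i: int = 0
) -> MolecularFormula:
    """Substitute H atoms of the halogen-free form of ``base`` with halogens."""
    scaffold = strip_halogens(base)
    total = n_cl + n_br + n_i
    if total > scaffold["H"]:
        raise FormulaError(
            f"cannot substitute {total} H atoms: {scaffold.hill()} has {scaffold['H']}"
        )
    counts = dict(scaffold.counts)
    counts["H"] -= total
    if counts["H"] == 0:
        del counts["H"]
    for el, n in (("Cl", n_cl), ("Br", n_br), ("I", n_i)):
        if n:
            counts[el] = counts.get(el, 0) + n
    return MolecularFormula(counts)
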