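import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halomet.chem import (
    ISOTOPES,
    PROTON_MASS,
    FormulaError,
    MolecularFormula,
    adduct_mz,
    enumerate_formulas,
    halogen_shift,
    isotope_pattern,
    isotope_pattern_brute_force,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    rdbe,
    strip_halogens,
    substitute_halogens,
)


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C23H32O4", {"C": 23, "H": 32, "O": 4}),
            ("H2O", {"H": 2, "O": 1}),
            ("C21H23ClO5", {"C": 21, "H": 23, "Cl": 1, "O": 5}),
            ("C23H23BrO5", {"C": 23, "H": 23, "Br": 1, "O": 5}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_examples(self, text, expected):
        assert dict(parse_formula(text).counts) == expected

    def test_round_trips_to_hill(self):
        for text in ["C23H32O4", "C21H23ClO5", "C23H23BrO5", "H2O", "CHBrClINaO"]:
            assert parse_formula(text).hill() == text

    def test_unknown_element_named_in_error(self):
        with pytest.raises(FormulaError, match="Xe"):
            parse_formula("C2Xe3")

    def test_zero_count_rejected(self):
        with pytest.raises(FormulaError):
            parse_formula("C0H4")

    @pytest.mark.parametrize("bad", ["", "  ", "12C", "C-3", "c2h4"])
    def test_garbage_rejected(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_empty_formula_object_rejected(self):
        with pytest.raises(FormulaError):
            MolecularFormula({})


@st.composite
def formulas(draw, max_count=8):
    elements = draw(
        st.lists(
            st.sampled_from(["C", "H", "N", "O", "S", "Cl", "Br", "I"]),
            min_size=1,
            max_size=4,
            unique=True,
        )
    )
    counts = {el: draw(st.integers(1, max_count)) for el in elements}
    return MolecularFormula(counts)


@given(formulas())
@settings(max_examples=100, deadline=None)
def test_hill_string_round_trip(f):
    assert parse_formula(f.hill()).counts == f.counts


class TestMasses:
    def test_hydrogen_atom(self):
        assert monoisotopic_mass(parse_formula("H")) == pytest.approx(
            1.007825, abs=5e-7
        )

    def test_carbon_12_scale(self):
        assert monoisotopic_mass(parse_formula("C")) == 12.0

    def test_grifolic_acid_neutral(self):
        # hand sum: 23*12 + 32*1.0078250319 + 4*15.9949146196
        expected = 23 * 12 + 32 * 1.0078250319 + 4 * 15.9949146196
        assert monoisotopic_mass(parse_formula("C23H32O4")) == pytest.approx(expected)
        assert round(monoisotopic_mass(parse_formula("C23H32O4")), 4) == 372.2301

    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C23H32O4", 373.2373),
            ("C23H23BrO5", 459.0802),
            ("C19H24O4", 317.1747),
            ("C23H32O3", 357.2424),
            ("C21H23ClO5", 391.1307),
        ],
    )
    def test_protonated_mz(self, formula, expected):
        assert round(adduct_mz(parse_formula(formula)), 4) == expected

    @given(formulas())
    @settings(max_examples=50, deadline=None)
    def test_protonation_adds_proton_mass(self, f):
        assert adduct_mz(f) - monoisotopic_mass(f) == pytest.approx(
            PROTON_MASS, abs=1e-12
        )

    def test_unsupported_adduct(self):
        with pytest.raises(ValueError):
            adduct_mz(parse_formula("H2O"), "[M+NH4]+")


class TestPpmError:
    def test_identity_is_exactly_zero(self):
        assert ppm_error(373.2373, 373.2373) == 0.0

    def test_positive_error(self):
        assert round(ppm_error(373.2380, 373.2373), 1) == 1.9

    def test_negative_error(self):
        assert round(ppm_error(459.0798, 459.0802), 1) == -0.9

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


def assert_patterns_match(fast, slow, ab_tol=1e-9, floor=1e-9):
    """Peak-wise equality; isotopologues below ``floor`` may be absent."""
    slow_peaks = [(m, a) for m, a in slow.peaks if a > floor]
    fast_peaks = [(m, a) for m, a in fast.peaks if a > floor]
    assert len(fast_peaks) == len(slow_peaks)
    for (mf, af), (ms, as_) in zip(fast_peaks, slow_peaks):
        # weighted-mean masses may group slightly differently between routes
        assert mf == pytest.approx(ms, abs=1e-4)
        assert af == pytest.approx(as_, abs=ab_tol)


class TestIsotopePattern:
    def test_single_chlorine(self):
        p = isotope_pattern(parse_formula("Cl"))
        assert [round(m, 4) for m in p.masses] == [34.9689, 36.9659]
        assert p.abundances == pytest.approx((0.7577, 0.2423))

    def test_two_chlorines_binomial(self):
        p = isotope_pattern(parse_formula("Cl2"))
        # (0.7577 + 0.2423)^2 expanded
        assert p.abundances == pytest.approx(
            (0.7577**2, 2 * 0.7577 * 0.2423, 0.2423**2), abs=1e-12
        )

    def test_abundances_sum_to_one_unpruned(self):
        rng = np.random.default_rng(7)
        symbols = ["C", "H", "N", "O", "S", "Cl", "Br", "I"]
        for _ in range(200):
            els = rng.choice(symbols, size=rng.integers(1, 5), replace=False)
            f = MolecularFormula({el: int(rng.integers(1, 21)) for el in els})
            p = isotope_pattern(f, prune=0.0)
            assert sum(p.abundances) == pytest.approx(1.0, abs=1e-9)

    def test_masses_strictly_increasing(self):
        p = isotope_pattern(parse_formula("C21H23ClO5"), prune=0.0)
        assert all(b > a for a, b in zip(p.masses, p.masses[1:]))

    def test_invalid_parameters(self):
        f = parse_formula("CH4")
        with pytest.raises(ValueError):
            isotope_pattern(f, prune=1.0)
        with pytest.raises(ValueError):
            isotope_pattern(f, merge_tol=0.0)

    def test_matches_brute_force_enumeration(self):
        """Oracle equivalence on 50 random small formulas (<=12 polyisotopic)."""
        rng = np.random.default_rng(11)
        poly = ["C", "Cl", "Br", "S", "N", "O"]
        for _ in range(50):
            els = rng.choice(poly, size=rng.integers(1, 4), replace=False)
            counts = {}
            budget = 12
            for el in els:
                n = int(rng.integers(1, min(6, budget) + 1))
                counts[el] = n
                budget -= n
                if budget <= 0:
                    break
            counts["H"] = int(rng.integers(1, 4))  # near-monoisotopic, cheap
            f = MolecularFormula(counts)
            assert_patterns_match(
                isotope_pattern(f, prune=0.0), isotope_pattern_brute_force(f, prune=0.0)
            )

    def test_additivity_under_convolution(self):
        """Pattern of f1+f2 equals the brute-force pattern of the union."""
        pairs = [("C3Cl2", "C2Br"), ("C4S", "Cl3"), ("C5N2", "C2OCl")]
        for a, b in pairs:
            combined = parse_formula(a) + parse_formula(b)
            assert_patterns_match(
                isotope_pattern(combined, prune=0.0),
                isotope_pattern_brute_force(combined, prune=0.0),
            )

    def test_pruning_drops_minor_peaks(self):
        f = parse_formula("C30H40Cl2O6")
        full = isotope_pattern(f, prune=0.0)
        pruned = isotope_pattern(f, prune=1e-2)
        assert len(pruned.masses) < len(full.masses)
        threshold = 1e-2 * max(pruned.abundances)
        assert all(ab >= threshold for ab in pruned.abundances)


class TestEnumerateFormulas:
    def test_recovers_grifolic_acid(self):
        hits = enumerate_formulas(
            373.2373, tol_ppm=5.0, bounds={"C": 30, "H": 60, "O": 10},
            rdbe_range=(0, 20),
        )
        assert "C23H32O4" in {f.hill() for f, _ in hits}

    def test_infeasible_bounds_empty(self):
        assert enumerate_formulas(373.2373, tol_ppm=0.01, bounds={"C": 3}) == []

    def test_recovers_brominated_azaphilone(self):
        hits = enumerate_formulas(
            459.0802, tol_ppm=3.0, bounds={"C": 30, "H": 40, "O": 8, "Br": 1}
        )
        assert "C23H23BrO5" in {f.hill() for f, _ in hits}

    def test_sorted_by_abs_ppm(self):
        hits = enumerate_formulas(373.2373, tol_ppm=20.0)
        errors = [abs(ppm) for _, ppm in hits]
        assert errors == sorted(errors)

    def test_matches_exhaustive_loop_oracle(self):
        bounds = {"C": 12, "H": 20, "O": 4, "Cl": 1}
        target, tol = 173.0364, 10.0
        oracle = set()
        for c, h, o, cl in itertools.product(
            range(13), range(21), range(5), range(2)
        ):
            if c + h + o + cl == 0:
                continue
            counts = {k: v for k, v in zip("CHOX", (c, h, o, cl)) if v}
            counts = {("Cl" if k == "X" else k): v for k, v in counts.items()}
            try:
                f = MolecularFormula(counts)
            except FormulaError:
                continue
            if abs(ppm_error(adduct_mz(f), target)) <= tol and 0 <= rdbe(f) <= 25:
                oracle.add(f.hill())
        hits = {f.hill() for f, _ in enumerate_formulas(target, tol_ppm=tol, bounds=bounds)}
        assert hits == oracle

    def test_empty_bounds_rejected(self):
        with pytest.raises(ValueError):
            enumerate_formulas(373.2373, bounds={})

    def test_generating_formula_always_recovered(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n_c = int(rng.integers(10, 25))
            f = MolecularFormula(
                {
                    "C": n_c,
                    "H": int(rng.integers(12, 2 * n_c + 2)),
                    "O": int(rng.integers(1, 7)),
                }
            )
            jitter = 1.0 + float(rng.normal(0, 2e-6))
            hits = enumerate_formulas(adduct_mz(f) * jitter, tol_ppm=8.0)
            assert f.hill() in {c.hill() for c, _ in hits}


class TestHalogenShift:
    @pytest.mark.parametrize(
        "halogen,expected",
        [("Cl", 33.9610), ("Br", 77.9105), ("I", 125.8966)],
    )
    def test_values(self, halogen, expected):
        assert round(halogen_shift(halogen), 4) == expected

    def test_hydrogen_is_zero(self):
        assert halogen_shift("H") == 0.0

    def test_other_elements_rejected(self):
        with pytest.raises(ValueError):
            halogen_shift("O")


class TestSubstitution:
    def test_strip_replaces_halogens_with_h(self):
        assert strip_halogens(parse_formula("C21H23ClO5")).hill() == "C21H24O5"

    def test_substitute_one_chlorine(self):
        out = substitute_halogens(parse_formula("C21H24O5"), n_cl=1)
        assert out.hill() == "C21H23ClO5"

    def test_substitution_mass_shift_is_halogen_shift(self):
        base = parse_formula("C19H24O4")
        for hal, kw in [("Cl", "n_cl"), ("Br", "n_br"), ("I", "n_i")]:
            sub = substitute_halogens(base, **{kw: 1})
            delta = monoisotopic_mass(sub) - monoisotopic_mass(base)
            assert delta == pytest.approx(halogen_shift(hal), abs=1e-9)

    def test_too_many_substitutions_rejected(self):
        with pytest.raises(FormulaError):
            substitute_halogens(parse_formula("CH4"), n_cl=5)
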