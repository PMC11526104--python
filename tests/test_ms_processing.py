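import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcellflux.ms_processing import (
    DEFAULT_ABUNDANCES,
    FragmentDef,
    MIDMeasurement,
    average_replicates,
    correct_mid,
    correction_matrix,
    load_fragment_library,
    natural_mid,
    parse_formula,
    read_mid_table,
    write_mid_table,
)

ALANINE = FragmentDef(
    "ALA_full", "ALA.c", (1, 2, 3), parse_formula("C11H26NO2Si2")
)


def sympy_natural_mid(fragment, abundances=DEFAULT_ABUNDANCES):
    """Independent polynomial-expansion oracle for the natural mass-shift
    distribution of all non-skeleton atoms."""
    import sympy

    z = sympy.Symbol("z")
    poly = sympy.Integer(1)
    counts = dict(fragment.formula)
    counts["C"] = counts["C"] - fragment.n_skeleton
    for element, n in sorted(counts.items()):
        pmf = abundances[element]
        factor = sum(
            sympy.Rational(str(p)) * z ** k for k, p in enumerate(pmf)
        )
        poly *= factor ** n
    poly = sympy.expand(poly)
    deg = sympy.degree(poly, z)
    return np.array([float(poly.coeff(z, k)) for k in range(deg + 1)])


class TestFormula:
    def test_parse(self):
        assert parse_formula("C11H26NO2Si2") == {
            "C": 11, "H": 26, "N": 1, "O": 2, "Si": 2,
        }

    def test_bad_formula(self):
        with pytest.raises(ValueError):
            parse_formula("C11x3")

    def test_fragment_rejects_too_few_carbons(self):
        with pytest.raises(ValueError, match="skeleton"):
            FragmentDef("f", "X.c", (1, 2, 3), {"C": 2})


class TestCorrectionMatrix:
    def test_zero_abundance_identity(self):
        zero = {el: (1.0,) + (0.0,) * (len(d) - 1) for el, d in DEFAULT_ABUNDANCES.items()}
        C = correction_matrix(ALANINE, zero)
        np.testing.assert_allclose(C[:4, :], np.eye(4), atol=1e-15)
        assert np.allclose(C[4:, :], 0)

    def test_single_derivatization_carbon_column(self):
        frag = FragmentDef("f", "X.c", (1,), {"C": 2})
        a = 0.0107
        only_c = {"C": (1 - a, a)}
        C = correction_matrix(frag, only_c)
        np.testing.assert_allclose(C[:, 0], [1 - a, a, 0], atol=1e-15)

    def test_column_sums_are_one(self, fragment_library):
        for frag in fragment_library.values():
            C = correction_matrix(frag)
            np.testing.assert_allclose(C.sum(axis=0), 1.0, atol=1e-12)

    def test_column0_equals_theoretical_natural_mid(self):
        C = correction_matrix(ALANINE)
        x0 = np.zeros(4)
        x0[0] = 1.0
        expected = sympy_natural_mid(ALANINE)
        raw = C @ x0
        np.testing.assert_allclose(raw[: len(expected)], expected, atol=1e-12)

    def test_zero_skeleton_rejected(self):
        frag = FragmentDef("f", "X.c", (1,), {"C": 1})
        object.__setattr__(frag, "atoms", ())
        with pytest.raises(ValueError, match="zero skeleton"):
            correction_matrix(frag)

    def test_negative_abundance_rejected(self):
        bad = dict(DEFAULT_ABUNDANCES)
        bad["Si"] = (1.1, -0.1)
        with pytest.raises(ValueError, match="negative abundance"):
            correction_matrix(ALANINE, bad)


class TestCorrectMid:
    def test_exact_inverse(self):
        x = np.array([0.3, 0.1, 0.15, 0.45])
        C = correction_matrix(ALANINE)
        raw = C @ x
        meas = MIDMeasurement("ALA_full", raw, np.full(len(raw), 0.003))
        corrected, sd = correct_mid(meas, ALANINE)
        np.testing.assert_allclose(corrected, x, atol=1e-10)
        assert sd.shape == (4,)

    def test_natural_sample_corrects_to_unlabeled(self):
        raw = sympy_natural_mid(ALANINE)
        meas = MIDMeasurement("ALA_full", raw, np.full(len(raw), 0.003))
        corrected, _ = correct_mid(meas, ALANINE)
        np.testing.assert_allclose(corrected, [1, 0, 0, 0], atol=1e-10)

    def test_montecarlo_mean_recovery(self):
        rng = np.random.default_rng(77)
        x = np.array([0.25, 0.2, 0.15, 0.4])
        C = correction_matrix(ALANINE)
        raw0 = C @ x
        sd = 0.003
        draws = []
        for _ in range(200):
            raw = np.clip(raw0 + rng.normal(0, sd, raw0.shape), 0, None)
            meas = MIDMeasurement("ALA_full", raw, np.full(len(raw), sd))
            corrected, _ = correct_mid(meas, ALANINE)
            draws.append(corrected)
        mean = np.vstack(draws).mean(axis=0)
        se = np.vstack(draws).std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert (np.abs(mean - x) <= 2 * se + 1e-3).all()

    def test_never_negative(self):
        rng = np.random.default_rng(5)
        C = correction_matrix(ALANINE)
        for _ in range(50):
            x = rng.dirichlet(np.ones(4))
            raw = np.clip(C @ x + rng.normal(0, 0.01, C.shape[0]), 0, None)
            meas = MIDMeasurement("ALA_full", raw, np.full(len(raw), 0.01))
            corrected, _ = correct_mid(meas, ALANINE)
            assert (corrected >= 0).all()

    def test_roundtrip_property_all_fragments(self, fragment_library):
        rng = np.random.default_rng(11)
        for frag in fragment_library.values():
            C = correction_matrix(frag)
            for _ in range(20):
                x = rng.dirichlet(np.ones(frag.n_skeleton + 1))
                raw = C @ x
                meas = MIDMeasurement(frag.id, raw, np.full(len(raw), 0.003))
                corrected, _ = correct_mid(meas, frag)
                np.testing.assert_allclose(corrected, x, atol=1e-10)

    def test_all_zero_measurement_rejected(self):
        meas = MIDMeasurement("ALA_full", np.zeros(5), np.full(5, 0.003))
        with pytest.raises(ValueError, match="all-zero"):
            correct_mid(meas, ALANINE)

    def test_too_short_measurement_rejected(self):
        meas = MIDMeasurement("ALA_full", np.ones(3) / 3, np.full(3, 0.003))
        with pytest.raises(ValueError, match="needs"):
            correct_mid(meas, ALANINE)


class TestTables:
    def _csv(self):
        rows = ["fragment_id,replicate,time_h,mass_shift,fraction,sd"]
        for fid in ("ALA_full", "LAC_full"):
            for k, f in enumerate([0.5, 0.2, 0.2, 0.1]):
                rows.append(f"{fid},r1,24,{k},{f},0.003")
        return "\n".join(rows) + "\n"

    def test_read_groups(self):
        ms = read_mid_table(io.StringIO(self._csv()))
        assert len(ms) == 2
        assert {m.fragment_id for m in ms} == {"ALA_full", "LAC_full"}

    def test_negative_fraction_rejected(self):
        bad = self._csv().replace("0.1", "-0.01", 1)
        with pytest.raises(ValueError, match="negative fraction"):
            read_mid_table(io.StringIO(bad))

    def test_missing_column_rejected(self):
        bad = self._csv().replace("sd", "stdev")
        with pytest.raises(ValueError, match="missing columns"):
            read_mid_table(io.StringIO(bad))

    def test_duplicate_rows_rejected(self):
        text = self._csv()
        bad = text + text.splitlines()[1] + "\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_mid_table(io.StringIO(bad))

    def test_unknown_fragment_rejected(self, fragment_library):
        bad = self._csv().replace("ALA_full", "XYZ_full")
        with pytest.raises(ValueError, match="unknown fragment"):
            read_mid_table(io.StringIO(bad), fragment_library)

    def test_write_read_roundtrip(self):
        ms = read_mid_table(io.StringIO(self._csv()))
        text = write_mid_table(ms)
        again = read_mid_table(io.StringIO(text))
        assert len(again) == len(ms)
        for a, b in zip(again, ms):
            assert a.fragment_id == b.fragment_id
            np.testing.assert_allclose(a.fractions, b.fractions)

    def test_average_replicates_floor(self):
        ms = []
        rng = np.random.default_rng(3)
        for rep in range(3):
            f = np.array([0.5, 0.2, 0.2, 0.1]) + rng.normal(0, 1e-5, 4)
            ms.append(
                MIDMeasurement("ALA_full", np.clip(f, 0, None),
                               np.full(4, 0.003), f"r{rep}", 24.0)
            )
        avg = average_replicates(ms)
        assert set(avg) == {"ALA_full"}
        # tiny replicate scatter: the SD floor must bind
        assert np.allclose(avg["ALA_full"].sd, 0.003)


class TestLibrary:
    def test_covers_measured_metabolites(self, fragment_library):
        pools = {f.metabolite for f in fragment_library.values()}
        assert "PYR.obs" in pools  # mixed pyruvate measurement pool
        assert len(fragment_library) == 11

    def test_skeleton_sizes_match_pools(self, builtin_model, fragment_library):
        for f in fragment_library.values():
            met = builtin_model.metabolites[f.metabolite]
            assert f.n_skeleton == met.n_carbons


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
def test_roundtrip_hypothesis(vals):
    x = np.array(vals)
    x /= x.sum()
    C = correction_matrix(ALANINE)
    meas = MIDMeasurement("ALA_full", C @ x, np.full(C.shape[0], 0.003))
    corrected, _ = correct_mid(meas, ALANINE)
    np.testing.assert_allclose(corrected, x, atol=1e-10)
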