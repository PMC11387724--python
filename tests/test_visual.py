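"""Cone templates, quantum catches and receptor-noise colour distances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plumagediv.spectra import CANONICAL_GRID, PATCHES, Spectrum
from plumagediv.visual import (
    ColorDistanceMatrix,
    ConeSet,
    QuantumCatch,
    cone_sensitivity,
    jnd,
    patch_distance_matrix,
    quantum_catch,
    whole_body_average,
)

from conftest import gaussian_spectrum


class TestConeSensitivity:
    @pytest.mark.parametrize("lmax", [372.0, 456.0, 544.0, 609.0])
    def test_peak_at_lambda_max(self, lmax):
        curve = cone_sensitivity(lmax)
        assert abs(CANONICAL_GRID[np.argmax(curve)] - lmax) <= 1.0
        assert curve.max() == pytest.approx(1.0)
        assert np.all(curve >= 0)

    def test_uv_and_lws_curves_cross_once_between_peaks(self):
        u = cone_sensitivity(372.0)
        l = cone_sensitivity(609.0)
        inside = (CANONICAL_GRID > 372) & (CANONICAL_GRID < 609)
        diff = (u - l)[inside]
        sign_changes = np.sum(np.diff(np.sign(diff)) != 0)
        assert sign_changes == 1

    def test_lambda_max_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            cone_sensitivity(250.0)


class TestQuantumCatch:
    def test_identity_reflectance_gives_sensitivity_sums(self, cones):
        s = Spectrum(CANONICAL_GRID, np.ones(401))
        q = quantum_catch(s, cones)
        np.testing.assert_allclose(q.q, cones.sensitivities.sum(axis=1), rtol=1e-12)

    def test_linearity_in_reflectance(self, cones):
        r = np.linspace(0.1, 0.9, 401)
        q1 = quantum_catch(Spectrum(CANONICAL_GRID, r), cones)
        q2 = quantum_catch(Spectrum(CANONICAL_GRID, 0.5 * r), cones)
        np.testing.assert_allclose(q2.q, 0.5 * q1.q, rtol=1e-12)

    def test_ramp_spectrum_favours_long_wavelength_cone(self, cones):
        # grid-sum oracle: increasing reflectance with wavelength stimulates
        # the 609 nm cone more, relative to equal stimulation, than the 372 nm
        ramp = np.linspace(0.01, 1.0, 401)
        q = quantum_catch(Spectrum(CANONICAL_GRID, ramp), cones)
        q_flat = quantum_catch(Spectrum(CANONICAL_GRID, np.ones(401)), cones)
        assert q.q[3] / q_flat.q[3] > q.q[0] / q_flat.q[0]

    def test_nonpositive_catch_impossible_after_floor(self, cones):
        with pytest.raises(ValueError):
            QuantumCatch(np.array([1.0, 0.0, 1.0, 1.0]), cones)


def tetrachromatic_jnd_oracle(qa, qb, e):
    """Tetrachromatic receptor-noise distance written out term by term."""
    f = np.log(qa) - np.log(qb)
    e1, e2, e3, e4 = e
    num = (
        (e1 * e2) ** 2 * (f[3] - f[2]) ** 2
        + (e1 * e3) ** 2 * (f[3] - f[1]) ** 2
        + (e1 * e4) ** 2 * (f[2] - f[1]) ** 2
        + (e2 * e3) ** 2 * (f[3] - f[0]) ** 2
        + (e2 * e4) ** 2 * (f[2] - f[0]) ** 2
        + (e3 * e4) ** 2 * (f[1] - f[0]) ** 2
    )
    den = (e1 * e2 * e3) ** 2 + (e1 * e2 * e4) ** 2 + (e1 * e3 * e4) ** 2 + (e2 * e3 * e4) ** 2
    return np.sqrt(num / den)


class TestJND:
    def test_identical_catches_are_zero(self, cones, rng):
        q = QuantumCatch(rng.uniform(1, 100, 4), cones)
        assert jnd(q, q) == 0.0

    def test_symmetry_and_nonnegativity(self, cones, rng):
        for _ in range(20):
            a = QuantumCatch(rng.uniform(1, 100, 4), cones)
            b = QuantumCatch(rng.uniform(1, 100, 4), cones)
            assert jnd(a, b) == pytest.approx(jnd(b, a), rel=1e-12)
            assert jnd(a, b) >= 0

    def test_common_scaling_cancels(self, cones, rng):
        r = rng.uniform(0.05, 0.9, 401)
        for c in (0.1, 3.7):
            qa = quantum_catch(Spectrum(CANONICAL_GRID, r), cones)
            qb = quantum_catch(Spectrum(CANONICAL_GRID, np.clip(c * r, None, None)), cones)
            assert jnd(qa, qb) == pytest.approx(0.0, abs=1e-10)

    def test_matches_term_by_term_formula_on_random_catches(self, cones, rng):
        e = cones.noise
        for _ in range(100):
            qa, qb = rng.uniform(0.5, 50, 4), rng.uniform(0.5, 50, 4)
            expected = tetrachromatic_jnd_oracle(qa, qb, e)
            got = jnd(QuantumCatch(qa, cones), QuantumCatch(qb, cones))
            assert got == pytest.approx(expected, rel=1e-12)

    def test_dichromat_closed_form(self, rng):
        two = ConeSet(lambda_max=(372.0, 609.0), densities=(1.0, 2.0), labels=("u", "l"))
        e = two.noise
        for _ in range(25):
            qa, qb = rng.uniform(0.5, 50, 2), rng.uniform(0.5, 50, 2)
            f = np.log(qa) - np.log(qb)
            expected = abs(f[0] - f[1]) / np.sqrt(e[0] ** 2 + e[1] ** 2)
            got = jnd(QuantumCatch(qa, two), QuantumCatch(qb, two))
            assert got == pytest.approx(expected, rel=1e-12)

    def test_mismatched_cone_sets_rejected(self, cones, rng):
        other = ConeSet(weber=0.05)
        a = QuantumCatch(rng.uniform(1, 10, 4), cones)
        b = QuantumCatch(rng.uniform(1, 10, 4), other)
        with pytest.raises(ValueError, match="cone"):
            jnd(a, b)

    @settings(derandomize=True, max_examples=50)
    @given(
        qa=st.lists(st.floats(0.01, 1000), min_size=4, max_size=4),
        qb=st.lists(st.floats(0.01, 1000), min_size=4, max_size=4),
        c=st.floats(0.01, 100),
    )
    def test_fuzzed_symmetry_nonnegativity_and_scale_invariance(self, qa, qb, c):
        cones = ConeSet()
        a = QuantumCatch(np.array(qa), cones)
        b = QuantumCatch(np.array(qb), cones)
        d = jnd(a, b)
        assert d >= 0
        assert d == pytest.approx(jnd(b, a), rel=1e-12)
        scaled = QuantumCatch(c * np.array(qa), cones)
        assert jnd(scaled, QuantumCatch(c * np.array(qb), cones)) == pytest.approx(
            d, rel=1e-9, abs=1e-9
        )

    def test_perturbing_one_catch_changes_distance(self, cones, rng):
        qa = rng.uniform(1, 10, 4)
        qb = qa * rng.uniform(0.8, 1.2, 4)
        base = jnd(QuantumCatch(qa, cones), QuantumCatch(qb, cones))
        qb2 = qb.copy()
        qb2[3] *= 1.5
        moved = jnd(QuantumCatch(qa, cones), QuantumCatch(qb2, cones))
        assert moved != pytest.approx(base, rel=1e-6)


class TestDistanceMatrices:
    def test_identical_spectra_give_zero_matrix(self, cones):
        from plumagediv.spectra import PatchSpectraSet

        grouped = {
            (sp, "male", "crown"): [gaussian_spectrum(500, 0.5, sp)]
            for sp in ("a", "b", "c")
        }
        m = patch_distance_matrix(PatchSpectraSet(grouped), "crown", "male", cones)
        assert np.allclose(m.values, 0.0, atol=1e-10)

    def test_matrix_matches_pairwise_jnd_oracle(self, cones, random_spectra_set):
        from plumagediv.spectra import regrid

        m = patch_distance_matrix(random_spectra_set, "throat", "male", cones)
        for i, j in itertools.combinations(range(len(m.species)), 2):
            a = quantum_catch(
                regrid(random_spectra_set.get(m.species[i], "male", "throat")), cones
            )
            b = quantum_catch(
                regrid(random_spectra_set.get(m.species[j], "male", "throat")), cones
            )
            assert m.values[i, j] == pytest.approx(jnd(a, b), rel=1e-10)

    def test_missing_patch_excluded(self, cones, random_spectra_set):
        del random_spectra_set.spectra[("spB", "male", "crown")]
        m = patch_distance_matrix(random_spectra_set, "crown", "male", cones)
        assert m.species == ["spA", "spC", "spD"]

    def test_whole_body_average_is_cellwise_mean(self, rng):
        species = ["a", "b", "c"]
        mats = []
        for patch in PATCHES:
            v = np.abs(rng.normal(size=(3, 3)))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            mats.append(ColorDistanceMatrix(patch, species, v))
        avg = whole_body_average(mats)
        np.testing.assert_allclose(avg.values, np.mean([m.values for m in mats], axis=0))
        assert avg.patch == "average"

    def test_average_of_constant_matrices(self):
        species = ["a", "b"]
        z = ColorDistanceMatrix("crown", species, np.array([[0.0, 0.0], [0.0, 0.0]]))
        six = ColorDistanceMatrix("mantle", species, np.array([[0.0, 6.0], [6.0, 0.0]]))
        avg = whole_body_average([z, six])
        assert avg.values[0, 1] == pytest.approx(3.0)

    def test_mismatched_species_lists_rejected(self):
        m1 = ColorDistanceMatrix("crown", ["a", "b"], np.zeros((2, 2)))
        m2 = ColorDistanceMatrix("mantle", ["a", "c"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="species"):
            whole_body_average([m1, m2])
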