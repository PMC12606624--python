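import numpy as np
import pytest

from saxsens import ensemble as eio
from saxsens import forward
from saxsens.formfactors import (FormFactorTable, atomic_table,
                                 bead_table_from_structure, default_bead_table,
                                 solvated_bead_factor, water_form_factor)
from saxsens.forward import SaxsCurve, debye_spectrum

from conftest import make_toy_protein, random_rigid_motion


class _Const:
    def __init__(self, c=1.0):
        self.c = c

    def __call__(self, q):
        return np.full_like(np.asarray(q, dtype=float), self.c)


CONST_TABLE = FormFactorTable({"X": _Const(1.0), "Y": _Const(3.0)})


class TestDebye:
    def test_single_particle_self_term(self):
        q = np.linspace(0, 0.5, 7)
        out = debye_spectrum(np.zeros((1, 3)), ["Y"], CONST_TABLE, q)
        assert np.allclose(out.intensity, 9.0)

    def test_two_scatterers_closed_form(self):
        r = 6.0
        q = np.linspace(0.0, 0.5, 11)
        out = debye_spectrum(np.array([[0, 0, 0], [r, 0, 0.0]]),
                             ["X", "X"], CONST_TABLE, q)
        with np.errstate(invalid="ignore"):
            expected = 2 + 2 * np.where(q > 0, np.sin(q * r) / (q * r), 1.0)
        assert np.allclose(out.intensity, expected, rtol=1e-12)
        assert out.intensity[0] == pytest.approx(4.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(0, 8, (10, 3))
        kinds = rng.choice(["C", "N", "O", "S"], 10)
        table = atomic_table()
        q = np.linspace(0.0, 0.4, 9)
        out = debye_spectrum(coords, kinds, table, q)
        # independently coded double loop
        oracle = np.zeros_like(q)
        for i in range(10):
            fi = table[kinds[i]](q)
            for j in range(10):
                fj = table[kinds[j]](q)
                r = np.linalg.norm(coords[i] - coords[j])
                sinc = np.ones_like(q) if r == 0 else np.where(
                    q > 0, np.sin(q * r) / np.where(q > 0, q * r, 1.0), 1.0)
                oracle += fi * fj * sinc
        assert np.allclose(out.intensity, oracle, rtol=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(0, 5, (12, 3))
        q = np.linspace(0.01, 0.3, 8)
        base = debye_spectrum(coords, ["X"] * 12, CONST_TABLE, q).intensity
        R, t = random_rigid_motion(rng)
        moved = debye_spectrum(coords @ R.T + t, ["X"] * 12, CONST_TABLE, q).intensity
        assert np.allclose(moved, base, rtol=1e-12)

    def test_forward_intensity_at_zero_is_squared_sum(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(0, 5, (15, 3))
        kinds = rng.choice(["C", "N", "O"], 15)
        table = atomic_table()
        q = np.array([0.0])
        out = debye_spectrum(coords, kinds, table, q)
        f0 = sum(float(table[k](q)[0]) for k in kinds)
        assert out.intensity[0] == pytest.approx(f0 ** 2, rel=1e-12)

    def test_guinier_slope(self):
        # homogeneous toy particle: ln I vs q^2 slope = -Rg^2/3 within 2%
        axes = np.arange(-8, 9) * 1.5
        g = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"), -1).reshape(-1, 3)
        pts = g[np.linalg.norm(g, axis=1) <= 10]
        rg = np.sqrt(((pts - pts.mean(0)) ** 2).sum(1).mean())
        q = np.linspace(1e-3, 0.6 / rg, 12)
        I = debye_spectrum(pts, ["X"] * len(pts), CONST_TABLE, q).intensity
        slope = np.polyfit(q ** 2, np.log(I), 1)[0]
        assert slope == pytest.approx(-rg ** 2 / 3, rel=0.02)

    def test_missing_kind_raises(self):
        with pytest.raises(KeyError, match="Z"):
            debye_spectrum(np.zeros((1, 3)), ["Z"], CONST_TABLE, np.array([0.1]))


class TestCoarseGrainAgreement:
    # configured acceptance bound for the bead approximation at low angle
    LOW_Q_BOUND = 0.25

    @pytest.mark.parametrize("scheme", ["single-bead", "martini-like"])
    def test_bead_spectrum_tracks_atomistic_at_low_q(self, toy_protein, scheme):
        q = np.linspace(0.01, 0.30, 20)
        at = atomic_table()
        I_atom = debye_spectrum(toy_protein.coords[0], toy_protein.elements,
                                at, q).intensity
        beads = eio.map_to_beads(toy_protein, scheme=scheme)
        bt = bead_table_from_structure(toy_protein, beads)
        I_bead = debye_spectrum(beads.bead_coords[0], beads.bead_kind,
                                bt, q).intensity
        assert np.abs(I_bead / I_atom - 1).max() < self.LOW_Q_BOUND


class TestSolvatedBead:
    def test_contrast_zero_reduces_to_vacuum(self):
        q = np.linspace(0, 0.3, 7)
        vac = default_bead_table(["B"])["B"]
        out = solvated_bead_factor(vac, 0.7, q, contrast=0.0)
        assert np.allclose(out, vac(q))

    def test_buried_bead_reduces_to_vacuum(self):
        q = np.linspace(0, 0.3, 7)
        vac = default_bead_table(["B"])["B"]
        out = solvated_bead_factor(vac, 0.0, q, contrast=2.5)
        assert np.allclose(out, vac(q))

    def test_linearity_in_exposure(self):
        q = np.array([0.0])
        vac = default_bead_table(["B"])["B"]
        contrast = 1.7
        f_half = solvated_bead_factor(vac, 0.5, q, contrast)
        f_full = solvated_bead_factor(vac, 1.0, q, contrast)
        assert (f_full - f_half)[0] == pytest.approx(
            contrast * 0.5 * water_form_factor(q)[0])

    def test_exposure_out_of_range_raises(self):
        vac = default_bead_table(["B"])["B"]
        with pytest.raises(ValueError, match="exposure"):
            solvated_bead_factor(vac, 1.2, np.array([0.1]), 1.0)


class TestEnsembleSpectrum:
    def test_one_hot_selects_frame(self):
        q = np.linspace(0.01, 0.3, 5)
        s = np.arange(15, dtype=float).reshape(3, 5) + 1
        out = forward.ensemble_spectrum(s, np.array([0, 1, 0.0]), q)
        assert np.allclose(out.intensity, s[1])

    def test_equal_weights_mean(self):
        q = np.linspace(0.01, 0.3, 5)
        s = np.array([[1.0] * 5, [3.0] * 5])
        out = forward.ensemble_spectrum(s, np.array([0.5, 0.5]), q)
        assert np.allclose(out.intensity, 2.0)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            forward.ensemble_spectrum(np.ones((2, 4)), np.array([0.5, 0.5]),
                                      np.linspace(0.01, 0.3, 5))


class TestSmoothing:
    def test_constant_curve_unchanged(self):
        c = SaxsCurve(np.linspace(0.01, 0.3, 60), np.full(60, 2.0))
        out = forward.smooth_experimental(c, 51)
        assert np.allclose(out.intensity, 2.0)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        c = SaxsCurve(np.linspace(0.01, 0.3, 30), rng.uniform(1, 2, 30))
        out = forward.smooth_experimental(c, 1)
        assert np.allclose(out.intensity, c.intensity)

    def test_linear_ramp_fixed_point(self):
        # symmetric (shrinking) windows leave a linear ramp unchanged
        n = 40
        c = SaxsCurve(np.linspace(0.01, 0.3, n), 1.0 + 0.1 * np.arange(n))
        out = forward.smooth_experimental(c, 11)
        assert np.allclose(out.intensity, c.intensity, atol=1e-12)

    def test_even_window_raises(self):
        c = SaxsCurve(np.linspace(0.01, 0.3, 10), np.ones(10))
        with pytest.raises(ValueError, match="odd"):
            forward.smooth_experimental(c, 10)


class TestResample:
    def test_same_grid_identity(self):
        rng = np.random.default_rng(1)
        q = np.linspace(0.01, 0.3, 12)
        c = SaxsCurve(q, rng.uniform(1, 2, 12), se=rng.uniform(0.01, 0.1, 12))
        out = forward.resample_curve(c, q)
        assert np.allclose(out.intensity, c.intensity)
        assert np.allclose(out.se, c.se)

    def test_midpoint_average(self):
        c = SaxsCurve(np.array([0.1, 0.2]), np.array([1.0, 3.0]))
        out = forward.resample_curve(c, np.array([0.15]))
        assert out.intensity[0] == pytest.approx(2.0)

    def test_extrapolation_raises(self):
        c = SaxsCurve(np.array([0.1, 0.2]), np.array([1.0, 3.0]))
        with pytest.raises(ValueError, match="beyond"):
            forward.resample_curve(c, np.array([0.25]))


class TestScaleFit:
    def _curves(self, factor, seed=0):
        rng = np.random.default_rng(seed)
        q = np.linspace(0.01, 0.3, 15)
        exp_I = rng.uniform(1, 5, 15)
        exp = SaxsCurve(q, exp_I, se=rng.uniform(0.05, 0.2, 15))
        calc = SaxsCurve(q, factor * exp_I)
        return calc, exp

    def test_identical_curves(self):
        calc, exp = self._curves(1.0)
        assert forward.fit_scale(calc, exp) == pytest.approx(1.0)

    def test_double_intensity(self):
        calc, exp = self._curves(2.0)
        assert forward.fit_scale(calc, exp) == pytest.approx(0.5)

    def test_matches_grid_scan(self):
        rng = np.random.default_rng(3)
        q = np.linspace(0.01, 0.3, 15)
        calc = SaxsCurve(q, rng.uniform(1, 5, 15))
        exp = SaxsCurve(q, rng.uniform(1, 5, 15), se=rng.uniform(0.05, 0.2, 15))
        c = forward.fit_scale(calc, exp)
        grid = np.linspace(0.01, 5, 200001)
        obj = [(((g * calc.intensity - exp.intensity) / exp.se) ** 2).sum()
               for g in grid]
        assert c == pytest.approx(grid[int(np.argmin(obj))], abs=1e-4)

    def test_zero_calc_raises(self):
        q = np.linspace(0.01, 0.3, 5)
        exp = SaxsCurve(q, np.ones(5), se=np.ones(5))
        calc = SaxsCurve(q, np.full(5, 1.0))
        calc.intensity = np.zeros(5)  # bypass positivity check at build time
        with pytest.raises(ValueError, match="zero"):
            forward.fit_scale(calc, exp)


class TestDatIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        c = SaxsCurve(np.linspace(0.01, 0.3, 9), rng.uniform(1, 2, 9),
                      se=rng.uniform(0.01, 0.1, 9))
        path = tmp_path / "c.dat"
        forward.write_dat(c, path, header="test curve")
        back = forward.read_dat(path)
        assert np.allclose(back.q, c.q)
        assert np.allclose(back.intensity, c.intensity, rtol=1e-6)
        assert np.allclose(back.se, c.se, rtol=1e-6)

    def test_sasbdb_dialect(self, tmp_path):
        path = tmp_path / "sas.dat"
        path.write_text(
            "Sample description: some complex in buffer\n"
            "# q I sigma\n"
            " 1.000000E-02  5.2E+00 1.1E-01\n"
            " 2.000000E-02  4.9E+00 1.0E-01\n"
            " 3.000000E-02  4.1E+00 9.0E-02\n")
        c = forward.read_dat(path)
        assert len(c) == 3
        assert c.intensity[1] == pytest.approx(4.9)
        assert c.se[2] == pytest.approx(0.09)
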