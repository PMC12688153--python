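"""Titration engine: exact enumeration, Monte Carlo, pKa and ΔQ extraction."""

import numpy as np
import pytest

from bcoi.constants import LN10_RT, R_KJ, T_DEFAULT
from bcoi.structure import IonizableSite
from bcoi.titration import (
    DEFAULT_PH_GRID,
    MicrostateSystem,
    TitrationCurve,
    closed_form_ionisation,
    delta_q_at_ph,
    enumerate_titration,
    mc_titration,
    model_compound_protonation,
    pka_from_curve,
)


def make_system(groups, pkas, W=None):
    from bcoi.constants import GAMMA

    n = len(groups)
    return MicrostateSystem(
        site_ids=[("p", "A", i + 1, g) for i, g in enumerate(groups)],
        gammas=np.array([GAMMA[g] for g in groups], dtype=float),
        intrinsic_pkas=np.array(pkas, dtype=float),
        W=np.zeros((n, n)) if W is None else np.asarray(W, float))


def fixture_systems():
    """Coupled systems representative of buried-charge clusters (≤ 12 sites)."""
    out = [
        make_system(["ASP"], [4.0]),
        make_system(["HIS"], [6.3]),
        make_system(["ASP", "LYS"], [6.1, 8.3],
                    [[0, -34.7], [-34.7, 0]]),
        make_system(["ASP", "ASP"], [6.1, 6.1],
                    [[0, 11.5], [11.5, 0]]),
        make_system(["ASP", "LYS", "GLU"], [6.1, 8.3, 6.5],
                    [[0, -34.7, 34.7], [-34.7, 0, -34.7], [34.7, -34.7, 0]]),
    ]
    rng = np.random.default_rng(17)
    n = 12
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.25:
                W[i, j] = W[j, i] = rng.uniform(-15, 15)
    groups = rng.choice(["ASP", "GLU", "LYS", "ARG", "HIS"], size=n)
    out.append(make_system(list(groups), rng.uniform(3, 11, n), W))
    return out


class TestEnumeration:
    def test_single_acid_half_ionised_at_pka(self):
        (curve,) = enumerate_titration(make_system(["ASP"], [4.0]))
        k = np.where(curve.ph_grid == 4.0)[0][0]
        assert curve.mean_ionisation[k] == pytest.approx(0.5, abs=1e-12)
        assert curve.apparent_pka == pytest.approx(4.0, abs=1e-9)

    def test_single_his_half_protonated_at_model_pka(self):
        grid = np.arange(0, 14.01, 0.1)
        (curve,) = enumerate_titration(make_system(["HIS"], [6.3]), grid)
        assert curve.protonation_at(6.3) == pytest.approx(0.5, abs=1e-9)

    def test_two_identical_acids_match_hand_enumeration(self):
        """Repulsively coupled acid pair vs direct 4-microstate sums."""
        w = 11.5
        sys2 = make_system(["ASP", "ASP"], [4.0, 4.0], [[0, w], [w, 0]])
        grid = np.arange(0, 14.01, 0.05)
        curves = enumerate_titration(sys2, grid)

        rt = R_KJ * T_DEFAULT

        def hand_mean(ph):
            h = -LN10_RT * (ph - 4.0)  # gamma = −1
            energies = {(0, 0): 0.0, (1, 0): h, (0, 1): h, (1, 1): 2 * h + w}
            z = sum(np.exp(-e / rt) for e in energies.values())
            return sum(s[0] * np.exp(-e / rt)
                       for s, e in energies.items()) / z

        expect = np.array([hand_mean(ph) for ph in grid])
        np.testing.assert_allclose(curves[0].mean_ionisation, expect,
                                   atol=1e-10)
        # stepwise macroscopic pKas: pKa ∓ log10(2) plus the 2-unit coupling
        # split (statistical factor 2 for identical sites)
        total = curves[0].mean_ionisation + curves[1].mean_ionisation
        ph_first = np.interp(0.5, total, grid)
        ph_second = np.interp(1.5, total, grid)
        assert ph_first == pytest.approx(4.0 - np.log10(2), abs=0.03)
        assert ph_second == pytest.approx(6.0 + np.log10(2), abs=0.03)
        assert ph_second - ph_first == pytest.approx(2 + 2 * np.log10(2),
                                                     abs=0.05)

    def test_uncoupled_sites_follow_henderson_hasselbalch(self):
        sys3 = make_system(["ASP", "HIS", "LYS"], [4.0, 6.3, 10.4])
        curves = enumerate_titration(sys3)
        for c, pka in zip(curves, [4.0, 6.3, 10.4]):
            expect = closed_form_ionisation(c.gamma, pka, c.ph_grid)
            np.testing.assert_allclose(c.mean_ionisation, expect, atol=1e-12)

    def test_site_limit_enforced(self):
        sysbig = make_system(["ASP"] * 21, [4.0] * 21)
        with pytest.raises(ValueError, match="mc_titration"):
            enumerate_titration(sysbig)

    def test_total_protonation_non_increasing_in_ph(self):
        for system in fixture_systems():
            curves = enumerate_titration(system)
            prot = np.zeros_like(curves[0].ph_grid)
            for c in curves:
                ion = c.mean_ionisation
                prot += ion if c.gamma > 0 else 1.0 - ion
            assert np.all(np.diff(prot) <= 1e-9)


class TestMonteCarlo:
    def test_agrees_with_enumeration_on_fixture_systems(self):
        for si, system in enumerate(fixture_systems()):
            exact = enumerate_titration(system)
            mc = mc_titration(system, seed=100 + si)
            for a, b in zip(exact, mc):
                assert np.abs(a.mean_ionisation
                              - b.mean_ionisation).max() < 0.02
                if not a.censored and not b.censored:
                    assert abs(a.apparent_pka - b.apparent_pka) < 0.05

    def test_uncoupled_thirty_site_system_matches_closed_form(self):
        rng = np.random.default_rng(9)
        groups = rng.choice(["ASP", "LYS", "HIS", "GLU"], size=30)
        pkas = rng.uniform(3, 11, 30)
        system = make_system(list(groups), pkas)
        curves = mc_titration(system, seed=4)
        for c, pka in zip(curves, pkas):
            expect = closed_form_ionisation(c.gamma, pka, c.ph_grid)
            assert np.abs(c.mean_ionisation - expect).max() < 0.02

    def test_same_seed_bit_identical(self):
        system = fixture_systems()[4]
        a = mc_titration(system, seed=7)
        b = mc_titration(system, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.mean_ionisation, y.mean_ionisation)

    def test_minimum_sweeps_enforced(self):
        with pytest.raises(ValueError, match="1000"):
            mc_titration(make_system(["ASP"], [4.0]), n_sweeps=10)


class TestPkaFromCurve:
    def _curve(self, grid, vals, model_pka=7.0, gamma=-1):
        return TitrationCurve(site_id=("p", "A", 1, "ASP"), gamma=gamma,
                              model_pka=model_pka,
                              ph_grid=np.asarray(grid, float),
                              mean_ionisation=np.asarray(vals, float))

    def test_linear_interpolation_between_brackets(self):
        pka, censored = pka_from_curve(self._curve([4.0, 4.2], [0.45, 0.55],
                                                   model_pka=4.0))
        assert pka == pytest.approx(4.1)
        assert not censored

    def test_no_crossing_censored_at_boundary(self):
        grid = np.arange(0, 14.1, 0.5)
        vals = np.linspace(0.0, 0.4, len(grid))
        pka, censored = pka_from_curve(self._curve(grid, vals))
        assert censored and pka == pytest.approx(14.0)

    def test_closed_form_curve_recovered_to_hundredth(self):
        grid = np.arange(0, 14.01, 0.25)
        vals = closed_form_ionisation(-1, 7.25, grid)
        pka, censored = pka_from_curve(self._curve(grid, vals, model_pka=7.25))
        assert not censored
        assert pka == pytest.approx(7.25, abs=0.01)

    def test_multiple_crossings_pick_nearest_model_pka(self):
        grid = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        vals = np.array([0.4, 0.6, 0.4, 0.6, 0.7])  # crossings at 2.5, 3.5, 4.5
        pka, _ = pka_from_curve(self._curve(grid, vals, model_pka=4.4))
        assert pka == pytest.approx(4.5)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            pka_from_curve(self._curve([7.0], [0.5]))


class TestDeltaQ:
    def _site(self, group):
        return IonizableSite(protein_id="p", chain="A", seq_number=1,
                             group_label=group)

    def test_unperturbed_site_has_zero_delta_q(self):
        (curve,) = enumerate_titration(make_system(["ASP"], [4.0]))
        for ph in (3.0, 7.0, 10.0):
            assert delta_q_at_ph(curve, self._site("ASP"),
                                 ph).delta_q == pytest.approx(0.0, abs=1e-9)

    def test_buried_his_closed_form_value(self):
        """Desolvation-shifted His (intrinsic 4.21): ΔQ(7) ≈ 0.165."""
        (curve,) = enumerate_titration(make_system(["HIS"], [4.21]))
        expect = abs(model_compound_protonation(4.21, 7.0)
                     - model_compound_protonation(6.3, 7.0))
        res = delta_q_at_ph(curve, self._site("HIS"), 7.0)
        assert res.delta_q == pytest.approx(expect, abs=1e-3)
        assert res.delta_q == pytest.approx(0.165, abs=0.002)

    def test_shifted_acid_at_model_pka(self):
        """Acid shifted +2 units, evaluated at its model pKa (4.0)."""
        (curve,) = enumerate_titration(make_system(["ASP"], [6.0]))
        expect = abs(model_compound_protonation(6.0, 4.0)
                     - model_compound_protonation(4.0, 4.0))
        res = delta_q_at_ph(curve, self._site("ASP"), 4.0)
        assert res.delta_q == pytest.approx(expect, abs=1e-3)

    def test_ph_outside_grid_rejected(self):
        (curve,) = enumerate_titration(make_system(["ASP"], [4.0]),
                                       np.arange(2, 10, 0.25))
        with pytest.raises(ValueError, match="outside"):
            curve.protonation_at(12.0)
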