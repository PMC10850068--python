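"""Quality scores: closed-form values, numerical-integration oracles, invariants."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from lipidbank import quality as q
from lipidbank import synthetic as syn
from lipidbank.errors import InputError


class TestBondQuality:
    def test_centred_value_is_half(self):
        # S_mean = S_exp, sem = dS = 0.02: F1(1) - F1(-1) = 0.5 for the Cauchy
        n = 50
        s_var = 0.02**2 * n  # sem = sqrt(s/n) = 0.02
        bq = q.bond_quality(0.2, s_var, n, 0.2, 0.02)
        assert bq.P == pytest.approx(0.5, abs=1e-12)

    def test_vanishing_sem_limit(self):
        bq = q.bond_quality(0.2, 1e-18, 50, 0.2, 0.02)
        assert bq.P == pytest.approx(1.0, abs=1e-6)

    def test_far_tail_is_small(self):
        # |S_mean - S_exp| = 100 sem with dS = sem
        n = 4
        sem = 0.0005
        bq = q.bond_quality(0.0, sem**2 * n, n, 100 * sem, sem)
        assert bq.P is not None and bq.P < 0.01

    def test_excluded_when_sim_error_exceeds_experimental(self):
        bq = q.bond_quality(0.2, 0.05**2 * 10, 10, 0.2, 0.02)
        assert bq.excluded and bq.P is None

    @pytest.mark.parametrize(
        "s_mean,s_exp,sem",
        [(0.10, 0.12, 0.01), (0.00, 0.05, 0.02), (-0.2, -0.21, 0.005), (0.3, 0.3, 0.015)],
    )
    def test_matches_numerical_integration(self, s_mean, s_exp, sem):
        n = 25
        bq = q.bond_quality(s_mean, sem**2 * n, n, s_exp, 0.02)
        lo = (s_exp - 0.02 - s_mean) / sem
        hi = (s_exp + 0.02 - s_mean) / sem
        oracle, _ = integrate.quad(stats.t(df=1).pdf, lo, hi)
        assert bq.P == pytest.approx(oracle, abs=1e-6)

    def test_monotonic_in_deviation_and_error(self):
        deviations = np.linspace(0.0, 0.5, 100)
        ps = [
            q.bond_quality(0.0, 0.01**2 * 30, 30, d, 0.02).P for d in deviations
        ]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
        errors = np.linspace(0.011, 0.2, 100)  # above sem so nothing is excluded
        ps = [q.bond_quality(0.0, 0.01**2 * 30, 30, 0.1, e).P for e in errors]
        assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_too_few_lipids_rejected(self):
        with pytest.raises(InputError):
            q.bond_quality(0.2, 0.0001, 1, 0.2)


class TestFragmentAndSystem:
    membership = {"b1": "sn-1", "b2": "sn-1", "b3": "headgroup"}

    def test_plain_average(self):
        bq = {"b1": q.BondQuality(0.8), "b2": q.BondQuality(0.6), "b3": None}
        frag = q.fragment_quality(bq, self.membership, "sn-1")
        assert frag.P_frag == pytest.approx(0.7)
        assert frag.F_frag == 1.0

    def test_missing_bond_penalty(self):
        bq = {"b1": q.BondQuality(0.8), "b2": None, "b3": None}
        frag = q.fragment_quality(bq, self.membership, "sn-1")
        assert frag.P_frag == pytest.approx(0.8 * 0.5)

    def test_excluded_bond_counts_against_coverage(self):
        bq = {
            "b1": q.BondQuality(0.8),
            "b2": q.BondQuality(None, excluded=True),
            "b3": None,
        }
        frag = q.fragment_quality(bq, self.membership, "sn-1")
        assert frag.F_frag == 0.5

    def test_empty_fragment_absent(self):
        bq = {"b1": None, "b2": None, "b3": None}
        assert q.fragment_quality(bq, self.membership, "sn-1") is None
        assert q.fragment_quality(bq, self.membership, "sn-2") is None

    def test_system_weighting(self):
        per_lipid = {
            "POPC": {"total": 0.8, "sn-1": 0.8, "sn-2": 0.8},
            "POPE": {"total": 0.4, "sn-1": 0.4, "sn-2": 0.4},
        }
        sq = q.system_quality(per_lipid, {"POPC": 0.75, "POPE": 0.25})
        assert sq.P["total"] == pytest.approx(0.7)
        assert sq.P["tails"] == pytest.approx(0.7)

    def test_single_lipid_identity_and_permutation_symmetry(self):
        per_lipid = {"POPC": {"total": 0.63, "headgroup": 0.5}}
        sq = q.system_quality(per_lipid, {"POPC": 1.0})
        assert sq.P["total"] == pytest.approx(0.63)
        two = {
            "POPC": {"total": 0.8},
            "POPE": {"total": 0.4},
        }
        a = q.system_quality(two, {"POPC": 0.6, "POPE": 0.4}).P["total"]
        b = q.system_quality(dict(reversed(two.items())), {"POPE": 0.4, "POPC": 0.6}).P[
            "total"
        ]
        assert a == pytest.approx(b)

    def test_qualities_bounded(self):
        bq = {"b1": q.BondQuality(1.0), "b2": q.BondQuality(0.0), "b3": None}
        frag = q.fragment_quality(bq, self.membership, "total")
        assert 0.0 <= frag.P_frag <= 1.0


class TestFormFactorScaling:
    def test_proportional_curves(self):
        f_exp = np.array([1.0, 2.0, 3.0])
        assert q.scale_experimental_form_factor(2 * f_exp, f_exp, np.ones(3)) == 2.0

    def test_worked_arithmetic(self):
        k = q.scale_experimental_form_factor(
            np.array([3.0, 3.0]), np.array([1.0, 2.0]), np.array([1.0, 1.0])
        )
        assert k == pytest.approx(1.8)

    def test_matches_numeric_minimizer(self, rng):
        f_exp = rng.uniform(0.1, 2.0, 40)
        f_sim = rng.uniform(0.1, 2.0, 40)
        df = rng.uniform(0.05, 0.3, 40)
        k = q.scale_experimental_form_factor(f_sim, f_exp, df)
        oracle = optimize.minimize_scalar(
            lambda kk: np.sum((f_sim - kk * f_exp) ** 2 / df**2),
            bounds=(0.0, 10.0),
            method="bounded",
            options={"xatol": 1e-12},
        ).x
        assert k == pytest.approx(oracle, abs=1e-8)

    def test_zero_experiment_rejected(self):
        with pytest.raises(InputError):
            q.scale_experimental_form_factor(np.ones(3), np.zeros(3), np.ones(3))


class TestFormFactorQuality:
    qgrid = np.arange(0.0, 1.0001, 0.001)

    def test_identical_curves_score_zero(self):
        f = syn.slab_form_factor(self.qgrid, 40.0, 0.1)
        res = q.form_factor_quality(self.qgrid, f, self.qgrid, f, np.ones_like(f))
        assert res.FF_q == pytest.approx(0.0, abs=1e-9)

    def test_two_slab_widths_give_sinc_zero_distance(self):
        f40 = syn.slab_form_factor(self.qgrid, 40.0, 0.1)
        f38 = syn.slab_form_factor(self.qgrid, 38.0, 0.1)
        res = q.form_factor_quality(self.qgrid, f40, self.qgrid, f38, np.ones_like(f40))
        expected = abs(2 * np.pi / 40 - 2 * np.pi / 38) * 100
        assert res.FF_q == pytest.approx(expected, abs=0.05)

    def test_noise_robustness_of_filtered_minimum(self, rng):
        f = syn.slab_form_factor(self.qgrid, 40.0, 0.1)
        noisy = f + 0.002 * rng.standard_normal(len(f))
        clean = q.first_form_factor_minimum(self.qgrid, f)
        perturbed = q.first_form_factor_minimum(self.qgrid, noisy)
        assert abs(clean - perturbed) * 100 < 0.05

    def test_invariant_under_positive_scaling(self):
        f40 = syn.slab_form_factor(self.qgrid, 40.0, 0.1)
        f38 = syn.slab_form_factor(self.qgrid, 38.0, 0.1)
        a = q.form_factor_quality(self.qgrid, f40, self.qgrid, f38, np.ones_like(f40))
        b = q.form_factor_quality(
            self.qgrid, 7.0 * f40, self.qgrid, 0.3 * f38, np.ones_like(f40)
        )
        assert a.FF_q == pytest.approx(b.FF_q, abs=1e-9)

    def test_no_minimum_returns_none(self):
        flat = np.exp(-self.qgrid)  # monotonically decreasing, no local minimum
        assert q.first_form_factor_minimum(self.qgrid, flat) is None
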