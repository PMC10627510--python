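"""Closed-form solutions: printed-key arithmetic, limits, reduction
identities and agreement with the detailed-balance oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rafpa import (
    ModelParams,
    Variant,
    active_raf_fraction,
    baseline_active_fraction,
    dimensionless_groups,
    species_distribution,
    total_dimer_ratio,
)
from rafpa.oracle import build_network, solve_equilibrium

from conftest import sample_params


class TestDimensionlessGroups:
    def test_zero_drug_limits(self, unified_default):
        g = dimensionless_groups(unified_default, 0.0)
        assert g.d_rel == 0.0
        assert g.E1 == 1.0 + unified_default.K_A
        assert g.E1n == 1.0
        assert g.E2c == pytest.approx(8 * g.RAF_rel)
        assert g.E2u == pytest.approx(8 * g.RAF_rel)

    def test_methods_default_E3(self):
        # K_A = 10, K_dim = 0.1 uM, raf_total = 0.04 uM -> RAF_rel = 0.4
        p = ModelParams(K_A=10.0, K_dim=0.1, K_d=0.1, raf_total=0.04,
                        variant=Variant.CA)
        g = dimensionless_groups(p, 0.0)
        assert g.RAF_rel == pytest.approx(0.4)
        assert g.E3 == pytest.approx(3.2 / 121)

    def test_no_autoinhibition_matches_plain_dimerization(self):
        p = ModelParams(K_A=0.0, K_dim=0.1, K_d=0.1, raf_total=0.04,
                        variant=Variant.CA)
        g = dimensionless_groups(p, 0.0)
        assert g.E3 == pytest.approx(8 * g.RAF_rel)

    def test_negative_drug_rejected(self, unified_default):
        with pytest.raises(ValueError):
            dimensionless_groups(unified_default, -1.0)


class TestBaseline:
    def test_saturating_dimerization_limit(self):
        p = ModelParams(K_A=0.0, K_dim=1e-4, K_d=0.1, raf_total=1e3,
                        variant=Variant.DP, f=0.5)
        assert baseline_active_fraction(p) == pytest.approx(1.0, abs=1e-3)

    def test_dilute_limit(self):
        p = ModelParams(K_A=0.0, K_dim=1e3, K_d=0.1, raf_total=1e-4,
                        variant=Variant.DP, f=0.5)
        assert baseline_active_fraction(p) == pytest.approx(0.0, abs=1e-6)

    def test_ca_without_autoinhibition_equals_dp(self):
        ca = ModelParams(K_A=0.0, K_dim=0.1, K_d=0.1, raf_total=0.04,
                         variant=Variant.CA)
        dp = ModelParams(K_A=0.0, K_dim=0.1, K_d=0.1, f=0.5, raf_total=0.04,
                         variant=Variant.DP)
        assert baseline_active_fraction(ca) == pytest.approx(
            baseline_active_fraction(dp), rel=1e-14
        )

    def test_monotone_in_raf_rel_and_K_A(self):
        fracs = [
            baseline_active_fraction(
                ModelParams(K_A=5.0, K_dim=0.1, K_d=0.1, raf_total=r,
                            variant=Variant.CA)
            )
            for r in np.logspace(-3, 2, 12)
        ]
        assert np.all(np.diff(fracs) > 0)
        fracs = [
            baseline_active_fraction(
                ModelParams(K_A=k, K_dim=0.1, K_d=0.1, raf_total=0.04,
                            variant=Variant.CA)
            )
            for k in np.linspace(0, 50, 12)
        ]
        assert np.all(np.diff(fracs) < 0)


class TestActiveFraction:
    def test_zero_drug_reduces_to_baseline(self, sweep_grid):
        rng = np.random.default_rng(7)
        for variant in Variant:
            p = sample_params(rng, variant)
            assert active_raf_fraction(p, 0.0) == pytest.approx(
                baseline_active_fraction(p), rel=1e-12
            )

    def test_fully_autoinhibited_limit(self):
        p = ModelParams(K_A=1e8, K_dim=0.1, K_d=0.1, raf_total=0.04,
                        variant=Variant.CA)
        assert active_raf_fraction(p, 0.0) < 1e-8

    def test_high_dose_limit_is_zero(self):
        rng = np.random.default_rng(11)
        for variant in Variant:
            p = sample_params(rng, variant)
            assert active_raf_fraction(p, 1e12 * p.K_d) < 1e-6

    @pytest.mark.parametrize("variant", list(Variant))
    def test_matches_oracle_over_dose_sweep(self, variant):
        """Central property: analytic solution == brute-force equilibrium."""
        rng = np.random.default_rng(int(np.where([v == variant for v in Variant])[0][0]) + 3)
        for _ in range(40):
            p = sample_params(rng, variant)
            net = build_network(p)
            doses = np.concatenate([[0.0], 10 ** rng.uniform(-4, 2, size=9)])
            analytic = np.atleast_1d(active_raf_fraction(p, doses))
            for dose, a in zip(doses, analytic):
                s = solve_equilibrium(net, p.raf_total, float(dose))
                truth = s.active_protomers / p.raf_total
                assert a == pytest.approx(truth, rel=1e-6, abs=1e-300)

    def test_fraction_bounds(self):
        rng = np.random.default_rng(5)
        for variant in Variant:
            for _ in range(25):
                p = sample_params(rng, variant)
                doses = np.concatenate([[0.0], 10 ** rng.uniform(-6, 6, 20)])
                frac = np.atleast_1d(active_raf_fraction(p, doses))
                assert np.all(frac >= 0)
                assert np.all(frac <= 1 + 1e-12)


class TestReductionIdentities:
    """UNIFIED collapses exactly onto each single-mechanism variant."""

    @pytest.mark.parametrize(
        "variant,pins",
        [
            (Variant.CA, dict(f=1.0, g=1.0)),
            (Variant.DP, dict(K_A=0.0, g=1.0)),
            (Variant.NC, dict(K_A=0.0, f=1.0)),
        ],
    )
    def test_unified_reduces(self, variant, pins):
        rng = np.random.default_rng(17)
        doses = np.concatenate([[0.0], np.logspace(-4, 3, 15)])
        for _ in range(30):
            p = sample_params(rng, variant)
            u = p.as_unified()
            assert p.to_dict()["variant"] == variant.value
            a_v = np.atleast_1d(active_raf_fraction(p, doses))
            a_u = np.atleast_1d(active_raf_fraction(u, doses))
            np.testing.assert_allclose(a_v, a_u, rtol=1e-12)
            assert baseline_active_fraction(p) == pytest.approx(
                baseline_active_fraction(u), rel=1e-12
            )
            r_v = np.atleast_1d(total_dimer_ratio(p, doses))
            r_u = np.atleast_1d(total_dimer_ratio(u, doses))
            np.testing.assert_allclose(r_v, r_u, rtol=1e-12)


class TestDimerRatio:
    def test_half_at_zero_drug_for_every_variant(self):
        rng = np.random.default_rng(23)
        for variant in Variant:
            p = sample_params(rng, variant)
            assert total_dimer_ratio(p, 0.0) == pytest.approx(0.5, rel=1e-12)

    def test_matches_oracle_species_counts(self, ca_default):
        net = build_network(ca_default)
        for dose in [0.01, 0.1, 1.0, 10.0]:
            s = solve_equilibrium(net, ca_default.raf_total, dose)
            expect = s.dimer_total / s.active_protomers
            assert total_dimer_ratio(ca_default, dose) == pytest.approx(
                expect, rel=1e-9
            )

    def test_grows_with_dose(self, ca_default):
        # drugged dimers accumulate: dimers per active protomer = (1+d)/2
        doses = np.logspace(-2, 2, 10)
        ratios = np.atleast_1d(total_dimer_ratio(ca_default, doses))
        assert np.all(np.diff(ratios) > 0)
        assert ratios[-1] == pytest.approx((1 + 1e2 / ca_default.K_d) / 2)


class TestSpeciesDistribution:
    def test_no_drug_no_drugged_species(self, unified_default):
        s = species_distribution(unified_default, 0.0)
        assert s.RD == s.R2D == s.R2D2 == 0.0
        s.check_conservation(unified_default.raf_total)

    def test_autoinhibited_limit(self):
        p = ModelParams(K_A=1e6, K_dim=0.1, K_d=0.1, raf_total=0.04,
                        variant=Variant.CA)
        s = species_distribution(p, 0.0)
        assert s.A / p.raf_total == pytest.approx(1.0, abs=1e-3)

    def test_consistent_with_active_fraction(self):
        rng = np.random.default_rng(31)
        for variant in Variant:
            p = sample_params(rng, variant)
            for dose in [0.0, 0.05, 5.0]:
                s = species_distribution(p, dose)
                s.check_conservation(p.raf_total)
                assert s.active_protomers / p.raf_total == pytest.approx(
                    float(active_raf_fraction(p, dose)), rel=1e-10
                )

    def test_dose_sweep_progression(self, ca_default):
        """Autoinhibited pool declines; singly bound dimers rise then fall;
        doubly bound dimers saturate."""
        doses = np.logspace(-3, 3, 40)
        states = [species_distribution(ca_default, d) for d in doses]
        A = np.array([s.A for s in states])
        R2D = np.array([s.R2D for s in states])
        R2D2 = np.array([s.R2D2 for s in states])
        assert np.all(np.diff(A) < 0)
        i = int(np.argmax(R2D))
        assert 0 < i < len(doses) - 1
        assert np.all(np.diff(R2D[: i + 1]) > 0) and np.all(np.diff(R2D[i:]) < 0)
        assert np.all(np.diff(R2D2) > 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    log_KA=st.floats(-3, 2),
    log_Kdim=st.floats(-4, 4),
    log_Kd=st.floats(-4, 4),
    log_f=st.floats(-5, 2),
    log_g=st.floats(0, 4),
    log_raf=st.floats(-4, 3),
    log_dose=st.floats(-6, 4),
)
def test_property_unified_oracle_agreement(
    log_KA, log_Kdim, log_Kd, log_f, log_g, log_raf, log_dose
):
    """Analytic unified solution agrees with the brute-force solver
    anywhere inside the fitting search domain."""
    p = ModelParams(
        K_A=10**log_KA, K_dim=10**log_Kdim, K_d=10**log_Kd,
        f=10**log_f, g=10**log_g, raf_total=10**log_raf,
    )
    dose = 10**log_dose
    s = solve_equilibrium(build_network(p), p.raf_total, dose)
    truth = s.active_protomers / p.raf_total
    assert float(active_raf_fraction(p, dose)) == pytest.approx(
        truth, rel=1e-6, abs=1e-300
    )
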