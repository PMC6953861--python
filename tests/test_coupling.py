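"""Huang-Rhys factors, reorganization-energy partitioning, activation
energy and phonon estimate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vibronic as vb
from vibronic.synthetic import make_displaced_diatomic, make_random_polyatomic


def si_huang_rhys(omega_cm1: float, dq_amu_ang: float) -> float:
    """Independent SI-unit evaluation of S = omega_ang * dq^2 / (2 hbar)."""
    from scipy import constants as sc

    omega_ang = 2 * np.pi * sc.c * 100.0 * omega_cm1  # rad/s (c in m/s)
    dq_si_sq = dq_amu_ang**2 * sc.atomic_mass * 1e-20  # kg m^2
    return omega_ang * dq_si_sq / (2 * sc.hbar)


def si_mode_energy_ev(omega_cm1: float, dq_amu_ang: float) -> float:
    """Harmonic energy (eV) stored at displacement dq: 0.5 omega^2 dq^2."""
    from scipy import constants as sc

    omega_ang = 2 * np.pi * sc.c * 100.0 * omega_cm1
    dq_si_sq = dq_amu_ang**2 * sc.atomic_mass * 1e-20
    return 0.5 * omega_ang**2 * dq_si_sq / sc.e


class TestHuangRhys:
    def test_zero_displacement(self):
        assert vb.huang_rhys(1234.0, 0.0) == 0.0

    def test_si_oracle(self):
        # omega=1000 cm^-1, dq=1 amu^1/2 A -> S ~ 14.83
        assert vb.huang_rhys(1000.0, 1.0) == pytest.approx(
            si_huang_rhys(1000.0, 1.0), rel=1e-9
        )
        assert vb.huang_rhys(1000.0, 1.0) == pytest.approx(14.83, abs=0.01)

    @pytest.mark.parametrize("omega,s", [(2149.0, 1.978), (500.0, 0.02)])
    def test_algebraic_inverse(self, omega, s):
        dq = vb.delta_q_from_huang_rhys(omega, s)
        assert vb.huang_rhys(omega, dq) == pytest.approx(s, abs=1e-10)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(vb.ValidationError):
            vb.huang_rhys(-100.0, 0.1)
        with pytest.raises(vb.ValidationError):
            vb.huang_rhys(0.0, 0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        omega=st.floats(100.0, 4000.0),
        dq1=st.floats(0.001, 2.0),
        factor=st.floats(1.01, 5.0),
    )
    def test_monotone_in_displacement(self, omega, dq1, factor):
        assert vb.huang_rhys(omega, dq1 * factor) > vb.huang_rhys(omega, dq1)


class TestReorgEnergy:
    @pytest.mark.parametrize(
        "omega,s,lam",
        [(2149.0, 1.978, 0.527), (1704.0, 1.594, 0.337), (2149.0, 0.0, 0.0)],
    )
    def test_mode_reorg_published_values(self, omega, s, lam):
        assert vb.mode_reorg_energy(omega, s) == pytest.approx(lam, abs=5e-4)

    def test_adiabatic_identical_minima(self):
        summary = vb.adiabatic_reorg(-10.0, -10.0, -9.0, -9.0)
        assert summary.lambda_n == 0.0
        assert summary.lambda_i == summary.lambda_n + summary.lambda_c

    def test_adiabatic_negative_relaxation_rejected(self):
        with pytest.raises(vb.ValidationError, match="negative relaxation"):
            vb.adiabatic_reorg(0.0, -0.1, 0.0, 0.0)

    def test_single_mode_quadratic_partition(self):
        # both surfaces omega=1000 cm^-1, displaced by dq=0.3: adiabatic
        # relaxation energy equals hbar*omega*S exactly
        omega, dq = 1000.0, 0.3
        lam = si_mode_energy_ev(omega, dq)
        summary = vb.adiabatic_reorg(0.0, lam, 0.0, lam)
        s = vb.huang_rhys(omega, dq)
        assert summary.lambda_n == pytest.approx(
            vb.mode_reorg_energy(omega, s), rel=1e-9
        )
        assert summary.lambda_i == pytest.approx(2 * lam, rel=1e-9)

    def test_table1_totals(self, hcn_tables):
        neutral, anionic = hcn_tables
        # sums of the printed per-mode lambdas
        assert neutral.total_reorg() == pytest.approx(0.563, abs=1e-9)
        assert anionic.total_reorg() == pytest.approx(0.350, abs=1e-9)
        summary = vb.ReorgSummary(
            neutral.total_reorg(), anionic.total_reorg(), neutral, anionic
        )
        assert summary.lambda_i == pytest.approx(0.913, abs=1e-9)


class TestActivationEnergy:
    def test_activationless_at_s_phonons(self):
        assert vb.activation_energy(2149.0, 1.978, 1.978) == 0.0

    def test_parabola_value(self):
        expected = vb.CONST.wavenumber_to_eV * 2149.0 * (1 - 1.978) ** 2 / (4 * 1.978)
        got = vb.activation_energy(2149.0, 1.978, 1)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0322, abs=5e-5)

    def test_parabola_symmetry_about_s(self):
        s = 1.3
        assert vb.activation_energy(1500.0, s, 2 * s) == pytest.approx(
            vb.activation_energy(1500.0, s, 0.0), rel=1e-12
        )

    def test_singular_at_zero_s(self):
        with pytest.raises(vb.ValidationError, match="singular"):
            vb.activation_energy(1000.0, 0.0, 1)


@pytest.mark.parametrize(
    "s,expected", [(1.978, 2), (1.594, 2), (0.0, 0), (0.5, 1), (2.5, 3), (0.49, 0)]
)
def test_phonon_estimate_half_away_from_zero(s, expected):
    assert vb.phonon_estimate(s) == expected


class TestModeTablePipeline:
    def test_diatomic_recovers_analytic_s(self, diatomic_pair):
        neutral, anion, s_expected = diatomic_pair
        table = vb.build_mode_table(neutral, anion, "neutral")
        assert len(table) == 1
        assert table.rows[0].huang_rhys == pytest.approx(s_expected, abs=1e-8)

    def test_identical_states_all_zero(self, polyatomic_pair):
        neutral, _, _ = polyatomic_pair
        from vibronic.models import StateHarmonicModel

        twin = StateHarmonicModel(
            "anion", -1, neutral.atoms, neutral.geometry.copy(),
            neutral.frequencies, neutral.mode_matrix,
        )
        table = vb.build_mode_table(neutral, twin, "neutral")
        np.testing.assert_allclose(table.huang_rhys_factors, 0.0, atol=1e-12)

    def test_parameter_recovery_random_polyatomic(self, polyatomic_pair):
        neutral, anion, s_targets = polyatomic_pair
        table = vb.build_mode_table(neutral, anion, "neutral")
        np.testing.assert_allclose(
            table.huang_rhys_factors, s_targets, atol=1e-8
        )

    def test_table_sorted_by_frequency(self, polyatomic_pair):
        neutral, anion, _ = polyatomic_pair
        table = vb.build_mode_table(neutral, anion, "neutral")
        assert np.all(np.diff(table.omegas) >= 0)

    def test_harmonic_partition_identity(self, polyatomic_pair):
        # sum_j hbar*omega_j*S_j equals the independently computed quadratic
        # relaxation energy to 1e-10 (relative)
        neutral, anion, _ = polyatomic_pair
        res = vb.normal_mode_displacements(neutral, anion, "neutral")
        adiabatic = sum(
            si_mode_energy_ev(w, dq)
            for w, dq in zip(neutral.frequencies, res.delta_q)
        )
        table = vb.build_mode_table(neutral, anion, "neutral")
        assert table.total_reorg() == pytest.approx(adiabatic, rel=1e-10)

    def test_isotope_substitution_closed_form(self):
        # H->D on a heteronuclear diatomic: omega scales by sqrt(muH/muD)
        # and the recovered S follows S = k omega mu dr^2
        m_heavy, dr, omega_h = 12.0, 0.05, 3000.0
        mu_h = 1.0 * m_heavy / (1.0 + m_heavy)
        mu_d = 2.0 * m_heavy / (2.0 + m_heavy)
        omega_d = omega_h * np.sqrt(mu_h / mu_d)
        pair_h = make_displaced_diatomic(1.0, m_heavy, omega_h, dr)
        pair_d = make_displaced_diatomic(2.0, m_heavy, omega_d, dr)
        s_h = vb.build_mode_table(pair_h[0], pair_h[1], "neutral").huang_rhys_factors[0]
        s_d = vb.build_mode_table(pair_d[0], pair_d[1], "neutral").huang_rhys_factors[0]
        assert s_h == pytest.approx(si_huang_rhys(omega_h, np.sqrt(mu_h) * dr), rel=1e-9)
        assert s_d / s_h == pytest.approx((omega_d * mu_d) / (omega_h * mu_h), rel=1e-9)

    def test_reorg_summary_combines_both_bases(self):
        neutral, anion = make_random_polyatomic(4, 3, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        summary = vb.reorg_summary(neutral, anion)
        assert summary.lambda_i == pytest.approx(
            summary.lambda_n + summary.lambda_c, rel=1e-12
        )
        assert summary.per_mode_neutral.total_reorg() == pytest.approx(
            summary.lambda_n
        )
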