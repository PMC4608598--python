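import numpy as np
import pandas as pd
import pytest

from antioxkit.dpph import absorbance_to_dpph
from antioxkit.exceptions import DomainError, ValidationError
from antioxkit.io import read_timecourses
from antioxkit.simulate import (
    SimSpec,
    bcb_spec,
    caa_spec,
    dpph_ec50_spec,
    dpph_kinetics_spec,
    dr2_spec,
    simulate_bcb,
    simulate_caa,
    simulate_dpph,
    simulate_dr2,
    stoichiometry_for_ec50,
    true_dpph_ec50,
)


class TestSimSpec:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValidationError):
            SimSpec("dpph", (1.0, 2.0), (0.0, 60.0), {}, seed=None)

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            SimSpec("dpph", (1.0, 1.0), (0.0, 60.0), {}, seed=1)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            SimSpec("dpph", (1.0, 2.0), (0.0, 60.0), {}, seed=1, noise_sd=-0.1)


class TestDpphSimulator:
    def test_zero_rate_constant_gives_flat_absorbance(self):
        spec = dpph_kinetics_spec(k2=0.0, seed=1, noise_sd=0.0)
        table = simulate_dpph(spec)
        sig = table.select(role="sample")["signal"]
        expected = 12509.0 * 70e-6 - 2.58e-3
        assert np.allclose(sig, expected, atol=1e-12)

    def test_pseudo_first_order_limit_matches_exponential(self):
        """With the antioxidant in large excess the radical trace is a
        single exponential with kobs = k2 * [AH]0 over the first half-life."""
        k2, aox0 = 1e-4, 2000.0
        kobs = k2 * aox0
        half_life = np.log(2) / kobs
        t = tuple(np.linspace(0, half_life, 12))
        spec = SimSpec(
            "dpph", (aox0,), t,
            {"k2": k2, "s": 1.0, "dpph0_uM": 70.0},
            seed=2, noise_sd=0.0, replicates=1,
        )
        table = simulate_dpph(spec)
        a = table.select(role="sample")["signal"].to_numpy()
        d = absorbance_to_dpph(np.clip(a, 0, None)) * 1e6
        expected = 70.0 * np.exp(-kobs * np.asarray(t))
        assert np.allclose(d, expected, rtol=0.02)

    def test_seed_determinism_is_byte_identical(self, tmp_path):
        spec = dpph_kinetics_spec(k2=1e-5, seed=7, noise_sd=0.002)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        simulate_dpph(spec).to_csv(p1)
        simulate_dpph(dpph_kinetics_spec(k2=1e-5, seed=7, noise_sd=0.002)).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_stoichiometry_targets_the_ec50(self):
        assert stoichiometry_for_ec50(20.0, 70.0) == pytest.approx(1.75)
        spec = dpph_ec50_spec(ec50_uM=20.0, seed=1)
        assert true_dpph_ec50(spec) == pytest.approx(20.0, rel=0.005)

    def test_non_physical_parameters_rejected(self):
        spec = dpph_kinetics_spec(k2=1e-5, seed=1)
        spec.true_params["s"] = -1.0
        with pytest.raises(DomainError):
            simulate_dpph(spec)


class TestDr2Simulator:
    def test_zero_k_s_gives_flat_inhibition(self):
        spec = dr2_spec(k_s=0.0, k_dr=3.1e9, seed=3, noise_sd=0.0)
        table = simulate_dr2(spec)
        from antioxkit.deoxyribose import dr2_inhibition_curve

        curve = dr2_inhibition_curve(table, "cmpd")
        assert np.allclose(curve.response, 0.0, atol=1e-9)

    def test_control_corrected_to_a0(self):
        spec = dr2_spec(k_s=9e9, k_dr=3.1e9, seed=4, noise_sd=0.0, a0=0.85)
        from antioxkit.deoxyribose import dr2_blank_correct

        _, _, a0 = dr2_blank_correct(simulate_dr2(spec), "cmpd")
        assert a0 == pytest.approx(0.85, abs=1e-12)


class TestGeneratedTablesParse:
    """Every generator's output survives a CSV round trip through the reader."""

    @pytest.mark.parametrize(
        "make",
        [
            lambda: simulate_dpph(dpph_kinetics_spec(k2=1e-5, seed=11)),
            lambda: simulate_dpph(dpph_ec50_spec(ec50_uM=20.0, seed=12)),
            lambda: simulate_dr2(dr2_spec(k_s=9.05e9, k_dr=3.1e9, seed=13)),
            lambda: simulate_bcb(bcb_spec(seed=14, ic50_uM=36.0)),
            lambda: simulate_caa(caa_spec(protection_factor=0.5, seed=15)),
        ],
        ids=["dpph-kinetics", "dpph-ec50", "dr2", "bcb", "caa"],
    )
    def test_round_trip(self, make, tmp_path):
        table = make()
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = read_timecourses(path)
        assert len(back) == len(table)
        pd.testing.assert_frame_equal(
            back.data, table.data.reset_index(drop=True), check_exact=False, rtol=0, atol=1e-12
        )
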