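"""Species × PPFD regression, response curves, early-PCS correlation."""

import numpy as np
import pandas as pd
import pytest

from canolux import (
    LightTreatment,
    NoiseModel,
    RegressionSpec,
    SyntheticExperiment,
    early_pcs_correlation,
    fit_response_curve,
    fit_species_ppfd_model,
    generate_experiment,
    generate_physiology,
)
from canolux.light import MEASURED_PPFDS


def _physiology_table(species, noise, seed=0, n_blocks=3):
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species.values():
        for p in MEASURED_PPFDS:
            for block in range(1, n_blocks + 1):
                rows.append(generate_physiology(
                    sp, LightTreatment(ppfd=p), noise, block=block, rng=rng
                ))
    return pd.DataFrame(rows)


class TestSpeciesPpfdModel:
    def test_zero_noise_additive_model_recovered(self, species, zero_noise):
        """Φ_PSII: common slope −0.0003 and +0.05 mizuna offset with no
        interaction — the pruning drops the interaction and recovers both
        coefficients exactly."""
        df = _physiology_table(species, zero_noise)
        res = fit_species_ppfd_model(df, RegressionSpec(response="phipsii"))
        assert res.interaction_dropped
        assert res.coefficients["ppfd"] == pytest.approx(-0.0003, rel=1e-9)
        assert res.coefficients["species"] == pytest.approx(0.05, rel=1e-9)
        assert set(res.coefficients) == {"intercept", "ppfd", "species"}

    def test_species_specific_slopes_keep_interaction(self, species):
        """CCI slopes 0.08 vs 0.01 differ strongly: the interaction is
        retained at default noise and the mizuna slope is recovered."""
        df = _physiology_table(species, NoiseModel(), seed=10)
        res = fit_species_ppfd_model(df, RegressionSpec(response="cci"))
        assert not res.interaction_dropped
        assert res.slope_for("mizuna") == pytest.approx(0.08, rel=0.15)
        assert res.slope_for("lettuce") == pytest.approx(0.01, abs=0.01)

    def test_constant_response_degenerate(self, species):
        df = _physiology_table(species, NoiseModel().zero())
        df["flat"] = 7.0
        res = fit_species_ppfd_model(df, RegressionSpec(response="flat"))
        assert res.coefficients["ppfd"] == 0.0
        assert res.coefficients["species"] == 0.0
        assert res.r_squared == 0.0

    def test_reference_swap_negates_offset(self, species):
        """Dummy-coding equivalence: swapping the reference species negates
        the species offset and preserves fitted values."""
        df = _physiology_table(species, NoiseModel(), seed=3)
        a = fit_species_ppfd_model(
            df, RegressionSpec(response="phipsii", reference_species="lettuce")
        )
        b = fit_species_ppfd_model(
            df, RegressionSpec(response="phipsii", reference_species="mizuna")
        )
        assert a.coefficients["species"] == pytest.approx(
            -b.coefficients["species"], rel=1e-9
        )
        assert a.r_squared == pytest.approx(b.r_squared, rel=1e-12)

    def test_single_species_rejected(self, species, zero_noise):
        df = _physiology_table(species, zero_noise)
        with pytest.raises(ValueError, match="2 species"):
            fit_species_ppfd_model(df[df.species == "mizuna"],
                                   RegressionSpec(response="cci"))

    def test_interaction_type_i_error_near_alpha(self, species):
        """On null (no-interaction) data the interaction is retained in
        ≈ α of simulations — the pruning rule's false-keep rate."""
        rng = np.random.default_rng(12)
        ppfd = np.tile(np.repeat(MEASURED_PPFDS, 3), 2)
        dummy = np.repeat([0.0, 1.0], 18)
        kept = 0
        n_sim = 500
        for _ in range(n_sim):
            y = 0.7 - 0.0003 * ppfd + 0.05 * dummy + rng.normal(0, 0.02, 36)
            df = pd.DataFrame({
                "species": np.where(dummy > 0, "mizuna", "lettuce"),
                "ppfd": ppfd, "y": y,
            })
            res = fit_species_ppfd_model(df, RegressionSpec(response="y"))
            kept += not res.interaction_dropped
        rate = kept / n_sim
        # binomial 99.9% band around 0.05 with n=500 is ±~0.032
        assert 0.05 - 0.035 <= rate <= 0.05 + 0.035


class TestResponseCurves:
    def test_exponential_rise_recovery(self):
        x = np.array(MEASURED_PPFDS)
        y = 340.0 * (1.0 - np.exp(-0.015 * x))
        res = fit_response_curve(x, y, form="exponential_rise")
        assert res.parameters["A"] == pytest.approx(340.0, rel=1e-3)
        assert res.parameters["k"] == pytest.approx(0.015, rel=1e-3)

    def test_collinear_linear_fit_r2_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = fit_response_curve(x, 2.5 * x + 1.0, form="linear")
        assert res.r_squared == pytest.approx(1.0)

    def test_two_point_dry_weight_slope(self):
        """The mizuna dry-weight endpoints give 15.8 mg per µmol m⁻² s⁻¹."""
        res = fit_response_curve([50.0, 425.0], [0.11, 6.02], form="linear")
        slope_mg = res.parameters["slope"] * 1000
        assert slope_mg == pytest.approx(15.76, abs=1e-9)
        assert float(f"{slope_mg:.3g}") == 15.8

    def test_quadratic_exact(self):
        x = np.arange(5.0)
        res = fit_response_curve(x, 2 - x + 0.5 * x**2, form="quadratic")
        assert res.parameters["c2"] == pytest.approx(0.5, rel=1e-9)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError, match="unknown form"):
            fit_response_curve([1, 2, 3], [1, 2, 3], form="cubic")


class TestEarlyPcsCorrelation:
    def test_proportional_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = early_pcs_correlation(x, 3 * x)
        assert r == pytest.approx(1.0)
        r, _ = early_pcs_correlation(x, -2 * x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            early_pcs_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_generator_reproduces_strong_early_dw_correlation(self, tmp_path):
        """Across seeds, early PCS (day 8 mizuna / day 10 lettuce) and final
        dry weight correlate strongly — the generator's shared PPFD
        dependence.  Mizuna's PCS asymptote rises over four PPFD levels, so
        its median R clears 0.8; lettuce PCS plateaus at all PPFD ≥ 128
        (identical asymptote), which caps the early-PCS spread and hence
        the attainable correlation for lettuce."""
        config = SyntheticExperiment(
            write_images=False, base_imaging_days=(4, 7, 8, 10, 14, 18, 21, 25)
        )
        rs = {"mizuna": [], "lettuce": []}
        for seed in range(20):
            d = tmp_path / f"s{seed}"
            generate_experiment(config, d, seed=seed)
            pcs = pd.read_csv(d / "pcs_truth_long.csv")
            harvest = pd.read_csv(d / "harvest.csv")
            for sp, day in (("mizuna", 8), ("lettuce", 10)):
                early = pcs[(pcs.species == sp) & (pcs.day == day)]
                m = early.merge(harvest[harvest.species == sp],
                                on=["species", "ppfd", "block"])
                r, _ = early_pcs_correlation(m["pcs_cm2_per_plant"],
                                             m["dry_weight_g"])
                rs[sp].append(r)
        assert np.median(rs["mizuna"]) >= 0.8
        assert np.median(rs["lettuce"]) >= 0.6
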