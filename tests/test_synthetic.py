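"""Synthetic experiment generator: parameters, trajectories, images, dataset."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canolux import (
    LightTreatment,
    NoiseModel,
    SyntheticExperiment,
    default_species_params,
    generate_experiment,
    generate_pcs_trajectory,
    generate_physiology,
    render_canopy_image,
    true_total_incident_light,
)


class TestDefaultSpeciesParams:
    def test_reference_anchored_values(self, species):
        mz, lt = species["mizuna"], species["lettuce"]
        assert mz.pcs_asymptote_by_ppfd[210.0] == 340.0
        assert lt.pcs_asymptote_by_ppfd[281.0] == 240.0
        assert mz.phipsii_slope == pytest.approx(-0.0003)
        assert lt.phipsii_slope == pytest.approx(-0.0003)
        assert mz.cci_slope == pytest.approx(0.08)
        assert lt.cci_slope == pytest.approx(0.01)
        assert mz.aci_slope == pytest.approx(0.015)
        assert lt.aci_slope == pytest.approx(0.004)
        assert mz.assim_slope == pytest.approx(0.044)
        assert lt.assim_slope == pytest.approx(0.035)
        assert mz.harvest_day == 27 and lt.harvest_day == 28

    def test_species_offsets(self, species):
        mz, lt = species["mizuna"], species["lettuce"]
        # Φ_PSII of mizuna sits ~0.05 above lettuce at equal PPFD
        assert mz.phipsii_intercept - lt.phipsii_intercept == pytest.approx(0.05)
        # mizuna LUE exceeds lettuce LUE at every PPFD
        for p, lue in mz.lue_by_ppfd.items():
            assert lue > lt.lue_by_ppfd[p]

    def test_invariant_validation(self, species):
        mz = species["mizuna"]
        with pytest.raises(ValueError, match="overlap"):
            type(mz)(**{**mz.__dict__, "overlap_ratio_by_ppfd": {210.0: 0.5}})
        with pytest.raises(ValueError, match="harvest_day"):
            type(mz)(**{**mz.__dict__, "harvest_day": 40})


class TestPcsTrajectory:
    def test_midpoint_and_derived_values(self, species, treatment_by_ppfd,
                                          zero_noise):
        mz = species["mizuna"]
        traj = generate_pcs_trajectory(
            mz, treatment_by_ppfd[210.0], zero_noise, [4, 11, 18, 25]
        )
        # at d = x0 the noise-free PCS equals a/2 exactly
        assert traj.pcs[2] == pytest.approx(340.0 / 2, rel=1e-12)
        assert traj.truth == {"a": 340.0, "x0": 18.0, "b": 3.0}

    def test_lettuce_point_value(self, species, treatment_by_ppfd, zero_noise):
        lt = species["lettuce"]
        traj = generate_pcs_trajectory(
            lt, treatment_by_ppfd[281.0], zero_noise, [4, 8, 12, 16]
        )
        assert traj.pcs[2] == pytest.approx(28.6087012853, rel=1e-9)

    def test_noise_is_mean_one(self, species, treatment_by_ppfd):
        """Multiplicative PCS noise has unit mean: the average over many
        draws converges to the clean sigmoid."""
        mz = species["mizuna"]
        noise = NoiseModel(pcs_cv=0.05)
        rng = np.random.default_rng(3)
        vals = [
            generate_pcs_trajectory(mz, treatment_by_ppfd[210.0], noise,
                                    [18], rng=rng).pcs[0]
            for _ in range(3000)
        ]
        assert np.mean(vals) == pytest.approx(170.0, rel=0.01)

    def test_empty_days_rejected(self, species, treatment_by_ppfd, zero_noise):
        with pytest.raises(ValueError):
            generate_pcs_trajectory(
                species["mizuna"], treatment_by_ppfd[210.0], zero_noise, []
            )


class TestRenderCanopyImage:
    def test_pixel_count_matches_requested_area(self):
        img, gt = render_canopy_image(100.0, 2.0, n_plants=1,
                                      pixel_scale=0.05, seed=0)
        assert gt["foreground_px"] == pytest.approx(100.0 / 0.05**2, rel=0.01)

    def test_degenerate_area_rejected(self):
        with pytest.raises(ValueError):
            render_canopy_image(0.0, 2.0)

    def test_drawn_leaf_area_tracks_overlap_ratio(self):
        """PCS 240 cm² at overlap 5 draws ≈ 1200 cm² of leaf per plant."""
        img, gt = render_canopy_image(240.0, 5.0, n_plants=1,
                                      pixel_scale=0.1, seed=1)
        assert gt["drawn_leaf_area_cm2"] == pytest.approx(1200.0, rel=0.03)

    def test_contrast_separation(self):
        img, _ = render_canopy_image(50.0, 1.5, n_plants=4, pixel_scale=0.1,
                                     seed=2, noise_sd=4.0)
        fg = img.pixels[img.pixels > 100]
        bg = img.pixels[img.pixels <= 100]
        assert fg.min() - bg.max() >= 50

    def test_canvas_capacity_guard(self):
        with pytest.raises(ValueError, match="canvas"):
            render_canopy_image(300.0, 2.0, n_plants=9, pixel_scale=0.1,
                                canvas_px=(50, 50))

    @given(pcs=st.floats(10.0, 400.0), ov=st.sampled_from([1.1, 2.3, 5.2]))
    @settings(max_examples=15, deadline=None)
    def test_area_accuracy_sweep(self, pcs, ov):
        """Foreground area is within 1% of the request across the PCS range."""
        _, gt = render_canopy_image(pcs, ov, n_plants=1, pixel_scale=0.1,
                                    seed=7)
        assert gt["pcs_per_plant_cm2"] == pytest.approx(pcs, rel=0.01)


class TestPhysiology:
    def test_intercepts_at_zero_ppfd(self, species, zero_noise):
        mz = species["mizuna"]
        rec = generate_physiology(mz, LightTreatment(ppfd=0.0), zero_noise)
        assert rec["cci"] == pytest.approx(mz.cci_intercept)
        assert rec["aci"] == pytest.approx(mz.aci_intercept)
        assert rec["phipsii"] == pytest.approx(mz.phipsii_intercept)
        assert rec["assimilation"] == pytest.approx(mz.assim_intercept)

    def test_printed_response_deltas(self, species, zero_noise):
        """ΔCCI over the 50→400 PPFD span is 0.08 × 350 = 28 for mizuna and
        ΔACI is 0.004 × 350 = 1.4 for lettuce."""
        lo, hi = LightTreatment(ppfd=50.0), LightTreatment(ppfd=400.0)
        for name, key, delta in (("mizuna", "cci", 28.0),
                                 ("lettuce", "aci", 1.4)):
            sp = species[name]
            r_lo = generate_physiology(sp, lo, zero_noise)
            r_hi = generate_physiology(sp, hi, zero_noise)
            assert r_hi[key] - r_lo[key] == pytest.approx(delta, rel=1e-9)

    def test_phipsii_stays_physical(self, species):
        noise = NoiseModel(physiology_sd={"cci": 0, "aci": 0,
                                          "phipsii": 0.5, "assimilation": 0})
        rng = np.random.default_rng(0)
        for _ in range(50):
            rec = generate_physiology(species["lettuce"],
                                      LightTreatment(ppfd=410.0), noise,
                                      rng=rng)
            assert 0 < rec["phipsii"] < 0.85


class TestGenerateExperiment:
    def test_unit_count_and_tables(self, default_dataset):
        harvest = pd.read_csv(default_dataset["harvest"])
        assert len(harvest) == 6 * 2 * 3  # PPFDs x species x blocks
        truth = pd.read_csv(default_dataset["truth"])
        assert len(truth) == 36
        pcs = pd.read_csv(default_dataset["pcs_truth_long"])
        # every unit has >= 5 imaging days (here 8)
        assert pcs.groupby(["species", "ppfd", "block"]).size().min() >= 5

    def test_dry_weight_lue_identity_noise_free(self, tmp_path, species,
                                                treatments):
        """With dw_cv = 0, harvest DW / true incident light reproduces the
        generating LUE to round-off for every unit."""
        config = SyntheticExperiment(noise=NoiseModel().zero(),
                                     write_images=False)
        generate_experiment(config, tmp_path, seed=5)
        harvest = pd.read_csv(tmp_path / "harvest.csv")
        truth = pd.read_csv(tmp_path / "truth.csv")
        m = harvest.merge(truth, on=["species", "ppfd", "block"])
        lue = m["dry_weight_g"] / m["true_total_incident_mol"]
        assert np.allclose(lue, m["true_lue_g_mol"], rtol=1e-12)
        # leaf area identity: overlap ratio x PCS at harvest
        assert np.allclose(
            m["leaf_area_cm2"],
            m["true_overlap_ratio"] * m["true_pcs_at_harvest_cm2"],
            rtol=1e-12,
        )

    def test_same_seed_byte_identical(self, tmp_path):
        """The determinism contract: one seed, one dataset."""
        config = SyntheticExperiment(write_images=False)
        digests = []
        for sub in ("a", "b"):
            paths = generate_experiment(config, tmp_path / sub, seed=99)
            h = hashlib.sha256()
            for name in sorted(paths):
                h.update(Path(paths[name]).read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_mizuna_ppfd128_unit_lue(self, species, treatment_by_ppfd):
        """The low-PPFD mizuna unit is built at the maximum LUE 1.26 g/mol."""
        mz = species["mizuna"]
        t = treatment_by_ppfd[128.0]
        assert mz.lue_by_ppfd[128.0] == 1.26
        dw = mz.lue_by_ppfd[128.0] * true_total_incident_light(mz, t)
        assert dw / true_total_incident_light(mz, t) == pytest.approx(1.26)
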