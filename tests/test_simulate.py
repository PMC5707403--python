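"""Cohort generator and spectral renderer: determinism, closed forms, caps."""
import math

import numpy as np
import pandas as pd
import pytest

from arrestomix.simulate import (
    CohortConfig,
    MetaboliteSpec,
    default_cohort_config,
    generate_cohort,
    generate_spectra,
    to_tidy,
)


def one_metabolite_config(slope=math.log(2.0), cap=math.inf, **overrides):
    spec = MetaboliteSpec(
        name="m", baseline_mean=10.0, baseline_cv=0.0, animal_intercept_sd=0.0,
        slope_per_min={("ACA", "asphyxia", "*"): slope},
        max_fold_change={} if math.isinf(cap) else {"*": cap},
        ppm_peaks=[(2.0, 1.0, 0.01)],
    )
    kwargs = dict(
        n_animals_per_group=2,
        metabolite_specs=[spec],
        noise_sd_frac=0.0,
        asphyxia_duration_range_min=(4, 4),
        cpr_duration_range_min=(3, 3),
        random_seed=5,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


class TestGenerateCohort:
    def test_doubling_slope_two_minutes_gives_ratio_four(self):
        quant, meta, truth = generate_cohort(one_metabolite_config())
        aca = meta[(meta.group == "ACA") & (meta.phase == "asphyxia") & (meta.minute_in_phase == 2)]
        base = meta[(meta.group == "ACA") & (meta.phase == "baseline")]
        for animal in aca.animal_id:
            v2 = quant.loc[aca[aca.animal_id == animal].index[0], "m"]
            v0 = quant.loc[base[base.animal_id == animal].index[0], "m"]
            assert v2 / v0 == pytest.approx(4.0, rel=1e-12)

    def test_same_seed_identical_tables(self):
        config = default_cohort_config(seed=42)
        q1, m1, t1 = generate_cohort(config)
        q2, m2, t2 = generate_cohort(default_cohort_config(seed=42))
        pd.testing.assert_frame_equal(q1, q2)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1.fold_change, t2.fold_change)

    def test_noiseless_matches_closed_form_trajectory(self):
        slope = 0.31
        quant, meta, truth = generate_cohort(one_metabolite_config(slope=slope))
        asp = meta[meta.phase == "asphyxia"]
        for sid, row in asp.iterrows():
            g = truth.fold_change.loc[sid, "m"]
            assert g == pytest.approx(math.exp(slope * row.minute_in_phase), rel=1e-12)
            assert quant.loc[sid, "m"] == pytest.approx(10.0 * g, rel=1e-12)

    def test_succinate_fold_change_caps_by_damage_class(self, cohort):
        """Damaged animals at most 40-fold, no-damaged at most 3-fold above baseline."""
        _, quant, meta, truth = None, *cohort[1:]
        fc = truth.fold_change["succinate"]
        damaged = meta[meta.damage_class == "damaged"].index
        nodam = meta[meta.damage_class == "no-damaged"].index
        assert fc.loc[damaged].max() <= 40.0 * (1 + 1e-12)
        assert fc.loc[nodam].max() <= 3.0 * (1 + 1e-12)
        # the damaged trajectories actually reach far above the no-damaged cap
        assert fc.loc[damaged].max() > 10.0

    def test_damaged_fraction_exact_and_only_aca(self, cohort):
        config, _, meta, _ = cohort
        per_animal = meta.drop_duplicates("animal_id")
        aca = per_animal[per_animal.group == "ACA"]
        vfca = per_animal[per_animal.group == "VFCA"]
        assert (aca.damage_class == "damaged").sum() == round(
            config.damaged_fraction_aca * config.n_animals_per_group
        )
        assert (vfca.damage_class == "n/a").all()

    def test_metadata_keys_unique(self, cohort):
        _, _, meta, _ = cohort
        keys = meta.reset_index()[["animal_id", "phase", "minute_in_phase"]]
        assert not keys.duplicated().any()

    def test_post_rosc_decays_toward_baseline(self):
        quant, meta, truth = generate_cohort(one_metabolite_config(slope=0.4, cap=10.0))
        late = meta[(meta.group == "ACA") & (meta.phase == "24h")]
        assert (truth.fold_change.loc[late.index, "m"] < 1.05).all()

    def test_empty_specs_error(self):
        with pytest.raises(ValueError, match="metabolite_specs"):
            CohortConfig(metabolite_specs=[])

    def test_nonpositive_duration_error(self):
        with pytest.raises(ValueError, match="duration"):
            one_metabolite_config(asphyxia_duration_range_min=(0, 4))

    def test_tidy_layout_round_trips_values(self, cohort):
        _, quant, meta, _ = cohort
        tidy = to_tidy(quant, meta)
        assert set(tidy.columns) >= {"sample_id", "animal_id", "group", "phase",
                                     "minute", "metabolite", "value"}
        wide = tidy.pivot(index="sample_id", columns="metabolite", values="value")
        np.testing.assert_allclose(
            wide.loc[quant.index, quant.columns].to_numpy(), quant.to_numpy()
        )


class TestGenerateSpectra:
    def one_peak_spec(self, center=2.0):
        return MetaboliteSpec(name="m", baseline_mean=1.0,
                              ppm_peaks=[(center, 1.0, 0.01)])

    def test_area_linear_in_concentration(self):
        quant = pd.DataFrame({"m": [1.0, 3.5]}, index=["s1", "s2"])
        raw = generate_spectra(quant, [self.one_peak_spec()], noise_sd=0.0)
        areas = np.trapezoid(raw.intensities, raw.ppm, axis=1)
        assert areas[1] / areas[0] == pytest.approx(3.5, rel=1e-6)

    def test_disjoint_peaks_recover_concentration_ratio(self):
        """Numeric integration over each peak's region recovers the ratio."""
        s1 = MetaboliteSpec(name="a", baseline_mean=1.0, ppm_peaks=[(2.0, 1.0, 0.005)])
        s2 = MetaboliteSpec(name="b", baseline_mean=1.0, ppm_peaks=[(7.0, 1.0, 0.005)])
        quant = pd.DataFrame({"a": [2.0], "b": [5.0]}, index=["s"])
        raw = generate_spectra(quant, [s1, s2], ppm_grid_step=0.001, noise_sd=0.0)
        ra = (raw.ppm > 1.5) & (raw.ppm < 2.5)
        rb = (raw.ppm > 6.5) & (raw.ppm < 7.5)
        ia = np.trapezoid(raw.intensities[0, ra], raw.ppm[ra])
        ib = np.trapezoid(raw.intensities[0, rb], raw.ppm[rb])
        assert ib / ia == pytest.approx(5.0 / 2.0, rel=1e-3)

    def test_zero_concentration_gives_flat_baseline(self):
        quant = pd.DataFrame({"m": [0.0]}, index=["s"])
        raw = generate_spectra(quant, [self.one_peak_spec()], baseline_amp=2.0, noise_sd=0.0)
        expected = 2.0 * np.exp(-((raw.ppm - 4.5) ** 2) / 18.0)
        np.testing.assert_allclose(raw.intensities[0], expected, atol=1e-12)

    def test_peak_outside_grid_errors(self):
        quant = pd.DataFrame({"m": [1.0]}, index=["s"])
        with pytest.raises(ValueError, match="outside"):
            generate_spectra(quant, [self.one_peak_spec()], ppm_min=3.0, ppm_max=9.0)

    def test_intensities_clipped_nonnegative(self):
        quant = pd.DataFrame({"m": [0.1]}, index=["s"])
        raw = generate_spectra(quant, [self.one_peak_spec()], noise_sd=5.0, seed=1)
        assert raw.intensities.min() >= 0.0
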