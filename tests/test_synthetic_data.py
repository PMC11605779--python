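"""Dose arithmetic, kinetic primitives, and cohort-generator guarantees."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from silycat.kinetics import feature_kinetics
from silycat.metabolome_stats import effect_table
from silycat.synthetic_data import (
    CohortDesign,
    DoseSpec,
    build_reference_fixture,
    default_kinetic_specs,
    final_concentration,
    final_course,
    parent_decay,
    simulate_cohort,
    transient_course,
)


class TestDoseArithmetic:
    def test_standard_well_reaches_50_ug_ml(self):
        # 25 µL of 2 mg/mL into the 1000 µL well (835 + 40 + 100 + 25)
        assert final_concentration(DoseSpec()) == pytest.approx(50.0)

    def test_zero_treatment_volume(self):
        assert final_concentration(replace(DoseSpec(), treatment_ul=0.0)) == 0.0

    def test_scaling_all_volumes_leaves_concentration_unchanged(self):
        d = DoseSpec()
        doubled = DoseSpec(
            working_concentration=d.working_concentration,
            medium_ul=2 * d.medium_ul,
            reducing_ul=2 * d.reducing_ul,
            fecal_ul=2 * d.fecal_ul,
            treatment_ul=2 * d.treatment_ul,
        )
        assert final_concentration(doubled) == pytest.approx(final_concentration(d))
        assert final_concentration(d) == pytest.approx(
            d.working_concentration * d.treatment_ul / 1000.0
        )


class TestKineticPrimitives:
    def test_parent_decay_closed_forms(self):
        assert parent_decay(5.0, 0.3, 0.0) == 5.0
        np.testing.assert_allclose(parent_decay(5.0, 0.0, [0, 4, 24]), 5.0)
        k = 0.4
        assert parent_decay(8.0, k, np.log(2) / k) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            parent_decay(1.0, 0.1, -1.0)

    def test_transient_starts_at_zero_and_peaks_at_closed_form_argmax(self):
        k1, k2 = 0.5, 0.15
        assert transient_course(3.0, k1, k2, 0.0) == 0.0
        t_star = np.log(k2 / k1) / (k2 - k1)
        grid = np.linspace(0.01, 30, 5000)
        vals = transient_course(3.0, k1, k2, grid)
        assert grid[np.argmax(vals)] == pytest.approx(t_star, abs=0.02)

    def test_equal_rate_limit_is_continuous(self):
        t = np.array([0.5, 2.0, 6.0])
        lim = transient_course(1.0, 0.4, 0.4, t)
        near = transient_course(1.0, 0.4, 0.4000001, t)
        np.testing.assert_allclose(lim, near, rtol=1e-4)
        np.testing.assert_allclose(lim, 0.4 * t * np.exp(-0.4 * t))

    def test_slow_decay_limit_approaches_cumulative_formation(self):
        t = np.array([1.0, 4.0, 12.0])
        slow = transient_course(1.0, 0.3, 1e-7, t)
        np.testing.assert_allclose(slow, 1.0 - np.exp(-0.3 * t), rtol=1e-5)

    def test_lagged_final_course_silent_before_onset(self):
        v = final_course(2.0, 0.25, np.array([0.0, 2.0, 4.0, 8.0, 24.0]), lag=6.0)
        assert (v[:3] == 0.0).all() and v[3] > 0 and v[4] > v[3]


class TestCohortGenerator:
    def test_same_seed_is_byte_identical(self):
        a = simulate_cohort(CohortDesign(seed=5))
        b = simulate_cohort(CohortDesign(seed=5))
        pd.testing.assert_frame_equal(a.features, b.features)
        pd.testing.assert_frame_equal(a.metabolites, b.metabolites)
        pd.testing.assert_frame_equal(a.taxa_genus, b.taxa_genus)

    def test_control_wells_carry_no_silymarin_signal(self, cohort):
        ctrl = cohort.meta.index[cohort.meta["arm"] == "control"]
        signal_ids = [s.feature_id for s in cohort.kinetic_specs if s.role != "decoy"]
        assert (cohort.features.loc[signal_ids, ctrl].to_numpy() == 0.0).all()

    def test_parents_fully_degraded_by_24h(self, cohort):
        t24 = cohort.meta.index[
            (cohort.meta["arm"] == "treatment") & (cohort.meta["timepoint"] == 24.0)
        ]
        parent_ids = [s.feature_id for s in cohort.kinetic_specs if s.role == "parent"]
        t0 = cohort.meta.index[
            (cohort.meta["arm"] == "treatment") & (cohort.meta["timepoint"] == 0.0)
        ]
        frac = (
            cohort.features.loc[parent_ids, t24].to_numpy().mean()
            / cohort.features.loc[parent_ids, t0].to_numpy().mean()
        )
        assert frac < 0.01

    def test_group_multiplier_transfers_exactly_to_auc_without_noise(self):
        specs = [
            replace(s, group_multiplier=2.5) if s.feature_id == "C08" else s
            for s in default_kinetic_specs()
        ]
        c = simulate_cohort(
            CohortDesign(seed=0),
            kinetic_specs=specs,
            donor_amplitude_sd=0.0,
            donor_rate_sd=0.0,
            intensity_cv=0.0,
        )
        kin = feature_kinetics(c.features.loc[["C08"]], c.meta)
        donors = c.design.donors
        young = kin[[f"auc_{d}" for d in donors[:10]]].to_numpy().mean()
        elder = kin[[f"auc_{d}" for d in donors[10:]]].to_numpy().mean()
        assert elder / young == pytest.approx(2.5, abs=1e-6)

    def test_unknown_coupling_taxon_rejected(self):
        specs = [
            replace(s, coupled_taxon="NoSuchGenus") if s.feature_id == "C01" else s
            for s in default_kinetic_specs()
        ]
        with pytest.raises(ValueError, match="unknown taxon"):
            simulate_cohort(CohortDesign(seed=0), kinetic_specs=specs)

    def test_planted_group_differential_genera(self, cohort):
        gen = cohort.taxa_genus
        meta = cohort.taxa_meta
        young = meta.index[(meta["age_group"] == "young") & (meta["timepoint"] == 0.0) & (meta["arm"] == "control")]
        elder = meta.index[(meta["age_group"] == "elder") & (meta["timepoint"] == 0.0) & (meta["arm"] == "control")]
        rel = gen / gen.sum(axis=0)
        assert rel.loc["Faecalibacterium", young].mean() > 1.5 * rel.loc["Faecalibacterium", elder].mean()
        assert rel.loc["Oscillibacter", elder].mean() > 1.5 * rel.loc["Oscillibacter", young].mean()


def test_relative_change_estimates_center_on_generator_effects():
    """Across seeded cohorts the paired-test pipeline's relative-change
    estimates are centred on the planted per-group effect sizes."""
    targets = {"isovalerate": (-6.16, -11.41), "tryptophan": (8.17, 9.64)}
    est: dict = {m: ([], []) for m in targets}
    for seed in range(40):
        c = simulate_cohort(CohortDesign(seed=100 + seed))
        table = effect_table(c.metabolites, c.meta)
        for m in targets:
            est[m][0].append(table.loc[m, "rel_change_pct_young"])
            est[m][1].append(table.loc[m, "rel_change_pct_elder"])
    for m, (young_t, elder_t) in targets.items():
        bias_young = abs(float(np.mean(est[m][0])) - young_t)
        bias_elder = abs(float(np.mean(est[m][1])) - elder_t)
        assert bias_young < 0.2 * abs(young_t)
        assert bias_elder < 0.2 * abs(elder_t)


class TestReferenceFixture:
    def test_fixture_is_deterministic(self):
        a, b = build_reference_fixture(), build_reference_fixture()
        pd.testing.assert_frame_equal(a.features, b.features)

    def test_decoys_identical_across_arms(self, reference_fixture):
        fx = reference_fixture
        trt = fx.meta.index[fx.meta["arm"] == "treatment"]
        ctl = fx.meta.index[fx.meta["arm"] == "control"]
        for x in fx.decoy_ids:
            np.testing.assert_array_equal(
                fx.features.loc[x, trt].to_numpy(), fx.features.loc[x, ctl].to_numpy()
            )

    def test_fast_parents_gone_by_8h(self, reference_fixture):
        fx = reference_fixture
        # silychristin (P5) and 2,3-dehydrosilybin (P8) vanish by 8 h
        w8 = fx.meta.index[
            (fx.meta["arm"] == "treatment") & (fx.meta["timepoint"] == 8.0)
        ]
        assert (fx.features.loc[["P5", "P8"], w8].to_numpy() == 0.0).all()
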