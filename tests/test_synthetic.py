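"""Generator behavior: reproducibility, parameter recovery, the over-call
channel, and the truncated-rounded-normal Likert calibration."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from stampc import (
    CalibrationError,
    ConfigError,
    GeneratorConfig,
    calibrate_truncated_likert,
    generate_registry,
    generate_report_abstractions,
    generate_survey,
    generate_source_scores,
    likert_moments,
    solve_doc_given_absent,
)
from stampc.catalog import patient_specific_ids
from stampc.dataset import write_registry_csv


def zero_doc_config(**kw):
    base = GeneratorConfig()
    return dataclasses.replace(
        base,
        doc_prob={k: 0.0 for k in base.doc_prob},
        doc_prob_given_present={k: 0.0 for k in base.doc_prob_given_present},
        doc_prob_given_absent={k: 0.0 for k in base.doc_prob_given_absent},
        **kw,
    )


class TestRegistry:
    def test_same_seed_same_bytes(self, default_config, registry, tmp_path):
        again = generate_registry(default_config)
        assert again == registry
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_registry_csv(registry, p1)
        write_registry_csv(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_mesh_prevalence_within_central_99pct_binomial_band(self, registry):
        n, q = len(registry), 0.711
        count = sum(r.prior_mesh_present for r in registry)
        lo, hi = sps.binom.ppf([0.005, 0.995], n, q)
        assert lo <= count <= hi

    def test_zero_prevalence_means_no_findings(self):
        cfg = dataclasses.replace(
            GeneratorConfig(n_patients=500, seed=3),
            prevalence={k: 0.0 for k in GeneratorConfig().prevalence},
        )
        registry = generate_registry(cfg)
        assert not any(
            r.prior_mesh_present or r.mesh_fracture or r.mesh_migration
            or r.concurrent_inguinal or r.concurrent_parastomal
            or r.wall_abnormality or r.ongoing_sso
            for r in registry
        )

    def test_certain_mesh_gives_every_patient_a_plane(self):
        prev = dict(GeneratorConfig().prevalence, prior_mesh=1.0)
        cfg = dataclasses.replace(
            GeneratorConfig(n_patients=2000, seed=5), prevalence=prev
        )
        registry = generate_registry(cfg)
        assert all(r.mesh_plane is not None for r in registry)
        counts = np.array(
            [
                sum(r.mesh_plane.value == plane for r in registry)
                for plane in ("onlay", "sublay", "underlay")
            ]
        )
        expected = np.array(cfg.plane_mix) * len(registry)
        # multinomial counts near the configured mix (4 sigma per cell)
        sd = np.sqrt(expected * (1 - np.array(cfg.plane_mix)))
        assert (np.abs(counts - expected) < 4 * sd).all()

    def test_fracture_and_migration_only_with_mesh(self, registry):
        assert all(
            r.prior_mesh_present or not (r.mesh_fracture or r.mesh_migration)
            for r in registry
        )

    def test_defect_dimensions_positive(self, registry):
        assert min(r.defect_width_cm for r in registry) > 0
        assert min(r.defect_length_cm for r in registry) > 0

    def test_invalid_probability_rejected(self):
        cfg = dataclasses.replace(
            GeneratorConfig(), prevalence=dict(GeneratorConfig().prevalence, prior_mesh=1.2)
        )
        with pytest.raises(ConfigError, match="outside"):
            generate_registry(cfg)


class TestReports:
    def test_zero_probabilities_give_all_false_flags(self):
        cfg = zero_doc_config(n_patients=300, seed=11)
        registry = generate_registry(cfg)
        reports = generate_report_abstractions(registry, cfg)
        assert not any(any(r.documented.values()) for r in reports)

    def test_defect_width_documented_count_near_published(self, reports):
        # doc probability 0.326 at n=834 -> expected 272 documented
        count = sum(r.documented["defect_width"] for r in reports)
        lo, hi = sps.binom.ppf([0.005, 0.995], len(reports), 0.326)
        assert lo <= count <= hi

    def test_overcall_channel_solves_published_inguinal_ratio(self):
        # expected documented = 2.412 x expected present with P(doc|present)=0.5
        p_a = solve_doc_given_absent(0.041, 2.412, 0.5)
        marginal = 0.041 * 0.5 + 0.959 * p_a
        assert marginal / 0.041 == pytest.approx(2.412, abs=1e-12)
        cfg = GeneratorConfig(n_patients=50_000, seed=13)
        registry = generate_registry(cfg)
        reports = generate_report_abstractions(registry, cfg)
        documented = sum(r.documented["concurrent_inguinal"] for r in reports)
        present = sum(r.concurrent_inguinal for r in registry)
        assert documented / present == pytest.approx(2.412, rel=0.05)

    def test_plane_documentation_subset_of_mesh_documentation(self, reports):
        assert all(
            r.documented["prior_mesh"] or not r.documented["old_mesh_plane"]
            for r in reports
        )

    def test_registry_config_mismatch_rejected(self, registry):
        cfg = dataclasses.replace(GeneratorConfig(), doc_prob_given_present={})
        with pytest.raises(ConfigError):
            generate_report_abstractions(registry, cfg)


class TestLikertCalibration:
    def test_symmetric_target_centers_latent_mean(self):
        mu, sigma = calibrate_truncated_likert(5.5, 2.0)
        assert mu == pytest.approx(5.5, abs=1e-6)
        assert sigma > 0

    @pytest.mark.parametrize("target", [(9.16, 2.02), (7.28, 2.98), (8.05, 2.53)])
    def test_published_moment_pairs_reproduced_within_1e3(self, target):
        mean, sd = target
        mu, sigma = calibrate_truncated_likert(mean, sd)
        # independent oracle: exact moment sums over the 10 support points
        support = np.arange(1, 11)
        cdf = sps.norm.cdf(np.arange(1.5, 10.0), loc=mu, scale=sigma)
        pmf = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        m1 = pmf @ support
        m2 = np.sqrt(pmf @ (support - m1) ** 2)
        assert m1 == pytest.approx(mean, abs=1e-3)
        assert m2 == pytest.approx(sd, abs=1e-3)
        assert likert_moments(mu, sigma) == pytest.approx((mean, sd), abs=1e-3)

    def test_infeasible_pair_near_bound_raises_with_feasible_range(self):
        with pytest.raises(CalibrationError, match="feasible sd range"):
            calibrate_truncated_likert(9.99, 2.0)

    def test_mean_outside_open_interval_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_truncated_likert(10.0, 1.0)
        with pytest.raises(CalibrationError):
            calibrate_truncated_likert(5.0, 0.0)


class TestSurvey:
    def test_degenerate_zero_sd_gives_constant_ratings(self):
        survey = generate_survey(20, {"defect_width": (8.6, 0.0)}, seed=1)
        assert (survey.ratings["defect_width"] == 9).all()

    def test_single_rater_values_in_support(self):
        survey = generate_survey(1, {"defect_width": (9.16, 2.02)}, seed=1)
        assert survey.ratings.shape == (1, 1)
        assert survey.ratings.iloc[0, 0] in range(1, 11)

    def test_sample_mean_recovers_target_within_3se(self, survey):
        mean = survey.ratings["defect_width"].mean()
        assert abs(mean - 9.16) <= 3 * 2.02 / np.sqrt(61)

    def test_same_seed_reproducible(self, survey):
        again = generate_survey(61, {"defect_width": (9.16, 2.02)}, seed=7)
        assert (again.ratings["defect_width"] == survey.ratings["defect_width"]).all()


class TestSourceScores:
    def test_top_audit_rank_gives_top_expert_score(self, sources):
        assert sources.loc["defect_width", "expert_audit"] == sources["expert_audit"].max() == 16

    def test_survey_column_is_sample_means(self, survey, sources):
        assert sources["surgeon_survey"].equals(survey.ratings.mean(axis=0))

    def test_all_equal_inputs_give_constant_columns(self):
        survey = generate_survey(5, {"a": (7.0, 0.0), "b": (7.0, 0.0)}, seed=2)
        table = generate_source_scores(
            survey, {"a": 8, "b": 8}, {"a": 20, "b": 20}
        )
        assert (table.nunique() == 1).all()

    def test_rank_and_frequency_bounds_enforced(self, survey):
        ranks = {p: 17 for p in survey.ratings.columns}
        with pytest.raises(ValueError, match="outside 1..16"):
            generate_source_scores(survey, ranks, {p: 1 for p in survey.ratings.columns})
        good_ranks = {p: 1 for p in survey.ratings.columns}
        with pytest.raises(ValueError, match="outside 0..40"):
            generate_source_scores(survey, good_ranks, {p: 41 for p in survey.ratings.columns})
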