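"""Normalization, weighted aggregation, tiering against the published
prioritization, STAMP-C panel extraction, and weight-perturbation stability."""

import numpy as np
import pandas as pd
import pytest

from stampc import reference
from stampc.catalog import PARAMETER_IDS, stampc_ids
from stampc.mcda import (
    MCDAConfig,
    MCDAError,
    aggregate,
    normalize_source,
    rank_and_tier,
    stampc_panel,
    weight_sensitivity,
)

# published final prioritization order, top to bottom
PUBLISHED_ORDER = [
    "defect_width",
    "prior_mesh",
    "old_mesh_plane",
    "tanaka_index",
    "ehs_location",
    "concurrent_parastomal",
    "concurrent_inguinal",
    "wall_abnormality",
    "rectus_measurements",
    "ongoing_sso",
    "mesh_fracture",
    "mesh_migration",
    "defect_length",
    "hernia_content",
    "patient_habitus",
    "number_of_defects",
]


def reference_scores() -> pd.Series:
    return pd.Series({p: reference.FINAL_SCORES[p] for p in PARAMETER_IDS})


class TestNormalization:
    def test_constant_column_sum_to_100(self):
        assert normalize_source([1, 1, 1, 1], "sum_to_100") == pytest.approx([25] * 4)

    def test_min_max_affine(self):
        assert normalize_source([2, 4, 6], "min_max") == pytest.approx([0, 0.5, 1])

    def test_z_score_moments(self):
        z = normalize_source([3, 1, 7, 9], "z_score")
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_survey_means_sum_to_100_with_defect_width_largest(self):
        means = pd.Series({p: m for p, (m, _) in reference.SURVEY_MEAN_SD.items()})
        out = normalize_source(means, "sum_to_100")
        assert out.sum() == pytest.approx(100.0)
        assert out.argmax() == list(means.index).index("defect_width")

    def test_degenerate_columns_rejected(self):
        with pytest.raises(MCDAError, match="constant"):
            normalize_source([5, 5, 5], "min_max")
        with pytest.raises(MCDAError, match="constant"):
            normalize_source([5, 5, 5], "z_score")
        with pytest.raises(MCDAError, match="at least 2"):
            normalize_source([5], "sum_to_100")


class TestAggregation:
    def make_sources(self, cols):
        return pd.DataFrame(cols, index=["p1", "p2", "p3"])

    def test_single_source_weight_one_passthrough(self):
        src = self.make_sources({"only": [1.0, 2.0, 5.0]})
        cfg = MCDAConfig(weights=(1.0,), criteria=("only",))
        final = aggregate(src, cfg)
        assert final.to_numpy() == pytest.approx(
            normalize_source([1, 2, 5], "sum_to_100")
        )

    def test_identical_columns_are_a_fixed_point(self):
        col = [3.0, 1.0, 6.0]
        src = self.make_sources(
            {"systematic_review": col, "expert_audit": col, "surgeon_survey": col}
        )
        final = aggregate(src, MCDAConfig())
        assert final.to_numpy() == pytest.approx(normalize_source(col, "sum_to_100"))

    def test_hand_computed_weighted_sum(self):
        src = self.make_sources(
            {
                "systematic_review": [10.0, 20.0, 70.0],
                "expert_audit": [1.0, 2.0, 2.0],
                "surgeon_survey": [5.0, 5.0, 10.0],
            }
        )
        final = aggregate(src, MCDAConfig())
        # spreadsheet-style arithmetic, sum_to_100 per column then weights
        review = [10.0, 20.0, 70.0]
        audit = [20.0, 40.0, 40.0]
        survey = [25.0, 25.0, 50.0]
        expected = [
            0.406 * r + 0.323 * a + 0.271 * s
            for r, a, s in zip(review, audit, survey)
        ]
        assert final.to_numpy() == pytest.approx(expected)

    def test_axis_mismatch_rejected(self):
        src = self.make_sources({"systematic_review": [1.0, 2.0, 3.0]})
        with pytest.raises(MCDAError, match="missing criteria"):
            aggregate(src, MCDAConfig())

    def test_invalid_weights_rejected(self):
        with pytest.raises(MCDAError, match="sum to 1"):
            MCDAConfig(weights=(0.5, 0.4, 0.2)).validate()


class TestRankAndTier:
    def test_published_scores_reproduce_rank_order_and_tiers(self):
        result = rank_and_tier(reference_scores())
        table = result.table.sort_values("rank")
        assert list(table.index) == PUBLISHED_ORDER
        sizes = table["tier"].value_counts().sort_index()
        assert list(sizes) == [7, 3, 6]
        assert table.loc["concurrent_inguinal", "tier"] == 1  # 9.52
        assert table.loc["wall_abnormality", "tier"] == 2  # 8.73
        assert table.loc["mesh_fracture", "tier"] == 3  # 5.68
        assert list(table["recommendation"].unique()) == [
            "Essential",
            "Highly Recommended",
            "Recommended",
        ]

    def test_boundary_score_is_tier_one(self):
        scores = pd.Series({"a": 9.0, "b": 6.0, "c": 5.999})
        table = rank_and_tier(scores).table
        assert table.loc["a", "tier"] == 1
        assert table.loc["b", "tier"] == 2
        assert table.loc["c", "tier"] == 3

    def test_ties_broken_by_catalog_order_with_consecutive_ranks(self):
        scores = pd.Series({"x": 5.0, "y": 5.0, "z": 7.0})
        table = rank_and_tier(scores).table
        assert table.loc["z", "rank"] == 1
        assert table.loc["x", "rank"] == 2  # first in the incoming order
        assert table.loc["y", "rank"] == 3

    def test_tier_partition_and_rank_permutation(self):
        table = rank_and_tier(reference_scores()).table
        assert sorted(table["rank"]) == list(range(1, 17))
        assert set(table["tier"]) <= {1, 2, 3}
        assert table["tier"].notna().all()

    def test_permutation_equivariance(self):
        scores = reference_scores()
        base = rank_and_tier(scores).table["rank"]
        shuffled = scores.sample(frac=1.0, random_state=3)
        perm = rank_and_tier(shuffled).table["rank"]
        assert (perm.sort_index() == base.sort_index()).all()

    def test_monotone_boost_never_drops_below_previously_lower(self, sources):
        cfg = MCDAConfig()
        base = rank_and_tier(aggregate(sources, cfg), cfg).table
        boosted_sources = sources.copy()
        pid = "ongoing_sso"
        boosted_sources.loc[pid, "surgeon_survey"] += 2.0
        boosted = rank_and_tier(aggregate(boosted_sources, cfg), cfg).table
        below_before = set(base.index[base["rank"] > base.loc[pid, "rank"]])
        for other in below_before:
            if other == pid:
                continue
            assert boosted.loc[pid, "rank"] < boosted.loc[other, "rank"] or (
                other not in below_before
            )


class TestStampcPanel:
    def test_published_scores_give_canonical_seven_letter_panel(self):
        result = rank_and_tier(reference_scores())
        panel = stampc_panel(result)
        assert result.warnings == []
        assert set(panel) == {"S", "T", "A", "M", "P", "C"}
        assert sorted(panel["C"]) == ["concurrent_inguinal", "concurrent_parastomal"]
        members = [p for ids in panel.values() for p in ids]
        assert set(members) == set(stampc_ids())

    def test_all_low_scores_give_empty_panel_with_warning(self):
        scores = pd.Series({p: 1.0 + i * 0.1 for i, p in enumerate(PARAMETER_IDS)})
        result = rank_and_tier(scores)
        with pytest.warns(UserWarning, match="differs from the canonical"):
            panel = stampc_panel(result)
        assert panel == {}
        assert result.warnings

    def test_single_qualifier_gives_single_letter(self):
        scores = pd.Series({p: 1.0 for p in PARAMETER_IDS})
        scores["defect_width"] = 9.5
        result = rank_and_tier(scores)
        with pytest.warns(UserWarning):
            panel = stampc_panel(result)
        assert panel == {"S": ["defect_width"]}


class TestSensitivity:
    @staticmethod
    def separated_sources():
        # same strict ordering in every source with wide gaps: any convex
        # weight combination preserves the ranking exactly
        vals = np.array([100.0 - 6 * i for i in range(16)])
        return pd.DataFrame(
            {
                "systematic_review": vals,
                "expert_audit": vals / 10,
                "surgeon_survey": vals / 25,
            },
            index=pd.Index(PARAMETER_IDS, name="parameter"),
        )

    def test_huge_concentration_freezes_ranking(self, sources):
        res = weight_sensitivity(
            sources, MCDAConfig(), n_draws=25, concentration=1e9, seed=0
        )
        assert res.top_k_stability == 1.0
        assert res.mean_rank_correlation == pytest.approx(1.0)

    def test_identical_columns_are_weight_invariant(self):
        col = np.linspace(10, 1, 16)
        src = pd.DataFrame(
            {c: col for c in reference.AHP_CRITERIA}, index=PARAMETER_IDS
        )
        res = weight_sensitivity(src, MCDAConfig(), n_draws=25, concentration=5, seed=1)
        assert res.top_k_stability == 1.0

    def test_separated_scores_stable_at_concentration_100(self):
        res = weight_sensitivity(
            self.separated_sources(),
            MCDAConfig(),
            n_draws=500,
            concentration=100.0,
            seed=5,
        )
        assert res.top_k_stability >= 0.95
        assert -1.0 <= res.mean_rank_correlation <= 1.0

    def test_seeded_reproducibility(self, sources):
        a = weight_sensitivity(sources, MCDAConfig(), 50, 50.0, seed=9)
        b = weight_sensitivity(sources, MCDAConfig(), 50, 50.0, seed=9)
        assert a.top_k_stability == b.top_k_stability
        assert a.mean_rank_correlation == b.mean_rank_correlation

    def test_invalid_settings_rejected(self, sources):
        with pytest.raises(MCDAError):
            weight_sensitivity(sources, MCDAConfig(), n_draws=0)
        with pytest.raises(MCDAError):
            weight_sensitivity(sources, MCDAConfig(), concentration=0.0)
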