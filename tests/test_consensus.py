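import itertools

import numpy as np
import pandas as pd
import pytest

from crowdkappa.consensus import (
    ConsensusConfig,
    build_gold_standard,
    is_qualified,
    qualify_users,
    select_completers,
    split_gold_validation,
    thresholded_consensus_reader,
    vote_status,
)
from crowdkappa.errors import ConfigError, ValidationError
from crowdkappa.simulate import SimulationConfig, simulate_study

from conftest import make_table


def panel_table(votes, feature="dots", image="i1", taxonomy=None):
    rows = [
        (f"e{k}", image, feature, v, np.nan, "panel") for k, v in enumerate(votes)
    ]
    return make_table(rows, taxonomy=taxonomy)


class TestGoldStandard:
    @pytest.mark.parametrize(
        "votes,expected",
        [((1, 1, 1, 0, 0), "present"), ((0, 0, 0, 0, 0), "absent"),
         ((1, 1, 0, 0, 0), "test"), ((1, 0, 0, 0, 0), "test"),
         ((1, 1, 1, 1, 1), "present")],
    )
    def test_vote_rules(self, votes, expected, taxonomy):
        gold = build_gold_standard(panel_table(votes, taxonomy=taxonomy))
        assert list(gold["status"]) == [expected]
        assert gold["n_present_votes"].iloc[0] == sum(votes)
        assert gold["n_panel"].iloc[0] == 5

    def test_statuses_partition_all_pairs(self, small_dataset):
        gold = build_gold_standard(small_dataset.ratings.subset(cohort="panel"))
        n_pairs = small_dataset.config.n_images * len(
            small_dataset.config.superfeatures
        )
        assert len(gold) == n_pairs
        assert gold.groupby(["image_id", "superfeature"]).size().eq(1).all()
        assert set(gold["status"]) <= {"present", "absent", "test"}

    def test_consensus_monotone_in_votes(self):
        """Flipping one vote from absent to present never flips the status
        from present to absent."""
        order = {"absent": 0, "test": 1, "present": 2}
        for votes in itertools.product([0, 1], repeat=5):
            s0 = vote_status(sum(votes), 3)
            for k in range(5):
                if votes[k] == 0:
                    flipped = list(votes)
                    flipped[k] = 1
                    s1 = vote_status(sum(flipped), 3)
                    assert order[s1] >= order[s0]

    def test_short_panel_warns(self, taxonomy):
        with pytest.warns(UserWarning, match="fewer than"):
            build_gold_standard(panel_table((1, 1, 1), taxonomy=taxonomy))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ConsensusConfig(present_min=0).validate()
        with pytest.raises(ConfigError):
            ConsensusConfig(present_min=6, panel_size=5).validate()


class TestValidationSplit:
    def _gold(self, n_present=8, n_absent=8):
        rows = []
        for k in range(n_present):
            rows.append((f"p{k}", "dots", "present", 4, 5))
        for k in range(n_absent):
            rows.append((f"a{k}", "dots", "absent", 0, 5))
        rows.append(("t0", "dots", "test", 1, 5))
        return pd.DataFrame(
            rows,
            columns=["image_id", "superfeature", "status", "n_present_votes", "n_panel"],
        )

    def test_split_is_stratified_and_seeded(self):
        gold = self._gold()
        s1 = split_gold_validation(gold, 0.5, seed=3)
        s2 = split_gold_validation(gold, 0.5, seed=3)
        pd.testing.assert_frame_equal(s1, s2)
        val = s1[s1["role"] == "validation"]
        assert val.groupby("status").size().to_dict() == {"absent": 4, "present": 4}
        assert (s1[s1["status"] == "test"]["role"] == "none").all()

    def test_different_seeds_differ(self):
        gold = self._gold(20, 20)
        s1 = split_gold_validation(gold, 0.5, seed=3)
        s2 = split_gold_validation(gold, 0.5, seed=4)
        assert not s1["role"].equals(s2["role"])


class TestQualification:
    def test_predicate_examples(self):
        assert is_qualified(10, 12, 0.83)       # 0.8333 >= 0.83
        assert not is_qualified(9, 12, 0.83)    # 0.75
        assert not is_qualified(0, 0, 0.83)     # no evidence

    def test_threshold_monotonicity(self):
        for total in range(1, 31):
            for correct in range(total + 1):
                q_low = is_qualified(correct, total, 0.7)
                q_high = is_qualified(correct, total, 0.9)
                assert q_low or not q_high  # raising theta never adds users

    def test_qualify_users_end_to_end(self, taxonomy):
        gold = pd.DataFrame(
            [(f"p{k}", "dots", "present", 4, 5) for k in range(6)]
            + [(f"a{k}", "dots", "absent", 0, 5) for k in range(6)],
            columns=["image_id", "superfeature", "status", "n_present_votes", "n_panel"],
        )
        cfg = ConsensusConfig(validation_fraction=0.5)
        split = split_gold_validation(gold, 0.5, seed=11)
        val = split[split["role"] == "validation"]
        truth = val.set_index("image_id")["status"].map({"present": 1, "absent": 0})
        # good user: all validation items correct; bad user: all wrong;
        # silent user: rates no validation item
        rows = [("good", img, "dots", int(t)) for img, t in truth.items()]
        rows += [("bad", img, "dots", 1 - int(t)) for img, t in truth.items()]
        train_img = split[split["role"] == "training"]["image_id"].iloc[0]
        rows += [("silent", train_img, "dots", 1)]
        crowd = make_table(rows, taxonomy=taxonomy)
        qualified, table = qualify_users(crowd, gold, cfg, seed=11)
        assert "good" in qualified["dots"]
        assert "bad" not in qualified["dots"]
        assert "silent" not in qualified["dots"]
        stats = table.set_index("rater_id")
        assert stats.loc["good", "n_correct"] == stats.loc["good", "n_validation"] == len(val)
        assert stats.loc["silent", "n_validation"] == 0

    def test_single_class_gold_rejected(self, taxonomy):
        gold = pd.DataFrame(
            [("p0", "dots", "present", 4, 5)],
            columns=["image_id", "superfeature", "status", "n_present_votes", "n_panel"],
        )
        crowd = make_table([("u1", "p0", "dots", 1)], taxonomy=taxonomy)
        with pytest.raises(ValidationError, match="both present and absent"):
            qualify_users(crowd, gold, ConsensusConfig(), seed=0)

    def test_feature_mismatch_rejected(self, taxonomy):
        gold = pd.DataFrame(
            [("p0", "dots", "present", 4, 5), ("a0", "dots", "absent", 0, 5)],
            columns=["image_id", "superfeature", "status", "n_present_votes", "n_panel"],
        )
        crowd = make_table([("u1", "p0", "vessels", 1)], taxonomy=taxonomy)
        with pytest.raises(ValidationError, match="vessels"):
            qualify_users(crowd, gold, ConsensusConfig(), seed=0)

    def test_empty_gold_rejected(self, taxonomy):
        crowd = make_table([("u1", "i1", "dots", 1)], taxonomy=taxonomy)
        with pytest.raises(ValidationError, match="empty gold"):
            qualify_users(crowd, crowd.df.iloc[0:0], ConsensusConfig(), seed=0)


class TestThresholdedConsensus:
    def _ec_table(self, taxonomy, n_raters=5, n_images=4, short_last=False):
        rows = []
        for r in range(n_raters):
            n = n_images - (1 if short_last and r == n_raters - 1 else 0)
            for i in range(n):
                rows.append((f"x{r}", f"i{i}", "dots", int(i < 2), np.nan,
                             "expert_crowd"))
        return make_table(rows, taxonomy=taxonomy)

    def test_three_of_five_is_present(self, taxonomy):
        rows = [
            (f"x{r}", "i1", "dots", v, np.nan, "expert_crowd")
            for r, v in enumerate([1, 1, 1, 0, 0])
        ]
        out = thresholded_consensus_reader(make_table(rows, taxonomy=taxonomy))
        assert list(out["present"]) == [1]

    def test_unanimous_absent(self, taxonomy):
        rows = [
            (f"x{r}", "i1", "dots", 0, np.nan, "expert_crowd") for r in range(5)
        ]
        out = thresholded_consensus_reader(make_table(rows, taxonomy=taxonomy))
        assert list(out["present"]) == [0]

    def test_incomplete_images_excluded_with_warning(self, taxonomy):
        table = self._ec_table(taxonomy, short_last=True)
        with pytest.warns(UserWarning, match="excluded"):
            out = thresholded_consensus_reader(table)
        assert len(out) == 3  # last image lacks the fifth rater

    def test_completer_proxy_prefers_most_ratings_then_id(self, taxonomy):
        rows = []
        for r in range(6):
            n = 4 if r != 5 else 2  # x5 rated fewest
            for i in range(n):
                rows.append((f"x{r}", f"i{i}", "dots", 1, np.nan, "expert_crowd"))
        table = make_table(rows, taxonomy=taxonomy)
        chosen = select_completers(table, "dots", n=5)
        assert chosen == ["x0", "x1", "x2", "x3", "x4"]

    def test_explicit_rater_list_overrides(self, taxonomy):
        table = self._ec_table(taxonomy, n_raters=6)
        chosen = select_completers(
            table, "dots", n=5, raters=["x1", "x2", "x3", "x4", "x5"]
        )
        assert chosen[0] == "x1"

    def test_perfect_raters_recover_truth(self):
        cfg = SimulationConfig(
            n_images=40, substudies=4, n_panel_experts=20, panel_size=5,
            crowd_users=3, crowd_ratings_median=15,
            panel_ability=("fixed", 1.0), crowd_ability=("fixed", 1.0),
            expert_crowd_ability=("fixed", 1.0), prevalence=0.5,
            difficulty_easy_mean=1e-9, difficulty_hard_fraction=0.0,
        )
        ds = simulate_study(cfg, seed=5)
        consensus = thresholded_consensus_reader(
            ds.ratings.subset(cohort="expert_crowd")
        )
        truth = ds.truth.rename(
            columns={"present": "z", "superfeature": "superfeature"}
        )
        merged = consensus.merge(truth, on=["image_id", "superfeature"])
        assert (merged["present"] == merged["z"]).all()
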