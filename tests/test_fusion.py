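"""Decision fusion: majority / weighted voting, stacking, grouping levels."""

import numpy as np
import pandas as pd
import pytest

from skinspec import ALL_CHANNELS, FusionSpec, fit_stacker, fuse, majority_vote, weighted_vote
from skinspec.datamodel import DataError, LeakageError
from skinspec.fusion import channel_weights


class TestMajorityVote:
    def test_plain_majority(self):
        votes = ["BCC"] * 13 + ["H"] * 11
        assert majority_vote(votes) == "BCC"

    def test_tie_broken_by_summed_scores(self):
        votes = ["H"] * 12 + ["BCC"] * 12
        assert majority_vote(votes, scores={"H": 5.0, "BCC": 3.0}) == "H"

    def test_tie_without_scores_prefers_more_severe_class(self):
        assert majority_vote(["H", "BCC"]) == "BCC"

    def test_single_vote_wins(self):
        assert majority_vote(["AK"]) == "AK"

    def test_all_abstain_is_unfusable(self):
        with pytest.raises(DataError, match="abstained"):
            majority_vote([None, None])


class TestWeightedVote:
    def test_summed_weights_decide(self):
        votes = {"c1": "A", "c2": "B", "c3": "B"}
        weights = {"c1": 0.6, "c2": 0.3, "c3": 0.4}
        assert weighted_vote(votes, weights) == "B"  # 0.7 > 0.6

    def test_equal_weights_reduce_to_majority(self, rng):
        chans = [c.key for c in ALL_CHANNELS]
        for _ in range(20):
            labels = rng.choice(["H", "AK", "BCC"], size=24)
            votes = dict(zip(chans, labels))
            eq = {c: 1.0 for c in chans}
            assert weighted_vote(votes, eq) == majority_vote(labels)

    def test_single_nonzero_weight_dictates(self):
        votes = {"c1": "A", "c2": "B", "c3": "B"}
        assert weighted_vote(votes, {"c1": 1.0, "c2": 0.0, "c3": 0.0}) == "A"


def make_decisions(preds_by_channel, truth, folds=None, repeat=0):
    """Long decision table from {channel: [pred per sample]}."""
    n = len(truth)
    folds = folds if folds is not None else np.zeros(n, dtype=int)
    rows = []
    for ch, preds in preds_by_channel.items():
        for i in range(n):
            if preds[i] is None:
                continue
            rows.append(
                {
                    "sample_id": f"s{i}",
                    "channel": ch,
                    "repeat": repeat,
                    "fold": int(folds[i]),
                    "truth": truth[i],
                    "pred": preds[i],
                }
            )
    return pd.DataFrame(rows)


class TestStacker:
    def _unanimous_table(self):
        truth = ["H", "BCC"] * 10
        chans = ["AF1-1", "AF2-1", "DR-1"]
        return make_decisions({c: truth for c in chans}, truth,
                              folds=np.arange(20) % 2)

    def test_reproduces_unanimous_votes(self):
        dec = self._unanimous_table()
        stk = fit_stacker(dec, meta="svm", seed=0)
        votes = np.array([["H", "H", "H"], ["BCC", "BCC", "BCC"]], dtype=object)
        np.testing.assert_array_equal(stk.predict(votes), ["H", "BCC"])

    def test_random_forest_has_80_trees(self):
        stk = fit_stacker(self._unanimous_table(), meta="random_forest", seed=0)
        assert stk.n_estimators == 80

    def test_channel_permutation_invariance(self):
        truth = ["H", "BCC"] * 15
        rng = np.random.default_rng(0)
        preds = {
            "AF1-1": list(rng.choice(["H", "BCC"], 30)),
            "AF2-1": truth,
            "DR-1": list(rng.choice(["H", "BCC"], 30)),
        }
        dec = make_decisions(preds, truth)
        order1 = ["AF1-1", "AF2-1", "DR-1"]
        order2 = ["DR-1", "AF1-1", "AF2-1"]
        s1 = fit_stacker(dec, meta="svm", seed=1, channel_order=order1)
        s2 = fit_stacker(dec, meta="svm", seed=1, channel_order=order2)
        test = np.array([["H", "H", "BCC"], ["BCC", "BCC", "H"]], dtype=object)
        # permute columns consistently with each stacker's channel order
        perm = [order1.index(c) for c in order2]
        np.testing.assert_array_equal(s1.predict(test), s2.predict(test[:, perm]))

    def test_leakage_error_on_test_rows_in_training(self):
        dec = self._unanimous_table()
        with pytest.raises(LeakageError, match="test samples"):
            fit_stacker(dec, test_sample_ids=["s0"])


class TestChannelWeights:
    def test_weights_track_accuracy_and_sum_to_one(self):
        truth = ["H"] * 10
        dec = make_decisions(
            {"AF1-1": ["H"] * 10, "DR-1": ["H"] * 5 + ["BCC"] * 5}, truth
        )
        w = channel_weights(dec)
        assert w["AF1-1"] == pytest.approx(1.0 / 1.5)
        assert sum(w.values()) == pytest.approx(1.0)

    def test_excluded_fold_does_not_influence_weights(self):
        truth = ["H"] * 8
        folds = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        # channel perfect on fold 0 only
        preds = {"AF1-1": ["H"] * 4 + ["BCC"] * 4, "DR-1": ["H"] * 8}
        dec = make_decisions(preds, truth, folds=folds)
        w_excl0 = channel_weights(dec, exclude_fold=0)
        assert w_excl0["AF1-1"] == pytest.approx(0.0)


class TestFuse:
    def test_unanimous_channels_agree_for_every_method(self):
        truth = ["H", "BCC"] * 10
        chans = [c.key for c in ALL_CHANNELS[:6]]
        # both classes present in every fold
        dec = make_decisions({c: truth for c in chans}, truth,
                             folds=(np.arange(20) // 2) % 2)
        for method in ("majority", "weighted", "stacking"):
            res = fuse(dec, FusionSpec(method=method, level="all"))
            fused = res.fused.sort_values("sample_id")
            assert (fused["pred"] == fused["truth"]).all()

    def test_level_all_yields_single_group(self):
        truth = ["H", "BCC"] * 5
        dec = make_decisions({c.key: truth for c in ALL_CHANNELS}, truth)
        res = fuse(dec, FusionSpec(method="majority", level="all"))
        assert set(res.fused["group"]) == {"all"}
        assert len(res.fused) == 10

    def test_per_modality_and_per_sds_group_counts(self):
        truth = ["H", "BCC"] * 5
        dec = make_decisions({c.key: truth for c in ALL_CHANNELS}, truth)
        res_m = fuse(dec, FusionSpec(method="majority", level="per_modality"))
        assert set(res_m.fused["group"]) == {"AF1", "AF2", "AF3", "AF4", "AF5", "DR"}
        res_s = fuse(dec, FusionSpec(method="majority", level="per_sds"))
        assert set(res_s.fused["group"]) == {"SDS1", "SDS2", "SDS3", "SDS4"}

    def test_abstaining_channel_contributes_nothing(self):
        truth = ["H"] * 4
        preds = {
            "AF1-1": ["BCC", None, None, None],
            "AF2-1": ["H", "H", "H", "H"],
            "AF3-1": [None, "H", "H", "H"],
        }
        dec = make_decisions(preds, truth)
        res = fuse(dec, FusionSpec(method="weighted", level="all"))
        by_sample = res.fused.set_index("sample_id")["pred"]
        assert (by_sample[["s1", "s2", "s3"]] == "H").all()

    def test_fused_accuracy_not_far_below_best_channel(self, rng):
        """Independent above-chance channels: fusion keeps (or improves on)
        the best single channel's accuracy."""
        n = 300
        truth = rng.choice(["H", "BCC"], size=n)
        accs = np.linspace(0.62, 0.72, 24)
        preds = {}
        for ch, acc in zip(ALL_CHANNELS, accs):
            correct = rng.random(n) < acc
            flipped = np.where(truth == "H", "BCC", "H")
            preds[ch.key] = list(np.where(correct, truth, flipped))
        dec = make_decisions(preds, truth, folds=np.arange(n) % 3)
        res = fuse(dec, FusionSpec(method="majority", level="all"))
        fused_acc = (res.fused["pred"] == res.fused["truth"]).mean()
        best_single = max(
            (np.array(p) == truth).mean() for p in preds.values()
        )
        assert fused_acc >= best_single - 0.01
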