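"""Bayesian SAR model: scoring, analytic leave-one-out, Pa/Pi calibration, serialization."""

import math

import numpy as np
import pytest

from mnasar import DescriptorSet, LabeledSet, ModelConfig, SarModel, train
from mnasar.model import ActivityStats


def retrain_without(feats, labeled, cid, config):
    """Oracle: explicit retrain with one compound removed."""
    members = tuple((c, a) for c, a in labeled.members if c != cid)
    sub = LabeledSet(activity_id=labeled.activity_id, members=members)
    reduced_feats = {c: feats[c] for c, _ in members}
    return train([sub], reduced_feats, config, compute_calibration=False)


class TestAnalyticLoo:
    def test_loo_equals_explicit_retrain(self, toy_dataset, toy_config):
        """The analytic count-removal LOO score must equal retraining without the compound."""
        feats, labeled = toy_dataset
        model = train([labeled], feats, toy_config)
        is_active = dict(labeled.members)
        for cid in feats:
            analytic = model.loo_score(feats[cid], "TOY", is_active[cid])
            oracle = retrain_without(feats, labeled, cid, toy_config).score(feats[cid], "TOY")
            assert analytic == pytest.approx(oracle, abs=1e-12), cid

    def test_loo_differs_from_plain_score_when_vocab_overlaps(self, toy_dataset, toy_config):
        feats, labeled = toy_dataset
        model = train([labeled], feats, toy_config)
        is_active = dict(labeled.members)
        for cid in feats:
            assert model.loo_score(feats[cid], "TOY", is_active[cid]) != model.score(feats[cid], "TOY")

    def test_removing_inactive_leaves_active_counts_untouched(self, toy_dataset, toy_config):
        feats, labeled = toy_dataset
        model = train([labeled], feats, toy_config)
        # i5 carries the enriched descriptor; its LOO must still use the full n_da
        reduced = retrain_without(feats, labeled, "i5", toy_config)
        assert reduced.activities["TOY"].n_da == model.activities["TOY"].n_da


class TestScoring:
    def test_enriched_descriptor_raises_conditional_above_prior(self, toy_dataset, toy_config):
        feats, labeled = toy_dataset
        model = train([labeled], feats, toy_config)
        st = model.activities["TOY"]
        p_a = st.n_a / model.N
        p_enr = (st.n_da["enr"] + p_a) / (model.n_d["enr"] + 1)
        assert p_enr > p_a

    def test_empty_vocabulary_overlap_falls_back_to_prior(self, toy_dataset, toy_config):
        feats, labeled = toy_dataset
        model = train([labeled], feats, toy_config)
        novel = DescriptorSet(frozenset({"never-seen-1", "never-seen-2"}), "q")
        p_a = model.activities["TOY"].n_a / model.N
        assert model.score(novel, "TOY") == pytest.approx(math.asin(2 * p_a - 1))

    def test_irrelevant_descriptor_never_changes_predictions(self, toy_dataset, toy_config):
        feats, labeled = toy_dataset
        model = train([labeled], feats, toy_config)
        q = feats["a1"]
        q_plus = DescriptorSet(q.descriptors | {"ghost-descriptor"}, "q+")
        assert model.predict(q) == model.predict(q_plus)

    def test_duplicate_of_training_compound_scores_identically(self, toy_dataset, toy_config):
        feats, labeled = toy_dataset
        model = train([labeled], feats, toy_config)
        dup = DescriptorSet(feats["a2"].descriptors, "copy-of-a2")
        assert model.score(dup, "TOY") == model.score(feats["a2"], "TOY")

    def test_unknown_activity_and_empty_query_rejected(self, toy_dataset, toy_config):
        feats, labeled = toy_dataset
        model = train([labeled], feats, toy_config)
        with pytest.raises(KeyError):
            model.score(feats["a1"], "NOPE")
        with pytest.raises(ValueError):
            DescriptorSet(frozenset(), "empty")


def _fabricated_model(cal_active, cal_inactive):
    stats = ActivityStats(
        n_a=len(cal_active),
        n_da={},
        cal_active=np.sort(np.array(cal_active, dtype=float)),
        cal_inactive=np.sort(np.array(cal_inactive, dtype=float)),
    )
    n = len(cal_active) + len(cal_inactive)
    return SarModel(N=n, n_d={"d": n}, activities={"A": stats}, config=ModelConfig(min_actives=1))


class TestPaPiRanks:
    """Pa/Pi are rank positions in the calibration arrays; checked on fabricated scores."""

    def _pa_pi(self, model, s):
        from mnasar.model import _rank_position_above, _rank_position_below

        st = model.activities["A"]
        return _rank_position_below(st.cal_active, s), _rank_position_above(st.cal_inactive, s)

    def test_rank_extremes(self):
        m = _fabricated_model([0.1, 0.2, 0.3], [-0.2, -0.1, 0.0])
        assert self._pa_pi(m, 1.0) == (1.0, 0.0)
        assert self._pa_pi(m, -1.0) == (0.0, 1.0)

    def test_all_ties_give_half(self):
        m = _fabricated_model([0.5, 0.5], [0.5, 0.5])
        assert self._pa_pi(m, 0.5) == (0.5, 0.5)

    def test_pa_monotone_nondecreasing_pi_nonincreasing(self):
        rng = np.random.default_rng(7)
        m = _fabricated_model(rng.normal(size=40), rng.normal(size=60))
        grid = np.linspace(-3, 3, 101)
        pas, pis = zip(*(self._pa_pi(m, s) for s in grid))
        assert all(a <= b for a, b in zip(pas, pas[1:]))
        assert all(a >= b for a, b in zip(pis, pis[1:]))

    def test_predictions_sorted_by_pa_minus_pi(self, planted_model, planted_fixture):
        features, labeled = planted_fixture
        preds = planted_model.predict(features[labeled.actives[0]])
        gaps = [p.pa - p.pi for p in preds]
        assert gaps == sorted(gaps, reverse=True)


class TestCalibrationUniformity:
    """LOO Pa of training actives is ~uniform: a Pa > t filter loses ~t of true actives."""

    def test_uniform_loss_fractions(self, planted_model, planted_fixture):
        _, labeled = planted_fixture
        pa = planted_model.loo_pa_of_actives(labeled.activity_id)
        for t in (0.3, 0.5, 0.7, 0.9):
            lost = float(np.mean(pa <= t))
            assert lost == pytest.approx(t, abs=0.05)


class TestTrainingContracts:
    def test_activity_without_inactives_or_enough_actives_excluded(self):
        feats = {f"c{i}": DescriptorSet(frozenset({f"d{i}"}), f"c{i}") for i in range(4)}
        all_active = LabeledSet("ALL", tuple((c, True) for c in feats))
        with pytest.raises(ValueError):
            train([all_active], feats, ModelConfig(min_actives=1))
        two_active = LabeledSet("FEW", (("c0", True), ("c1", True), ("c2", False), ("c3", False)))
        with pytest.raises(ValueError):
            train([two_active], feats, ModelConfig(min_actives=3))

    def test_missing_features_rejected(self, toy_dataset, toy_config):
        feats, labeled = toy_dataset
        feats = dict(feats)
        del feats["a1"]
        with pytest.raises(ValueError, match="lack descriptor"):
            train([labeled], feats, toy_config)

    def test_count_invariants(self, planted_model):
        st = planted_model.activities["SYNTH-CYTOTOX"]
        for d, nda in st.n_da.items():
            assert 0 <= nda <= min(planted_model.n_d[d], st.n_a) <= planted_model.N
        assert st.cal_active.size == st.n_a
        assert st.cal_inactive.size == planted_model.N - st.n_a


class TestSerialization:
    def test_round_trip_preserves_predictions_bit_exactly(self, toy_dataset, toy_config, tmp_path):
        feats, labeled = toy_dataset
        model = train([labeled], feats, toy_config)
        path = tmp_path / "model.json"
        model.save(path)
        again = SarModel.load(path)
        assert again.N == model.N and again.n_d == model.n_d
        for cid in feats:
            assert again.predict(feats[cid]) == model.predict(feats[cid])

    def test_bad_model_file_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="not a"):
            SarModel.load(p)
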