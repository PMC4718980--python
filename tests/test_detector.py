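"""EER operating point, efficiency, and speaker-grouped cross-validation."""

import numpy as np
import pandas as pd
import pytest

import modspec as m
from modspec.exceptions import ClassError, SizeError


def scores_frame(scores, labels, speakers=None, recordings=None):
    n = len(scores)
    if speakers is None:
        speakers = [f"s{i}" for i in range(n)]
    if recordings is None:
        recordings = [f"r{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "score": scores,
            "label": labels,
            "speaker_id": speakers,
            "recording_id": recordings,
            "frame_index": range(n),
        }
    )


def eer_sweep_oracle(scores, labels):
    """Exhaustive sweep over all candidate thresholds and both orientations,
    counting errors item by item."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    path_high = scores[labels == "pathological"].mean() >= scores[labels == "normal"].mean()
    unique = np.unique(scores)
    candidates = [-np.inf] + list((unique[:-1] + unique[1:]) / 2) + [np.inf]
    best_gap, best_thr, best_eer = None, None, None
    for thr in candidates:
        fp = fn = 0
        for s, lab in zip(scores, labels):
            pred_path = s >= thr if path_high else s <= thr
            if pred_path and lab == "normal":
                fp += 1
            if not pred_path and lab == "pathological":
                fn += 1
        fpr = fp / np.sum(labels == "normal")
        fnr = fn / np.sum(labels == "pathological")
        gap = abs(fpr - fnr)
        if best_gap is None or gap < best_gap - 1e-15:
            best_gap, best_thr, best_eer = gap, thr, (fpr + fnr) / 2
    return best_thr, best_eer


class TestFoldAssignment:
    def test_one_speaker_per_fold(self):
        speakers = pd.DataFrame(
            {"speaker_id": [f"s{i}" for i in range(7)],
             "label": ["normal"] * 4 + ["pathological"] * 3}
        )
        plan = m.assign_speaker_folds(speakers, k=7, seed=0)
        assert sorted(plan.speaker_to_fold.values()) == list(range(7))

    def test_stratified_round_robin(self):
        speakers = pd.DataFrame(
            {"speaker_id": [f"s{i}" for i in range(21)],
             "label": ["normal"] * 7 + ["pathological"] * 14}
        )
        plan = m.assign_speaker_folds(speakers, k=7, seed=1)
        df = speakers.assign(fold=[plan.speaker_to_fold[s] for s in speakers["speaker_id"]])
        counts = df.groupby(["fold", "label"]).size().unstack()
        assert (counts["normal"] == 1).all()
        assert (counts["pathological"] == 2).all()

    def test_deterministic(self):
        speakers = pd.DataFrame(
            {"speaker_id": [f"s{i}" for i in range(10)],
             "label": ["normal", "pathological"] * 5}
        )
        assert m.assign_speaker_folds(speakers, 7, seed=42) == m.assign_speaker_folds(speakers, 7, seed=42)

    def test_too_few_speakers(self):
        speakers = pd.DataFrame({"speaker_id": ["a", "b"], "label": ["normal", "pathological"]})
        with pytest.raises(SizeError):
            m.assign_speaker_folds(speakers, k=7, seed=0)


class TestEERPoint:
    def test_separable(self):
        df = scores_frame([0.1, 0.2, 0.8, 0.9], ["normal", "normal", "pathological", "pathological"])
        op = m.eer_point(df)
        assert op.eer == 0.0
        assert 0.2 < op.threshold < 0.8
        assert op.orientation == "pathological_high"

    def test_indistinguishable(self):
        df = scores_frame([1, 2, 3, 1, 2, 3], ["normal"] * 3 + ["pathological"] * 3)
        assert m.eer_point(df).eer == 0.5

    def test_inverted_orientation_learned(self):
        df = scores_frame([0.9, 0.8, 0.1, 0.2], ["normal", "normal", "pathological", "pathological"])
        op = m.eer_point(df)
        assert op.orientation == "pathological_low"
        assert op.eer == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ClassError):
            m.eer_point(scores_frame([1, 2], ["normal", "normal"]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_sweep(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.concatenate([rng.normal(0, 1, 200), rng.normal(0.8, 1.2, 200)])
        labels = ["normal"] * 200 + ["pathological"] * 200
        op = m.eer_point(scores_frame(scores, labels))
        thr, eer = eer_sweep_oracle(scores, labels)
        assert op.threshold == thr
        assert op.eer == pytest.approx(eer, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(1.0, 1, 60)])
        labels = ["normal"] * 60 + ["pathological"] * 60
        op_raw = m.eer_point(scores_frame(scores, labels))
        op_exp = m.eer_point(scores_frame(np.exp(scores), labels))
        assert op_raw.eer == pytest.approx(op_exp.eer, abs=1e-12)
        assert op_raw.orientation == op_exp.orientation


class TestEfficiency:
    def test_separable_is_one_flipped_is_zero(self):
        op = m.EEROperatingPoint(threshold=0.5, eer=0.0, orientation="pathological_high")
        good = scores_frame([0.1, 0.9], ["normal", "pathological"])
        flipped = scores_frame([0.1, 0.9], ["pathological", "normal"])
        assert m.efficiency_at(good, op) == 1.0
        assert m.efficiency_at(flipped, op) == 0.0

    def test_tie_goes_pathological(self):
        op = m.EEROperatingPoint(threshold=0.5, eer=0.0, orientation="pathological_high")
        df = scores_frame([0.5], ["pathological"])
        assert m.efficiency_at(df, op) == 1.0

    def test_counting_oracle(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0, 1, 100)
        labels = rng.choice(["normal", "pathological"], 100)
        op = m.EEROperatingPoint(threshold=0.4, eer=0.2, orientation="pathological_high")
        expected = np.mean(
            [(s >= 0.4) == (lab == "pathological") for s, lab in zip(scores, labels)]
        )
        assert m.efficiency_at(scores_frame(scores, labels), op) == pytest.approx(expected)


class TestCrossValidation:
    def _grouped_scores(self, rng, separation, n_speakers=14, frames=10):
        rows = []
        for i in range(n_speakers):
            label = "normal" if i % 2 == 0 else "pathological"
            base = rng.normal(0 if label == "normal" else separation, 1.0)
            for j in range(frames):
                rows.append(
                    {
                        "score": base + rng.normal(0, 0.3),
                        "label": label,
                        "speaker_id": f"s{i}",
                        "recording_id": f"s{i}r0",
                        "frame_index": j,
                    }
                )
        return pd.DataFrame(rows)

    def test_seven_folds_reported(self):
        rng = np.random.default_rng(20)
        df = self._grouped_scores(rng, separation=5.0)
        plan = m.assign_speaker_folds(df[["speaker_id", "label"]], k=7, seed=0)
        res = m.cv_single_metric_efficiency(df, plan)
        assert len(res.per_fold_efficiency) == 7
        assert res.mean_efficiency == pytest.approx(np.mean(res.per_fold_efficiency))
        assert res.sd == pytest.approx(np.std(res.per_fold_efficiency, ddof=1))

    def test_strong_separation_high_efficiency(self):
        rng = np.random.default_rng(21)
        df = self._grouped_scores(rng, separation=6.0)
        plan = m.assign_speaker_folds(df[["speaker_id", "label"]], k=7, seed=1)
        res = m.cv_single_metric_efficiency(df, plan)
        assert res.mean_efficiency >= 0.95

    def test_label_independent_scores_near_chance(self):
        # mean over 20 seeds of permuted-score CV efficiency
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = self._grouped_scores(rng, separation=0.0)
            plan = m.assign_speaker_folds(df[["speaker_id", "label"]], k=7, seed=seed)
            means.append(m.cv_single_metric_efficiency(df, plan).mean_efficiency)
        assert 0.40 <= np.mean(means) <= 0.60

    def test_recording_level_aggregation(self):
        rng = np.random.default_rng(22)
        df = self._grouped_scores(rng, separation=6.0)
        plan = m.assign_speaker_folds(df[["speaker_id", "label"]], k=7, seed=2)
        res = m.cv_single_metric_efficiency(df, plan, level="recording")
        # one decision per recording: fold efficiency granularity is 1/recordings
        assert res.mean_efficiency >= 0.95

    def test_missing_speaker_rejected(self):
        rng = np.random.default_rng(23)
        df = self._grouped_scores(rng, separation=1.0)
        plan = m.assign_speaker_folds(df[["speaker_id", "label"]].iloc[:-10], k=7, seed=0)
        if set(df["speaker_id"]) - set(plan.speaker_to_fold):
            with pytest.raises(SizeError):
                m.cv_single_metric_efficiency(df, plan)
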