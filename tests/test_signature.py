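import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oxysig.clogit import PenaltySpec
from oxysig.containers import OxylipinMatrix
from oxysig.signature import (
    FittedSignature,
    adjustment_report,
    delong_ci,
    evaluate,
    fit_signature,
    oxyscore,
    rank_auc,
    transfer_evaluate,
)


def brute_force_auc(scores, labels):
    """Concordant-pair counting over every (case, control) pair."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a, b in itertools.product(pos, neg):
        total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def make_signature(coefs: dict) -> FittedSignature:
    s = pd.Series(coefs, dtype=float)
    return FittedSignature(
        analytes=list(s.index[s != 0] if (s != 0).any() else s.index),
        coefficients=s,
        penalty=PenaltySpec(1.0, 0.0),
    )


class TestOxyScore:
    def test_zero_linear_predictor_gives_half(self):
        sig = make_signature({"a": 1.0, "b": -1.0})
        x = pd.Series({"a": 1.0, "b": 1.0})
        assert oxyscore(sig, x) == pytest.approx(0.5)

    def test_log3_gives_three_quarters(self):
        sig = make_signature({"a": math.log(3.0)})
        assert oxyscore(sig, pd.Series({"a": 1.0})) == pytest.approx(0.75)

    def test_all_zero_coefficients_give_half_everywhere(self):
        sig = make_signature({"a": 0.0, "b": 0.0})
        frame = pd.DataFrame({"a": [1.0, -2.0], "b": [0.3, 5.0]})
        assert (oxyscore(sig, frame) == 0.5).all()

    def test_missing_analyte_named(self):
        sig = make_signature({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="'b'"):
            oxyscore(sig, pd.Series({"a": 1.0}))

    def test_strictly_increasing_in_linear_predictor(self):
        sig = make_signature({"a": 2.0})
        grid = [oxyscore(sig, pd.Series({"a": v})) for v in np.linspace(-3, 3, 11)]
        assert all(x < y for x, y in zip(grid, grid[1:]))


class TestAUC:
    def test_worked_four_subject_example(self):
        scores = np.array([0.9, 0.6, 0.7, 0.2])
        labels = np.array([True, True, False, False])
        assert rank_auc(scores, labels) == pytest.approx(3 / 4)

    def test_rank_formula_equals_brute_force_exhaustively(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            # discrete scores force ties
            scores = rng.integers(0, 6, size=n).astype(float)
            if labels.all() or not labels.any():
                continue
            assert rank_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_delong_interval_contains_auc(self):
        rng = np.random.default_rng(13)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.array([True] * 40 + [False] * 40)
        auc, lo, hi = delong_ci(scores, labels)
        assert lo < auc < hi
        assert auc == pytest.approx(rank_auc(scores, labels))


class TestFitSignature:
    def test_redundant_candidates_pruned(self, small_study_prepped):
        """Duplicating a signal column makes the union collinear; the
        LASSO support must not keep both copies."""
        study, truth = small_study_prepped
        signal = next(iter(truth))
        values = study.matrix.values.copy()
        values["dup_signal"] = values[signal]
        mat = OxylipinMatrix(values, standardized=True)
        dup_study = study.with_matrix(mat)
        union = list(study.matrix.analytes) + ["dup_signal"]
        sig = fit_signature(dup_study, union, seed=0)
        assert len(sig.analytes) < len(union)
        assert not {signal, "dup_signal"} <= set(sig.analytes)

    def test_single_candidate_union(self, small_study_prepped):
        study, truth = small_study_prepped
        signal = next(iter(truth))
        sig = fit_signature(study, [signal], seed=0)
        assert sig.analytes in ([signal], [])

    def test_empty_union_rejected(self, small_study_prepped):
        study, _ = small_study_prepped
        with pytest.raises(ValueError, match="empty"):
            fit_signature(study, [])

    def test_absent_candidate_named(self, small_study_prepped):
        study, _ = small_study_prepped
        with pytest.raises(ValueError, match="nope"):
            fit_signature(study, ["nope"])


class TestEvaluate:
    def test_perfect_separation(self, small_study_prepped):
        study, truth = small_study_prepped
        sig = make_signature({a: 5.0 for a in truth})
        # score with the labels themselves: force perfect ranking
        labels = study.labels()
        scores = labels.astype(float) * 0.8 + 0.1
        from oxysig.signature import _confusion

        auc, lo, hi = delong_ci(scores.to_numpy(), labels.to_numpy())
        assert auc == pytest.approx(1.0)
        conf = _confusion(scores, labels, 0.5)
        assert conf["fp"] == conf["fn"] == 0

    def test_label_independent_scores_near_half(self, small_study_prepped):
        study, _ = small_study_prepped
        rng = np.random.default_rng(14)
        labels = study.labels().to_numpy()
        n_pos = labels.sum()
        n_neg = len(labels) - n_pos
        se = math.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        aucs = [
            rank_auc(rng.standard_normal(len(labels)), labels) for _ in range(50)
        ]
        assert abs(np.mean(aucs) - 0.5) < 3 * se

    def test_cv_auc_high_on_signal_study(self, small_study_prepped):
        study, truth = small_study_prepped
        sig = fit_signature(study, list(truth), seed=0)
        perf = evaluate(sig, study, k=5, seed=0)
        assert perf.auc > 0.7
        assert sum(perf.confusion.values()) == 2 * study.n_pairs

    def test_leave_pair_out_matches_direct(self, small_study_prepped):
        """k = n_pairs agrees with an explicitly coded leave-pair-out loop."""
        from oxysig.clogit import fit_clogit
        from scipy.special import expit

        study, truth = small_study_prepped
        analytes = list(truth)
        sig = fit_signature(study, analytes, penalty=PenaltySpec(1.0, 0.0), seed=0)
        sig.analytes = analytes
        sig.coefficients = sig.coefficients.reindex(analytes).fillna(0.0)
        perf = evaluate(sig, study, k=study.n_pairs, seed=3, retune=False)
        z, cols = study.design(analytes)
        direct = {}
        for i in range(study.n_pairs):
            train = np.delete(z, i, axis=0)
            beta = fit_clogit(
                train, PenaltySpec(1.0, 0.0), analytes=cols, tol=1e-7
            ).coefficients
            for sid in (study.case_ids[i], study.control_ids[i]):
                x = study.matrix.values.loc[sid, cols]
                direct[sid] = float(expit(x @ beta))
        direct = pd.Series(direct)
        pd.testing.assert_series_equal(
            perf.scores.sort_index(), direct.sort_index(),
            check_names=False, atol=1e-9, rtol=0,
        )


class TestTransfer:
    def test_same_study_equals_apparent_auc(self, small_study_prepped):
        study, truth = small_study_prepped
        sig = fit_signature(study, list(truth), seed=0)
        perf = transfer_evaluate(sig, study)
        scores = oxyscore(sig, study.matrix.values)
        assert perf.auc == pytest.approx(
            rank_auc(scores.to_numpy(), study.labels().to_numpy())
        )

    def test_signal_free_target_near_chance(self, small_study_prepped):
        from oxysig.preprocess import preprocess_pipeline
        from oxysig.synthetic import SimulationConfig, generate_study

        study, truth = small_study_prepped
        sig = fit_signature(study, list(truth), seed=0)
        null = generate_study(
            SimulationConfig(n_pairs=150, n_analytes=12, n_signal=0, seed=77)
        )
        std, _, _ = preprocess_pipeline(null.matched_study.matrix)
        perf = transfer_evaluate(sig, null.matched_study.with_matrix(std))
        n = 150
        se = math.sqrt((2 * n + 1) / (12 * n * n))
        assert abs(perf.auc - 0.5) < 3 * se


class TestAdjustment:
    def test_empty_criteria_list(self, small_study_prepped):
        study, truth = small_study_prepped
        report = adjustment_report(study, list(truth), [])
        assert len(report) == 0

    def test_noise_criterion_keeps_support(self, small_study_prepped):
        study, truth = small_study_prepped
        study = study.with_matrix(study.matrix.copy())
        rng = np.random.default_rng(15)
        study.subjects["noise_crit"] = rng.standard_normal(len(study.subjects))
        report = adjustment_report(study, list(truth), ["noise_crit"])
        assert report.loc["noise_crit", "n_excluded"] == 0

    def test_duplicated_signal_criterion_displaces_analyte(self, small_study_prepped):
        study, truth = small_study_prepped
        signal = next(iter(truth))
        study = study.with_matrix(study.matrix.copy())
        study.subjects["dup_crit"] = study.matrix.values[signal]
        report = adjustment_report(study, list(truth), ["dup_crit"])
        assert signal in report.loc["dup_crit", "excluded_oxylipins"].split("; ")
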