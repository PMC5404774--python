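import numpy as np
import pytest

from snpconsensus.consensus import (
    build_vote_matrix,
    confidence,
    consensus_select,
    count_frequency,
    summarise,
)
from snpconsensus.regression import MethodCall
from snpconsensus.rf_stage import RFIterationRecord


def call(method, snp, it=4, significant=True, stat=0.005, covariate=False):
    return MethodCall(method=method, snp_id=snp, statistic=stat,
                      significant=significant, iteration_index=it,
                      is_covariate=covariate)


# the published simulated-data vote pattern: per SNP the methods that
# flagged it in the final iteration (S=stepwise, R=ridge, L=lasso, B=boruta)
PUBLISHED_VOTES = {
    "X1306": "SRLB", "X92": "SRL", "X1112": "SRLB", "X808": "SL",
    "X859": "SRL", "X263": "SRLB", "X829": "RL", "X1203": "RB",
    "X242": "RLB", "X56": "RLB", "X1051": "RL", "X877": "R",
    "X512": "RL", "X847": "L", "X760": "B",
}
PUBLISHED_CONSENSUS = ["X1306", "X92", "X1112", "X859", "X263", "X242", "X56"]
METHOD_OF = {"S": "stepwise", "R": "ridge", "L": "lasso", "B": "boruta"}


def published_calls(it=4):
    calls = []
    for snp, methods in PUBLISHED_VOTES.items():
        for m in methods:
            calls.append(call(METHOD_OF[m], snp, it=it))
    return calls


class TestBuildVoteMatrix:
    def test_empty_when_no_significant_calls(self):
        votes = build_vote_matrix([call("ridge", "s1", significant=False)], 4)
        assert votes.snp_ids == []
        assert votes.votes.shape == (0, 4)

    def test_unanimous_and_minority_rows(self):
        votes = build_vote_matrix(published_calls(), 4)
        assert votes.n_votes("X1306") == 4
        assert votes.n_votes("X808") == 2

    def test_only_final_iteration_counts(self):
        calls = [call("ridge", "s1", it=2), call("lasso", "s1", it=4)]
        votes = build_vote_matrix(calls, 4)
        assert votes.n_votes("s1") == 1

    def test_covariates_excluded(self):
        votes = build_vote_matrix([call("ridge", "age", covariate=True)], 4)
        assert votes.snp_ids == []


class TestConsensusSelect:
    def test_reproduces_published_consensus_column(self):
        votes = build_vote_matrix(published_calls(), 4)
        assert consensus_select(votes, 3) == PUBLISHED_CONSENSUS

    def test_three_vote_row_selected_two_vote_row_not(self):
        votes = build_vote_matrix(published_calls(), 4)
        selected = consensus_select(votes, 3)
        assert "X242" in selected  # ridge + lasso + boruta
        assert "X808" not in selected  # stepwise + lasso only

    def test_min_methods_one_selects_every_voted_snp(self):
        votes = build_vote_matrix(published_calls(), 4)
        assert set(consensus_select(votes, 1)) == set(PUBLISHED_VOTES)

    def test_selection_is_subset_of_rows(self):
        votes = build_vote_matrix(published_calls(), 4)
        for m in (1, 2, 3, 4):
            assert set(consensus_select(votes, m)) <= set(votes.snp_ids)

    def test_invalid_min_methods(self):
        votes = build_vote_matrix(published_calls(), 4)
        with pytest.raises(ValueError):
            consensus_select(votes, 0)


class TestCountFrequency:
    def test_full_grid_reaches_sixteen(self):
        calls = [call(m, "s1", it=i) for i in (1, 2, 3, 4)
                 for m in ("stepwise", "ridge", "lasso", "boruta")]
        (rec,) = count_frequency(calls)
        assert rec.count == 16
        assert rec.by_iteration == {1: 4, 2: 4, 3: 4, 4: 4}

    def test_method_counts_once_per_iteration(self):
        calls = [call("ridge", "s1", it=1), call("ridge", "s1", it=1)]
        (rec,) = count_frequency(calls)
        assert rec.count == 1

    def test_insignificant_calls_are_absent(self):
        assert count_frequency([call("ridge", "s1", significant=False)]) == []

    def test_single_appearance(self):
        (rec,) = count_frequency([call("lasso", "s9", it=3)])
        assert rec.count == 1 and rec.by_iteration == {3: 1}


class TestConfidence:
    @pytest.mark.parametrize("count,expected", [
        (13, 0.8125), (16, 1.0), (11, 0.6875), (0, 0.0),
    ])
    def test_published_worked_examples(self, count, expected):
        score = confidence(count, 4, 4)
        assert score.score == pytest.approx(expected, abs=1e-12)

    def test_threshold_is_strict(self):
        assert not confidence(8, 4, 4).is_true_positive_candidate  # 0.5
        assert confidence(9, 4, 4).is_true_positive_candidate

    def test_score_one_only_when_called_everywhere(self):
        assert confidence(16, 4, 4).score == 1.0
        assert confidence(15, 4, 4).score < 1.0

    def test_out_of_range_count_rejected(self):
        with pytest.raises(ValueError):
            confidence(17, 4, 4)
        with pytest.raises(ValueError):
            confidence(-1, 4, 4)


class TestSummarise:
    def _records(self):
        return [RFIterationRecord(i, 500 * i, 0.0, 10.0, list(PUBLISHED_VOTES))
                for i in (1, 2, 3, 4)]

    def test_key_set_is_restriction_of_every_method(self):
        calls = published_calls()
        report = summarise(calls, self._records(), "Y")
        assert report.key_snps == PUBLISHED_CONSENSUS
        for method in ("stepwise", "ridge", "lasso", "boruta"):
            method_set = {c.snp_id for c in calls
                          if c.method == method and c.significant}
            union = {c.snp_id for c in calls if c.significant}
            assert set(report.key_snps) <= union
            assert len(report.key_snps) <= len(union)

    def test_confidence_counts_all_iterations(self):
        calls = published_calls(it=4) + published_calls(it=3)
        report = summarise(calls, self._records(), "Y")
        conf = {c.snp_id: c.score for c in report.confidences}
        assert conf["X1306"] == pytest.approx(8 / 16)

    def test_scores_bounded(self):
        report = summarise(published_calls(), self._records(), "Y")
        for c in report.confidences:
            assert 0.0 <= c.score <= 1.0
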