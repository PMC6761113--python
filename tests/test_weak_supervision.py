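import math

import numpy as np
import pytest

from implantwatch import synthetic_ehr, text_markup as tm, weak_supervision as ws
from implantwatch.entity_tagging import Entity
from implantwatch.weak_supervision import (
    LabelingFunction,
    LabelMatrix,
    LabelModelConfig,
    apply_lfs,
    fit_label_model,
    generate_candidates,
    predict_marginals,
    soft_majority_vote,
)


def make_entity(etype, span, note_id="n1", sent=0):
    return Entity(note_id, sent, span, etype, f"{etype}:x", "x", {}, frozenset())


def make_sentence(note_factory, text):
    (sent,) = tm.segment_and_tokenize(note_factory(text))
    return sent


class TestGenerateCandidates:
    def test_cartesian_product_count(self, note_factory):
        sent = make_sentence(note_factory, "w1 w2 w3 w4 w5 w6 w7 w8")
        ents = [
            make_entity("complication", (0, 2)),
            make_entity("complication", (3, 5)),
            make_entity("implant", (6, 8)),
            make_entity("implant", (9, 11)),
        ]
        cands = generate_candidates(ents, "implant_complication", sent, "p1")
        assert len(cands) == 4
        assert all(c.entity_a.entity_type == "complication" for c in cands)

    def test_missing_type_gives_zero_candidates(self, note_factory):
        sent = make_sentence(note_factory, "w1 w2")
        ents = [make_entity("pain", (0, 2))]
        assert generate_candidates(ents, "pain_anatomy", sent, "p1") == []

    def test_cross_sentence_pairs_never_created(self, note_factory, lexicon):
        from implantwatch import pipeline

        note = note_factory("Liner wear seen. The Depuy Pinnacle is stable.")
        cands = pipeline.note_candidates(note, "p1", lexicon)
        # complication in sentence 0, implant in sentence 1: no pair
        assert all(
            c.entity_a.sentence_index == c.entity_b.sentence_index for c in cands
        )
        assert not any(c.relation_type == "implant_complication" for c in cands)


class TestApplyLfs:
    def toy_candidates(self, note_factory, sections=("body", "past_medical_history")):
        sent = make_sentence(note_factory, "w1 w2 w3 w4")
        ents = [make_entity("complication", (0, 2)), make_entity("implant", (3, 5))]
        return [
            generate_candidates(ents, "implant_complication", sent, "p1", section=s)[0]
            for s in sections
        ]

    def test_section_lf_votes_false_in_history(self, note_factory):
        cands = self.toy_candidates(note_factory)
        lfs = [l for l in ws.default_lfs("implant_complication") if l.name == "lf_section_history"]
        L = apply_lfs(cands, lfs)
        assert L.votes[0, 0] == 0 and L.votes[1, 0] == -1

    def test_always_abstain_lf_gives_zero_column(self, note_factory):
        cands = self.toy_candidates(note_factory)
        L = apply_lfs(cands, [LabelingFunction("abstain", lambda c: 0)])
        assert (L.votes == 0).all()

    def test_matrix_equals_cell_by_cell_application(self, note_factory):
        cands = self.toy_candidates(note_factory)
        lfs = [
            LabelingFunction("pos", lambda c: 1),
            LabelingFunction("neg_in_pmh", lambda c: -1 if c.section == "past_medical_history" else 0),
            LabelingFunction("abstain", lambda c: 0),
        ]
        L = apply_lfs(cands, lfs)
        for i, cand in enumerate(cands):
            for j, lf in enumerate(lfs):
                assert L.votes[i, j] == lf(cand)

    def test_lf_exception_becomes_abstain_with_warning(self, note_factory, caplog):
        cands = self.toy_candidates(note_factory)

        def boom(c):
            raise RuntimeError("bug in LF")

        with caplog.at_level("WARNING"):
            L = apply_lfs(cands, [LabelingFunction("boom", boom)])
        assert (L.votes == 0).all()
        assert any("boom" in m for m in caplog.messages)

    def test_matrix_rejects_invalid_entries(self):
        with pytest.raises(ValueError):
            LabelMatrix(np.array([[2, 0]]), ("a", "b"))

    def test_mtx_round_trip(self, tmp_path):
        L = LabelMatrix(np.array([[1, 0, -1], [0, 0, 1]], dtype=np.int8), ("a", "b", "c"))
        L.save(tmp_path / "L.mtx", tmp_path / "names.json")
        L2 = LabelMatrix.load(tmp_path / "L.mtx", tmp_path / "names.json")
        assert (L2.votes == L.votes).all() and L2.lf_names == L.lf_names


class TestLabelModel:
    def test_single_vote_raises_posterior_above_prior(self):
        votes = np.zeros((5, 1), dtype=np.int8)
        votes[0, 0] = 1
        L = LabelMatrix(votes, ("lf",))
        params = fit_label_model(L)
        labels = predict_marginals(L, params)
        assert labels[0].probability > params.prior
        assert all(abs(l.probability - params.prior) < 1e-12 for l in labels[1:])

    def test_symmetric_conflict_returns_prior(self):
        L = LabelMatrix(np.array([[1, -1]], dtype=np.int8), ("a", "b"))
        params = fit_label_model(L)
        # equal accuracies by symmetry of the single conflicting row
        (label,) = predict_marginals(L, params)
        assert label.probability == pytest.approx(params.prior, abs=1e-9)

    def test_all_abstain_matrix_is_unfittable(self):
        L = LabelMatrix(np.zeros((4, 2), dtype=np.int8), ("a", "b"))
        with pytest.raises(ValueError, match="unfittable"):
            fit_label_model(L)

    def test_em_recovers_accuracies_against_grid_oracle(self):
        truth = np.array([0.9, 0.75, 0.6])
        rng = np.random.default_rng(17)
        y = np.where(rng.random(2000) < 0.5, 1, -1)
        L = synthetic_ehr.simulate_votes(y, truth, [0.8] * 3, seed=18)
        params = fit_label_model(L)
        assert np.abs(params.alpha - truth).max() < 0.05
        # independent coarse grid search over the same marginal likelihood
        from implantwatch.weak_supervision import _marginal_ll

        grid = np.arange(0.55, 1.0, 0.05)
        best, best_ll = None, -np.inf
        for a0 in grid:
            for a1 in grid:
                for a2 in grid:
                    ll = _marginal_ll(
                        L.votes.astype(int), np.array([a0, a1, a2]), params.beta, 0.5
                    )
                    if ll > best_ll:
                        best, best_ll = (a0, a1, a2), ll
        assert np.abs(np.array(best) - truth).max() <= 0.051
        # EM likelihood must be at least the best grid point's
        assert params.log_likelihood_path[-1] >= best_ll - 1e-6

    def test_em_log_likelihood_monotone(self):
        rng = np.random.default_rng(3)
        y = np.where(rng.random(500) < 0.5, 1, -1)
        L = synthetic_ehr.simulate_votes(y, [0.8, 0.7], [0.7, 0.9], seed=4)
        params = fit_label_model(L)
        path = params.log_likelihood_path
        assert all(b >= a - 1e-8 for a, b in zip(path, path[1:]))


class TestMarginals:
    def params(self, alphas, prior=0.5):
        return ws.LabelModelParams(np.array(alphas), np.ones(len(alphas)), prior)

    def test_all_abstain_row_gets_prior(self):
        L = LabelMatrix(np.zeros((1, 2), dtype=np.int8), ("a", "b"))
        (lab,) = predict_marginals(L, self.params([0.9, 0.9], prior=0.3))
        assert lab.probability == pytest.approx(0.3)

    def test_two_positive_votes_bayes_rule(self):
        L = LabelMatrix(np.array([[1, 1]], dtype=np.int8), ("a", "b"))
        (lab,) = predict_marginals(L, self.params([0.9, 0.9]))
        expected = 0.81 * 0.5 / (0.81 * 0.5 + 0.01 * 0.5)
        assert lab.probability == pytest.approx(expected, abs=1e-9)
        assert lab.probability == pytest.approx(0.9878, abs=5e-4)

    def test_conflicting_equal_accuracy_votes_give_half(self):
        L = LabelMatrix(np.array([[1, -1]], dtype=np.int8), ("a", "b"))
        (lab,) = predict_marginals(L, self.params([0.8, 0.8]))
        assert lab.probability == pytest.approx(0.5)

    def test_adding_positive_vote_never_decreases_posterior(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.integers(2, 6)
            alphas = rng.uniform(0.51, 0.99, m)
            row = rng.choice([-1, 0, 1], size=m)
            j = rng.integers(m)
            row_plus = row.copy()
            row_plus[j] = 1
            if row[j] == 1:
                continue
            L1 = LabelMatrix(row[None, :].astype(np.int8), tuple(map(str, range(m))))
            L2 = LabelMatrix(row_plus[None, :].astype(np.int8), tuple(map(str, range(m))))
            p1 = predict_marginals(L1, self.params(alphas))[0].probability
            p2 = predict_marginals(L2, self.params(alphas))[0].probability
            assert p2 >= p1 - 1e-12

    def test_equal_accuracies_rank_like_smv(self):
        # With equal accuracies the posterior is monotone in the vote
        # margin (#pos - #neg); among rows casting the same number of
        # votes that ordering coincides with the SMV score ordering.
        rng = np.random.default_rng(5)
        votes = rng.choice([-1, 0, 1], size=(60, 4)).astype(np.int8)
        votes[(votes != 0).sum(axis=1) == 0, 0] = 1  # avoid all-abstain ties
        L = LabelMatrix(votes, ("a", "b", "c", "d"))
        marg = [l.probability for l in predict_marginals(L, self.params([0.8] * 4))]
        smv = [s for s, _ in soft_majority_vote(L)]
        cast = (votes != 0).sum(axis=1)
        for i in range(len(marg)):
            for j in range(len(marg)):
                if cast[i] == cast[j] and smv[i] > smv[j]:
                    assert marg[i] > marg[j] - 1e-12


class TestSoftMajorityVote:
    def matrix(self, rows):
        arr = np.array(rows, dtype=np.int8)
        return LabelMatrix(arr, tuple(f"lf{j}" for j in range(arr.shape[1])))

    def test_two_of_three_positive(self):
        ((score, decision),) = soft_majority_vote(self.matrix([[1, 1, -1]]))
        assert score == pytest.approx(2 / 3)
        assert decision == "positive"

    def test_all_abstain_is_negative(self):
        ((score, decision),) = soft_majority_vote(self.matrix([[0, 0, 0]]))
        assert decision == "negative" and score == 0.0

    def test_unanimous_positive_scores_one(self):
        ((score, decision),) = soft_majority_vote(self.matrix([[1, 1, 1]]))
        assert score == 1.0 and decision == "positive"
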