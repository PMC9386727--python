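"""Dual-task loss, length scheduler, exclusion filter, training loop."""

import numpy as np
import pytest

from proteinlm import (AnnotationVocabulary, CorruptionConfig, LengthSchedule,
                       ModelConfig, ModelOutputs, apply_annotation_exclusion,
                       build_model, generate_corpus, pretraining_loss,
                       run_pretraining)
from proteinlm.autodiff import Tensor
from proteinlm.pretraining import CLIP_EPS, _loss_tensors
from proteinlm.synthetic import CorpusSpec


def scalar_loop_loss(token_probs, annot_probs, tokens, annots):
    """Element-by-element transcription of the summed dual loss (batch mean)."""
    B, L, K = token_probs.shape
    totals_seq, totals_ann = [], []
    for b in range(B):
        seq = 0.0
        for i in range(L):
            p = min(max(token_probs[b, i, tokens[b, i]], CLIP_EPS), 1 - CLIP_EPS)
            seq -= np.log(p)
        ann = 0.0
        for j in range(annot_probs.shape[1]):
            p = min(max(annot_probs[b, j], CLIP_EPS), 1 - CLIP_EPS)
            ann -= annots[b, j] * np.log(p) + (1 - annots[b, j]) * np.log(1 - p)
        totals_seq.append(seq)
        totals_ann.append(ann)
    return np.mean(totals_seq), np.mean(totals_ann)


class TestPretrainingLoss:
    def test_uniform_predictions_closed_form(self):
        """10 positions at 1/26 plus 100 absent annotations at 0.5 gives
        10 ln 26 + 100 ln 2."""
        outputs = ModelOutputs(Tensor(np.full((1, 10, 26), 1 / 26)),
                               Tensor(np.full((1, 100), 0.5)))
        lb = pretraining_loss(outputs, np.zeros((1, 10), dtype=int), np.zeros((1, 100)))
        assert lb.seq_loss == pytest.approx(10 * np.log(26), abs=1e-6)
        assert lb.annot_loss == pytest.approx(100 * np.log(2), abs=1e-6)
        assert lb.total == pytest.approx(10 * np.log(26) + 100 * np.log(2), abs=1e-6)

    def test_confident_correct_predictions_drive_loss_to_zero(self):
        probs = np.full((1, 4, 26), 1e-12)
        probs[0, :, 3] = 1.0
        outputs = ModelOutputs(Tensor(probs), Tensor(np.array([[1.0 - 1e-12, 1e-12]])))
        lb = pretraining_loss(outputs, np.full((1, 4), 3), np.array([[1, 0]]))
        assert lb.total < 1e-5

    def test_matches_scalar_loop_oracle_on_random_instances(self, rng):
        for _ in range(10):
            B, L, J = 3, 7, 11
            tp = rng.dirichlet(np.ones(26), size=(B, L))
            ap = rng.random((B, J))
            tokens = rng.integers(0, 26, (B, L))
            annots = rng.integers(0, 2, (B, J))
            lb = pretraining_loss(ModelOutputs(Tensor(tp), Tensor(ap)), tokens, annots)
            seq_ref, ann_ref = scalar_loop_loss(tp, ap, tokens, annots)
            assert lb.seq_loss == pytest.approx(seq_ref, abs=1e-8)
            assert lb.annot_loss == pytest.approx(ann_ref, abs=1e-8)

    def test_loss_scales_linearly_with_length_for_uniform_predictions(self):
        for L in (1, 5, 50):
            outputs = ModelOutputs(Tensor(np.full((1, L, 26), 1 / 26)),
                                   Tensor(np.zeros((1, 0))))
            lb = pretraining_loss(outputs, np.zeros((1, L), dtype=int), np.zeros((1, 0)))
            assert lb.seq_loss == pytest.approx(L * np.log(26), rel=1e-10)
            assert lb.annot_loss == 0.0

    def test_shape_mismatch_raises(self):
        outputs = ModelOutputs(Tensor(np.full((1, 4, 26), 1 / 26)),
                               Tensor(np.full((1, 3), 0.5)))
        with pytest.raises(ValueError):
            pretraining_loss(outputs, np.zeros((1, 5), dtype=int), np.zeros((1, 3)))
        with pytest.raises(ValueError):
            pretraining_loss(outputs, np.zeros((1, 4), dtype=int), np.zeros((1, 4)))

    def test_gradient_vanishes_for_confident_correct_prediction(self, rng):
        """Near-perfect predictions: d loss / d probs at the true entries ~ -1,
        and a finite-difference step toward the target does not reduce loss
        noticeably (the optimum has been reached)."""
        probs = np.full((1, 2, 26), 1e-9)
        probs[0, :, 5] = 1.0 - 25e-9
        tp = Tensor(probs, requires_grad=True)
        ap = Tensor(np.array([[1.0 - 1e-9]]), requires_grad=True)
        seq, ann = _loss_tensors(ModelOutputs(tp, ap), np.full((1, 2), 5),
                                 np.array([[1.0]]))
        (seq + ann).backward()
        # clipped at 1-eps: gradient magnitude bounded by 1/(1-eps)
        assert np.abs(tp.grad[0, :, 5]).max() <= 1.0 / (1 - CLIP_EPS) + 1e-6


class TestLengthSchedule:
    def test_alternates_exactly_every_switch_every_steps(self):
        sched = LengthSchedule((16, 32), switch_every=10)
        lengths = [sched.length_at(s) for s in range(40)]
        assert lengths == [16] * 10 + [32] * 10 + [16] * 10 + [32] * 10

    def test_rejects_duplicate_or_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            LengthSchedule((16, 16), 5)
        with pytest.raises(ValueError):
            LengthSchedule((0,), 5)


class TestAnnotationExclusion:
    RECORDS = [(f"P{i}", "ACDEF", frozenset({"a"})) for i in range(100)]

    def test_empty_exclusion_passes_stream_through(self):
        out = list(apply_annotation_exclusion(self.RECORDS, set()))
        assert out == self.RECORDS

    def test_full_exclusion_empties_every_annotation_set(self):
        out = list(apply_annotation_exclusion(self.RECORDS, {f"P{i}" for i in range(100)}))
        assert all(ann == frozenset() for _, _, ann in out)
        assert all(seq == "ACDEF" for _, seq, _ in out)

    def test_mixed_exclusion_hits_exactly_the_listed_ids(self):
        excluded = {f"P{i}" for i in range(0, 100, 10)}
        out = list(apply_annotation_exclusion(self.RECORDS, excluded))
        lost = [pid for pid, _, ann in out if not ann]
        assert sorted(lost) == sorted(excluded)
        assert sum(bool(ann) for _, _, ann in out) == 90


class TestRunPretraining:
    def _setup(self, n_records=60):
        corpus = generate_corpus(CorpusSpec(n_records=n_records, seed=5))
        vocab = AnnotationVocabulary.from_ids(
            sorted({a for _, _, ann in corpus for a in ann}))
        cfg = ModelConfig(d_local=8, d_global=16, n_blocks=1, n_heads=2,
                          d_key=4, n_annotations=vocab.size)
        return corpus, vocab, cfg

    def test_scheduler_contract_and_history_shape(self):
        corpus, vocab, cfg = self._setup()
        model = build_model(cfg, rng=0)
        hist = run_pretraining(model, corpus, vocab,
                               schedule=LengthSchedule((16, 32), 5),
                               steps=20, batch_size=4, seed=0)
        assert [row[1] for row in hist] == [16] * 5 + [32] * 5 + [16] * 5 + [32] * 5
        assert all(row[4] == pytest.approx(row[2] + row[3]) for row in hist)
        assert all(row[2] >= 0 and row[3] >= 0 for row in hist)

    def test_two_seeded_runs_produce_identical_histories(self):
        corpus, vocab, cfg = self._setup()
        hists = []
        for _ in range(2):
            model = build_model(cfg, rng=3)
            hists.append(run_pretraining(model, corpus, vocab,
                                         schedule=LengthSchedule((24,), 100),
                                         steps=8, batch_size=4, seed=9))
        assert hists[0] == hists[1]

    def test_short_run_reduces_loss(self):
        corpus, vocab, cfg = self._setup(n_records=200)
        model = build_model(cfg, rng=1)
        hist = run_pretraining(model, corpus, vocab,
                               schedule=LengthSchedule((48,), 1000),
                               steps=60, batch_size=8, learning_rate=2e-3, seed=2)
        first = np.mean([r[4] for r in hist[:5]])
        last = np.mean([r[4] for r in hist[-5:]])
        assert last < first
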