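"""Metric implementations against brute-force oracles and hand counts."""

import math

import numpy as np
import pytest
from rdkit.ML.Scoring import Scoring as rdkit_scoring

from evimol.metrics import (
    bedroc,
    brier,
    classification_summary,
    confidence_percentile_curve,
    ece,
    enrichment_factor,
    ofn,
    ofr,
)


# ------------------------------------------------------------ oracle helpers
def ece_bruteforce(probs, labels, n_bins):
    """Loop-based reference: equal-width bins on confidence max(p, 1-p)."""
    n = len(probs)
    total = 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        members = []
        for p, y in zip(probs, labels):
            c = max(p, 1 - p)
            inside = (c >= lo and c < hi) if b < n_bins - 1 else (c >= lo and c <= hi)
            if inside:
                members.append((c, int((p > 0.5) == y)))
        if members:
            conf = sum(m[0] for m in members) / len(members)
            acc = sum(m[1] for m in members) / len(members)
            total += len(members) / n * abs(acc - conf)
    return total


def curve_bruteforce(probs, labels, grid):
    out = []
    n = len(probs)
    ent = []
    for p in probs:
        if 0 < p < 1:
            ent.append(-p * math.log(p) - (1 - p) * math.log(1 - p))
        else:
            ent.append(0.0)
    ranked = sorted(range(n), key=lambda i: (-ent[i], i))
    for f in grid:
        if f >= 1:
            continue
        keep = ranked[math.ceil(f * n):]
        acc = sum(int((probs[i] > 0.5) == labels[i]) for i in keep) / len(keep)
        out.append((f, acc))
    return out


# -------------------------------------------------------------------- tests
class TestECE:
    def test_perfect_confident_predictions(self):
        assert ece([1.0, 0.0, 1.0], [1, 0, 1], 10) == 0.0

    def test_single_bin_hand_count(self):
        # acc 0.75 vs conf 0.8 in the lone bin
        val = ece([0.8] * 4, [1, 1, 1, 0], n_bins=1)
        assert val == pytest.approx(0.05, abs=1e-12)

    def test_matches_bruteforce(self, random_predictions):
        probs, labels = random_predictions
        assert ece(probs, labels, 10) == pytest.approx(
            ece_bruteforce(probs, labels, 10), abs=1e-12)

    def test_permutation_invariant(self, random_predictions):
        probs, labels = random_predictions
        perm = np.random.default_rng(3).permutation(len(probs))
        assert ece(probs[perm], labels[perm], 10) == pytest.approx(
            ece(probs, labels, 10), abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ece([1.2], [1], 10)


class TestBrier:
    def test_exact_predictions(self):
        assert brier([0.0, 1.0], [0, 1]) == 0.0

    def test_coin_flip_is_quarter(self):
        assert brier([0.5] * 6, [0, 1, 0, 1, 1, 0]) == pytest.approx(0.25)

    def test_matches_bruteforce(self, random_predictions):
        probs, labels = random_predictions
        ref = sum((p - y) ** 2 for p, y in zip(probs, labels)) / len(probs)
        assert brier(probs, labels) == pytest.approx(ref, abs=1e-12)


class TestOverconfidence:
    def test_ofr_hand_count(self):
        # high-confidence set {0.05, 0.95, 0.92}; one wrong (0.92 with y=0)
        assert ofr([0.05, 0.95, 0.5, 0.92], [0, 1, 1, 0]) == pytest.approx(1 / 3)

    def test_ofr_nan_when_never_confident(self):
        assert math.isnan(ofr([0.5, 0.3, 0.7], [0, 1, 0]))

    def test_ofr_zero_when_confident_and_right(self):
        assert ofr([0.01, 0.99], [0, 1]) == 0.0

    def test_ofn_hand_count(self):
        probs = [0.05] + [0.5] * 9
        labels = [1] + [0] * 9
        assert ofn(probs, labels) == pytest.approx(0.1)

    def test_ofn_zero_without_confident_negatives(self):
        assert ofn([0.5, 0.9], [1, 0]) == 0.0

    def test_ofn_is_first_ofr_numerator_term_over_n(self, random_predictions):
        probs, labels = random_predictions
        ref = np.mean((probs < 0.1) & (labels == 1))
        assert ofn(probs, labels) == pytest.approx(ref, abs=1e-12)


class TestConfidencePercentileCurve:
    def test_perfectly_separated(self):
        probs = [0.01, 0.02, 0.98, 0.99]
        labels = [0, 0, 1, 1]
        for _, acc in confidence_percentile_curve(probs, labels):
            assert acc == 1.0

    def test_zero_removal_is_plain_accuracy(self, random_predictions):
        probs, labels = random_predictions
        curve = confidence_percentile_curve(probs, labels, removal_grid=[0.0])
        assert curve[0][1] == pytest.approx(
            np.mean((probs > 0.5).astype(int) == labels))

    def test_matches_bruteforce(self, random_predictions):
        probs, labels = random_predictions
        grid = [0.0, 0.1, 0.25, 0.5, 0.9]
        ours = confidence_percentile_curve(probs, labels, removal_grid=grid)
        ref = curve_bruteforce(list(probs), list(labels), grid)
        for (f1, a1), (f2, a2) in zip(ours, ref):
            assert f1 == f2
            assert a1 == pytest.approx(a2, abs=1e-12)

    def test_full_removal_skipped(self):
        curve = confidence_percentile_curve([0.6], [1], removal_grid=[0.0, 1.0])
        assert len(curve) == 1


class TestEnrichmentFactor:
    def test_all_actives_on_top(self):
        scores = np.concatenate([np.linspace(2, 3, 10), np.linspace(0, 1, 990)])
        labels = np.concatenate([np.ones(10), np.zeros(990)]).astype(int)
        assert enrichment_factor(scores, labels, 0.01) == pytest.approx(100.0)

    def test_all_actives_last(self):
        scores = np.concatenate([np.zeros(10), np.ones(990)])
        labels = np.concatenate([np.ones(10), np.zeros(990)]).astype(int)
        assert enrichment_factor(scores, labels, 0.01) == 0.0

    def test_random_scores_average_near_one(self):
        g = np.random.default_rng(42)
        labels = np.zeros(500, dtype=int)
        labels[:50] = 1
        vals = []
        for _ in range(200):
            scores = g.random(500)
            vals.append(enrichment_factor(scores, labels, 0.1))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * se + 1e-9

    def test_requires_actives(self):
        with pytest.raises(ValueError):
            enrichment_factor([0.1, 0.2], [0, 0])


class TestBEDROC:
    @staticmethod
    def _rdkit_bedroc(scores, labels, alpha):
        order = np.argsort(-np.asarray(scores), kind="stable")
        ranked = [[scores[i], labels[i]] for i in order]
        return rdkit_scoring.CalcBEDROC(ranked, 1, alpha)

    def test_perfect_ranking_near_one(self):
        scores = np.concatenate([np.linspace(2, 3, 10), np.linspace(0, 1, 990)])
        labels = np.concatenate([np.ones(10), np.zeros(990)]).astype(int)
        assert bedroc(scores, labels, 80.5) >= 0.99

    def test_inverted_ranking_near_zero(self):
        scores = np.concatenate([np.zeros(10), np.ones(990) + 1])
        labels = np.concatenate([np.ones(10), np.zeros(990)]).astype(int)
        assert bedroc(scores, labels, 80.5) <= 0.01

    @pytest.mark.parametrize("alpha", [5.0, 20.0, 80.5])
    def test_matches_rdkit_reference(self, alpha):
        g = np.random.default_rng(9)
        scores = g.random(400)
        labels = (g.random(400) < 0.1).astype(int)
        labels[0] = 1
        labels[1] = 0
        assert bedroc(scores, labels, alpha) == pytest.approx(
            self._rdkit_bedroc(scores, labels, alpha), abs=1e-10)

    def test_bounded(self, random_predictions):
        probs, labels = random_predictions
        assert 0.0 <= bedroc(probs, labels, 80.5) <= 1.0


class TestClassificationSummary:
    def test_perfect_separation(self):
        rep = classification_summary([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert rep["auroc"] == 1.0
        assert rep["mcc"] == 1.0

    def test_constant_probs_auroc_half(self):
        rep = classification_summary([0.7] * 6, [0, 1, 0, 1, 1, 0])
        assert rep["auroc"] == pytest.approx(0.5)

    def test_mcc_hand_formula(self):
        # confusion: TP 3, FP 1, FN 1, TN 5
        probs = [0.9] * 3 + [0.9] + [0.1] + [0.1] * 5
        labels = [1] * 3 + [0] + [1] + [0] * 5
        tp, fp, fn, tn = 3, 1, 1, 5
        mcc = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        rep = classification_summary(probs, labels)
        assert rep["mcc"] == pytest.approx(mcc)
        assert rep["accuracy"] == pytest.approx(0.8)

    def test_settings_recorded(self):
        rep = classification_summary([0.2, 0.8], [0, 1], n_bins=5)
        assert rep.settings["n_bins"] == 5
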