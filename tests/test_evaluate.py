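"""Native contact maps and the four evaluation metrics."""

import numpy as np
import pytest

from msacontact import (
    LONG,
    MEDIUM,
    SHORT,
    ContactPrediction,
    ContactScoreMatrix,
    NativeContactMap,
    StructureMappingError,
    accuracy_top,
    mcc_full,
    native_contact_map,
    pr_auc,
    xd_score,
)
from msacontact.evaluate import RangeClass, confusion_counts
from msacontact.synth import _pdb_text


def make_native(L, contact_pairs, contact_dist=5.0, far_dist=30.0, resolved=None):
    dist = np.full((L, L), far_dist)
    np.fill_diagonal(dist, 0.0)
    for i, j in contact_pairs:
        dist[i, j] = dist[j, i] = contact_dist
    if resolved is None:
        resolved = np.ones(L, dtype=bool)
    else:
        resolved = np.asarray(resolved, dtype=bool)
        dist[~resolved, :] = np.nan
        dist[:, ~resolved] = np.nan
    return NativeContactMap(dist=dist, resolved=resolved)


def preds(pairs, scores=None):
    if scores is None:
        scores = range(len(pairs), 0, -1)
    return [ContactPrediction(i=i + 1, j=j + 1, score=float(s), rank=r + 1)
            for r, ((i, j), s) in enumerate(zip(pairs, scores))]


class TestRangeClasses:
    @pytest.mark.parametrize("sep, expect", [
        (5, None), (6, "short"), (11, "short"), (12, "medium"),
        (23, "medium"), (24, "long"), (100, "long"),
    ])
    def test_separation_bounds(self, sep, expect):
        hit = [rc.label for rc in (SHORT, MEDIUM, LONG) if rc.contains(sep)]
        assert hit == ([expect] if expect else [])


class TestNativeContactMap:
    @pytest.fixture()
    def boundary_map(self, tmp_path_factory):
        # residue pairs at exactly 7.9 and 8.0 A; one glycine pair at 5.0
        L = 16
        ca = np.zeros((L, 3))
        spread = np.arange(L, dtype=float) * 60.0
        ca[:, 2] = spread
        ca[0] = (0.0, 0.0, 0.0)
        ca[7] = (7.9, 0.0, 0.0)      # sep 7: contact
        ca[1] = (0.0, 300.0, 0.0)
        ca[9] = (8.0, 300.0, 0.0)    # sep 8: exactly at cutoff -> no contact
        ca[2] = (0.0, 600.0, 0.0)
        ca[12] = (5.0, 600.0, 0.0)   # glycine pair via CA
        seq = list("A" * L)
        seq[2] = seq[12] = "G"
        seq = "".join(seq)
        pdb = _pdb_text(ca, ca.copy(), seq)
        path = tmp_path_factory.mktemp("bnd") / "boundary.pdb"
        path.write_text(pdb)
        return native_contact_map(path, seq)

    def test_strict_cutoff(self, boundary_map):
        assert boundary_map.contact[0, 7]
        assert not boundary_map.contact[1, 9]
        assert boundary_map.dist[1, 9] == pytest.approx(8.0, abs=1e-3)

    def test_glycine_uses_ca(self, boundary_map):
        assert boundary_map.contact[2, 12]
        assert boundary_map.dist[2, 12] == pytest.approx(5.0, abs=1e-3)

    def test_unresolved_tail_flagged_not_false_asserted(self, tmp_path):
        ca = np.zeros((16, 3))
        ca[:, 0] = np.arange(16) * 20.0
        pdb = _pdb_text(ca, ca + 0.3, "ACDEFGHIKLMNPQRS")
        path = tmp_path / "short.pdb"
        path.write_text(pdb)
        nat = native_contact_map(path, "ACDEFGHIKLMNPQRSTV")  # 2 unresolved targets
        assert not nat.resolved[16] and not nat.resolved[17]
        assert np.isnan(nat.dist[16, 0])
        iu, ju = nat.pair_indices(RangeClass("all", 6, np.inf))
        assert 16 not in set(iu) | set(ju) and 17 not in set(iu) | set(ju)

    def test_mapping_failure_raises(self, tmp_path):
        ca = np.zeros((10, 3))
        ca[:, 0] = np.arange(10) * 20.0
        path = tmp_path / "mismatch.pdb"
        path.write_text(_pdb_text(ca, ca + 0.3, "A" * 10))
        with pytest.raises(StructureMappingError):
            native_contact_map(path, "W" * 10)


class TestAccuracy:
    def test_worked_example_49_of_62(self):
        # 62 long-range predictions, 49 of them native contacts
        L = 130
        true_pairs = [(i, i + 30) for i in range(49)]
        false_pairs = [(i, i + 40) for i in range(13)]
        native = make_native(L, true_pairs)
        pred = preds(true_pairs + false_pairs)
        acc = accuracy_top(pred, native, 62, LONG)
        assert round(acc, 2) == 0.79

    def test_worked_example_39_of_62(self):
        L = 130
        true_pairs = [(i, i + 30) for i in range(39)]
        false_pairs = [(i, i + 40) for i in range(23)]
        native = make_native(L, true_pairs)
        pred = preds(true_pairs + false_pairs)
        assert round(accuracy_top(pred, native, 62, LONG), 2) == 0.63

    def test_all_correct_is_one(self):
        native = make_native(40, [(0, 30), (1, 28), (3, 33)])
        pred = preds([(0, 30), (1, 28), (3, 33)])
        assert accuracy_top(pred, native, 3, LONG) == 1.0

    def test_range_restriction_applies_before_truncation(self):
        # a short-range pair ahead in rank must not consume a long-range slot
        native = make_native(60, [(0, 30)])
        pred = preds([(2, 10), (0, 30)])  # short pair ranked first
        assert accuracy_top(pred, native, 1, LONG) == 1.0

    def test_empty_restricted_list_is_nan(self):
        native = make_native(40, [(0, 30)])
        assert np.isnan(accuracy_top(preds([(0, 30)]), native, 5, SHORT))

    def test_list_size_below_one_rejected(self):
        native = make_native(40, [])
        with pytest.raises(ValueError):
            accuracy_top(preds([(0, 30)]), native, 0, LONG)

    def test_monotone_score_transform_invariant(self):
        native = make_native(60, [(0, 30), (2, 40)])
        pairs = [(0, 30), (1, 35), (2, 40)]
        base = preds(pairs, scores=[3.0, 2.0, 1.0])
        squashed = preds(pairs, scores=[np.exp(3), np.exp(2), np.exp(1)])
        for k in (1, 2, 3):
            assert accuracy_top(base, native, k, LONG) == accuracy_top(
                squashed, native, k, LONG)

    def test_random_permutation_accuracy_matches_prevalence(self, rng):
        # uninformative rankings score at chance = contact prevalence
        L = 60
        pairs = [(i, j) for i in range(L) for j in range(i + 24, L)]
        contact_pairs = [p for k, p in enumerate(pairs) if k % 10 == 0]
        native = make_native(L, contact_pairs)
        prevalence = len(contact_pairs) / len(pairs)
        accs = []
        for _ in range(300):
            perm = rng.permutation(len(pairs))
            pred = preds([pairs[k] for k in perm])
            accs.append(accuracy_top(pred, native, 30, LONG))
        assert np.mean(accs) == pytest.approx(prevalence, abs=0.02)


class TestXd:
    def test_identical_distributions_give_exact_zero(self):
        L = 60
        native = make_native(L, [(0, 30)], contact_dist=6.0, far_dist=33.0)
        iu, ju = native.pair_indices(LONG)
        pred = preds(list(zip(iu, ju)))  # predict every class pair
        assert xd_score(pred, native, LONG) == 0.0

    def test_short_distance_enrichment_positive(self):
        L = 60
        contact_pairs = [(i, i + 30) for i in range(10)]
        native = make_native(L, contact_pairs, contact_dist=5.0, far_dist=40.0)
        pred = preds(contact_pairs)
        assert xd_score(pred, native, LONG) > 0.0

    def test_termwise_hand_evaluation(self):
        # predicted pairs in bin 2 (6 A), class background at 45 A (bin 12)
        # and 70 A (overflow -> bin 15)
        L = 80
        close = [(0, 40), (1, 43)]
        native = make_native(L, close, contact_dist=6.0, far_dist=45.0)
        native.dist[2, 50] = native.dist[50, 2] = 70.0
        pred = preds(close)
        iu, ju = native.pair_indices(LONG)
        all_d = native.dist[iu, ju]
        # independent 15-term sum
        pip = np.zeros(15)
        pip[1] = 1.0
        pia = np.zeros(15)
        for d in all_d:
            b = min(int(np.ceil(d / 4.0)), 15) - 1
            pia[b] += 1.0 / len(all_d)
        expected = sum((pip[k] - pia[k]) / (((k + 1) / 15.0) * 15) for k in range(15))
        assert xd_score(pred, native, LONG) == pytest.approx(expected, abs=1e-12)

    def test_empty_prediction_list_is_nan(self):
        native = make_native(40, [(0, 30)])
        assert np.isnan(xd_score([], native, LONG))


def scored_native(L, contact_pairs, score_fn, range_class=LONG):
    """Native map + a corrected score matrix filled per pair."""
    native = make_native(L, contact_pairs)
    corrected = np.zeros((L, L))
    iu, ju = native.pair_indices(range_class)
    for i, j in zip(iu, ju):
        corrected[i, j] = corrected[j, i] = score_fn(int(i), int(j))
    return native, ContactScoreMatrix(raw=np.abs(corrected), corrected=corrected)


class TestMCC:
    def test_perfect_separation_is_one(self):
        contact_pairs = [(i, i + 30) for i in range(10)]
        native, scores = scored_native(
            70, contact_pairs,
            lambda i, j: 1.0 if (i, j) in set(contact_pairs) else 0.0,
        )
        assert mcc_full(scores, native, LONG) == pytest.approx(1.0)

    def test_derived_confusion_counts(self):
        # L=38 has 105 long-range pairs; removing residue 9 (degree 5)
        # leaves exactly 100, arranged into counts (TP,FP,TN,FN)=(6,2,90,2)
        L = 38
        resolved = np.ones(L, dtype=bool)
        resolved[9] = False
        pairs = [(i, j) for i in range(L) for j in range(i + 24, L)
                 if 9 not in (i, j)]
        assert len(pairs) == 100
        contact_pairs = pairs[:8]
        high = set(pairs[:6] + pairs[8:10])  # 6 contacts + 2 non-contacts high
        native = make_native(L, contact_pairs, resolved=resolved)
        corrected = np.zeros((L, L))
        for i, j in high:
            corrected[i, j] = corrected[j, i] = 1.0
        scores = ContactScoreMatrix(raw=np.abs(corrected), corrected=corrected)
        tp, fp, tn, fn = confusion_counts(scores, native, LONG)
        assert (tp, fp, tn, fn) == (6, 2, 90, 2)
        expected = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert mcc_full(scores, native, LONG) == pytest.approx(expected)

    def test_score_independent_of_truth_near_zero(self, rng):
        L = 60
        pairs = [(i, j) for i in range(L) for j in range(i + 24, L)]
        contact_pairs = pairs[::7]
        native, scores = scored_native(
            L, contact_pairs, lambda i, j: float(rng.random() > 0.5),
        )
        assert abs(mcc_full(scores, native, LONG)) < 0.15

    def test_max_mcc_rule_at_least_default(self):
        contact_pairs = [(i, i + 30) for i in range(8)]
        native, scores = scored_native(
            70, contact_pairs,
            lambda i, j: 0.9 if (i, j) in set(contact_pairs) else 0.1,
        )
        assert (mcc_full(scores, native, LONG, "max-mcc")
                >= mcc_full(scores, native, LONG, "minmax-0.5"))


class TestPRAuc:
    @staticmethod
    def brute_force_auc(y, s):
        """Threshold enumeration + trapezoid, written independently."""
        points = []
        for t in sorted(set(s), reverse=True):
            sel = [k for k in range(len(s)) if s[k] >= t]
            tp = sum(1 for k in sel if y[k])
            points.append((tp / sum(y), tp / len(sel)))
        recalls = [0.0] + [r for r, _ in points]
        precisions = [points[0][1]] + [p for _, p in points]
        area = 0.0
        for k in range(1, len(recalls)):
            area += (recalls[k] - recalls[k - 1]) * (
                precisions[k] + precisions[k - 1]) / 2
        return area

    def test_perfect_ranking_is_one(self):
        contact_pairs = [(i, i + 30) for i in range(6)]
        native, scores = scored_native(
            70, contact_pairs,
            lambda i, j: 2.0 if (i, j) in set(contact_pairs) else 1.0 / (1 + i + j),
        )
        assert pr_auc(scores, native, LONG) == pytest.approx(1.0)

    def test_six_pair_toy_matches_brute_force(self):
        L = 40
        pairs = [(0, 30), (1, 28), (2, 33), (3, 35), (4, 29), (5, 31)]
        truths = [1, 0, 1, 0, 0, 1]
        svals = [0.9, 0.8, 0.7, 0.7, 0.2, 0.1]
        native = make_native(L, [p for p, t in zip(pairs, truths) if t])
        keep = np.zeros((L, L), bool)
        for i, j in pairs:
            keep[i, j] = True
        native.dist[~(keep | keep.T | np.eye(L, dtype=bool))] = np.nan
        corrected = np.zeros((L, L))
        for (i, j), s in zip(pairs, svals):
            corrected[i, j] = corrected[j, i] = s
        scores = ContactScoreMatrix(raw=np.abs(corrected), corrected=corrected)
        expected = self.brute_force_auc(truths, svals)
        assert pr_auc(scores, native, LONG) == pytest.approx(expected, abs=1e-12)

    def test_tied_scores_give_prevalence(self):
        L = 60
        pairs = [(i, j) for i in range(L) for j in range(i + 24, L)]
        contact_pairs = pairs[::5]
        native, scores = scored_native(L, contact_pairs, lambda i, j: 1.0)
        prevalence = len(contact_pairs) / len(pairs)
        assert pr_auc(scores, native, LONG) == pytest.approx(prevalence, abs=1e-12)

    def test_no_positive_pairs_is_nan(self):
        native, scores = scored_native(60, [], lambda i, j: 1.0)
        assert np.isnan(pr_auc(scores, native, LONG))

    def test_monotone_transform_invariant(self, rng):
        L = 60
        pairs = [(i, j) for i in range(L) for j in range(i + 24, L)]
        contact_pairs = pairs[::6]
        native, scores = scored_native(L, contact_pairs,
                                       lambda i, j: float(rng.random()))
        base = pr_auc(scores, native, LONG)
        scores2 = ContactScoreMatrix(raw=scores.raw,
                                     corrected=np.exp(scores.corrected))
        assert pr_auc(scores2, native, LONG) == pytest.approx(base, abs=1e-12)
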