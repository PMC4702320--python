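import math

import numpy as np
import pytest

from sspred import (
    AlignedMotifSet,
    SaeClassifier,
    dsae,
    estimate_threshold,
    fit_conditionals,
    fit_sae,
    predict,
    sae_position,
    sae_total,
)
from sspred.sae import _crossing

from conftest import BASES, random_motifs


def brute_conditionals(motifs):
    """p(s_i | t_j) = n_ij(s,t) / n_j(t) by explicit loops."""
    P = len(motifs[0])
    out = {}
    for i in range(P):
        for j in range(P):
            if i == j:
                continue
            for s in BASES:
                for t in BASES:
                    nj = sum(m[j] == t for m in motifs)
                    nij = sum(m[i] == s and m[j] == t for m in motifs)
                    out[(i, j, s, t)] = nij / nj if nj else None
    return out


class TestFitConditionals:
    def test_single_motif(self):
        m = fit_conditionals(AlignedMotifSet(("AT",)), pseudocount=0.5)
        # with one AT motif and alpha=0.5: p(A_1|T_2) = (1+0.5)/(1+2) = 0.5
        assert m.cond[0, 1, 0, 1] == pytest.approx(1.5 / 3)

    def test_two_motifs_exact_ratio(self):
        m = fit_conditionals(AlignedMotifSet(("AT", "GT")), pseudocount=0.5)
        # p(A_1|T_2) at alpha=0: 1/2; smoothing pulls toward 1/4
        assert m.cond[0, 1, 0, 1] == pytest.approx(1.5 / 4)

    def test_alpha_zero_matches_bruteforce(self, rng):
        mset = random_motifs(rng, 50, 9)
        m = fit_conditionals(mset, pseudocount=0.0)
        oracle = brute_conditionals(mset.motifs)
        for (i, j, s, t), v in oracle.items():
            got = m.cond[i, j, BASES.index(s), BASES.index(t)]
            assert got == pytest.approx(v)

    def test_alpha_zero_unseen_base_errors(self):
        with pytest.raises(ValueError, match="pseudocount > 0"):
            fit_conditionals(AlignedMotifSet(("AT", "AT")), pseudocount=0.0)

    def test_normalization_any_alpha(self, rng):
        mset = random_motifs(rng, 30, 5)
        for alpha in (0.0, 0.5, 2.0):
            m = fit_conditionals(mset, pseudocount=alpha)
            sums = np.nansum(m.cond, axis=2)  # sum over s
            off = sums[~np.eye(5, dtype=bool)]
            assert np.allclose(off, 1.0)

    def test_negative_pseudocount_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_conditionals(random_motifs(rng, 5, 3), pseudocount=-1)


class TestSaeValues:
    def test_perfectly_predictable_motif_scores_zero(self):
        # training set of identical motifs: every conditional for that motif is 1
        m = fit_conditionals(AlignedMotifSet(("ATG",) * 4), pseudocount=0.5)
        # smoothing keeps it near 0; exact 0 requires alpha=0 which errors on
        # the unseen bases, so check the alpha->0 limit with a complete set
        full = AlignedMotifSet(("AAA", "TTT", "GGG", "CCC"))
        m0 = fit_conditionals(full, pseudocount=0.0)
        assert sae_total(m0, "AAA") == pytest.approx(0.0)

    def test_never_predictable_motif_hits_upper_bound(self):
        # "AAA" conditionals are all 0 under a model trained without A co-occurrences
        full = AlignedMotifSet(("AAA", "TTT", "GGG", "CCC"))
        m0 = fit_conditionals(full, pseudocount=0.0)
        # ATG: p(A_1|T_2)=0, p(A_1|G_3)=0, etc -> every term 1-p = 1
        P = 3
        assert sae_total(m0, "ATG") == pytest.approx(2 * P * (P - 1))

    def test_position_value_matches_term_enumeration(self, rng):
        train = AlignedMotifSet(("ATG", "AGG", "TTC"))
        m = fit_conditionals(train, pseudocount=0.5)
        seq = "ATG"
        oracle = {}
        for i in range(3):
            total = 0.0
            for j in range(3):
                if j == i:
                    continue
                njt = sum(x[j] == seq[j] for x in train.motifs)
                nij = sum(x[i] == seq[i] and x[j] == seq[j] for x in train.motifs)
                p = (nij + 0.5) / (njt + 2.0)
                total += 2 * (1 - p)
            oracle[i] = total
        for i in range(3):
            assert sae_position(m, seq, i) == pytest.approx(oracle[i])

    def test_total_is_sum_of_positions(self, rng):
        mset = random_motifs(rng, 40, 6)
        m = fit_conditionals(mset, pseudocount=0.5)
        for seq in random_motifs(rng, 5, 6):
            parts = sum(sae_position(m, seq, i) for i in range(6))
            assert sae_total(m, seq) == pytest.approx(parts)

    def test_total_matches_closed_form(self, rng):
        """SAE_ap == 2P(P-1) - 2 * sum of table lookups, computed independently."""
        mset = random_motifs(rng, 40, 5)
        m = fit_conditionals(mset, pseudocount=0.5)
        seq = mset.motifs[0]
        lookup_sum = 0.0
        for i in range(5):
            for j in range(5):
                if i != j:
                    lookup_sum += m.cond[
                        i, j, BASES.index(seq[i]), BASES.index(seq[j])
                    ]
        assert sae_total(m, seq) == pytest.approx(2 * 5 * 4 - 2 * lookup_sum)

    def test_bounds_on_random_inputs(self, rng):
        mset = random_motifs(rng, 60, 7)
        m = fit_conditionals(mset, pseudocount=0.5)
        for seq in random_motifs(rng, 20, 7):
            v = sae_total(m, seq)
            assert 0.0 <= v <= 2 * 7 * 6

    def test_wrong_length_rejected(self, rng):
        m = fit_conditionals(random_motifs(rng, 10, 4), pseudocount=0.5)
        with pytest.raises(ValueError):
            sae_total(m, "AAA")


class TestDsaeAndPredict:
    def test_identical_models_give_zero(self, rng):
        mset = random_motifs(rng, 30, 5)
        X = list(mset.motifs) * 2
        y = ["TSS"] * 30 + ["FSS"] * 30
        clf = SaeClassifier(pseudocount=0.5, epsilon=0.0).fit(X, y)
        for seq in random_motifs(rng, 10, 5):
            assert dsae(clf, seq) == pytest.approx(0.0)

    def test_identical_models_with_negative_epsilon_predict_fss(self, rng):
        mset = random_motifs(rng, 30, 5)
        X = list(mset.motifs) * 2
        y = ["TSS"] * 30 + ["FSS"] * 30
        clf = SaeClassifier(pseudocount=0.5, epsilon=-1.0).fit(X, y)
        label, score = predict(clf, mset.motifs[0])
        assert label == "FSS"

    def test_boundary_dsae_equal_epsilon_is_fss(self, rng):
        mset = random_motifs(rng, 30, 5)
        tss, fss = random_motifs(rng, 30, 5), random_motifs(rng, 30, 5)
        clf = fit_sae(tss, fss, pseudocount=0.5, epsilon=0.0)
        seq = mset.motifs[0]
        d = dsae(clf, seq)
        clf2 = fit_sae(tss, fss, pseudocount=0.5, epsilon=d)
        assert predict(clf2, seq)[0] == "FSS"
        clf3 = fit_sae(tss, fss, pseudocount=0.5, epsilon=d + 1e-9)
        assert predict(clf3, seq)[0] == "TSS"

    def test_extreme_dsae_for_fully_separated_models(self):
        tss = AlignedMotifSet(("AAA", "TTT", "GGG", "CCC"))
        fss = AlignedMotifSet(("ATG", "TGC", "GCA", "CAT"))
        clf = fit_sae(tss, fss, epsilon=0.0)  # alpha=0, complete columns
        # "AAA": all TSS conditionals 1 -> SAE^T = 0; all FSS conditionals 0
        # -> SAE^F = 2P(P-1) -> dSAE = -2P(P-1)
        assert dsae(clf, "AAA") == pytest.approx(-2 * 3 * 2)

    def test_model_swap_negates_dsae(self, rng):
        tss, fss = random_motifs(rng, 25, 4), random_motifs(rng, 25, 4)
        a = fit_sae(tss, fss, pseudocount=0.5, epsilon=0.0)
        b = fit_sae(fss, tss, pseudocount=0.5, epsilon=0.0)
        for seq in random_motifs(rng, 10, 4):
            assert dsae(a, seq) == pytest.approx(-dsae(b, seq))

    def test_labels_consistent_with_sign_test(self, rng):
        tss, fss = random_motifs(rng, 25, 4), random_motifs(rng, 25, 4)
        clf = fit_sae(tss, fss, pseudocount=0.5, epsilon=0.3)
        seqs = list(random_motifs(rng, 30, 4))
        d = clf.dsae(seqs)
        labels = clf.predict(seqs)
        assert all(
            (lab == "TSS") == (v < 0.3) for lab, v in zip(labels, d)
        )

    def test_score_is_negated_dsae(self, rng):
        tss, fss = random_motifs(rng, 25, 4), random_motifs(rng, 25, 4)
        clf = fit_sae(tss, fss, pseudocount=0.5, epsilon=0.0)
        seqs = list(random_motifs(rng, 10, 4))
        assert np.allclose(clf.decision_function(seqs), -clf.dsae(seqs))

    def test_unfitted_errors(self):
        with pytest.raises(ValueError, match="not fitted"):
            SaeClassifier().predict(["AAAA"])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        tss, fss = random_motifs(rng, 30, 5), random_motifs(rng, 30, 5)
        clf = fit_sae(tss, fss, pseudocount=0.5, epsilon=-2.5)
        path = tmp_path / "model.json"
        clf.save(path)
        back = SaeClassifier.load(path)
        seqs = list(random_motifs(rng, 10, 5))
        assert np.allclose(back.dsae(seqs), clf.dsae(seqs))
        assert back.epsilon_ == clf.epsilon_
        assert list(back.predict(seqs)) == list(clf.predict(seqs))

    def test_rejects_foreign_json(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text("{}")
        with pytest.raises(ValueError, match="not an sspred"):
            SaeClassifier.load(p)


class TestThresholdEstimation:
    def test_symmetric_separation_gives_midpoint_zero(self):
        d_t = np.full(7, -10.0)
        d_f = np.full(7, 10.0)
        assert _crossing(d_t, d_f) == pytest.approx(0.0)

    def test_crossing_matches_fine_grid_oracle(self, rng):
        d_t = rng.normal(-2, 1.5, size=20)
        d_f = rng.normal(2, 1.5, size=20)
        got = _crossing(d_t, d_f)
        grid = np.linspace(min(d_t.min(), d_f.min()) - 1,
                           max(d_t.max(), d_f.max()) + 1, 200001)
        sens = np.mean(d_t[None, :] < grid[:, None], axis=1)
        spec = np.mean(d_f[None, :] >= grid[:, None], axis=1)
        diff = np.abs(sens - spec)
        best = grid[diff == diff.min()]
        # the optimal region is an interval; our candidate is its midpoint
        assert best.min() <= got <= best.max()
        assert got == pytest.approx((best.min() + best.max()) / 2, abs=0.01)

    def test_reproducible_from_seed(self, donor_sets):
        tss, fss = donor_sets
        a = estimate_threshold(tss, fss, seed=7, pseudocount=0.5)
        b = estimate_threshold(tss, fss, seed=7, pseudocount=0.5)
        assert a.per_fold == b.per_fold and a.epsilon == b.epsilon

    def test_epsilon_is_mean_of_folds(self, donor_sets):
        tss, fss = donor_sets
        est = estimate_threshold(tss, fss, seed=3, pseudocount=0.5)
        assert len(est.per_fold) == 10
        assert est.epsilon == pytest.approx(np.mean(est.per_fold))

    def test_class_swap_negates_crossing(self, rng):
        d_t = rng.normal(-1, 1, size=15)
        d_f = rng.normal(1, 1, size=15)
        assert _crossing(d_t, d_f) == pytest.approx(-_crossing(-d_f, -d_t))

    def test_too_few_motifs_per_fold_errors(self, rng):
        tss, fss = random_motifs(rng, 8, 4), random_motifs(rng, 8, 4)
        with pytest.raises(ValueError, match="fold"):
            estimate_threshold(tss, fss, k=10, seed=1, pseudocount=0.5)

    def test_skew_invariance_with_folds_fixed(self, rng):
        """With held-out scores fixed, duplicating every negative m-fold
        leaves the sensitivity=specificity crossing unchanged: both rates
        are class-conditional fractions."""
        d_t = rng.normal(-2, 1, size=25)
        d_f = rng.normal(2, 1, size=25)
        base = _crossing(d_t, d_f)
        for m in (2, 5, 8):
            assert _crossing(d_t, np.tile(d_f, m)) == pytest.approx(base)


class TestFitEstimatesEpsilon:
    def test_fit_with_epsilon_none_runs_procedure(self, donor_sets):
        tss, fss = donor_sets
        X = list(tss.motifs) + list(fss.motifs)
        y = ["TSS"] * tss.N + ["FSS"] * fss.N
        clf = SaeClassifier(pseudocount=0.5, random_state=11).fit(X, y)
        assert clf.threshold_estimate_ is not None
        assert clf.epsilon_ == pytest.approx(clf.threshold_estimate_.epsilon)
        # donor-like data separates: threshold is clearly negative
        assert clf.epsilon_ < 0

    def test_sklearn_params_round_trip(self):
        clf = SaeClassifier(pseudocount=0.5, epsilon=-1.0)
        params = clf.get_params()
        clone = SaeClassifier(**params)
        assert clone.get_params() == params
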