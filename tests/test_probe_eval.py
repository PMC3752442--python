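"""Decoding, CdA statistic, and repeated-measures statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sstats

import dualpath as dp
from dualpath.probe_eval import ProbeRecord


def make_record(target, d1, d2, word=True, k=0):
    return ProbeRecord(target, word, k, d1, d2)


class TestDecode:
    def test_exact_code_decodes_to_itself(self, tiny_corpus):
        inv = tiny_corpus.mora_inventory
        for m in inv:
            assert dp.decode_event(m.features.astype(float), inv) == m.id

    def test_tie_breaks_to_lowest_id(self):
        inv = dp.build_inventory(8, 8, seed=0)
        # equidistant between morae 3 and 7
        midpoint = (inv[3].features + inv[7].features) / 2
        assert dp.decode_event(midpoint, [inv[3], inv[7]]) == 3
        assert dp.decode_event(midpoint, [inv[7], inv[3]]) == 3

    def test_matches_brute_force_nearest_neighbor(self, tiny_corpus):
        inv = tiny_corpus.mora_inventory
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.random(tiny_corpus.feature_dim)
            dists = [(float(np.linalg.norm(v - m.features)), m.id) for m in inv]
            best = min(d for d, _ in dists)
            expected = min(i for d, i in dists if math.isclose(d, best))
            assert dp.decode_event(v, inv) == expected


class TestProbeDoubleRepetition:
    def test_record_count_51_items_5_probes(self, tiny_net, tiny_corpus):
        items = (tiny_corpus.train_words * 3)[:51]
        records = dp.probe_double_repetition(
            tiny_net, items, tiny_corpus.mora_inventory, 5, seed=0)
        assert len(records) == 255

    def test_seeded_determinism_with_noise(self, tiny_net, tiny_corpus):
        tiny_net.noise_sd["iSMG"] = 0.2
        a = dp.probe_double_repetition(
            tiny_net, tiny_corpus.probe_words, tiny_corpus.mora_inventory, 2, 7)
        b = dp.probe_double_repetition(
            tiny_net, tiny_corpus.probe_words, tiny_corpus.mora_inventory, 2, 7)
        assert a == b

    def test_noiseless_probes_identical_across_draws(self, tiny_net,
                                                     tiny_corpus):
        records = dp.probe_double_repetition(
            tiny_net, tiny_corpus.probe_words[:3],
            tiny_corpus.mora_inventory, 4, seed=0)
        by_item = {}
        for r in records:
            by_item.setdefault(r.item_ref, set()).add((r.decoded1, r.decoded2))
        assert all(len(v) == 1 for v in by_item.values())


class TestCdaRate:
    def test_arithmetic(self):
        tgt = (0, 1, 2)
        wrong, right = (1, 1, 2), tgt
        records = (
            [make_record(tgt, wrong, right, k=i) for i in range(3)]     # corrected
            + [make_record(tgt, wrong, wrong, k=i) for i in range(7)]   # not
            + [make_record(tgt, right, right, k=i) for i in range(5)]   # no error
        )
        res = dp.cda_rate(records)
        assert (res.n_first_errors, res.n_self_corrected) == (10, 3)
        assert res.rate == pytest.approx(0.3)

    def test_undefined_when_no_first_errors(self):
        tgt = (0, 1, 2)
        res = dp.cda_rate([make_record(tgt, tgt, tgt)])
        assert not res.defined and res.rate is None

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        tgt = (0, 1, 2)
        pool = [tgt, (1, 1, 2), (0, 1, 1), (2, 2, 2)]
        records = [
            make_record(tgt, pool[rng.integers(4)], pool[rng.integers(4)], k=i)
            for i in range(200)
        ]
        res = dp.cda_rate(records)
        n_err = sum(1 for r in records if r.decoded1 != tgt)
        n_fix = sum(1 for r in records if r.decoded1 != tgt and r.decoded2 == tgt)
        assert (res.n_first_errors, res.n_self_corrected) == (n_err, n_fix)
        assert 0.0 <= res.rate <= 1.0


class TestRepeatedMeasures:
    def test_equal_conditions_give_zero_F(self):
        a = [0.3, 0.4, 0.5]
        res = dp.repeated_measures_2level(a, a)
        assert res.F == 0.0 and res.cohen_d == 0.0

    def test_zero_variance_nonzero_mean_flags_infinite_F(self):
        res = dp.repeated_measures_2level([1, 2, 3, 4], [0, 1, 2, 3])
        assert res.infinite and res.p == 0.0

    def test_F_is_paired_t_squared(self):
        a, b = [0.3, 0.4, 0.5], [0.1, 0.2, 0.35]
        res = dp.repeated_measures_2level(a, b)
        # independent oracle: hand paired-t formula
        d = np.array(a) - np.array(b)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.F == pytest.approx(t_hand ** 2, rel=1e-12)
        assert res.df == (1, 2)
        # and against scipy's paired t implementation
        t_scipy = sstats.ttest_rel(a, b)
        assert res.F == pytest.approx(t_scipy.statistic ** 2, rel=1e-12)
        assert res.p == pytest.approx(t_scipy.pvalue, rel=1e-9)
        assert res.cohen_d == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-12)

    def test_identity_holds_on_random_samples(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            a, b = rng.random(n), rng.random(n)
            res = dp.repeated_measures_2level(a, b)
            t = sstats.ttest_rel(a, b)
            assert res.F == pytest.approx(t.statistic ** 2, rel=1e-9)
            assert res.p == pytest.approx(t.pvalue, rel=1e-6)


class TestInteraction:
    def test_identical_conditions_null(self):
        x = [0.2, 0.3, 0.4]
        res = dp.interaction_2x2(x, x, x, x)
        assert res.F == 0.0

    def test_equal_drops_null_interaction(self):
        # drops are exactly 0.25 per network in both lexicality conditions
        wp, wq = [0.5, 0.625, 0.75], [0.25, 0.375, 0.5]
        np_, nq = [0.5, 0.25, 0.75], [0.25, 0.0, 0.5]
        res = dp.interaction_2x2(wp, wq, np_, nq)
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_matches_double_difference_t_squared(self):
        rng = np.random.default_rng(4)
        wp, wq, np_, nq = (rng.random(6) for _ in range(4))
        res = dp.interaction_2x2(wp, wq, np_, nq)
        dd = (wp - wq) - (np_ - nq)
        t = sstats.ttest_1samp(dd, 0.0)
        assert res.F == pytest.approx(t.statistic ** 2, rel=1e-9)
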