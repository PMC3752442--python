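"""Network core: forward dynamics, BPTT gradients, masking contracts."""

import numpy as np
import pytest

import dualpath as dp
from dualpath.srn_core import (
    ArchitectureSpec,
    trial_loss,
    trial_loss_and_grads,
    _sigmoid,
)
from dualpath.task_schedule import TrialSpec


def chain_spec(n=1):
    """Single-unit chain In -> H -> Out with Elman context."""
    return ArchitectureSpec(
        layers={"In": n, "H": n, "Out": n},
        feedforward=(("In", "H"), ("H", "Out")),
        input_layers=("In",),
    )


class TestInit:
    def test_seed_determinism(self, tiny_net, tiny_corpus):
        arch = tiny_net.spec
        again = dp.init_network(arch, 42)
        for k in tiny_net.weights:
            assert np.array_equal(tiny_net.weights[k], again.weights[k])
        other = dp.init_network(arch, 43)
        assert any(not np.array_equal(tiny_net.weights[k], other.weights[k])
                   for k in tiny_net.weights)

    def test_intact_start(self, tiny_net):
        assert all(np.all(m == 1) for m in tiny_net.masks.values())
        assert all(sd == 0 for sd in tiny_net.noise_sd.values())
        assert all(np.all(np.abs(w) <= 0.1) for w in tiny_net.weights.values())

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(layers={"A": 2, "B": 2},
                             feedforward=(("B", "A"),), input_layers=("A",))


class TestForward:
    def test_zero_weights_give_half(self, tiny_net, tiny_corpus):
        for k in tiny_net.weights:
            tiny_net.weights[k][:] = 0
        for k in tiny_net.biases:
            tiny_net.biases[k][:] = 0
        trial = dp.make_repetition(tiny_corpus.train_words[0],
                                   tiny_corpus.mora_inventory)
        acts = dp.forward_trial(tiny_net, trial)
        for l in tiny_net.spec.computed_layers:
            assert np.allclose(acts[l], 0.5)

    def test_noiseless_forward_is_deterministic(self, tiny_net, tiny_corpus):
        trial = dp.make_cda(tiny_corpus.train_words[0],
                            tiny_corpus.mora_inventory)
        a = dp.forward_trial(tiny_net, trial)
        b = dp.forward_trial(tiny_net, trial)
        for l in a:
            assert np.array_equal(a[l], b[l])

    def test_hand_computed_chain(self):
        """Pencil-and-paper two-event forward pass on a 1-unit chain."""
        net = dp.init_network(chain_spec(), 0)
        w_ih, w_ho = 0.7, -0.4
        r_h, r_o = 0.3, 0.2
        b_h, b_o = 0.05, -0.1
        net.weights["In->H"][:] = w_ih
        net.weights["H->Out"][:] = w_ho
        net.weights["rec:H"][:] = r_h
        net.weights["rec:Out"][:] = r_o
        net.biases["H"][:] = b_h
        net.biases["Out"][:] = b_o
        x1, x2 = 1.0, 0.0
        trial = TrialSpec("repetition", 2,
                          {"In": {1: np.array([x1]), 2: np.array([x2])}},
                          {}, (0, 0, 0))
        acts = dp.forward_trial(net, trial)

        def sig(v):
            return 1 / (1 + np.exp(-v))

        h1 = sig(w_ih * x1 + r_h * 0.5 + b_h)
        o1 = sig(w_ho * h1 + r_o * 0.5 + b_o)
        h2 = sig(w_ih * x2 + r_h * h1 + b_h)
        o2 = sig(w_ho * h2 + r_o * o1 + b_o)
        assert acts["H"][0, 0] == pytest.approx(h1, abs=1e-12)
        assert acts["Out"][0, 0] == pytest.approx(o1, abs=1e-12)
        assert acts["H"][1, 0] == pytest.approx(h2, abs=1e-12)
        assert acts["Out"][1, 0] == pytest.approx(o2, abs=1e-12)

    def test_noise_requires_rng_and_is_seeded(self, tiny_net, tiny_corpus):
        tiny_net.noise_sd["iSMG"] = 0.2
        trial = dp.make_repetition(tiny_corpus.train_words[0],
                                   tiny_corpus.mora_inventory)
        with pytest.raises(ValueError):
            dp.forward_trial(tiny_net, trial)
        a = dp.forward_trial(tiny_net, trial, np.random.default_rng(5))
        b = dp.forward_trial(tiny_net, trial, np.random.default_rng(5))
        for l in a:
            assert np.array_equal(a[l], b[l])
        assert np.all(a["iSMG"] >= 0) and np.all(a["iSMG"] <= 1)


def _numeric_check(net, trial, n_samples=5, h=1e-5, tol=1e-4):
    """Central-difference gradient check with an absolute floor so that
    finite-difference roundoff on near-zero entries does not dominate."""
    loss, g_w, g_b = trial_loss_and_grads(net, trial)
    rng = np.random.default_rng(0)
    entries = [(net.weights[k], g_w[k]) for k in g_w]
    entries += [(net.biases[k], g_b[k]) for k in g_b]
    for arr, g in entries:
        for _ in range(n_samples):
            idx = tuple(rng.integers(s) for s in arr.shape)
            orig = arr[idx]
            arr[idx] = orig + h
            lp = trial_loss(net, trial)
            arr[idx] = orig - h
            lm = trial_loss(net, trial)
            arr[idx] = orig
            num = (lp - lm) / (2 * h)
            denom = max(abs(num), abs(g[idx]), 1e-3)
            assert abs(num - g[idx]) / denom < tol, (idx, num, g[idx])


class TestGradients:
    @pytest.mark.parametrize("task", ["repetition", "cda", "comprehension",
                                      "speaking"])
    def test_bptt_matches_finite_differences(self, tiny_corpus, task):
        """Analytic BPTT gradient agrees with central differences through
        recurrent context, within-event depth, clamps and event masks."""
        arch = dp.dual_pathway_architecture(
            tiny_corpus.feature_dim, tiny_corpus.semantic_dim, 5, 4)
        net = dp.init_network(arch, 7)
        item = tiny_corpus.train_words[0]
        inv = tiny_corpus.mora_inventory
        if task == "comprehension":
            trial = dp.make_comprehension(item, inv, "recovery")
        else:
            trial = getattr(dp, f"make_{task}")(item, inv)
        _numeric_check(net, trial)

    def test_two_unit_two_event_toy_net(self):
        """The minimal recurrent case: 2-unit chain over 2 events."""
        net = dp.init_network(chain_spec(2), 3)
        trial = TrialSpec(
            "repetition", 2,
            {"In": {1: np.array([1.0, 0.0]), 2: np.array([0.0, 1.0])}},
            {"Out": {1: np.array([1.0, 0.0]), 2: np.array([0.0, 1.0])}},
            (0, 0, 0))
        _numeric_check(net, trial, n_samples=8)

    def test_loss_reads_only_target_events(self, tiny_corpus):
        """The loss is the cross-entropy recounted over exactly the defined
        (layer, event) targets — free-running events contribute nothing."""
        arch = dp.dual_pathway_architecture(
            tiny_corpus.feature_dim, tiny_corpus.semantic_dim, 5, 4)
        net = dp.init_network(arch, 9)
        item = tiny_corpus.train_words[1]
        trial = dp.make_cda(item, tiny_corpus.mora_inventory)
        assert set(trial.targets["SpeechMotor"]) == {7, 8, 9}
        acts = dp.forward_trial(net, trial)
        expected = 0.0
        for layer, events in trial.targets.items():
            for ev, y in events.items():
                a = np.clip(acts[layer][ev - 1], 1e-7, 1 - 1e-7)
                expected -= np.sum(y * np.log(a) + (1 - y) * np.log(1 - a))
        assert trial_loss(net, trial) == pytest.approx(expected, rel=1e-12)


class TestTraining:
    def test_zero_lr_only_decays(self, tiny_net, tiny_corpus):
        before = {k: v.copy() for k, v in tiny_net.weights.items()}
        trials = dp.build_epoch(tiny_corpus, "development", 0)[:10]
        cfg = dp.TrainingConfig(learning_rate=0.0, weight_decay=1e-3)
        dp.train_epoch(tiny_net, trials, cfg, seed=0)
        factor = (1 - 1e-3) ** len(trials)
        for k in before:
            assert np.allclose(tiny_net.weights[k], before[k] * factor,
                               rtol=1e-12)

    def test_masked_weights_stay_zero_through_training(self, tiny_net,
                                                       tiny_corpus):
        k = "iSMG->SpeechMotor"
        tiny_net.masks[k].ravel()[:20] = 0
        tiny_net.weights[k].ravel()[:20] = 0
        trials = dp.build_epoch(tiny_corpus, "development", 0)
        cfg = dp.TrainingConfig(0.2, 1e-7)
        for ep in range(3):
            dp.train_epoch(tiny_net, trials, cfg, seed=ep)
        assert np.all(tiny_net.weights[k].ravel()[:20] == 0)

    def test_trial_order_seeded_but_multiset_fixed(self, tiny_corpus):
        trials = dp.build_epoch(tiny_corpus, "development", 0)
        assert dp.build_epoch(tiny_corpus, "development", 0) is not trials
        t1 = [t.item_ref + (t.task,) for t in
              dp.build_epoch(tiny_corpus, "development", 1)]
        t2 = [t.item_ref + (t.task,) for t in
              dp.build_epoch(tiny_corpus, "development", 2)]
        assert t1 != t2
        assert sorted(t1) == sorted(t2)


class TestCheckpoint:
    def test_roundtrip_is_exact(self, tiny_net, tmp_path):
        tiny_net.noise_sd["iSMG"] = 0.2
        tiny_net.masks["iSMG->SpeechMotor"].ravel()[:5] = 0
        tiny_net.epoch = 17
        p = tmp_path / "net.h5"
        dp.save_checkpoint(tiny_net, p)
        back = dp.load_checkpoint(p)
        assert back.spec == tiny_net.spec
        assert back.epoch == 17
        assert back.noise_sd == tiny_net.noise_sd
        for k in tiny_net.weights:
            assert np.array_equal(back.weights[k], tiny_net.weights[k])
            assert np.array_equal(back.masks[k], tiny_net.masks[k])
        for k in tiny_net.biases:
            assert np.array_equal(back.biases[k], tiny_net.biases[k])


def test_learning_reaches_high_repetition_accuracy():
    """Development schedule on a 10-word toy corpus reaches >=95% repetition
    accuracy within 200 epochs (smoke check that the model family learns)."""
    from dualpath.pipeline import evaluate_tasks

    corpus = dp.generate_corpus(n_morae=10, n_words=10, n_probe_words=10,
                                n_nonwords=0, seed=5)
    net = dp.init_network(
        dp.dual_pathway_architecture(corpus.feature_dim, corpus.semantic_dim),
        0)
    cfg = dp.TrainingConfig(0.1, 1e-7, 200, 5)
    for ep in range(200):
        trials = dp.build_epoch(corpus, "development", ep)
        net, _ = dp.train_epoch(net, trials, cfg, 1000 + ep)
    acc = evaluate_tasks(net, corpus, 1, 0)
    assert acc["repetition"] >= 0.95
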