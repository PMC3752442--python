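"""Simple-recurrent (Elman) network over discrete time events.

The architecture is a layered graph with feedforward connections and a
per-layer Elman context: every computed layer receives a trainable recurrent
projection from its own previous-event activation.  The canonical
dual-pathway instance has a dorsal route Auditory -> iSMG -> SpeechMotor and
a ventral route Auditory -> aSTG_STS -> vATL -> SpeechMotor; vATL doubles as
the semantic input/output layer (clamped during speaking, supervised during
comprehension).

Activation flows through the whole depth within one time event (input layers
first, then computed layers in topological order), so a target can co-occur
with its input at the same event.  Units are logistic sigmoid; optional
Gaussian output noise (the lesion model's cortical-damage proxy) is added to
unit outputs independently at every event and the result clipped to [0, 1].
Training is online backpropagation through time with cross-entropy loss
summed over only the (layer, event) pairs where the trial defines a target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from dualpath.task_schedule import TrialSpec

__all__ = [
    "ArchitectureSpec",
    "NetworkState",
    "TrainingConfig",
    "dual_pathway_architecture",
    "init_network",
    "forward_trial",
    "trial_loss",
    "trial_loss_and_grads",
    "train_epoch",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7          # cross-entropy clamp
_CONTEXT_INIT = 0.5  # neutral sigmoid resting state at event 1
_INIT_RANGE = 0.1    # uniform weight-initialization half-range


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer sizes plus the feedforward graph; every non-input layer also
    carries an implicit self-recurrent (Elman context) connection."""

    layers: dict[str, int]
    feedforward: tuple[tuple[str, str], ...]
    input_layers: tuple[str, ...]

    def __post_init__(self):
        for s, t in self.feedforward:
            if s not in self.layers or t not in self.layers:
                raise ValueError(f"connection {s}->{t} references unknown layer")
            if t in self.input_layers:
                raise ValueError(f"input layer {t} cannot receive connections")
        targets = {t for _, t in self.feedforward}
        for l in self.layers:
            if l not in self.input_layers and l not in targets:
                raise ValueError(f"layer {l} is unreachable")

    @property
    def computed_layers(self) -> tuple[str, ...]:
        """Non-input layers in topological (activation-flow) order."""
        order: list[str] = []
        pending = {l for l in self.layers if l not in self.input_layers}
        resolved = set(self.input_layers)
        while pending:
            ready = sorted(
                l for l in pending
                if all(s in resolved for s, t in self.feedforward if t == l)
            )
            if not ready:
                raise ValueError("feedforward graph has a cycle")
            for l in ready:
                order.append(l)
                resolved.add(l)
                pending.discard(l)
        return tuple(order)

    def incoming(self, layer: str) -> list[str]:
        return [s for s, t in self.feedforward if t == layer]


def dual_pathway_architecture(n_phon: int, n_sem: int, n_ismg: int = 100,
                              n_astg: int = 45,
                              cross_link: bool = True) -> ArchitectureSpec:
    """The dual-pathway instance: dorsal Auditory->iSMG->SpeechMotor and
    ventral Auditory->aSTG_STS->vATL->SpeechMotor.  vATL width equals the
    semantic dimensionality; Auditory and SpeechMotor share the mora feature
    dimensionality.

    ``cross_link`` adds a vATL->iSMG projection, the point where ventral
    (semantic) activation can interact with the dorsal route below the motor
    output.  It gives the dorsal hidden layer signal during speaking (where
    nothing auditory drives it) and is the default: without it, production
    from meaning is disproportionately fragile to dorsal noise damage.
    """
    ff = [("Auditory", "iSMG"), ("iSMG", "SpeechMotor"),
          ("Auditory", "aSTG_STS"), ("aSTG_STS", "vATL"),
          ("vATL", "SpeechMotor")]
    if cross_link:
        ff.append(("vATL", "iSMG"))
    return ArchitectureSpec(
        layers={"Auditory": n_phon, "iSMG": n_ismg, "aSTG_STS": n_astg,
                "vATL": n_sem, "SpeechMotor": n_phon},
        feedforward=tuple(ff),
        input_layers=("Auditory",),
    )


def _ff_key(src: str, tgt: str) -> str:
    return f"{src}->{tgt}"


def _rec_key(layer: str) -> str:
    return f"rec:{layer}"


@dataclass
class NetworkState:
    """Weights, structural-lesion masks, per-layer output-noise levels."""

    spec: ArchitectureSpec
    weights: dict[str, np.ndarray]   # ff key "s->t" and recurrent key "rec:l"
    biases: dict[str, np.ndarray]    # per computed layer
    masks: dict[str, np.ndarray]     # same keys as weights; 0 = lesioned
    noise_sd: dict[str, float]       # per computed layer
    seed: int
    epoch: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            spec=self.spec,
            weights={k: v.copy() for k, v in self.weights.items()},
            biases={k: v.copy() for k, v in self.biases.items()},
            masks={k: v.copy() for k, v in self.masks.items()},
            noise_sd=dict(self.noise_sd),
            seed=self.seed,
            epoch=self.epoch,
        )

    def connection_keys(self) -> list[str]:
        keys = [_ff_key(s, t) for s, t in self.spec.feedforward]
        keys += [_rec_key(l) for l in self.spec.computed_layers]
        return keys

    def incoming_keys(self, layer: str) -> list[str]:
        """All weight-matrix keys targeting ``layer`` (feedforward and the
        Elman self-recurrence)."""
        keys = [_ff_key(s, layer) for s in self.spec.incoming(layer)]
        keys.append(_rec_key(layer))
        return keys


def init_network(spec: ArchitectureSpec, seed: int) -> NetworkState:
    """Initialize weights uniform in [-0.1, 0.1]; masks all 1; noise 0."""
    rng = np.random.default_rng(seed)
    weights: dict[str, np.ndarray] = {}
    biases: dict[str, np.ndarray] = {}
    for s, t in spec.feedforward:
        weights[_ff_key(s, t)] = rng.uniform(
            -_INIT_RANGE, _INIT_RANGE, size=(spec.layers[s], spec.layers[t]))
    for l in spec.computed_layers:
        weights[_rec_key(l)] = rng.uniform(
            -_INIT_RANGE, _INIT_RANGE, size=(spec.layers[l], spec.layers[l]))
        biases[l] = rng.uniform(-_INIT_RANGE, _INIT_RANGE, size=spec.layers[l])
    masks = {k: np.ones_like(v) for k, v in weights.items()}
    noise = {l: 0.0 for l in spec.computed_layers}
    return NetworkState(spec, weights, biases, masks, noise, seed)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _run_forward(net: NetworkState, trial: TrialSpec,
                 rng: np.random.Generator | None):
    """Forward pass caching everything the backward pass needs."""
    spec = net.spec
    T = trial.n_events
    order = spec.computed_layers
    acts: dict[str, np.ndarray] = {
        l: np.empty((T, n)) for l, n in spec.layers.items()}
    pre: dict[str, np.ndarray] = {l: np.empty((T, spec.layers[l]))
                                  for l in order}
    clip_ok: dict[str, np.ndarray] = {l: np.ones((T, spec.layers[l]), bool)
                                      for l in order}
    clamped: dict[str, np.ndarray] = {l: np.zeros(T, bool) for l in order}

    needs_noise = any(sd > 0 for sd in net.noise_sd.values())
    if needs_noise and rng is None:
        raise ValueError("network has output noise; an rng is required")

    for t in range(T):
        ev = t + 1
        for l in spec.input_layers:
            clamp = trial.inputs.get(l, {}).get(ev)
            acts[l][t] = clamp if clamp is not None else 0.0
        for l in order:
            clamp = trial.inputs.get(l, {}).get(ev)
            if clamp is not None:
                acts[l][t] = clamp
                clamped[l][t] = True
                continue
            x = net.biases[l].copy()
            for s in spec.incoming(l):
                x += acts[s][t] @ net.weights[_ff_key(s, l)]
            prev = acts[l][t - 1] if t > 0 else np.full(
                spec.layers[l], _CONTEXT_INIT)
            x += prev @ net.weights[_rec_key(l)]
            z = _sigmoid(x)
            pre[l][t] = z
            sd = net.noise_sd.get(l, 0.0)
            if sd > 0:
                raw = z + rng.normal(0.0, sd, size=z.shape)
                clip_ok[l][t] = (raw > 0.0) & (raw < 1.0)
                acts[l][t] = np.clip(raw, 0.0, 1.0)
            else:
                acts[l][t] = z
    return acts, pre, clip_ok, clamped


def forward_trial(net: NetworkState, trial: TrialSpec,
                  rng: np.random.Generator | None = None
                  ) -> dict[str, np.ndarray]:
    """Run one trial; returns per-layer activation arrays of shape
    (n_events, layer_size).  With all noise levels at 0 the result is a pure
    function of (weights, trial)."""
    acts, *_ = _run_forward(net, trial, rng)
    return acts

def _loss_terms(acts, trial):
    total = 0.0
    for l, events in trial.targets.items():
        for ev, y in events.items():
            a = np.clip(acts[l][ev - 1], _EPS, 1.0 - _EPS)
            total -= float(np.sum(y * np.log(a) + (1 - y) * np.log(1 - a)))
    return total


def trial_loss(net: NetworkState, trial: TrialSpec,
               rng: np.random.Generator | None = None) -> float:
    """Cross-entropy loss summed over the trial's target (layer, event) pairs."""
    acts, *_ = _run_forward(net, trial, rng)
    return _loss_terms(acts, trial)


def trial_loss_and_grads(net: NetworkState, trial: TrialSpec,
                         rng: np.random.Generator | None = None):
    """Loss plus gradients w.r.t. every weight matrix and bias (BPTT across
    the whole trial, through the within-event depth, the Elman context, and
    the event mask)."""
    spec = net.spec
    T = trial.n_events
    order = spec.computed_layers
    acts, pre, clip_ok, clamped = _run_forward(net, trial, rng)
    loss = _loss_terms(acts, trial)

    g_w = {k: np.zeros_like(v) for k, v in net.weights.items()}
    g_b = {k: np.zeros_like(v) for k, v in net.biases.items()}
    d_act = {l: np.zeros((T, spec.layers[l])) for l in order}

    for t in range(T - 1, -1, -1):
        ev = t + 1
        for l in reversed(order):
            da = d_act[l][t]
            y = trial.targets.get(l, {}).get(ev)
            if clamped[l][t] or (y is None and not np.any(da)):
                continue
            z = pre[l][t]
            dnet = da * clip_ok[l][t] * z * (1.0 - z)
            if y is not None:
                # sigmoid/cross-entropy cancellation at the supervised unit:
                # exact when the output is the raw sigmoid, and a bounded
                # error signal when output noise has shifted it
                dnet = dnet + (acts[l][t] - y)
            g_b[l] += dnet
            rk = _rec_key(l)
            prev = acts[l][t - 1] if t > 0 else np.full(
                spec.layers[l], _CONTEXT_INIT)
            g_w[rk] += np.outer(prev, dnet)
            if t > 0:
                d_act[l][t - 1] += net.weights[rk] @ dnet
            for s in spec.incoming(l):
                fk = _ff_key(s, l)
                g_w[fk] += np.outer(acts[s][t], dnet)
                if s in d_act and not clamped.get(s, np.zeros(T, bool))[t]:
                    d_act[s][t] += net.weights[fk] @ dnet
    return loss, g_w, g_b


@dataclass
class TrainingConfig:
    """Learning rate, multiplicative weight decay, epoch budget.

    ``max_grad_norm`` rescales each trial's gradient to at most that global
    L2 norm before the update — a stability guard for the large summed
    cross-entropy errors that long multi-event targets produce.
    ``momentum`` is classical heavy-ball momentum on the per-trial updates.
    """

    learning_rate: float = 0.1
    weight_decay: float = 1e-7
    epochs: int = 20
    eval_interval: int = 5
    max_grad_norm: float = 10.0
    momentum: float = 0.0


def train_epoch(net: NetworkState, trials: list[TrialSpec],
                cfg: TrainingConfig, seed: int) -> tuple[NetworkState, float]:
    """One epoch of online training: trials visited in seeded random order,
    per-trial gradient step (lr * grad) followed by multiplicative weight
    decay.  Structurally lesioned (masked) weights stay exactly 0; output
    noise, if any, is sampled per trial from the same seeded stream.

    Mutates ``net`` in place and returns it with the mean per-trial loss.
    """
    if not trials:
        raise ValueError("empty trial list")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    lr = cfg.learning_rate
    decay = 1.0 - cfg.weight_decay
    total = 0.0
    v_w = {k: np.zeros_like(w) for k, w in net.weights.items()}
    v_b = {k: np.zeros_like(b) for k, b in net.biases.items()}
    for i in order:
        trial = trials[i]
        loss, g_w, g_b = trial_loss_and_grads(net, trial, rng)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss on {trial.task} trial {trial.item_ref}")
        total += loss
        if cfg.max_grad_norm:
            norm = np.sqrt(sum(float(np.sum(g * g)) for g in g_w.values())
                           + sum(float(np.sum(g * g)) for g in g_b.values()))
            if norm > cfg.max_grad_norm:
                scale = cfg.max_grad_norm / norm
                for g in g_w.values():
                    g *= scale
                for g in g_b.values():
                    g *= scale
        if lr != 0.0:
            for k, g in g_w.items():
                v = v_w[k]
                v *= cfg.momentum
                v += g
                w = net.weights[k]
                w -= lr * v
                if decay != 1.0:
                    w *= decay
                np.multiply(w, net.masks[k], out=w)
            for k, g in g_b.items():
                v = v_b[k]
                v *= cfg.momentum
                v += g
                net.biases[k] -= lr * v
        elif decay != 1.0:
            for k in net.weights:
                net.weights[k] *= decay
                np.multiply(net.weights[k], net.masks[k], out=net.weights[k])
    net.epoch += 1
    return net, total / len(trials)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(net: NetworkState, path) -> None:
    """Write a self-describing HDF5 checkpoint (exact round trip)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["spec"] = json.dumps({
            "layers": net.spec.layers,
            "feedforward": list(map(list, net.spec.feedforward)),
            "input_layers": list(net.spec.input_layers),
        })
        fh.attrs["seed"] = net.seed
        fh.attrs["epoch"] = net.epoch
        fh.attrs["noise_sd"] = json.dumps(net.noise_sd)
        for grp, mats in (("weights", net.weights), ("masks", net.masks),
                          ("biases", net.biases)):
            g = fh.create_group(grp)
            for k, v in mats.items():
                g.create_dataset(k, data=v)


def load_checkpoint(path) -> NetworkState:
    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs["spec"])
        spec = ArchitectureSpec(
            layers=meta["layers"],
            feedforward=tuple(tuple(c) for c in meta["feedforward"]),
            input_layers=tuple(meta["input_layers"]),
        )
        weights = {k: fh["weights"][k][...] for k in fh["weights"]}
        masks = {k: fh["masks"][k][...] for k in fh["masks"]}
        biases = {k: fh["biases"][k][...] for k in fh["biases"]}
        noise = json.loads(fh.attrs["noise_sd"])
        return NetworkState(spec, weights, biases, masks, noise,
                            int(fh.attrs["seed"]), int(fh.attrs["epoch"]))
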