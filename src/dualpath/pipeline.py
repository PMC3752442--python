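"""End-to-end experiment orchestration.

The full protocol per replicate network: (1) development — train the intact
network on repetition/comprehension/speaking for the development epoch
budget; (2) dorsal lesion — remove 20% of iSMG->SpeechMotor links and add
output noise SD 0.2 to iSMG, producing conduction aphasia; (3) recovery —
retrain on the four-task schedule (adding the conduite d'approche trial and
the extended comprehension target) for 20 epochs, probing double repetition
on the word and nonword sets every 5 epochs; (4) diagnostic sweep — probe
again under each of the 20 independent ventral-damage severity levels.
Replicates differ only in their derived seeds (initial weights, lesion
draws, noise realizations); the statistics treat networks as subjects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dualpath import lexigen
from dualpath.lexigen import Corpus
from dualpath.lesion import DORSAL_LESION, apply_lesion, apply_severity, severity_grid
from dualpath.probe_eval import (
    CdAResult,
    cda_rate,
    decode_window,
    interaction_2x2,
    probe_double_repetition,
    repeated_measures_2level,
)
from dualpath.srn_core import (
    NetworkState,
    TrainingConfig,
    dual_pathway_architecture,
    forward_trial,
    init_network,
    save_checkpoint,
    train_epoch,
)
from dualpath.task_schedule import (
    build_epoch,
    make_comprehension,
    make_repetition,
    make_speaking,
)

__all__ = [
    "RunConfig",
    "ExperimentResult",
    "desk_config",
    "paper_config",
    "derive_seed",
    "run_development",
    "run_recovery",
    "run_sweep",
    "run_all",
    "evaluate_tasks",
]

log = logging.getLogger("dualpath")


def derive_seed(master: int, *tags: int) -> int:
    """Derive a collision-resistant child seed (< 2^31) from the master seed
    and a tuple of integer tags."""
    ss = np.random.SeedSequence([int(master), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Everything a full experiment needs; defaults are the study values."""

    # corpus
    n_morae: int = 20
    n_words: int = 300
    semantic_dim: int = 50
    semantic_sparsity: float = 0.2
    n_probe_words: int = 51
    n_probe_nonwords: int = 108
    # architecture
    n_ismg: int = 100
    n_astg: int = 45
    # schedule
    development_epochs: int = 200
    recovery_epochs: int = 20
    eval_interval: int = 5
    learning_rate: float = 0.1
    weight_decay: float = 1e-7
    max_grad_norm: float = 10.0
    bigram_tolerance: float = 0.05
    # replication
    n_networks: int = 10
    n_noise_probes: int = 5
    master_seed: int = 1
    # io
    output_dir: str | None = None
    save_checkpoints: bool = False
    make_plots: bool = False

    def training_config(self, epochs: int) -> TrainingConfig:
        return TrainingConfig(self.learning_rate, self.weight_decay,
                              epochs, self.eval_interval, self.max_grad_norm)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def paper_config(master_seed: int = 1, **overrides) -> RunConfig:
    """The full-scale preset: every printed study value at its default."""
    return RunConfig(master_seed=master_seed, **overrides)


def desk_config(master_seed: int = 1, **overrides) -> RunConfig:
    """Reduced preset for a single workstation: 150-word corpus, 2 replicate
    networks.  Probe sets, the lesion recipe, and every training constant
    keep their full-scale values."""
    kw = dict(n_words=150, n_networks=2)
    kw.update(overrides)
    return RunConfig(master_seed=master_seed, **kw)


def make_corpus(cfg: RunConfig) -> Corpus:
    return lexigen.generate_corpus(
        n_morae=cfg.n_morae, n_words=cfg.n_words,
        semantic_dim=cfg.semantic_dim, semantic_sparsity=cfg.semantic_sparsity,
        n_probe_words=cfg.n_probe_words, n_nonwords=cfg.n_probe_nonwords,
        seed=derive_seed(cfg.master_seed, 0),
        bigram_tolerance=cfg.bigram_tolerance)


# ---------------------------------------------------------------------------
# task evaluation (used for the conduction-aphasia signature)

def evaluate_tasks(net: NetworkState, corpus: Corpus, n_noise_probes: int,
                   seed: int) -> dict[str, float]:
    """Accuracy on the three developed tasks over the word probe set.

    Repetition: all three morae decoded correctly at events 4-6.
    Comprehension: the vATL pattern at event 3 is nearest (Euclidean) to the
    item's own semantic vector among all trained-word vectors.
    Naming: all three morae decoded correctly at events 1-3 from a semantic
    clamp.  Noisy networks are averaged over ``n_noise_probes`` draws.
    """
    rng = np.random.default_rng(seed)
    noisy = any(sd > 0 for sd in net.noise_sd.values())
    reps = n_noise_probes if noisy else 1
    inv = corpus.mora_inventory
    sem_matrix = np.stack([w.semantics for w in corpus.train_words])
    own_index = {w.morae: i for i, w in enumerate(corpus.train_words)}
    n_rep = n_comp = n_name = 0
    total = 0
    for item in corpus.probe_words:
        for _ in range(reps):
            total += 1
            r = forward_trial(net, make_repetition(item, inv),
                              rng if noisy else None)
            if decode_window(r["SpeechMotor"], range(4, 7), inv) == item.morae:
                n_rep += 1
            c = forward_trial(net, make_comprehension(item, inv),
                              rng if noisy else None)
            d2 = np.sum((sem_matrix - c["vATL"][2][None, :]) ** 2, axis=1)
            if int(np.argmin(d2)) == own_index[item.morae]:
                n_comp += 1
            s = forward_trial(net, make_speaking(item, inv),
                              rng if noisy else None)
            if decode_window(s["SpeechMotor"], range(1, 4), inv) == item.morae:
                n_name += 1
    return {"repetition": n_rep / total, "comprehension": n_comp / total,
            "naming": n_name / total}


# ---------------------------------------------------------------------------
# phases

def run_development(cfg: RunConfig, corpus: Corpus, network_index: int
                    ) -> NetworkState:
    """Train one randomly initialized network on the development schedule."""
    arch = dual_pathway_architecture(corpus.feature_dim, corpus.semantic_dim,
                                     cfg.n_ismg, cfg.n_astg)
    net = init_network(arch, derive_seed(cfg.master_seed, 1, network_index))
    tcfg = cfg.training_config(cfg.development_epochs)
    for epoch in range(cfg.development_epochs):
        trials = build_epoch(corpus, "development",
                             derive_seed(cfg.master_seed, 2, network_index, epoch))
        net, loss = train_epoch(net, trials, tcfg,
                                derive_seed(cfg.master_seed, 3, network_index, epoch))
        if (epoch + 1) % 25 == 0 or epoch == 0:
            log.info("net %d development epoch %d/%d loss %.4f",
                     network_index, epoch + 1, cfg.development_epochs, loss)
    return net


def _probe_rates(net: NetworkState, corpus: Corpus, cfg: RunConfig,
                 seed: int):
    """Word and nonword CdA results plus the raw records."""
    w_records = probe_double_repetition(
        net, corpus.probe_words, corpus.mora_inventory,
        cfg.n_noise_probes, derive_seed(seed, 0))
    n_records = probe_double_repetition(
        net, corpus.probe_nonwords, corpus.mora_inventory,
        cfg.n_noise_probes, derive_seed(seed, 1))
    return cda_rate(w_records), cda_rate(n_records), w_records, n_records


def run_recovery(net: NetworkState, cfg: RunConfig, corpus: Corpus,
                 network_index: int):
    """Retrain a dorsally lesioned network on the four-task recovery
    schedule, probing both item sets every ``eval_interval`` epochs.

    Returns ``(net, trajectory)`` where trajectory rows are
    (epoch, word CdAResult, nonword CdAResult); noise realizations are
    resampled at every checkpoint from derived seeds.
    """
    tcfg = cfg.training_config(cfg.recovery_epochs)
    trajectory = []
    for epoch in range(cfg.recovery_epochs):
        trials = build_epoch(corpus, "recovery",
                             derive_seed(cfg.master_seed, 4, network_index, epoch))
        net, loss = train_epoch(net, trials, tcfg,
                                derive_seed(cfg.master_seed, 5, network_index, epoch))
        done = epoch + 1
        if done % cfg.eval_interval == 0:
            w, n, _, _ = _probe_rates(
                net, corpus, cfg,
                derive_seed(cfg.master_seed, 6, network_index, done))
            trajectory.append((done, w, n))
            log.info("net %d recovery epoch %d loss %.4f word CdA %s "
                     "nonword CdA %s", network_index, done, loss,
                     w.rate, n.rate)
    return net, trajectory


def run_sweep(net: NetworkState, cfg: RunConfig, corpus: Corpus,
              network_index: int):
    """The ventral dose-response sweep on one recovered network.

    Returns rows (level, word CdAResult, nonword CdAResult) for level 0 (the
    unmodified post-recovery baseline) through level 20; each level damages
    an independent copy of the recovered network.
    """
    rows = []
    w, n, _, _ = _probe_rates(net, corpus, cfg,
                              derive_seed(cfg.master_seed, 7, network_index, 0))
    rows.append((0, w, n))
    for lvl in severity_grid():
        damaged = apply_severity(
            net, lvl, derive_seed(cfg.master_seed, 8, network_index, lvl.level))
        w, n, _, _ = _probe_rates(
            damaged, corpus, cfg,
            derive_seed(cfg.master_seed, 7, network_index, lvl.level))
        rows.append((lvl.level, w, n))
    return rows


# ---------------------------------------------------------------------------
# full experiment

@dataclass
class ExperimentResult:
    """Aggregated outcome of a full lesion-and-recovery experiment."""

    corpus_seed: int
    network_ids: list[int]
    signature: pd.DataFrame      # task accuracies pre/post dorsal lesion
    trajectory: pd.DataFrame     # CdA rates at each recovery checkpoint
    probe_records: pd.DataFrame  # final post-recovery per-probe scoring
    sweep: pd.DataFrame          # severity curves, level 0 = baseline
    stats: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.signature.to_csv(outdir / "signature.csv", index=False)
        self.trajectory.to_csv(outdir / "trajectory.csv", index=False)
        self.probe_records.to_csv(outdir / "probe_records.csv", index=False)
        self.sweep.to_csv(outdir / "sweep.csv", index=False)
        with open(outdir / "stats.json", "w", encoding="utf-8") as fh:
            json.dump(self.stats, fh, indent=2)


def _rate_or_nan(r: CdAResult) -> float:
    return r.rate if r.defined else float("nan")


def _paired_clean(a, b):
    """Drop pairs where either rate is undefined (logged)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.all():
        log.warning("excluding %d network(s) with undefined CdA rate from a "
                    "paired contrast", int((~ok).sum()))
    return a[ok], b[ok]


def _stats_entry(res) -> dict:
    return {"F": res.F, "df": list(res.df), "p": res.p, "cohen_d": res.cohen_d}


def _mean_defined(rates) -> float:
    """Mean over defined (non-NaN) rates; NaN when none are defined."""
    arr = np.asarray(rates, float)
    ok = ~np.isnan(arr)
    return float(arr[ok].mean()) if ok.any() else float("nan")


def run_all(cfg: RunConfig, sweep: bool = True) -> ExperimentResult:
    """Run the complete experiment for ``cfg.n_networks`` replicates.

    Skips a network that fails (with a logged error); at least two survivors
    are required for the statistics.  Deterministic under a fixed master
    seed.
    """
    corpus = make_corpus(cfg)
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    sig_rows, traj_rows, rec_rows, sweep_rows = [], [], [], []
    per_net = {}
    survivors = []
    for idx in range(cfg.n_networks):
        try:
            net = run_development(cfg, corpus, idx)
            pre = evaluate_tasks(net, corpus, cfg.n_noise_probes,
                                 derive_seed(cfg.master_seed, 9, idx))
            lesioned = apply_lesion(net, DORSAL_LESION,
                                    derive_seed(cfg.master_seed, 10, idx))
            post = evaluate_tasks(lesioned, corpus, cfg.n_noise_probes,
                                  derive_seed(cfg.master_seed, 11, idx))
            sig_rows.append({"network": idx,
                             **{f"pre_{k}": v for k, v in pre.items()},
                             **{f"post_{k}": v for k, v in post.items()}})
            recovered, trajectory = run_recovery(lesioned, cfg, corpus, idx)
            for epoch, w, n in trajectory:
                traj_rows.append({
                    "network": idx, "epoch": epoch,
                    "word_rate": _rate_or_nan(w),
                    "nonword_rate": _rate_or_nan(n),
                    "word_first_errors": w.n_first_errors,
                    "nonword_first_errors": n.n_first_errors})
            w_final, n_final, w_rec, n_rec = _probe_rates(
                recovered, corpus, cfg, derive_seed(cfg.master_seed, 12, idx))
            for r in w_rec + n_rec:
                rec_rows.append({
                    "network": idx, "item": "-".join(map(str, r.item_ref)),
                    "lexicality": "word" if r.is_word else "nonword",
                    "probe": r.probe_index,
                    "decoded1": "-".join(map(str, r.decoded1)),
                    "decoded2": "-".join(map(str, r.decoded2)),
                    "attempt1_correct": r.attempt1_correct,
                    "attempt2_correct": r.attempt2_correct})
            levels = run_sweep(recovered, cfg, corpus, idx) if sweep else []
            for lvl, w, n in levels:
                sweep_rows.append({"network": idx, "level": lvl,
                                   "word_rate": _rate_or_nan(w),
                                   "nonword_rate": _rate_or_nan(n)})
            per_net[idx] = {
                "word_final": _rate_or_nan(w_final),
                "nonword_final": _rate_or_nan(n_final),
                "trajectory": {e: (_rate_or_nan(w), _rate_or_nan(n))
                               for e, w, n in trajectory},
                "sweep": {lvl: (_rate_or_nan(w), _rate_or_nan(n))
                          for lvl, w, n in levels},
            }
            if outdir and cfg.save_checkpoints:
                save_checkpoint(recovered, outdir / f"net{idx:02d}_recovered.h5")
            survivors.append(idx)
        except Exception:
            log.exception("network %d failed; skipping", idx)
    if len(survivors) < 2:
        raise RuntimeError(f"only {len(survivors)} networks survived; "
                           "need at least 2 for statistics")

    stats: dict = {"n_networks": len(survivors)}
    wf = [per_net[i]["word_final"] for i in survivors]
    nf = [per_net[i]["nonword_final"] for i in survivors]
    stats["word_cda_rate_mean"] = _mean_defined(wf)
    stats["nonword_cda_rate_mean"] = _mean_defined(nf)
    a, b = _paired_clean(wf, nf)
    if a.size >= 2:
        stats["lexicality"] = _stats_entry(repeated_measures_2level(a, b))
    first, last = cfg.eval_interval, cfg.recovery_epochs
    e5 = [per_net[i]["trajectory"][first][0] for i in survivors]
    e20 = [per_net[i]["trajectory"][last][0] for i in survivors]
    a, b = _paired_clean(e20, e5)
    if a.size >= 2:
        stats["recovery_word"] = _stats_entry(repeated_measures_2level(a, b))
    if sweep:
        wb = [per_net[i]["sweep"][0][0] for i in survivors]
        w20 = [per_net[i]["sweep"][20][0] for i in survivors]
        nb = [per_net[i]["sweep"][0][1] for i in survivors]
        n20 = [per_net[i]["sweep"][20][1] for i in survivors]
        a, b = _paired_clean(wb, w20)
        if a.size >= 2:
            stats["ventral_damage_word"] = _stats_entry(
                repeated_measures_2level(a, b))
        a, b = _paired_clean(nb, n20)
        if a.size >= 2:
            stats["ventral_damage_nonword"] = _stats_entry(
                repeated_measures_2level(a, b))
        cols = np.array([wb, w20, nb, n20], float)
        ok = ~np.isnan(cols).any(axis=0)
        if ok.sum() >= 2:
            stats["interaction_lexicality_x_damage"] = _stats_entry(
                interaction_2x2(*(c[ok] for c in cols)))

    result = ExperimentResult(
        corpus_seed=corpus.seed,
        network_ids=survivors,
        signature=pd.DataFrame(sig_rows),
        trajectory=pd.DataFrame(traj_rows),
        probe_records=pd.DataFrame(rec_rows),
        sweep=pd.DataFrame(sweep_rows),
        stats=stats,
    )
    if outdir:
        result.write(outdir)
        if cfg.make_plots:
            write_figures(result, outdir)
    return result


def write_figures(result: ExperimentResult, outdir) -> None:
    """Simple line/bar summaries of the three result figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    fig, ax = plt.subplots()
    means = [result.stats["word_cda_rate_mean"],
             result.stats["nonword_cda_rate_mean"]]
    ax.bar(["words", "nonwords"], means)
    ax.set_ylabel("successful conduite d'approche rate")
    fig.savefig(outdir / "cda_lexicality.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    for col, label in (("word_rate", "words"), ("nonword_rate", "nonwords")):
        m = result.trajectory.groupby("epoch")[col].mean()
        ax.plot(m.index, m.values, marker="o", label=label)
    ax.set_xlabel("recovery epoch")
    ax.set_ylabel("CdA rate")
    ax.legend()
    fig.savefig(outdir / "cda_recovery.png", dpi=120)
    plt.close(fig)

    if len(result.sweep):
        fig, ax = plt.subplots()
        for col, label in (("word_rate", "words"),
                           ("nonword_rate", "nonwords")):
            m = result.sweep.groupby("level")[col].mean()
            ax.plot(m.index, m.values, marker=".", label=label)
        ax.set_xlabel("ventral damage severity level (0 = none)")
        ax.set_ylabel("CdA rate")
        ax.legend()
        fig.savefig(outdir / "cda_sweep.png", dpi=120)
        plt.close(fig)
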