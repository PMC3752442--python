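"""Synthetic 3-mora lexicon generation.

The training materials are an artificial language: a small inventory of
morae (subsyllabic timing units, each coded as a binary feature vector
presented one per time event), a vocabulary of 3-mora words paired with
sparse binary semantic vectors, a held-in word probe set, and a set of
nonwords whose pooled mora-bigram frequency profile matches the word probe
set.  Nonwords never collide with any trained word form and carry no
semantics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Mora",
    "LexiconItem",
    "Corpus",
    "build_inventory",
    "build_lexicon",
    "sample_probe_sets",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
    "bigram_counts",
    "chi_square_distance",
]

#: number of pitch-accent classes for 3-mora Japanese words (types 0-3);
#: a bookkeeping label only, never encoded in the input vectors.
N_ACCENT_CLASSES = 4


@dataclass(frozen=True)
class Mora:
    """One mora: an id, a display label and a binary feature code."""

    id: int
    label: str
    features: np.ndarray

    def __eq__(self, other):
        return (
            isinstance(other, Mora)
            and self.id == other.id
            and self.label == other.label
            and np.array_equal(self.features, other.features)
        )


@dataclass(frozen=True)
class LexiconItem:
    """A 3-mora form; words also carry a sparse binary semantic vector."""

    morae: tuple[int, int, int]
    semantics: np.ndarray  # empty array for nonwords
    is_word: bool
    accent_class: int = 0

    def __post_init__(self):
        if len(self.morae) != 3:
            raise ValueError(f"items are 3-mora sequences, got {len(self.morae)}")
        if self.is_word and self.semantics.size == 0:
            raise ValueError("word items need a non-empty semantic vector")
        if not self.is_word and self.semantics.size != 0:
            raise ValueError("nonword items must not carry semantics")

    def __eq__(self, other):
        return (
            isinstance(other, LexiconItem)
            and self.morae == other.morae
            and self.is_word == other.is_word
            and self.accent_class == other.accent_class
            and np.array_equal(self.semantics, other.semantics)
        )


@dataclass
class Corpus:
    """Mora inventory plus training words and the two probe sets."""

    mora_inventory: list[Mora]
    train_words: list[LexiconItem]
    probe_words: list[LexiconItem]
    probe_nonwords: list[LexiconItem]
    seed: int

    @property
    def feature_dim(self) -> int:
        return self.mora_inventory[0].features.size

    @property
    def semantic_dim(self) -> int:
        return self.train_words[0].semantics.size

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        codes = {m.features.tobytes() for m in self.mora_inventory}
        if len(codes) != len(self.mora_inventory):
            raise ValueError("mora feature codes are not pairwise distinct")
        train = {w.morae for w in self.train_words}
        if not {w.morae for w in self.probe_words} <= train:
            raise ValueError("probe words must come from the training vocabulary")
        for nw in self.probe_nonwords:
            if nw.morae in train:
                raise ValueError(f"nonword {nw.morae} collides with a trained word")
        sems = {w.semantics.tobytes() for w in self.train_words}
        if len(sems) != len(self.train_words):
            raise ValueError("word semantic vectors are not pairwise distinct")

    def __eq__(self, other):
        return (
            isinstance(other, Corpus)
            and self.seed == other.seed
            and self.mora_inventory == other.mora_inventory
            and self.train_words == other.train_words
            and self.probe_words == other.probe_words
            and self.probe_nonwords == other.probe_nonwords
        )


def build_inventory(n_morae: int, feature_dim: int, seed: int,
                    style: str = "onehot") -> list[Mora]:
    """Build ``n_morae`` pairwise-distinct binary mora codes.

    ``style='onehot'`` uses localist one-hot codes when ``feature_dim`` allows
    (the default coding); otherwise, or with ``style='distributed'``, distinct
    random binary vectors are drawn.  Raises if ``2**feature_dim < n_morae``
    (distinct codes impossible).
    """
    if n_morae < 2:
        raise ValueError("need at least 2 morae")
    if feature_dim < 1:
        raise ValueError("feature_dim must be positive")
    if feature_dim < 64 and 2 ** feature_dim < n_morae:
        raise ValueError(
            f"cannot code {n_morae} distinct morae in {feature_dim} bits"
        )
    labels = [f"m{i:02d}" for i in range(n_morae)]
    if style == "onehot" and feature_dim >= n_morae:
        vecs = [np.eye(feature_dim, dtype=np.float64)[i] for i in range(n_morae)]
    else:
        rng = np.random.default_rng(seed)
        seen: dict[bytes, None] = {}
        vecs = []
        attempts = 0
        while len(vecs) < n_morae:
            v = (rng.random(feature_dim) < 0.5).astype(np.float64)
            key = v.tobytes()
            if key not in seen:
                seen[key] = None
                vecs.append(v)
            attempts += 1
            if attempts > 10000 * n_morae:
                raise RuntimeError("could not draw distinct mora codes")
    return [Mora(i, labels[i], vecs[i]) for i in range(n_morae)]


def build_lexicon(inventory: list[Mora], n_words: int, semantic_dim: int,
                  semantic_sparsity: float, seed: int) -> list[LexiconItem]:
    """Sample ``n_words`` word items with distinct 3-mora forms and distinct
    sparse binary semantic vectors (``round(sparsity*dim)`` active bits each).
    """
    n_morae = len(inventory)
    capacity = n_morae ** 3
    if n_words > capacity:
        raise ValueError(
            f"{n_words} words exceed the {capacity} distinct 3-mora forms"
        )
    k_active = int(round(semantic_sparsity * semantic_dim))
    if k_active < 1:
        raise ValueError("semantic sparsity yields zero active bits")
    if math.comb(semantic_dim, k_active) < n_words:
        raise ValueError("semantic code capacity exceeded")
    rng = np.random.default_rng(seed)
    triple_idx = rng.choice(capacity, size=n_words, replace=False)
    triples = [
        (int(t // n_morae**2), int((t // n_morae) % n_morae), int(t % n_morae))
        for t in triple_idx
    ]
    sems: list[np.ndarray] = []
    seen: set[bytes] = set()
    attempts = 0
    while len(sems) < n_words:
        v = np.zeros(semantic_dim, dtype=np.float64)
        v[rng.choice(semantic_dim, size=k_active, replace=False)] = 1.0
        key = v.tobytes()
        if key not in seen:
            seen.add(key)
            sems.append(v)
        attempts += 1
        if attempts > 10000 * n_words:
            raise RuntimeError("could not draw distinct semantic vectors")
    accents = rng.integers(0, N_ACCENT_CLASSES, size=n_words)
    return [
        LexiconItem(triples[i], sems[i], True, int(accents[i]))
        for i in range(n_words)
    ]


def bigram_counts(items: list[LexiconItem], n_morae: int) -> np.ndarray:
    """Pooled position-free mora-bigram counts: item (a,b,c) contributes the
    ordered pairs (a,b) and (b,c).  Returns an (n_morae, n_morae) count table.
    """
    counts = np.zeros((n_morae, n_morae), dtype=np.float64)
    for it in items:
        a, b, c = it.morae
        counts[a, b] += 1
        counts[b, c] += 1
    return counts


def chi_square_distance(p_counts: np.ndarray, q_counts: np.ndarray) -> float:
    """Symmetric chi-square distance between two normalized histograms:
    0.5 * sum (p-q)^2 / (p+q) over cells with p+q > 0.
    """
    p = p_counts.ravel() / p_counts.sum()
    q = q_counts.ravel() / q_counts.sum()
    mask = (p + q) > 0
    return float(0.5 * np.sum((p[mask] - q[mask]) ** 2 / (p[mask] + q[mask])))


def sample_probe_sets(lexicon: list[LexiconItem], n_words: int = 51,
                      n_nonwords: int = 108, seed: int = 0,
                      n_morae: int | None = None,
                      tolerance: float = 0.05,
                      max_attempts: int = 200) -> tuple[list[LexiconItem], list[LexiconItem]]:
    """Draw the word probe set from the lexicon and construct bigram-matched
    nonwords.

    Nonword forms are sampled from a first-order Markov chain estimated from
    the probe-word bigram table, rejected on collision with any lexicon form,
    then refined by stochastic item replacement until the chi-square distance
    between the pooled bigram histograms of the two sets falls below
    ``tolerance``.  Nonword accent labels are drawn to match the word set's
    accent-class distribution (bookkeeping only).
    """
    if n_words > len(lexicon):
        raise ValueError("probe word set larger than the lexicon")
    if n_morae is None:
        n_morae = max(max(it.morae) for it in lexicon) + 1
    rng = np.random.default_rng(seed)
    word_idx = rng.choice(len(lexicon), size=n_words, replace=False)
    probe_words = [lexicon[i] for i in word_idx]
    if n_nonwords == 0:
        return probe_words, []

    word_counts = bigram_counts(probe_words, n_morae)
    lex_forms = {it.morae for it in lexicon}
    # Markov sampler matched to the word-set bigram profile
    first = word_counts.sum(axis=1)
    trans = word_counts + 1e-9  # smoothing keeps all continuations reachable
    trans = trans / trans.sum(axis=1, keepdims=True)
    first = first / first.sum()

    def draw_form() -> tuple[int, int, int]:
        a = int(rng.choice(n_morae, p=first))
        b = int(rng.choice(n_morae, p=trans[a]))
        c = int(rng.choice(n_morae, p=trans[b]))
        return (a, b, c)

    nonword_forms: list[tuple[int, int, int]] = []
    used = set(lex_forms)
    guard = 0
    while len(nonword_forms) < n_nonwords:
        f = draw_form()
        if f not in used:
            used.add(f)
            nonword_forms.append(f)
        guard += 1
        if guard > 10000 * n_nonwords:
            raise RuntimeError("could not sample enough non-colliding nonwords")

    # refine by coordinate descent: for each slot in turn, enumerate every
    # non-colliding candidate form and keep the one minimizing the chi-square
    # distance (incremental update over the <=4 affected bigram cells)
    p = word_counts.ravel() / word_counts.sum()
    q_total = 2.0 * n_nonwords
    q_counts = np.zeros(n_morae * n_morae)
    cell = lambda a, b: a * n_morae + b

    def form_cells(f):
        a, b, c = f
        return (cell(a, b), cell(b, c))

    for f in nonword_forms:
        for c_ in form_cells(f):
            q_counts[c_] += 1

    def term(cells):
        tot = 0.0
        for c_ in cells:
            s = p[c_] + q_counts[c_] / q_total
            if s > 0:
                tot += 0.5 * (p[c_] - q_counts[c_] / q_total) ** 2 / s
        return tot

    def total_distance():
        qq = q_counts / q_total
        mask = (p + qq) > 0
        return float(0.5 * np.sum((p[mask] - qq[mask]) ** 2 / (p[mask] + qq[mask])))

    all_forms = [(a, b, c) for a in range(n_morae) for b in range(n_morae)
                 for c in range(n_morae)]
    best = total_distance()
    for _ in range(max_attempts):
        if best <= tolerance:
            break
        improved = False
        for j in rng.permutation(n_nonwords):
            old = nonword_forms[j]
            out_cells = form_cells(old)
            for c_ in out_cells:
                q_counts[c_] -= 1
            best_f, best_delta = None, -1e-15
            for f in all_forms:
                if f in used and f != old:
                    continue
                in_cells = form_cells(f)
                affected = set(out_cells) | set(in_cells)
                # score this candidate vs keeping the old form; cells outside
                # `affected` contribute identically to both
                for c_ in in_cells:
                    q_counts[c_] += 1
                d_new = term(affected)
                for c_ in in_cells:
                    q_counts[c_] -= 1
                for c_ in out_cells:
                    q_counts[c_] += 1
                d_old = term(affected)
                for c_ in out_cells:
                    q_counts[c_] -= 1
                delta = d_new - d_old
                if delta < best_delta:
                    best_delta = delta
                    best_f = f
            chosen = best_f if best_f is not None else old
            for c_ in form_cells(chosen):
                q_counts[c_] += 1
            if chosen != old:
                used.discard(old)
                used.add(chosen)
                nonword_forms[j] = chosen
                improved = True
                best = total_distance()
                if best <= tolerance:
                    break
        if not improved:
            break
    if best > tolerance:
        raise RuntimeError(
            f"bigram matching failed: distance {best:.4f} > tolerance {tolerance}"
        )
    word_accents = [w.accent_class for w in probe_words]
    accents = rng.choice(word_accents, size=n_nonwords, replace=True)
    probe_nonwords = [
        LexiconItem(f, np.array([]), False, int(a))
        for f, a in zip(nonword_forms, accents)
    ]
    return probe_words, probe_nonwords


def generate_corpus(n_morae: int = 20, feature_dim: int | None = None,
                    n_words: int = 300, semantic_dim: int = 50,
                    semantic_sparsity: float = 0.2, n_probe_words: int = 51,
                    n_nonwords: int = 108, seed: int = 0,
                    bigram_tolerance: float = 0.05) -> Corpus:
    """Generate a complete corpus: inventory, lexicon, probe sets."""
    if feature_dim is None:
        feature_dim = n_morae
    inventory = build_inventory(n_morae, feature_dim, seed)
    lexicon = build_lexicon(inventory, n_words, semantic_dim,
                            semantic_sparsity, seed + 1)
    probe_words, probe_nonwords = sample_probe_sets(
        lexicon, n_probe_words, n_nonwords, seed + 2,
        n_morae=n_morae, tolerance=bigram_tolerance)
    corpus = Corpus(inventory, lexicon, probe_words, probe_nonwords, seed)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# serialization: line-oriented UTF-8 text

def _bits(v: np.ndarray) -> str:
    return "".join("1" if x > 0.5 else "0" for x in v)


def _item_line(it: LexiconItem) -> str:
    kind = "WORD" if it.is_word else "NONWORD"
    sem = _bits(it.semantics) if it.is_word else "-"
    morae = ",".join(str(m) for m in it.morae)
    return f"{kind}\t{morae}\t{sem}\t{it.accent_class}"


def write_corpus(corpus: Corpus, path) -> None:
    """Write a corpus to the line-oriented text format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#CORPUS seed={corpus.seed}\n")
        fh.write(f"#INVENTORY n={len(corpus.mora_inventory)}\n")
        for m in corpus.mora_inventory:
            fh.write(f"M\t{m.id}\t{m.label}\t{_bits(m.features)}\n")
        for section, items in (("TRAIN", corpus.train_words),
                               ("PROBE_WORDS", corpus.probe_words),
                               ("PROBE_NONWORDS", corpus.probe_nonwords)):
            fh.write(f"#SECTION {section} n={len(items)}\n")
            for it in items:
                fh.write(_item_line(it) + "\n")


class CorpusParseError(ValueError):
    """Malformed corpus file; message names the offending line."""


def read_corpus(path) -> Corpus:
    """Read a corpus written by :func:`write_corpus` (exact round trip)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#CORPUS"):
        raise CorpusParseError("line 1: missing #CORPUS header")
    try:
        seed = int(lines[0].split("seed=")[1])
    except (IndexError, ValueError):
        raise CorpusParseError("line 1: unreadable seed") from None
    inventory: list[Mora] = []
    sections: dict[str, list[LexiconItem]] = {
        "TRAIN": [], "PROBE_WORDS": [], "PROBE_NONWORDS": []}
    current: list[LexiconItem] | None = None
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        if raw.startswith("#INVENTORY"):
            continue
        if raw.startswith("#SECTION"):
            name = raw.split()[1]
            if name not in sections:
                raise CorpusParseError(f"line {ln}: unknown section {name!r}")
            current = sections[name]
            continue
        parts = raw.split("\t")
        if parts[0] == "M":
            if len(parts) != 4:
                raise CorpusParseError(f"line {ln}: malformed mora record")
            feats = np.array([float(c) for c in parts[3]], dtype=np.float64)
            inventory.append(Mora(int(parts[1]), parts[2], feats))
        elif parts[0] in ("WORD", "NONWORD"):
            if current is None:
                raise CorpusParseError(f"line {ln}: item before any #SECTION")
            if len(parts) != 4:
                raise CorpusParseError(f"line {ln}: malformed item record")
            try:
                morae = tuple(int(x) for x in parts[1].split(","))
                is_word = parts[0] == "WORD"
                sem = (np.array([float(c) for c in parts[2]], dtype=np.float64)
                       if is_word else np.array([]))
                current.append(LexiconItem(morae, sem, is_word, int(parts[3])))
            except ValueError as exc:
                raise CorpusParseError(f"line {ln}: {exc}") from None
        else:
            raise CorpusParseError(f"line {ln}: unrecognized record {parts[0]!r}")
    if not inventory:
        raise CorpusParseError("no mora inventory found")
    if not sections["TRAIN"]:
        raise CorpusParseError("no training words found")
    return Corpus(inventory, sections["TRAIN"], sections["PROBE_WORDS"],
                  sections["PROBE_NONWORDS"], seed)
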