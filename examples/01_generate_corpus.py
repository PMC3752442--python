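"""Generate a synthetic 3-mora corpus and inspect its probe sets.

Builds a small artificial lexicon (one-hot mora codes, sparse binary
semantic vectors), draws a word probe set and a bigram-matched nonword set,
and reports the chi-square distance between the pooled mora-bigram
histograms of the two probe sets — the matching criterion that makes word
and nonword repetition difficulty comparable.
"""

import dualpath as dp
from dualpath.lexigen import bigram_counts, chi_square_distance

corpus = dp.generate_corpus(n_morae=20, n_words=300, semantic_dim=50,
                            semantic_sparsity=0.2, n_probe_words=51,
                            n_nonwords=108, seed=7)
corpus.validate()

print(f"mora inventory : {len(corpus.mora_inventory)} morae, "
      f"{corpus.feature_dim}-bit one-hot codes")
print(f"training words : {len(corpus.train_words)} "
      f"(semantic dim {corpus.semantic_dim})")
print(f"probe words    : {len(corpus.probe_words)} (drawn from the lexicon)")
print(f"probe nonwords : {len(corpus.probe_nonwords)} "
      f"(forms absent from the lexicon)")

d = chi_square_distance(
    bigram_counts(corpus.probe_words, 20),
    bigram_counts(corpus.probe_nonwords, 20))
print(f"bigram chi-square distance words vs nonwords: {d:.4f} "
      f"(matched when <= 0.05)")

dp.write_corpus(corpus, "corpus.txt")
print("corpus written to corpus.txt (read back with dualpath.read_corpus)")
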