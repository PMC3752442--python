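# dualpath

A neurocomputational simulation of *conduite d'approche* — the
self-correcting successive repetition attempts of conduction aphasic
patients — in a dual dorsal-ventral pathway model of spoken language.

## The scientific problem

Conduction aphasia (disproportionately impaired repetition with relatively
preserved comprehension and speech) classically follows damage in or around
the arcuate fasciculus — the *dorsal* sound-to-motor pathway. Affected
patients often show conduite d'approche (CdA): repeated attempts at a word
that approach the correct form, more successfully for real words than for
nonwords, and mostly after a period of recovery. The leading account is
that intact *lexical-semantic* information, carried by the *ventral*
pathway through the anterior temporal lobe, "cleans up" the noisy
phonological output before the next attempt.

`dualpath` tests that account mechanistically. A simple-recurrent (Elman)
network with a dorsal route (Auditory → iSMG → SpeechMotor) and a ventral
route (Auditory → aSTG/STS → vATL → SpeechMotor, with a vATL → iSMG
cross-link) is trained on word repetition, comprehension and speaking over
a synthetic 3-mora lexicon. The dorsal route is then lesioned (20% of
iSMG → SpeechMotor links removed; Gaussian output noise SD 0.2 on iSMG),
producing conduction aphasia, and the model is retrained for 20 epochs on a
four-task recovery schedule that includes a repeat-twice trial: input at
events 1–3, supervised output only at events 7–9, with events 4–6 free.
Because standard repetition (output at 4–6) is trained in equal measure,
the network produces *two* attempts; the CdA statistic is

```
CdA rate = #(attempt 1 wrong AND attempt 2 right) / #(attempt 1 wrong)
```

i.e. the rate of successful self-correction, compared between matched word
and nonword probe sets, during recovery, and under graded diagnostic
lesions of the ventral pathway (20 severity levels of noise + link pruning
on vATL and aSTG/STS).

## Worked example

```python
import dualpath as dp

cfg = dp.desk_config(master_seed=1)      # 150-word corpus, 2 networks
result = dp.run_all(cfg)                 # develop -> lesion -> recover -> sweep
print(result.stats["word_cda_rate_mean"])
print(result.stats["nonword_cda_rate_mean"])
```

On the desk preset with master seed 1 this prints (about 9 minutes on one
CPU):

```
0.4104414261460102
0.010469211522142138
```

— after recovery, 41% of failed first repetition attempts at real words are
self-corrected on the second attempt, versus 1% for bigram-matched
nonwords: the lexicality effect that implicates semantic clean-up. (At
full scale the study value for words is ≈25%; the reduced corpus makes the
rate higher but the word ≫ nonword ordering and every directional effect
below are scale-robust.) The same run shows, per network:

- conduction aphasia immediately after the dorsal lesion — repetition
  accuracy drops by 0.76/0.72 while comprehension drops 0.00 and naming
  0.59/0.62;
- steadily improving self-correction across recovery checkpoints
  (epoch 5 → 20: 0.09 → 0.40 and 0.19 → 0.38);
- a monotone dose-response to diagnostic ventral damage: the word CdA rate
  falls from 0.43 (no additional damage) to 0.01 at the severest level
  while the nonword rate stays flat — the causal signature of the ventral
  pathway's contribution, words ≫ nonwords.

`result` carries tidy DataFrames (`signature`, `trajectory`,
`probe_records`, `sweep`) and a `stats` dict with the paired
repeated-measures contrasts (F = t², p, Cohen's d). The scripts in
`examples/` walk each capability separately: corpus generation, develop +
lesion, recovery + CdA, and the ventral sweep.

## Layout

- `src/dualpath/lexigen.py` — synthetic mora lexicon, semantic vectors,
  bigram-matched nonword probe sets, corpus file I/O
- `src/dualpath/srn_core.py` — the Elman network: forward dynamics, BPTT,
  checkpointing
- `src/dualpath/task_schedule.py` — event-indexed trial builders for the
  four tasks and the two phase schedules
- `src/dualpath/lesion.py` — dorsal lesion recipe and the 20-level ventral
  severity grid
- `src/dualpath/probe_eval.py` — output decoding, CdA statistic,
  repeated-measures statistics
- `src/dualpath/pipeline.py` — end-to-end orchestration, presets, outputs

See `docs/methods.md` for the model's assumptions, parameters, numerical
choices, and what the synthetic materials do and do not emulate.
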