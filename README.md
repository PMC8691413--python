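# plebeian

Sentiment-distribution profiling and democratic content-moderation
simulation for text-based social-media threads.

The package has four parts:

1. **Sentiment profiling** — deterministic text cleaning (HTML/URL/handle
   removal, emoji-to-name replacement, dictionary-ratio English check),
   lexicon-based polarity scoring with a pluggable backend and a bundled
   toy lexicon, and a distribution summary: a 30-bin histogram, a Gaussian
   KDE on [-1, 1], the locations and heights of the negative and positive
   modes (`mu_minus`, `mu_plus`, `f_minus`, `f_plus`), and a skewness
   `gamma = ln(f_plus / f_minus)` whose sign says which mode dominates.
2. **Moderation engine** — a two-phase pipeline. The *Flag Phase* samples
   comments of popular threads (views above a threshold) without
   replacement and flags threads whose mean compound sentiment leans
   negative. The *Jury Phase* selects exactly `ceil(10%)` of a post's
   viewers as jurors by simple random sampling; voting ends at a quorum or
   deadline, removal needs a strict majority, ties keep the post. Thread
   state compresses to one byte: a skip bit `phi_d` plus a 7-bit quantized
   thread-mean sentiment `beta`, maintainable recursively so interval
   sweeps rescore only new comments.
3. **Jury theory** — exact Condorcet majority probabilities for odd panels
   and a Monte-Carlo jury simulator with partial participation.
4. **Synthetic corpora** — a seeded generator whose root sentiments follow
   a truncated two-Gaussian mixture (modes near ∓0.5), with comment echo,
   lognormal view counts, misinformation labels logistically coupled to
   negative sentiment, and optional locational/biological virus-naming
   phrases, so every pipeline stage runs hermetically.

## CLI

```sh
plebeian simulate --n-threads 500 --seed 1 --out corpus.jsonl
plebeian analyze --input corpus.jsonl --out summary.json --plot dist.png
plebeian taxonomy --input corpus.jsonl --out categories.json
plebeian flag --input corpus.jsonl --v-thres 500 --seed 1 --out flags.json
plebeian jury --flags flags.json --participation 0.5 --quorum 10 --out verdicts.json
plebeian jury-theory --panel 11 --competence 0.6 --reps 100000
```

All commands are deterministic given `--seed`; exclusion counts are logged
to stderr and results are written as JSON with sorted keys.

## Library example

```python
import numpy as np
from plebeian import (
    FlagConfig, SyntheticConfig, generate_corpus, interval_sweep,
    score_corpus, summarize_distribution,
)

corpus, truth = generate_corpus(SyntheticConfig(n_threads=1000, seed=0))
scores = dict(score_corpus(corpus))
summary, hist, kde = summarize_distribution([s.compound for s in scores.values()])
print(summary.mu_minus, summary.mu_plus, summary.gamma)

sweep = interval_sweep(corpus, {}, scores, FlagConfig(v_thres=400, seed=0))
print(sum(f.flagged for f in sweep.flags), "threads flagged")
```
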