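# questqual

Quality measurement of consumer health questions posted to web Q&A
communities.

Laypeople increasingly ask their health questions on community and
expert Q&A platforms, and the answers they get depend heavily on how
well the question is posed. `questqual` implements a two-indicator
framework for scoring question quality *before any answer arrives*,
plus the statistical machinery to validate the scores and analyse what
drives them:

* **Readability** — the Flesch Reading Ease score

  `FRE = 206.835 − 1.015 · (words / sentences) − 84.6 · (syllables / words)`

  computed from a documented tokenizer and a curated-dictionary +
  heuristic syllable counter. Higher is easier to read.
* **Clarity** — interrogative words (*who, what, where, when, why,
  how*, including contractions such as *what's*) as a percentage of
  all words. A question that never signals what it asks scores 0.
* **Quality tiers** — k-means (Lloyd's algorithm, k-means++ seeding,
  best-of-restarts) on the z-standardized indicator pair, with an
  elbow diagnostic over the SSE curve; the three clusters are ranked
  into high (1) / average (2) / low (3) quality.
* **Human validation** — Cohen κ between judges (pairwise, with a
  weighted variant), and the Pearson correlation between consensus
  ratings and cluster tiers on the 1/2/3 coding.
* **Determinants** — a multinomial logistic regression of tier on
  content codes (shared medical/demographic information, stage of
  questioning, chronic-disease stage) and LIWC-style language
  percentages (pronouns, social, time orientation, body/health,
  affect), with the high tier as reference, quasi-complete-separation
  flagging and an optional ridge penalty; plus two-group platform
  contrasts (continuity-corrected chi-square, Welch t).
* **Synthetic corpora** — a generator that plants a three-tier
  structure and two platform subpopulations so the whole pipeline is
  testable without redistributing platform data.

## Worked example

Two sample questions about kidney disease; `Q1` asks explicitly, `Q2`
shares background but never asks:

```python
>>> from questqual import featurize
>>> from questqual.examples import Q1, Q2
>>> v = featurize(Q1)
>>> print(f"clarity={v.clarity:.2f} readability={v.readability:.2f} words={v.word_count}")
clarity=19.44 readability=96.13 words=36
>>> print(f"clarity={featurize(Q2).clarity:.2f}")
clarity=0.00
```

7 of Q1's 36 tokens are interrogative words, so its clarity is
19.44 % — an explicitly formulated information need. Q2's clarity of 0
flags a post that readers must interpret before they can answer.

The full pipeline, on a generated corpus:

```sh
questqual simulate -o demo --seed 7 --n-per-platform 100
questqual run --corpus demo/corpus.csv --codes demo/codes.csv \
              --ratings demo/ratings.csv -o demo_out --seed 7
```

```
Question quality measurement
  n = 200 records (0 excluded, empty text)
  k = 3 (seed 7, 20 restarts, SSE 21.712); elbow suggests k = 2

  tier           n      readability (min..max)        clarity (min..max)
  high          33     68.94 (40.41..94.02)     43.25 (33.82..60.42)
  average       48    102.91 (88.74..113.10)      4.30 (0.00..9.84)
  low          119    -12.56 (-53.70..20.35)      0.74 (0.00..4.55)
```

The high tier is set apart by clarity (all ≥ 33.8 %), the average and
low tiers by readability. `demo_out/` also contains the per-question
feature table and assignments, the serialized cluster model, a
stratified 10 % validation sample, judge agreement (pairwise κ ≈ 0.72
at the simulated 10 % rating noise, consensus-vs-tier Pearson
r ≈ 0.95), the regression coefficient table and the platform group
tests, plus a manifest recording seeds and configuration.

Library users can do the same through model objects:

```python
from questqual import QuestionQualityModel
results = QuestionQualityModel.from_csv("demo/corpus.csv").fit(seed=7)
print(results.summary())
results.quality          # per-record tier 1/2/3
results.validation_sample(fraction=0.10)
```

## Layout

```
src/questqual/
  textlex.py          tokenizer, syllables, lexicon matching
  lexicons/*.txt      open dictionary categories (one entry per line,
                      trailing * = prefix wildcard)
  data/syllables.txt  curated syllable dictionary
  metrics.py          readability, clarity, language features
  quality_cluster.py  k-means tiers, elbow, labeling, sampling
  validation.py       Cohen kappa, panel kappas, Pearson r
  determinants.py     multinomial logit, group tests
  synthetic.py        corpus / ratings / regression-sample generators
  pipeline.py         QuestionQualityModel / QuestionQualityResults
  cli_io.py, cli.py   file formats, configuration, CLI
```

See `docs/methods.md` for the modelling assumptions, parameter
defaults and known limitations.
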