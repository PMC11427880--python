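# Methods

This note records what `questqual` computes, the assumptions and
defaults behind each stage, and what the synthetic test corpora do and
do not establish about behaviour on real platform data.

## Text decomposition

Tokens are maximal runs of letters (with internal apostrophes, so
contractions stay whole) or maximal runs of digits; hyphens split.
Sentence boundaries are runs of `.`, `!`, `?` followed by whitespace or
end of text, with a small abbreviation stoplist (`Dr.`, `e.g.`, ...);
text without terminal punctuation counts as one sentence, and a run of
question marks is a single boundary. Curly apostrophes are normalised
to straight ones before matching.

Syllables are counted by dictionary lookup first — a curated ~250-word
list biased toward health vocabulary, shipped as
`data/syllables.txt` — and otherwise by a heuristic: vowel-group
counting with an i-hiatus rule (*dialysis* = 4), a silent `-ed` rule
(*diagnosed* = 3), and a silent-e rule that keeps consonant+`le`
syllabic (*stable*) but not vowel+`le` (*male*). The heuristic agrees
with the dictionary on 96 % of the dictionary's own entries; the
residual disagreements (*fatigue*, *anxiety*, *potassium*, ...) are
exactly why the dictionary is consulted first. Tokens without letters
(numbers) count one syllable. No POS tagging, lemmatisation or
spelling correction is attempted.

Question title and body are concatenated with a space by default; a
`body_only` flag restricts analysis to the body.

## Indicators

**Readability** is the Flesch Reading Ease score with the standard
constants (206.835, 1.015, 84.6), reported unclamped: scores above 100
(very short monosyllabic questions) and below 0 (long polysyllabic
run-ons) are meaningful and kept. Empty text has no defined score and
is recorded as missing (NaN), never 0 — a 0 is a legitimately very
hard text. Records with missing readability are excluded from
clustering with a logged count.

**Clarity** is 100 × (interrogative tokens / all tokens). The
interrogative lexicon is the closed set {who, whom, whose, what,
which, where, when, why, how} plus their `'s/'re/'d/'ll` contractions;
it is a plain-text config file and can be overridden. Matching
contractions is required for texts like *"What's the first thing
doctors do..."* where the asking word only appears contracted.

**Language features** are dictionary-category percentages in the LIWC
style: for each category, 100 × matching tokens / all tokens, a token
counting at most once per category but freely across categories. The
packaged categories (pronouns split personal/impersonal, social with
family/friend/female/male subsets, past/present/future focus,
body/health, affect with positive/negative emotion and
anxiety/anger/sadness subsets) are open word lists written for this
package, *not* the proprietary LIWC dictionaries; absolute percentages
are therefore not comparable to LIWC output, though the subset
relations (personal + impersonal ⊆ pronouns, anxiety ∪ anger ∪
sadness ⊆ negative ⊆ affect) are enforced and tested. Lexicon files
use one lowercase entry per line, `#` comments and a trailing `*` as a
prefix wildcard.

## Quality tiers

Indicator pairs are z-standardized before clustering: readability
spans roughly −50..120 while clarity spans 0..60, and unstandardized
k-means would be dominated by readability. A raw-space option exists
behind a flag.

The k-means implementation is Lloyd's algorithm with k-means++
seeding, best of `n_restarts` (default 20) by SSE, convergence when
assignments stabilise or after 300 iterations, and empty-cluster
repair by reseeding at the farthest point. The per-iteration SSE
monotonicity of Lloyd's algorithm is asserted inside the loop. Seeds
are explicit everywhere; there is no wall-clock seeding.

k is fixed to 3 in the reference pipeline. The elbow criterion is
formalised as the k maximising the discrete second difference of the
SSE-vs-k curve (ties toward smaller k) and is reported as an advisory
diagnostic alongside the fixed k; on corpora with a dominant low tier
the largest bend is often at k = 2, which is informative rather than
an error.

Clusters are ranked into tiers by composite = mean standardized
readability + mean standardized clarity of their members: highest →
high (1), lowest → low (3). Composite ties break toward the higher
clarity mean, then the lower cluster id, and are logged. The
validation sample takes round-half-up(fraction · n) per tier (minimum
1 per nonempty tier, default fraction 0.10) and shuffles the pooled
order so judges see tiers interleaved.

## Validation statistics

Cohen κ is unweighted by default — the ordinal levels justify the
linearly weighted variant, which is available by flag — and computed
per judge pair on complete cases, with the unweighted mean across
pairs reported. The degenerate case p_e = 1 (both raters constant on
the same level) is defined as κ = 1 with a warning rather than 0/0.
Consensus ratings are an explicit input; the package only synthesises
consensus by strict majority when asked, and tied records either
raise (default: they need human adjudication) or are dropped with a
logged count (pipeline mode). Validity is the Pearson r between
consensus and tier on the 1/2/3 codes; zero variance on either side
is an error, not a silent 0. Conventional reading: κ > 0.70
substantial reliability, r > 0.5 strong agreement.

## Determinants

The regression is a maximum-likelihood multinomial (softmax) logit
with the high tier as the default reference, fitted by Newton
iterations with step-halving (the log-likelihood never decreases) and
standard errors from the inverse observed information. Predictors
enter untransformed (binary codes as 0/1, percentages as-is). The
design matrix is checked for full column rank up front, and the error
names the collinear columns.

Quasi-complete separation — a predictor perfectly splitting tiers, so
its coefficient diverges while the gradient vanishes — is detected by
|coefficient| > 10 on the log-odds scale and flagged per term in the
output rather than hidden; an optional L2 (ridge) penalty on the
non-intercept coefficients stabilises such fits and its strength is
recorded on the result. No multiple-testing correction is applied by
default; a Benjamini–Hochberg flag would be a thin wrapper and was
deliberately left out of the core table to keep reported p-values raw.

Platform contrasts compare proportions by continuity-corrected
Pearson chi-square on the 2×2 table and means by Welch's t-test; a
zero-variance variable is reported as skipped with the reason.

A schema note: the chronic-disease stages are carried as three binary
indicators (when chronic, stable, unstable) following the regression
tables of the study design this package operationalises, although the
accompanying prose describes a two-way stable/nonstable grouping; the
three-indicator form is the superset and collapses to two by ignoring
one column.

## Synthetic corpora

The generator emulates the *shape* of a two-platform health-question
sample, not its language. Texts are bag-of-words draws from the
packaged syllable dictionary stratified into monosyllabic and
polysyllabic (≥ 3) banks, with interrogative, pronoun, affect and
social words injected at configurable rates. This makes readability
and clarity analytically steerable and licence-clean, at the cost of
all fluency: no grammar, no topic coherence, no misspellings.

Tier profiles (defaults): high quality asks explicitly while carrying
polysyllabic medical detail (10 words/sentence, 45 % polysyllabic
fillers, 42 % interrogative slots → top clarity, mid readability);
average quality is simple chatty prose (9 wps, 4 %, 4 % → top
readability, low clarity); low quality rambles (23 wps, 60 %, 1 % →
bottom readability, low clarity). The three tiers then sit near an
equilateral triangle in standardized indicator space, separated by
roughly 9–12 within-cluster standard deviations, which is what makes
planted-structure recovery a fair test of the clustering stage rather
than of luck. Default tier proportions are 0.162 / 0.271 / 0.567,
mirroring the published cluster-size proportions; the
`well_separated()` recipe used in recovery simulations switches to
equal thirds and 180-word questions to push every pairwise separation
above 8 within-cluster SDs.

Platform profiles (defaults) follow the published contrast
directions: the community-style platform ("yahoo") asks longer
questions (60 vs 42 words) with more pronouns, affect and social
words and more demographic information; the expert-style platform
("webmd") shares more diagnostic and treatment information. Content
codes are independent Bernoulli draws at roughly the published
prevalences, with the constraint that diagnostic or treatment
information implies medical information. Because the code indicators
are independent draws, their marginals — not their joint structure —
are the emulated quantity.

Judge ratings derive from planted tiers by symmetric flip noise: each
judge independently reports the true tier with probability 1 − f,
else a uniform other level. Under this model κ has a closed form
(p_o = Σ p_t[(1−f)² + f²/2], marginals q = (1−f)p + (f/2)(1−p)); at
f = 0.10 and the default tier mix the expected κ is ≈ 0.69, and at
f = 2/3 the reported levels are independent of truth and κ = 0.

Regression recovery simulations draw predictors (two binaries, one
standard normal) and outcomes from a known softmax model with
planted log-odds between 0.6 and 1.2 in magnitude; at n = 2000 the
95 % Wald intervals cover ≈ 95 % of planted coefficients and sign
recovery for effects ≥ 0.5 is essentially certain.

**What passing does not show.** Real questions differ from the
generator in every linguistic respect: tokenisation ambiguity,
spelling noise, genuinely ambiguous tier structure, correlated
content codes, judges whose errors are not symmetric flips. Results
on synthetic corpora certify the *machinery* (metrics computed as
specified, clustering finding structure that is present, statistics
matching their definitions), not the construct validity of
readability + clarity as question quality on any particular platform.

## Numerical choices and simulation sizes

Percentages are kept at full float precision internally and rounded
to two decimals only at the CLI/report layer. Cluster-recovery
simulations use 50 seeds at 150 questions per corpus and the
regression recovery 100 seeds at n = 2000, sizes at which the checked
proportions (≥ 95 % elbow hits, ≥ 90 % CI coverage) are stable; all
simulations are seeded and reproducible. JSON/CSV artefacts
round-trip exactly; the run manifest (config, seeds, package version,
config hash) suffices to replay a pipeline run.

## Known limitations

* The syllable dictionary is small; out-of-dictionary irregulars fall
  back to the heuristic and can be off by one syllable.
* The open lexicons are deliberately compact; category percentages
  are comparable within this package only.
* The elbow criterion (max second difference) is one of several
  formalisations; on strongly imbalanced tier mixes it prefers k = 2,
  and it is advisory only.
* Separation detection is a threshold rule on the coefficient scale;
  coefficients legitimately above 10 log-odds would be misflagged
  (none arise at the package's feature scales).
* The multinomial fit inverts the full (K−1)p × (K−1)p information
  matrix; it is sized for tens of predictors, not thousands.
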