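# Methods

## Scope and data model

The package analyzes one semi-structured interview per participant. An
`Interview` is a time-ordered sequence of turns; a turn is a maximal run
of same-speaker utterances; an utterance is a same-speaker token string.
Tokens are words or fillers and may carry onset/offset times in integer
milliseconds (TextGrid seconds are converted on read). Interviewer
material is kept only as time boundaries: it defines the turn-initial
latencies ("gaps") but contributes no tokens to any measure.

Raw audio is out of scope by design: timing enters through annotations
(per-token times in the JSONL dialect, utterance times via `%tim` lines in
the minimal CHAT dialect, or interval tiers in a Praat TextGrid). Acoustic
silence detection is an external tool's job, not a defined algorithm, so
the package consumes its output instead of imitating it.

### Segmentation

Utterance boundaries are computed from one rule — a silence of at least
1000 ms between consecutive tokens — plus any pre-annotated boundaries
(terminal intonation, grammatical completeness), which are honored and
never removed. Only the pause criterion is computable from timing alone;
the other two are inherently annotation-driven. Segmentation is idempotent
and never drops tokens.

In the minimal CHAT dialect, word-level timing is absent; tokens are laid
out contiguously across the utterance span so that no intra-utterance
silence is fabricated. Pause detection then sees only the real
between-utterance and between-turn silences.

### Token conventions

Normalization lowercases and strips surrounding punctuation but keeps
internal apostrophes (Italian clitics such as *l'ho*). Fillers (default
inventory *uhm*, *ehm*, *mh*, *eh*; configurable) are filled pauses: they
are excluded from every word-denominated count and never matched against
the category dictionary. Types are unique surface forms, not lemmas —
the frequency-lexicon abstraction accepts either kind of resource.
Explicitly marked non-verbal vocalizations and false starts are excluded
and tallied per interview.

## The nine measures

Thresholds and edge rules that matter:

* **Silent pause: strictly > 200 ms.** A within-turn silence of exactly
  200 ms is not a pause.
* **Gap:** interviewer-turn end to participant-turn start. A negative
  latency (overlapping start) is an overlap, not a silence, and is
  excluded rather than clipped to zero. Gaps are never counted as pauses.
* **Mean lexical frequency** averages over token occurrences (repeats
  counted each time), not over types; out-of-vocabulary tokens are
  excluded from the mean and logged. All-OOV input leaves the measure
  missing (NaN).
* An interview with no gaps (or no pauses) leaves the corresponding mean
  missing rather than zero; downstream reduction requires complete rows
  and drops (with a log line) participants with missing measures.

## Reduction

PCA is computed on the correlation matrix of the z-scored measures
(sd with the n−1 denominator). The Kaiser criterion (eigenvalue > 1,
strict) is applied to the correlation-matrix eigenvalues, not to rotated
variances. Retained loadings are varimax-rotated with Kaiser
normalization (SVD-based sweeps, tolerance 1e−6 on the criterion, max 100
sweeps). Scores use the regression (Thomson) method from the rotated
loadings, `S = Z R⁻¹ L_rot`; rotated components are ordered by decreasing
sum of squared loadings, and each component's sign is fixed so its
largest-|loading| feature loads positive — eigenvectors are
sign-ambiguous and tests need determinism. Salience flagging uses
|loading| strictly greater than 0.50.

Whether clustering should use rotated or unrotated scores is not
determined by the procedure itself; rotated scores are the default here
because the rotated components are the interpreted objects. Both are
derivable from the saved model JSON.

## Clustering and validation

k-means is Lloyd's algorithm, best of 25 random initializations by
within-cluster sum of squares, at most 300 iterations, Euclidean
distance, deterministic under the seed (scikit-learn's implementation
stands behind this surface). "25 random centroids" is read as the
standard n-init semantics. The candidate range is k = 2…8 — comfortably
above the expected two-profile solution for cohorts of tens of
participants; the average silhouette width selects k with ties broken
toward the smaller k (parsimony). Cluster ids are relabeled by decreasing
size so cluster 1 is always the larger group.

Validation is Gaussian LDA with pooled within-class covariance and priors
proportional to training class frequencies. Random splits are stratified
by cluster: with a 20-member cluster and a 25% training fraction an
unstratified split can lose a class entirely, which would make the
protocol ill-defined. Each class keeps at least two training and one test
member. Reported spreads are sd with ddof = 1 over the 50 iterations.
Leave-one-out refits the discriminant n times and reports the fraction of
held-out predictions agreeing with the k-means assignment.

## Group comparison

Student's pooled t is the default; when the two-variance F-test rejects
homoskedasticity at α = 0.05 the variable automatically falls back to
Welch's t (the report records which test ran). Normality is checked by a
Shapiro–Wilk advisory that only logs a warning — it never gates or
switches a test, replacing a visual check with an automated hint.
Missing values are removed pairwise per variable, so degrees of freedom
vary across rows. The FDR family is exactly the eight QLS + PANSS
comparisons, adjusted jointly by Benjamini–Hochberg; demographics and
cognitive scores are reported unadjusted. Within-cluster correlations use
pairwise-complete Pearson r with at least 4 complete pairs per cell,
flagged at p < 0.05 unadjusted (exploratory).

## Synthetic cohort generator

The generator emulates the *input* side of the study — timed transcripts
plus a clinical table — with a known two-profile ground truth, default
sizes 47 and 20 and a target of ~420 words per interview (per-participant
log-normal variation, σ = 0.20).

**Linguistic stream.** Interviewer question turns (3–8 words) alternate
with participant answer turns (1 + Poisson(2) utterances of
1 + Poisson(MLU−1) words) on a global millisecond clock. Words come from
a Zipfian master vocabulary whose sub-lists carry the category
dictionary's classes (pronouns, affective, cognitive-mechanism words), so
type-token ratio, mean lexical frequency, and the category percentages
are all controllable; a small out-of-lexicon neologism rate (0.01/word)
exercises the OOV path. Silent pauses are log-normal truncated above the
200 ms rule (every generated pause is detectable); utterance-boundary
silences are log-normal truncated above 1000 ms (segmentation exactly
recovers the generated boundaries); gaps and filler durations are
log-normal. Pause distributions being positive and right-skewed motivates
the log-normal choice.

**Profiles.** Profile 1 (fluent/repetitive): longer utterances (MLU
10), fewer and shorter pauses and gaps, more pronouns (15%/word) and
psychological lexicon, smaller and more concentrated vocabulary (220
types, Zipf exponent 1.35) — hence lower type-token ratio and higher mean
frequency. Profile 2 reverses every direction (MLU 4, 520 types,
exponent 0.85, gap median 1.5 s, ...). Individual variation within a
cluster is driven by four independent latent traits — fluency, lexical
richness, pronoun use, psychological-lexicon use — each modulating its
own block of generator parameters multiplicatively, plus small
block-internal noise.

A consequence worth stating: the between-cluster signal of any two-group
mixture is rank-one, so on the default cohort the correlation matrix
typically retains a single dominant component that carries the whole
profile contrast; k = 2 is then selected with a wide silhouette margin
and cluster recovery is essentially exact (adjusted Rand index 1.0 across
the evaluation seeds). A multi-component structure like the one seen in
real cohorts arises from within-cluster correlation blocks, which the
trait model produces only weakly at the default spread; the
multi-component code paths (varimax with m ≥ 2, score sign/permutation
invariance) are therefore exercised in the test suite on dedicated
factor-structured matrices rather than on the default cohort. Passing the
end-to-end tests shows the pipeline recovers a planted two-profile
structure under realistic measurement noise; it does not show how the
method behaves when cluster separation is marginal, nor does the
generator model topic structure, syntax, disfluency repairs, or
annotator error.

**Clinical table.** Covariates are truncated Gaussians with
cluster-conditional moments (defaults follow the published group
summaries of the reference cohort), independent of the linguistic stream
given the cluster — the emulated study reports between-cluster
differences, not within-cluster couplings. The PANSS disorganization
composite is realized as eight items in [1, 7] whose sum matches the
drawn composite; the QLS total is the exact sum of its three subscales
and the ToM total of its two subscores, matching how the printed totals
relate to their parts. Treatment type is Bernoulli with the published
atypical/typical proportions per cluster.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; the CLI fans a single
`--seed` out to per-stage derived seeds (a fixed affine map mod 2³¹−1),
so stages are independently reproducible and a rerun is byte-identical.
The test suite and the acceptance script use cohorts of 67 participants
(~420 words each), ten evaluation seeds for the end-to-end recovery
check, and 1000 label permutations for the null calibration of the
comparison battery; these sizes keep a full run in the tens of seconds
on a single core while leaving the Monte-Carlo bands narrow (the type-I
rate is asserted within [0.03, 0.07] of the nominal 0.05).

## Known limitations

* Only the pause criterion of utterance segmentation is computed; the
  intonation and grammatical criteria must arrive as annotations.
* Surface-form types: no lemmatization; morphologically rich text will
  read as lexically richer than a lemma-based analysis would report.
* LIWC-style matching is literal/prefix only (longest-stem-wins,
  literal-beats-stem); no disambiguation by context, so homographs count
  in every category their entry lists.
* The comparison battery assumes two clusters; k > 2 solutions are
  clustered and validated but not compared pairwise.
* The synthetic generator does not produce realistic Italian text, only
  distributionally controlled token streams; its fixture lexicon and
  dictionary are stand-ins, not the licensed resources.
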