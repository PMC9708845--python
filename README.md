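# lingclust

Speech-based linguistic profiling and data-driven subtyping of clinical
interview transcripts.

Language disturbance in chronic schizophrenia is heterogeneous: some
speakers are fluent but lexically repetitive, others dysfluent but
lexically varied. `lingclust` implements a complete pipeline for
discovering such profiles from semi-structured interviews: it extracts
nine formula-defined linguistic measures from timed, speaker-attributed
transcripts, reduces them to varimax-rotated principal components,
partitions participants with k-means under silhouette-based model
selection, validates the partition with linear discriminant analysis, and
compares the resulting subgroups on clinical, cognitive, and functional
variables. A built-in synthetic cohort generator provides fully timed
transcripts and clinical covariates with a known two-profile ground truth,
so the entire pipeline is exercisable end to end without any restricted
patient data.

It is aimed at researchers in computational psycholinguistics and clinical
phenotyping who want a reproducible, scriptable version of this analysis
chain for their own corpora (CHAT-style transcripts, Praat TextGrids) or
for methodological work on synthetic cohorts.

## The nine measures

For each participant, over their speech only:

| dimension | measure | definition |
|---|---|---|
| lexical richness | type-token ratio | unique word forms / total words |
| lexical richness | mean lexical frequency | token-wise mean of per-million corpus frequencies |
| fluency | mean length of utterance | total words / total utterances |
| fluency | mean gap duration (ms) | Σ turn-initial latencies / number of gaps |
| fluency | mean pause duration (ms) | Σ (silent + filled pause durations) / number of pauses |
| fluency | pause-to-word ratio | number of pauses / total words |
| pronouns | % personal pronouns | 100 · pronoun tokens / total words |
| psychological lexicon | % affective words | 100 · affective tokens / total words |
| psychological lexicon | % cognitive-mechanism words | 100 · cognitive-mechanism tokens / total words |

A *silent pause* is a within-turn silence strictly longer than 200 ms; a
*filled pause* is a filler vocalization (*uhm*, *ehm*, ...); a *gap* is the
silence between the interviewer's turn end and the participant's turn
start. Utterances are delimited by silences of 1 s or longer (annotated
boundaries from intonation or grammatical completeness are honored when
present).

## The statistical chain

1. **Reduction.** Measures are z-scored (sd with n−1); the correlation
   matrix R is eigen-decomposed; components with eigenvalue λ > 1 are
   retained (Kaiser); retained loadings L = VΛ^{1/2} are varimax-rotated
   with Kaiser normalization; participant scores are regression scores
   S = Z R⁻¹ (L T) for rotation T.
2. **Clustering.** k-means (Lloyd, best of 25 random initializations by
   within-cluster sum of squares) on the component scores for k = 2…8;
   the k with the highest average silhouette width
   s(i) = (b−a)/max(a,b) wins, ties toward smaller k.
3. **Validation.** Gaussian LDA with pooled covariance: (a) 50 stratified
   random splits at training fractions 0.75/0.50/0.25 with mean ± sd
   train/test accuracy, and (b) leave-one-out agreement with the k-means
   assignment.
4. **Comparison.** Per-variable pooled two-sample t-tests (automatic Welch
   fallback when the two-variance F-test rejects at α = 0.05), Fisher's
   exact test for treatment type, Benjamini–Hochberg FDR adjustment over
   the eight QLS + PANSS comparisons, and within-cluster Pearson
   correlations of component scores with cognitive subscores. The PANSS
   disorganization composite is the sum of items P2, N5, N7, G5, G10,
   G11, G12, G13 (range 8–56).

## Worked example

Run the whole pipeline on a synthetic cohort (47 + 20 participants,
~420 words each) and inspect the artifacts:

```bash
lingclust all --seed 1 --out out/
```

The log summarizes each stage:

```
INFO lingclust: simulate: 67 interviews written to out
INFO lingclust: extract: 67 participants x 9 measures
INFO lingclust: reduce: retained 1 components (78.7% variance)
INFO lingclust: cluster: k=2 sizes={1: 47, 2: 20} avg_sil=0.883
INFO lingclust: validate: loo agreement 1.000
INFO lingclust: compare: 24 variables tested
```

Reading: feature extraction found one dominant rotated component (78.7% of
variance) separating the two generated profiles; the silhouette method
selected two clusters (average width 0.883, next-best k = 3 at 0.654)
whose sizes 47/20 exactly recover the generated groups; leave-one-out LDA
agreed with every k-means assignment; and the clinical battery then
contrasts the two recovered subgroups (e.g. in this run QLS total differed
at p < 0.001 while age did not, p = 0.114). Artifacts are plain CSV/JSON:
`features.csv`, `loadings.csv`, `scores.csv`, `labels.csv`,
`silhouette_by_k.csv`, `validation.json`, `loo_predictions.csv`,
`comparison.csv`, `correlations_cluster{1,2}.csv`.

The same stages are available as library functions:

```python
from lingclust import (
    generate_cohort, compute_feature_matrix, fit_pca_varimax, select_k,
    fixture_frequency_lexicon, fixture_category_dictionary,
)
from lingclust.synthetic_data import CohortParams

cohort = generate_cohort(CohortParams(seed=1))
features = compute_feature_matrix(
    cohort.interviews, fixture_frequency_lexicon(), fixture_category_dictionary()
)
model, scores = fit_pca_varimax(features)
solution, by_k = select_k(scores, seed=1)
print(solution.k, solution.sizes())   # 2 {1: 47, 2: 20}
```

Real data enter through `read_transcript` (JSONL or minimal CHAT dialect
with `%tim` lines), `read_textgrid` (long-form Praat TextGrids),
`load_frequency_lexicon` (two-column TSV) and `load_category_dictionary`
(`.dic` dialect with `%`-delimited headers and wildcard stems).

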