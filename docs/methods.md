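# Methods

## Encounter model and synthetic generator

An encounter (`PatientCase`) carries gender, arrival transport, triage
acuity (1 = most urgent … 5 = least), a chief complaint, free-text
diagnoses, patient-reported and administered medication lists, and serial
vital signs: a triage measurement plus one in-ED reassessment by default.
Blood pressure is stored as separate systolic/diastolic fields and rendered
as `SBP/DBP`; with two measurements per encounter this makes the evaluated
item counts derivable (per dialogue: 4 blood-pressure values, 2 each of
heart rate, respiratory rate, O2 saturation and temperature, and 1 pain
score, recorded at triage only).

The generator draws uniformly within configurable plausible ranges
(temperature 95–104 °F, heart rate 40–180 /min, respiratory rate 8–40 /min,
O2 saturation 85–100 %, SBP 90–200 mmHg, DBP 50–120 mmHg with DBP < SBP − 9,
pain 0–10) and uniformly over acuity 1–5; arrival is WALK IN with
probability 0.2 (walk-ins are filtered out before dialogue generation, as
the transport field exists only for that purpose). Term lists are packaged
synthetic vocabularies (40 diagnoses, 36 medications, 18 complaints) of
realistic ED terms; real ICD titles are deliberately not bundled. Everything
is a pure function of `(n, seed, ranges, vocab)`.

Two generator properties exist purely to make the closed-loop evaluation
provable and are *not* claims about real data. First, vocabulary terms are
bounded in length (≤ 23 characters for diagnoses/complaints, ≤ 20 for
medications, commas excluded) so that every mock fact utterance fits in ≤ 41
characters; at the default chunking parameters (200-character windows,
160-character step) any span of ≤ 41 characters is guaranteed to lie wholly
inside at least one chunk, so no ground-truth value can be destroyed by a
chunk boundary. Second, the mock dialogue register is a flat sequence of
short single-line utterances — real transcripts are longer, noisier, and
can split facts across turns, so passing tests here demonstrate pipeline
correctness, not field performance.

## PRAM anonymization

Categorical values are replaced, never kept: the transition matrix over a
cluster of m values is uniform off the diagonal (p_ij = 1/(m−1), p_ii = 0),
so a two-member cluster forces the swap and a five-member cluster gives each
alternative probability 1/4. Clusters are built per vocabulary — diagnoses,
medications (both lists jointly, since reported and administered names are
the same kind of string), and chief complaints — by:

1. embedding the deduplicated terms (768-d for a transformer backend; the
   mock hash embedder uses 256-d),
2. PCA to `pca_dim` (default 65) — clamped to the matrix rank for small
   vocabularies so the paper-scale default remains usable at test scale,
3. L2 normalization, making inner products cosines,
4. constrained k-means into `k_clusters` equal-size groups (default 100,
   clamped to ⌊n/2⌋ so every cluster can support a swap). Sizes differ by at
   most one when n is not divisible by k. The solver alternates a
   capacity-constrained assignment — solved exactly with the Hungarian
   algorithm over per-cluster slots — with centroid updates, from a seeded
   kmeans++ start. This is exact per assignment step, deterministic, and
   entirely adequate at vocabulary scale (10²–10³ terms),
5. outlier pruning: within each cluster, the single farthest term is removed
   iff its cosine distance to the center exceeds mean + 3σ of the
   within-cluster distances; never more than one per cluster. Removed terms
   are still mapped to their nearest surviving center when they occur in a
   record, and are replaced by a uniform draw over that cluster's members.

Numeric vitals are swapped within the quantile bin (default 10 bins) of the
attribute's corpus-wide pool, so swapped values stay inside the observed
range; a value alone in its bin stays put, a constant pool raises. Blood
pressure is swapped as an (SBP, DBP) pair, binned on SBP — independent
swapping could produce DBP ≥ SBP. Gender and stay_id are never perturbed
(gender-specific diagnoses/medications must remain coherent); singleton
clusters raise rather than silently keeping an original, since the method's
point is forced replacement.

## Dialogue generation

Initial dialogues are four templated sections (ambulance contact; triage
with initial vitals and reported medication; administration with re-measured
vitals; hospital arrival with the diagnosis). The acuity band (1–2 critical,
3 urgent, 4–5 minor) selects the template tone variant. Templates are plain
text with `{placeholder}` slots; rendering fails loudly on unresolved names.
Default generation parameters: max 1500 tokens, temperature 0.7 (token
counting in mocks is whitespace-based; real adapters count model tokens).

Refinement applies hierarchical expansion per section: an outline and a
summary of the initial section, the cumulative summary of the *already
refined* earlier sections (so the chain is causal by construction), a
Current-Events block restating every fact introduced so far, and register
instructions (clinical terminology between professionals, plain language to
the patient, manner matched to condition); the refined text is then
translated to German via the backend. The mock translator is the identity
with a language-tag rewrite, which keeps ground truth invariant across the
translate → extract path. Token lengths are recorded as metadata, not
enforced — they are properties of external models.

A loop detector flags dialogues whose normalized adjacent utterance pair
(lowercased, punctuation stripped) repeats ≥ 3 consecutive times — the
known failure mode of long generative refinement — returning the offending
span as evidence.

## RAG extraction

Chunking is character-based: windows of 200 with 40 overlap, starting at 0
and stepping 160, stopping once a window reaches the text end (the tail
chunk is truncated, and a final partial chunk is always emitted — coverage
beats deduplication). One index per dialogue. Retrieval ranks by inner
product of unit-norm embeddings (≡ cosine), k = 12, ties broken by ascending
start offset for determinism. The prompt template concatenates retrieved
chunks newline-separated in retrieval order into the context slot and the
feature name + `q_data` keyword string into the query slot; an explicit
marker fills an empty context. Replies are parsed as newline-, semicolon- or
comma-delimited lists (bullets stripped); "no information available" is
matched case-insensitively. Refined German dialogues are translated back to
English before extraction. Per-feature `q_data` strings live in
`emsrag.features` as editable configuration.

## Evaluation

Numeric matching extracts `\d+\.?\d*` substrings and accepts exact equality,
the half-up integer-rounded truth at a word boundary, or |x − truth| ≤ 0.5
(plus a 1e-9 float guard; the tolerance is configurable per feature).
Nominal matching first normalizes by rule table (abbreviation expansion such
as N/V → Nausea + Vomiting, compound splitting; an optional LLM hook fires
only when rules miss and is off in tests), then takes the maximum cosine
similarity of any answer candidate against each truth component; the default
threshold 0.80 is configuration — no principled printed value exists, and
the match is monotone in the threshold by construction.

True negatives do not exist in this design (every truth item is injected
into the dialogue), so per truth item: matched → TP, answered-but-unmatched
→ FP, empty/no-info → FN, guaranteeing TP+FP+FN = n. Nominal features
contribute one item per dialogue (matched iff *all* the feature's values
match — the strictest consistent reading of per-dialogue counting), numeric
features one item per value. Precision, recall and F1 = 2PR/(P+R) are
reported in percent, half-up to two decimals.

The 95% CI for F1 = 2·TP/(2·TP+FP+FN) treats (TP, FP, FN) as one multinomial
draw of size n and propagates its covariance through the first-order Delta
method; bounds are clipped to [0, 100]. The derivation is guarded by a
bootstrap-agreement test (50 000 multinomial replicates, within 1 percentage
point).

Sentiment drift: per dialogue, the proportion of positive-labeled sentences
(mock: lexicon majority vote; ties neutral) in original vs refined versions,
compared by a one-sided Wilcoxon signed-rank test of H1 "refined < original"
(null: refinement does not reduce positivity). Zero differences are dropped
(Wilcoxon's original convention). Dual-judge analysis: composite = mean over
the eight rating dimensions on the 1–3 scale, compared by a two-sided paired
signed-rank test; inter-rater agreement by Cohen's κ with quadratic weights
w_ij = (i−j)²/(c−1)² and the Fleiss–Cohen–Everitt asymptotic variance, CI
clipped to [−1, 1]. Perfect agreement with degenerate marginals is defined
as κ = 1; a chance-only table raises. Both Wilcoxon statistics report W⁺
(sum of positive-difference ranks, average ranks on ties); p-values come
from the exact distribution where applicable and the normal approximation
otherwise, verified against full 2ⁿ enumeration for n ≤ 12 in the tests.

## Problem sizes and determinism

Tests and the acceptance script run the full loop at 20–40 encounters with
the 256-d hash embedder — enough to exercise every code path, including
multi-chunk retrieval, while the whole suite completes in seconds. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
mock backends take no random draws at all, so the pipeline is bitwise
reproducible end to end.

## Known limitations

- Mock dialogues cannot exhibit the precision degradation that motivates
  the refined-stage evaluation in practice; with echo backends both stages
  score identically. The harness is exercised on that regime by constructed
  confusion fixtures instead.
- The equal-size k-means is locally optimal (exact assignment step, greedy
  center iteration); global optimality is verified only against brute force
  at toy scale.
- The asymptotic κ CI is a large-sample approximation; at the 6-item test
  scale it is wide and only its bounds/ordering are asserted.
- Disclosure risk is not quantified; PRAM here targets plausible synthesis,
  not a formal privacy guarantee.
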