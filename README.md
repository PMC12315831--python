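# emsrag

Privacy-preserving synthetic emergency-medicine dialogues with known ground
truth, and retrieval-augmented extraction of protocol features back out of
them — plus the statistical harness to score the round trip.

## The problem

Emergency medical services (EMS) documentation is a natural target for
LLM-based information extraction, but two obstacles block development:
no public corpus of (German) EMS dialogue transcripts exists, and structured
patient records that could seed synthetic dialogues are bound by data-use
agreements that forbid sending them to hosted models. `emsrag` implements a
complete offline framework around both obstacles:

1. **ED records** (`emsrag.ed_records`) — an encounter model in the
   MIMIC-IV-ED table layout (`edstays`, `diagnosis`, `medrecon`, `pyxis`,
   `triage`, `vitalsign`) with a seeded synthetic generator, so every stage
   is testable without credentialed data.
2. **PRAM anonymization** (`emsrag.pram`) — an adapted Post-Randomization
   Method that makes records fully synthetic before any model sees them.
   Each categorical value *i* is replaced by a draw from a row-stochastic
   transition matrix **P** with p<sub>ii</sub> = 0 and p<sub>ij</sub> =
   1/(m−1) for the m−1 other members of its *semantic cluster*; clusters come
   from embedding → PCA → L2-normalization → constrained equal-size k-means,
   with at most one >3σ cosine-distance outlier removed per cluster. Numeric
   vitals are swapped within quantile bins of their empirical pools, which
   keeps them in plausible ranges; gender and stay_id are preserved.
3. **Dialogue generation** (`emsrag.dialogue`) — four-phase dialogues
   (ambulance contact, triage + vitals, medication + re-measurement,
   hospital arrival) rendered from templates whose placeholders inject the
   case's ground truth, then refined by *hierarchical expansion*: per-section
   outlines, section summaries, cumulative summaries of already-refined
   sections, and a Current-Events block that restates all facts so far, with
   a translation step to German.
4. **RAG extraction** (`emsrag.rag`) — 200-character chunks with 40-character
   overlap, unit-norm embeddings in an inner-product index, top-k = 12
   retrieval per feature query `q_data`, dynamic prompt assembly, and
   low-temperature (0.2) extraction returning value lists with a
   "No information available." sentinel.
5. **Evaluation** (`emsrag.metrics`) — tolerant numeric matching
   (regex `\d+\.?\d*`, exact / integer-rounded / ±0.5), nominal
   normalization + cosine matching, per-item TP/FP/FN without true
   negatives, precision/recall/F1 with Delta-method 95% CIs clipped to
   [0, 100]; one-sided Wilcoxon signed-rank for sentiment drift, paired
   two-sided Wilcoxon for dual-judge ratings, and quadratically weighted
   Cohen's κ with an asymptotic CI.

All model-dependent steps (generation, embedding, translation, sentiment)
sit behind a backend contract (`emsrag.backends`). The shipped mock backend
is deterministic and *echoes every injected fact verbatim*, which turns the
whole pipeline into a closed loop with provable ground truth: whatever goes
into a dialogue must come back out of extraction.

## Worked example

```python
from emsrag.pipeline import run_pipeline

result = run_pipeline(n_cases=20, seed=3)
for r in result.initial_reports[:3]:
    print(f"{r.feature:28s} n={r.n:3d} P={r.precision:6.2f} R={r.recall:6.2f} "
          f"F1={r.f1:6.2f} CI=({r.ci_low:.2f}, {r.ci_high:.2f})")
```

prints

```
Diagnosis                    n= 16 P=100.00 R=100.00 F1=100.00 CI=(100.00, 100.00)
Chief complaint              n= 16 P=100.00 R=100.00 F1=100.00 CI=(100.00, 100.00)
Medication patient reported  n= 16 P=100.00 R=100.00 F1=100.00 CI=(100.00, 100.00)
```

20 generated encounters lose 4 walk-ins to the transport filter, leaving 16
dialogues. Every feature scores 100% recall and precision: the mock
generator echoed each PRAM-swapped ground-truth value into the dialogue, the
retriever surfaced the chunk containing it, and the matcher recognized it —
the closed-loop consistency check the mock backends exist for. With real
model backends these numbers measure genuine extraction quality instead.

The same loop is available from the shell:

```bash
emsrag gen-records --n 100 --seed 7 --out records/
emsrag run --n 30 --seed 7 --out metrics/
emsrag judge-stats --ratings ratings.json
```

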