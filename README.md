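# ehrsigns

Evaluation toolkit for large-language-model extraction of clinical signs
from free-text veterinary electronic health records (EHRs).

## The problem

Retrospective veterinary studies need to know, for each visit record,
whether a set of clinical signs was present — e.g. the six signs
associated with feline chronic enteropathy (decreased appetite,
vomiting, weight loss, diarrhea, constipation, polyphagia). Manual
chart review is the gold standard but slow; an LLM can answer the same
binary questions from the free text, citing the passages that support
each verdict. Before trusting such a pipeline, one has to measure it
the way a diagnostic test is measured, against a defensible reference
standard, and understand where and why it fails.

`ehrsigns` implements that evaluation protocol end to end:

* **Reference standard** — the majority opinion (mode) of a blinded
  human panel per (record, sign) question; ties and abstentions give an
  undefined consensus that is excluded, never broken arbitrarily.
* **Diagnostic performance** — each LLM mode-of-runs verdict is scored
  as TP/FP/TN/FN per sign; sensitivity (Se), specificity (Sp), PPV and
  NPV are reported with 95% Wilson score intervals,

  $$\mathrm{CI} = \frac{\hat p + z^2/2n \;\pm\; z\sqrt{\hat p(1-\hat p)/n + z^2/4n^2}}{1 + z^2/n},$$

  together with F1 = 2·Se·PPV/(Se+PPV) and balanced accuracy
  (Se+Sp)/2, and summarized across signs as median (IQR).
* **Reproducibility** — Cohen's κ = (p_o − p_e)/(1 − p_e) for every
  unique pair of respondents or repeated runs, averaged; paired
  classifier comparisons use McNemar's χ² with continuity correction,
  χ² = max(|b−c|−1, 0)²/(b+c), 1 df.
* **Citation audit** — quoted citations are verified against the record
  through an ordered normalization ladder (exact → case-only →
  punctuation/spacing → shortened → scaffold-included → paraphrase →
  unmatched); a citation not found at any level is a hallucination
  candidate.
* **Error taxonomy** — every LLM-vs-reference disagreement is
  classified by error type (FP/FN), by how many humans sided with the
  model (dissent stratum), by interpretation-vs-citation discrepancy
  (same or different cited spans), and by adjudicated temporal or
  qualitative ambiguity labels.
* **Synthetic panels** — a seeded generator produces template-based
  corpora with exact gold citation spans, a five-human panel whose
  disagreement is driven by ambiguity, and a machine annotator with
  temperature-dependent run-to-run inconsistency, so the entire
  pipeline is testable without any clinical data.
* **Study design** — the sample-size calculation for estimating the
  sensitivity of a single test, n = ⌈z²·Se(1−Se)/d² / prev⌉.

## Worked example

```python
from ehrsigns import (
    SimConfig, generate_corpus, simulate_human_panel, simulate_llm_runs,
    evaluate_performance, reproducibility, human_panel, llm_run_panels,
    build_error_ledger, ambiguity_labels,
)

config = SimConfig(n_records=250, seed=7)
records, truth = generate_corpus(config)
humans = simulate_human_panel(records, truth, config)
runs = simulate_llm_runs(records, truth, config)

report = evaluate_performance(runs, humans, config.signs, temperature=0.0)
for name in ("sensitivity", "specificity", "ppv", "npv", "f1", "balanced_accuracy"):
    s = report.summary[name]
    print(f"{name:18s} median {100*s.median:5.1f}%  IQR {100*s.q1:5.1f}-{100*s.q3:5.1f}%")

_, kappa_h = reproducibility(human_panel(humans))
_, kappa_m = reproducibility(llm_run_panels(runs, 0.0))
print(f"mean pairwise kappa: humans {kappa_h:.2f}, runs at T=0 {kappa_m:.2f}")

ledger = build_error_ledger(runs, humans, {r.record_id: r for r in records},
                            temperature=0.0, ambiguity=ambiguity_labels(truth))
print(f"errors: {ledger.n_errors}/{ledger.total_questions} "
      f"({ledger.pct['error_rate']}%), "
      f"false positives {ledger.pct['false_positive_of_errors']}% of errors")
```

Output:

```
sensitivity        median  95.6%  IQR  94.1- 99.2%
specificity        median  97.2%  IQR  96.7- 97.8%
ppv                median  82.8%  IQR  81.0- 85.4%
npv                median  99.3%  IQR  99.0- 99.9%
f1                 median  88.5%  IQR  88.0- 89.8%
balanced_accuracy  median  96.4%  IQR  95.8- 97.8%
mean pairwise kappa: humans 0.84, runs at T=0 0.97
errors: 45/1500 (3.0%), false positives 80.0% of errors
```

The profile is characteristic of this task: near-perfect NPV and high
Se/Sp, a visibly lower PPV and F1 because errors are dominated by false
positives on ambiguous questions, and model self-agreement well above
human interobserver agreement.

A command-line layer wraps the same functions:

```bash
ehrsigns simulate --n 250 --seed 7 --out sim
ehrsigns run --corpus sim/corpus.csv --backend mock --temperatures 0,0.5,1 --repeats 5
ehrsigns evaluate --corpus sim/corpus.csv --llm sim/llm_responses.jsonl \
    --humans sim/human_responses.jsonl --labels sim/ambiguity_labels.csv
```

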