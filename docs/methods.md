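# Methods

This note records the statistical conventions, the design choices made
where the design was genuinely open, and what the synthetic panels do
and do not establish.

## Questions, verdicts, and consensus

The unit of analysis is a question: one (record, sign) pair with a
ternary verdict — true, false, or NA (abstention/unparseable output).
Consensus over a panel (five humans, or five repeated model runs at one
temperature) is the mode: NA verdicts are removed first, then a strict
majority is required. An exact true/false tie yields an NA consensus.
Questions with an NA consensus on either side are excluded from
confusion tables and counted in an explicit `excluded` field rather
than broken by a tie rule; with five-member panels and boolean answers
ties are rare, and exclusion is the conservative, fully logged choice.

## Performance metrics

Per sign, the human-majority consensus is the reference and the
mode-of-runs the test. Sensitivity, specificity, PPV and NPV are
binomial proportions k/n and carry 95% Wilson score intervals; the
interval is computed in closed form, clipped to [0, 1], with the exact
closed boundary returned at k = 0 and k = n (the formula is exact
there; the special case only avoids float round-off). n = 0 yields an
undefined-metric marker, not an exception, and undefined values
propagate into F1 and balanced accuracy. F1 and balanced accuracy are
derived from the other metrics and are reported without intervals.

Cross-sign summaries are median and quartiles with linear interpolation
between order statistics (numpy's default; the same convention as the
default `quantile` type of the common statistical environments). The
convention matters at six data points, so it is fixed here and the
summary also reports how many signs had undefined values.

## Agreement statistics

Cohen's kappa uses the standard two-rater form with chance agreement
from each vector's own marginals; pairs with NA on either side are
dropped and counted. Perfect agreement with degenerate marginals
(p_e = 1) is reported as κ = 1. Reproducibility is the arithmetic mean
of κ over all C(r, 2) unique pairs.

McNemar's test uses the continuity-corrected statistic
χ² = max(|b−c|−1, 0)²/(b+c) with 1 df. The max(·, 0) clamp makes
b = c give χ² = 0 and p = 1 (some library implementations return
(|b−c|−1)²/(b+c) unclamped, which is positive at b = c — an artifact
for near-equal discordants). b + c = 0 is defined as χ² = 0, p = 1.
Model-vs-model comparisons pool all (record × sign) questions using
each side's mode verdict; a per-sign breakdown is available by calling
the test on per-sign vectors.

## Citation audit

Respondents must support verdicts with copy-pasted text: quote-enclosed
segments, whitespace-separated, no ellipses. Extraction normalizes
typographic quotes, flags unquoted text, missing separators, ellipses,
and unbalanced quotes (best-effort extraction continues). Matching
applies an ordered ladder; the first firing level wins:

1. **exact** — contiguous substring of the record text (presenting
   complaint + pertinent history, the fields respondents saw);
2. **case_only** — substring after case folding;
3. **punct_space** — the segment's normalized tokens (case-folded,
   punctuation-stripped) appear contiguously in the record's
   normalized tokens;
4. **shortened** — the segment tokens form an ordered subsequence with
   gaps;
5. **scaffold_included** — exact/case match after stripping known
   question or field-name strings from the segment;
6. **paraphrase** — token containment (shared normalized tokens /
   segment tokens) ≥ τ_p, default 0.5;
7. **unmatched** — a hallucination candidate.

The shortening-vs-paraphrase boundary is this module's
operationalization of a distinction that is otherwise a human judgment:
an ordered subsequence preserves wording (shortening), while a
failed subsequence with high token overlap indicates rewording
(paraphrase). Meaning-altering shortenings that drop or inflect words
(e.g. quoting "occasional diarrhea" from a text that says
"occasionally strains …, no diarrhea") fail the subsequence test and
classify as paraphrase, which matches how such a case reads. τ_p and
the scaffold-string list are configurable.

A response is citation-compliant iff it has no format violations and
every segment matches exactly; a response citing nothing commits no
violation and counts as compliant (a false verdict needs no citation,
and the instructions do not force one).

## Error taxonomy

Errors are questions where both consensuses are defined and disagree.
Dissent is the number of humans whose verdict equals the model mode.
Discrepancy classification resolves the citations of the model runs
that voted with the model mode and of the majority-side humans to
character intervals and compares interval unions: Jaccard ≥ 0.5 (on
merged unions) is an interpretation discrepancy, anything less — or
either side citing nothing — is a citation discrepancy (someone missed
a passage). The threshold replaces a manual "same text sections"
judgment and is configurable. Ambiguity labels (temporal /
qualitative) are adjudication input, copied onto matching error cases
and never inferred from text.

## Synthetic panels

The generator assembles each record from filler sentences plus, per
sign drawn at prevalence 0.15, one template sentence: clear-present,
temporally ambiguous (historic or dated, e.g. a dated weight line), or
qualitatively equivocal; a fraction of absent signs get an explicit
negation. Gold spans are exact character intervals. Default
parameters, all configurable on `SimConfig`:

| parameter | default | role |
|---|---|---|
| `prevalence` | 0.15 | per-sign signal probability (the study's expected prevalence) |
| `p_temporal`, `p_qualitative` | 0.15, 0.10 | ambiguity classes given a signal |
| `eps_human` | 0.01 | human error rate on unambiguous questions |
| `pi_human` | 0.5 | per-human P(true) on ambiguous questions — the dissent engine |
| `mu_human` | 0.10 | P(no citation given a true verdict with a gold span) |
| `eps_machine`, `pi_machine` | 0.01, 0.8 | machine analogues; the true-bias on ambiguous questions makes errors FP-dominated |
| `flip_rates` | 0 → 0.002, 0.5 → 0.006, 1 → 0.012 | per-run flip probability of the per-question base answer |

The machine draws one base answer per question and each run flips it
independently at δ(T). This base-plus-flips structure (rather than
i.i.d. answers per run) is what makes run-pair agreement far exceed
human-human agreement even at the highest temperature. With the
defaults, mean run-pair κ lands near 0.98 / 0.95 / 0.93 at
temperatures 0 / 0.5 / 1 against human κ ≈ 0.8, overall
machine-vs-reference disagreement at 2–4% of questions, and roughly
80% false positives — the magnitudes this kind of extraction task
exhibits. Ambiguity prevalences are illustrative, not fitted.

What the generator does **not** emulate: realistic clinical language
(templates keep gold spans exact and tests hermetic); citation
deviations whose rates grow with temperature (deviation probabilities
are per-respondent constants); humans citing text to support *false*
verdicts — false verdicts cite nothing. A consequence of the last
point is that simulated model-vs-human errors always involve one side
citing nothing and therefore classify as citation discrepancies;
interpretation discrepancies are exercised by direct construction in
tests rather than by the generator. Passing on synthetic panels
establishes the statistical machinery, not performance on real
records.

## Problem sizes and determinism

The parameter-recovery check runs the full pipeline on 334-record
panels (≈ 2,000 questions) over 20 seeds with machine error 0.03,
near-perfect humans, and no ambiguity, asking that the 95% Wilson
intervals of estimated sensitivity and specificity cover the true
value in ≥ 90% of seeds; exact Wilson coverage at these (n, p) is
≈ 94–95%, so the 18-of-20 threshold sits deliberately close to the
nominal level. Coverage simulations use 2,000 binomial replicates at
p = 0.15, n ∈ {50, 250}, where the interval's exact coverage is within
the 95% ± 2% band. All simulation stages draw from named generators
spawned from a single seed, so corpora, human panels, and machine runs
are independently reproducible.

## Known limitations

* The paraphrase level uses token containment, not semantic
  similarity; a fluent paraphrase sharing few tokens lands in
  `unmatched` and is surfaced as a hallucination candidate for review.
* Character-interval resolution for discrepancy classification takes
  the first occurrence of a repeated span; records with heavily
  duplicated sentences could mis-localize a citation.
* The mock backend produces structurally perfect output; parser-repair
  paths are exercised by constructed malformed fixtures instead.
* Live-model execution (the optional OpenAI-compatible backend) is an
  adapter only; nothing in the analysis depends on it.
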