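"""End-to-end evaluation: responses in, metrics / agreement / ledger out.

Glue between the response format and the statistics modules: group
responses into per-respondent verdict panels, form consensus verdicts,
tabulate confusion against the human reference, and assemble the fully
classified error ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .agreement import pairwise_mean_kappa
from .citations import MatchThresholds, extract_citations, match_citation
from .corpus import EHRecord
from .errors import (
    ErrorLedger,
    attach_ambiguity,
    classify_discrepancy,
    dissent_count,
    identify_errors,
    summarize_ledger,
)
from .metrics import (
    ConfusionTable,
    MetricEstimate,
    PanelSummary,
    Verdict,
    confusion,
    mode_verdict,
    performance_metrics,
    summarize_across_signs,
)
from .prompting import QuestionResponse

QuestionKey = tuple[str, str]

__all__ = [
    "human_panel",
    "llm_run_panels",
    "consensus",
    "PerformanceReport",
    "evaluate_performance",
    "reproducibility",
    "build_error_ledger",
]


def human_panel(
    responses: Iterable[QuestionResponse],
) -> dict[str, dict[QuestionKey, Verdict]]:
    """Group human responses (no run index) by respondent."""
    panel: dict[str, dict[QuestionKey, Verdict]] = {}
    for r in responses:
        if r.run_index is not None:
            continue
        panel.setdefault(r.respondent_id, {})[(r.record_id, r.sign)] = r.verdict
    return panel


def llm_run_panels(
    responses: Iterable[QuestionResponse], temperature: float
) -> dict[str, dict[QuestionKey, Verdict]]:
    """Group machine responses at one temperature by run index."""
    panel: dict[str, dict[QuestionKey, Verdict]] = {}
    for r in responses:
        if r.temperature == temperature and r.run_index is not None:
            panel.setdefault(f"run_{r.run_index}", {})[(r.record_id, r.sign)] = r.verdict
    return panel


def consensus(panel: Mapping[str, Mapping[QuestionKey, Verdict]]) -> dict[QuestionKey, Verdict]:
    """Mode verdict per question across a respondent (or run) panel."""
    keys = set()
    for verdicts in panel.values():
        keys.update(verdicts)
    return {
        key: mode_verdict([panel[rid].get(key) for rid in panel])
        for key in sorted(keys)
    }


@dataclass
class PerformanceReport:
    per_sign_confusion: dict[str, ConfusionTable]
    per_sign_metrics: dict[str, dict[str, MetricEstimate]]
    summary: dict[str, PanelSummary]
    pooled_confusion: ConfusionTable
    pooled_metrics: dict[str, MetricEstimate] = field(default_factory=dict)


def evaluate_performance(
    llm_responses: Iterable[QuestionResponse],
    human_responses: Iterable[QuestionResponse],
    signs: Iterable[str],
    temperature: float = 0.0,
) -> PerformanceReport:
    """Mode-vs-mode diagnostic performance at one temperature.

    The human-majority consensus is the reference standard; the mode of
    the repeated machine runs is the test. Metrics are computed per
    sign and summarized (median/IQR) across signs; a pooled confusion
    table over all questions is also reported.
    """
    ref = consensus(human_panel(human_responses))
    test = consensus(llm_run_panels(llm_responses, temperature))
    per_sign_ct: dict[str, ConfusionTable] = {}
    for sign in signs:
        ref_s = {k: v for k, v in ref.items() if k[1] == sign}
        test_s = {k: v for k, v in test.items() if k[1] == sign}
        per_sign_ct[sign] = confusion(ref_s, test_s)
    per_sign_metrics = {s: performance_metrics(ct) for s, ct in per_sign_ct.items()}
    pooled = ConfusionTable()
    for ct in per_sign_ct.values():
        pooled = pooled + ct
    return PerformanceReport(
        per_sign_confusion=per_sign_ct,
        per_sign_metrics=per_sign_metrics,
        summary=summarize_across_signs(per_sign_metrics),
        pooled_confusion=pooled,
        pooled_metrics=performance_metrics(pooled),
    )


def reproducibility(panel: Mapping[str, Mapping[QuestionKey, Verdict]]):
    """Pairwise Cohen's kappa table and mean for a respondent or run panel."""
    return pairwise_mean_kappa(panel)


def _cited_intervals(
    responses: list[QuestionResponse],
    text: str,
    thresholds: MatchThresholds,
) -> list[tuple[int, int]]:
    intervals = []
    for resp in responses:
        for seg in extract_citations(resp.citation_raw).segments:
            verdict = match_citation(seg, text, thresholds)
            if verdict.interval is not None:
                intervals.append(verdict.interval)
    return intervals


def build_error_ledger(
    llm_responses: Iterable[QuestionResponse],
    human_responses: Iterable[QuestionResponse],
    records: Mapping[str, EHRecord],
    temperature: float = 0.0,
    ambiguity: Mapping[QuestionKey, str] | None = None,
    thresholds: MatchThresholds = MatchThresholds(),
    overlap_threshold: float = 0.5,
) -> ErrorLedger:
    """Identify, classify, and summarize every machine-vs-reference error.

    Discrepancy classification resolves the citations of the machine
    runs that voted with the machine mode, and of the humans on the
    majority side, to character intervals; dissent counts the humans
    siding with the machine. Ambiguity labels, when supplied, are
    copied onto the matching error cases.
    """
    llm_responses = list(llm_responses)
    human_responses = list(human_responses)
    humans = human_panel(human_responses)
    runs = llm_run_panels(llm_responses, temperature)
    human_mode = consensus(humans)
    llm_mode = consensus(runs)
    defined = {k for k in human_mode if human_mode[k] is not None and llm_mode.get(k) is not None}
    errors = identify_errors(
        {k: llm_mode[k] for k in defined}, {k: human_mode[k] for k in defined}
    )

    by_question_llm: dict[QuestionKey, list[QuestionResponse]] = {}
    for r in llm_responses:
        if r.temperature == temperature:
            by_question_llm.setdefault((r.record_id, r.sign), []).append(r)
    by_question_human: dict[QuestionKey, list[QuestionResponse]] = {}
    for r in human_responses:
        if r.run_index is None:
            by_question_human.setdefault((r.record_id, r.sign), []).append(r)

    for err in errors:
        key = (err.record_id, err.sign)
        text = records[err.record_id].visible_text
        llm_verdict = llm_mode[key]
        human_verdict = human_mode[key]
        human_rows = by_question_human.get(key, [])
        err.dissent_count = dissent_count([r.verdict for r in human_rows], llm_verdict)
        llm_side = [r for r in by_question_llm.get(key, []) if r.verdict == llm_verdict]
        majority_side = [r for r in human_rows if r.verdict == human_verdict]
        err.discrepancy = classify_discrepancy(
            _cited_intervals(llm_side, text, thresholds),
            _cited_intervals(majority_side, text, thresholds),
            overlap_threshold,
        )
    if ambiguity:
        attach_ambiguity(errors, ambiguity, corpus_keys=set(human_mode))
    # denominator is all aligned questions, as in "43 out of 1,500"
    return summarize_ledger(errors, total_questions=len(human_mode))
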