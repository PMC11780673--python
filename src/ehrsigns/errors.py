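"""Error identification and taxonomy for LLM-vs-reference disagreements.

An error is any question where the mode of repeated LLM runs differs
from the majority opinion of the human panel. Each error is classified
along four axes:

* error type — false positive (LLM true, humans false) or false negative;
* dissent stratum — how many humans sided with the LLM against their
  own majority (0..2 in a five-human panel), a proxy for how ambiguous
  the question was;
* discrepancy — ``interpretation`` when both sides cite the same text
  sections yet answer differently, ``citation`` when the cited text
  differs (or one side cites nothing), implying a missed passage;
* ambiguity — ``temporal`` or ``qualitative`` labels supplied by human
  adjudication (never inferred from text), else ``none``/``unlabeled``.

"Same text sections" is operationalized as interval-overlap Jaccard of
the resolved citation spans at a configurable threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

from .metrics import Verdict

QuestionKey = tuple[str, str]  # (record_id, sign)

__all__ = [
    "ErrorCase",
    "ErrorLedger",
    "identify_errors",
    "dissent_count",
    "interval_jaccard",
    "classify_discrepancy",
    "attach_ambiguity",
    "summarize_ledger",
]


@dataclass
class ErrorCase:
    record_id: str
    sign: str
    error_type: str  # false_positive | false_negative
    dissent_count: int | None = None
    discrepancy: str | None = None  # interpretation | citation
    ambiguity: str = "unlabeled"  # temporal | qualitative | none | unlabeled


def identify_errors(
    llm_mode: Mapping[QuestionKey, Verdict],
    human_mode: Mapping[QuestionKey, Verdict],
) -> list[ErrorCase]:
    """Questions where both consensuses are defined and disagree.

    False positive: LLM mode true, human mode false; false negative the
    converse. Questions with an undefined (NA) consensus on either side
    are not errors — they are excluded upstream in the confusion table.
    """
    missing = set(llm_mode) ^ set(human_mode)
    if missing:
        raise KeyError(f"question keys not shared: {sorted(missing)[:10]}")
    errors = []
    for key in llm_mode:
        llm, human = llm_mode[key], human_mode[key]
        if llm is None or human is None or llm == human:
            continue
        errors.append(
            ErrorCase(
                record_id=key[0],
                sign=key[1],
                error_type="false_positive" if llm else "false_negative",
            )
        )
    return errors


def dissent_count(human_verdicts: Sequence[Verdict], llm_mode: bool) -> int:
    """Number of human respondents whose verdict equals the LLM mode."""
    return sum(1 for v in human_verdicts if v is not None and v == llm_mode)


Interval = tuple[int, int]


def _merge(intervals: Sequence[Interval]) -> list[Interval]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


def interval_jaccard(a: Sequence[Interval], b: Sequence[Interval]) -> float:
    """Jaccard overlap of two unions of character intervals."""
    ma, mb = _merge(a), _merge(b)
    inter = 0
    for s1, e1 in ma:
        for s2, e2 in mb:
            inter += max(0, min(e1, e2) - max(s1, s2))
    union = sum(e - s for s, e in _merge(list(ma) + list(mb)))
    return inter / union if union else 0.0


def classify_discrepancy(
    llm_intervals: Sequence[Interval],
    human_intervals: Sequence[Interval],
    overlap_threshold: float = 0.5,
) -> str:
    """Interpretation vs citation discrepancy from resolved citation spans.

    ``llm_intervals`` are the spans cited by the LLM mode side;
    ``human_intervals`` the spans cited by humans on the majority side.
    If either side (or both) cited nothing the discrepancy is
    ``citation`` — somebody missed a passage. Otherwise it is
    ``interpretation`` when the interval-union Jaccard reaches the
    threshold (both sides looked at the same text), else ``citation``.
    """
    if not llm_intervals or not human_intervals:
        return "citation"
    if interval_jaccard(llm_intervals, human_intervals) >= overlap_threshold:
        return "interpretation"
    return "citation"


def attach_ambiguity(
    errors: list[ErrorCase],
    labels: Mapping[QuestionKey, str],
    corpus_keys: set[QuestionKey] | None = None,
) -> list[ErrorCase]:
    """Copy adjudicated ambiguity labels onto error cases; never inferred.

    Unlabeled questions stay ``unlabeled``. A label key outside the
    corpus raises a warning, not an error (labels may be partial or
    stale).
    """
    if corpus_keys is not None:
        stray = set(labels) - corpus_keys
        if stray:
            warnings.warn(f"{len(stray)} ambiguity label(s) not in corpus, e.g. {sorted(stray)[:3]}")
    for err in errors:
        key = (err.record_id, err.sign)
        if key in labels:
            err.ambiguity = labels[key]
    return errors


@dataclass
class ErrorLedger:
    """Marginal counts and printed-precision percentages over an error list."""

    total_questions: int
    n_errors: int
    counts: dict[str, int] = field(default_factory=dict)
    pct: dict[str, float] = field(default_factory=dict)
    cases: list[ErrorCase] = field(default_factory=list)


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else 0.0


def summarize_ledger(errors: list[ErrorCase], total_questions: int) -> ErrorLedger:
    """Tally the ledger marginals along every classification axis.

    Percentages are reported at one-decimal printed precision: error
    share of all questions; false-positive/negative shares of errors;
    dissent strata (2/1/0 humans siding with the LLM) as shares of
    errors and of all questions; interpretation/citation shares of
    errors; temporal/qualitative shares of interpretation errors.
    """
    n = len(errors)
    fp = sum(1 for e in errors if e.error_type == "false_positive")
    fn = n - fp
    dissent = {k: sum(1 for e in errors if e.dissent_count == k) for k in (2, 1, 0)}
    any_dissent = dissent[2] + dissent[1]
    interp = sum(1 for e in errors if e.discrepancy == "interpretation")
    cit = sum(1 for e in errors if e.discrepancy == "citation")
    temporal = sum(
        1 for e in errors if e.discrepancy == "interpretation" and e.ambiguity == "temporal"
    )
    qualitative = sum(
        1 for e in errors if e.discrepancy == "interpretation" and e.ambiguity == "qualitative"
    )
    counts = {
        "errors": n,
        "false_positive": fp,
        "false_negative": fn,
        "dissent_2": dissent[2],
        "dissent_1": dissent[1],
        "dissent_0": dissent[0],
        "any_dissent": any_dissent,
        "interpretation": interp,
        "citation": cit,
        "temporal": temporal,
        "qualitative": qualitative,
    }
    pct = {
        "error_rate": _pct(n, total_questions),
        "false_positive_of_errors": _pct(fp, n),
        "false_negative_of_errors": _pct(fn, n),
        "any_dissent_of_errors": _pct(any_dissent, n),
        "any_dissent_of_questions": _pct(any_dissent, total_questions),
        "dissent_2_of_errors": _pct(dissent[2], n),
        "dissent_2_of_questions": _pct(dissent[2], total_questions),
        "dissent_1_of_errors": _pct(dissent[1], n),
        "dissent_1_of_questions": _pct(dissent[1], total_questions),
        "dissent_0_of_errors": _pct(dissent[0], n),
        "dissent_0_of_questions": _pct(dissent[0], total_questions),
        "interpretation_of_errors": _pct(interp, n),
        "citation_of_errors": _pct(cit, n),
        "temporal_of_interpretation": _pct(temporal, interp),
        "qualitative_of_interpretation": _pct(qualitative, interp),
    }
    return ErrorLedger(
        total_questions=total_questions, n_errors=n, counts=counts, pct=pct, cases=list(errors)
    )
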