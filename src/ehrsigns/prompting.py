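"""Prompt construction and structured-output parsing for the classification task.

Each record yields one prompt asking six binary clinical-sign questions
(a "current" or "recently present" sign counts as present) plus a
citation task: quote supporting text verbatim, each section enclosed in
quotation marks, sections separated by whitespace, no ellipses. The
model must answer as a JSON object keyed by sign, each value carrying a
boolean ``answer`` and a ``citation`` string.

Parsing never raises on content: malformed output is conservatively
repaired when a single well-formed object can be unambiguously
recovered, and every repair or deviation is surfaced as a
:class:`ComplianceEvent`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .corpus import EHRecord
from .metrics import Verdict

DEFAULT_SIGNS = (
    "decreased appetite",
    "vomiting",
    "weight loss",
    "diarrhea",
    "constipation",
    "polyphagia",
)

_DEFAULT_TEMPLATE = """\
You are reviewing one veterinary electronic health record (EHR) for a cat.

EHR:
Admission date: {admission_date}
Presenting complaint: {presenting_complaint}
Pertinent history: {pertinent_history}

For each of the following clinical signs, determine whether the EHR
mentions the sign as present. A "current" or "recently present"
clinical sign qualifies as "present". Allowed answers are true or
false.

{question_blocks}

For every answer, cite the pertinent sections of the EHR supporting the
decision. Only copy-pasted text may be provided; enclose each text
section in quotation marks; separate different portions of text by
white space; do not use ellipses to shorten the text. If the answer is
false and no text supports the sign, leave the citation empty.

Output the response as a single JSON object, with one key per clinical
sign exactly as listed, each value an object with fields "answer"
(boolean) and "citation" (string). Output only the JSON object.
"""


@dataclass(frozen=True)
class PromptSpec:
    """The instruction template and the ordered list of clinical signs."""

    signs: tuple[str, ...] = DEFAULT_SIGNS
    template: str = _DEFAULT_TEMPLATE

    def question_blocks(self) -> str:
        return "\n".join(
            f"{i}. Is {sign} present? (true/false)" for i, sign in enumerate(self.signs, 1)
        )


@dataclass(frozen=True)
class QuestionResponse:
    """One respondent's verdict and citation for one (record, sign) question.

    ``verdict`` is ternary: True, False, or None for NA. ``run_index``
    and ``temperature`` are None for human respondents.
    """

    respondent_id: str
    record_id: str
    sign: str
    verdict: Verdict
    citation_raw: str = ""
    run_index: int | None = None
    temperature: float | None = None


@dataclass(frozen=True)
class ComplianceEvent:
    """One structured-output deviation or repair, attached to a run."""

    record_id: str
    run_key: str
    kind: str  # invalid_structure | repaired_structure | non_boolean_answer | missing_field | empty_output
    detail: str = ""


def build_prompt(record: EHRecord, spec: PromptSpec = PromptSpec()) -> str:
    """Render the prompt for one record; deterministic, fields embedded verbatim."""
    for name in ("presenting_complaint", "pertinent_history"):
        if getattr(record, name) is None:
            raise ValueError(f"record {record.record_id} missing field {name}")
    return spec.template.format(
        admission_date=record.admission_date.isoformat() if record.admission_date else "unknown",
        presenting_complaint=record.presenting_complaint,
        pertinent_history=record.pertinent_history,
        question_blocks=spec.question_blocks(),
    )


_FENCE_RE = re.compile(r"^```[a-zA-Z]*\s*|\s*```$", re.MULTILINE)
_TRAILING_SEP_RE = re.compile(r",\s*(?=[}\]])")


def _try_repair(raw: str) -> str | None:
    """Recover a single well-formed JSON object from near-miss output.

    Conservative by design: strips prose/code fences around one object,
    removes trailing separators, balances unclosed brackets at the end.
    Returns the repaired string only if it parses to a dict; otherwise
    None.
    """
    text = _FENCE_RE.sub("", raw).strip()
    start = text.find("{")
    if start == -1:
        return None
    text = text[start:]
    # trim prose after the final closing brace, if any brace closes the object
    depth = 0
    end = None
    for i, ch in enumerate(text):
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
            if depth == 0:
                end = i + 1
                break
    if end is not None:
        text = text[:end]
    else:
        # unclosed object: balance brackets at the end
        opens = text.count("{") - text.count("}")
        sq = text.count("[") - text.count("]")
        text = text.rstrip().rstrip(",") + "]" * max(sq, 0) + "}" * max(opens, 0)
    text = _TRAILING_SEP_RE.sub("", text)
    try:
        obj = json.loads(text)
    except json.JSONDecodeError:
        return None
    return text if isinstance(obj, dict) else None


def _coerce_answer(value) -> tuple[Verdict, bool]:
    """Map a raw answer to a verdict; second element flags a non-boolean."""
    if isinstance(value, bool):
        return value, False
    if isinstance(value, str) and value.strip().lower() in ("true", "false"):
        return value.strip().lower() == "true", False
    return None, True


def parse_model_output(
    raw: str,
    spec: PromptSpec,
    *,
    respondent_id: str = "model",
    record_id: str = "",
    run_index: int | None = None,
    temperature: float | None = None,
) -> tuple[list[QuestionResponse], list[ComplianceEvent]]:
    """Parse raw model output into one response per sign, plus compliance events.

    Never raises on content. Empty output, unrecoverable structure, a
    missing sign, or a non-boolean answer each produce an NA verdict for
    the affected sign(s) and exactly one event describing the deviation.
    """
    run_key = f"{respondent_id}|{record_id}|t={temperature}|run={run_index}"
    events: list[ComplianceEvent] = []

    def response(sign: str, verdict: Verdict, citation: str = "") -> QuestionResponse:
        return QuestionResponse(
            respondent_id=respondent_id,
            record_id=record_id,
            sign=sign,
            verdict=verdict,
            citation_raw=citation,
            run_index=run_index,
            temperature=temperature,
        )

    if not raw or not raw.strip():
        events.append(ComplianceEvent(record_id, run_key, "empty_output", "no text returned"))
        return [response(s, None) for s in spec.signs], events

    parsed: dict | None = None
    try:
        obj = json.loads(raw)
        if isinstance(obj, dict):
            parsed = obj
    except json.JSONDecodeError:
        pass
    if parsed is None:
        repaired = _try_repair(raw)
        if repaired is not None:
            parsed = json.loads(repaired)
            events.append(
                ComplianceEvent(record_id, run_key, "repaired_structure", "recovered one JSON object")
            )
        else:
            events.append(
                ComplianceEvent(record_id, run_key, "invalid_structure", raw[:120])
            )
            return [response(s, None) for s in spec.signs], events

    # case-insensitive sign lookup; values may be {answer, citation} or bare
    lowered = {str(k).strip().lower(): v for k, v in parsed.items()}
    out: list[QuestionResponse] = []
    for sign in spec.signs:
        if sign.lower() not in lowered:
            events.append(ComplianceEvent(record_id, run_key, "missing_field", sign))
            out.append(response(sign, None))
            continue
        value = lowered[sign.lower()]
        citation = ""
        if isinstance(value, dict):
            citation = str(value.get("citation", "") or "")
            value = value.get("answer")
        verdict, non_bool = _coerce_answer(value)
        if non_bool:
            events.append(
                ComplianceEvent(record_id, run_key, "non_boolean_answer", f"{sign}: {value!r}")
            )
        out.append(response(sign, verdict, citation))
    return out, events


@dataclass
class ComplianceSummary:
    """Structure/answer compliance rates for one respondent-temperature cell."""

    respondent_id: str
    temperature: float | None
    n_runs: int
    n_questions: int
    structure_valid_rate: float
    boolean_answer_rate: float
    na_rate: float
    events: dict[str, int] = field(default_factory=dict)


def compliance_summary(
    responses: list[QuestionResponse],
    events: list[ComplianceEvent],
) -> list[ComplianceSummary]:
    """Per (respondent, temperature) compliance rates with their denominators.

    Structure validity is assessed per run (a record at one temperature
    and run index): a run is structure-valid when it produced neither an
    ``invalid_structure`` nor a ``repaired_structure`` event. The
    boolean-answer rate is the fraction of question responses whose
    verdict is true or false (NA complements it).
    """
    if not responses:
        raise ValueError("empty response set")
    by_cell: dict[tuple[str, float | None], list[QuestionResponse]] = {}
    for r in responses:
        by_cell.setdefault((r.respondent_id, r.temperature), []).append(r)
    bad_runs: dict[str, str] = {}
    for ev in events:
        if ev.kind in ("invalid_structure", "repaired_structure", "empty_output"):
            bad_runs[ev.run_key] = ev.kind
    out = []
    for (rid, temp), rows in sorted(by_cell.items(), key=lambda kv: (kv[0][0], repr(kv[0][1]))):
        run_keys = {f"{r.respondent_id}|{r.record_id}|t={r.temperature}|run={r.run_index}" for r in rows}
        n_bad = sum(1 for k in run_keys if k in bad_runs)
        n_bool = sum(1 for r in rows if r.verdict is not None)
        cell_events: dict[str, int] = {}
        for ev in events:
            if ev.run_key in run_keys:
                cell_events[ev.kind] = cell_events.get(ev.kind, 0) + 1
        out.append(
            ComplianceSummary(
                respondent_id=rid,
                temperature=temp,
                n_runs=len(run_keys),
                n_questions=len(rows),
                structure_valid_rate=1.0 - n_bad / len(run_keys),
                boolean_answer_rate=n_bool / len(rows),
                na_rate=1.0 - n_bool / len(rows),
                events=cell_events,
            )
        )
    return out
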