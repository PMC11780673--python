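"""Readers and writers for the pipeline's plain-text interchange formats.

Corpora travel as CSV or JSON-lines with the five record fields;
responses as JSON-lines (one verdict + citation per line, verdict
serialized as ``"true"``/``"false"``/``"NA"``); exclusion logs, metric
tables, and ambiguity labels as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .corpus import EHRecord, ExclusionLog
from .errors import ErrorLedger
from .metrics import MetricEstimate, PanelSummary
from .prompting import ComplianceEvent, QuestionResponse

__all__ = [
    "read_corpus",
    "write_corpus",
    "read_responses",
    "write_responses",
    "write_exclusion_log",
    "read_ambiguity_labels",
    "write_metrics_csv",
    "write_summary_csv",
    "write_ledger",
    "write_events",
]

_CORPUS_FIELDS = ["record_id", "patient_id", "admission_date", "presenting_complaint", "pertinent_history"]


def read_corpus(path: str | Path) -> list[dict]:
    """Raw record rows from CSV or JSON-lines (extension-sniffed), unvalidated.

    Feed the result to :func:`ehrsigns.corpus.load_and_filter_corpus`,
    which owns validation and exclusion logging.
    """
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        rows = []
        with path.open() as fh:
            for line in fh:
                if line.strip():
                    rows.append(json.loads(line))
        return rows
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.to_dict(orient="records")


def write_corpus(records: Iterable[EHRecord], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "record_id": r.record_id,
            "patient_id": r.patient_id,
            "admission_date": r.admission_date.isoformat() if r.admission_date else "",
            "presenting_complaint": r.presenting_complaint,
            "pertinent_history": r.pertinent_history,
        }
        for r in records
    ]
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with path.open("w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        pd.DataFrame(rows, columns=_CORPUS_FIELDS).to_csv(path, index=False)


def _verdict_str(v: bool | None) -> str:
    return "NA" if v is None else ("true" if v else "false")


def _verdict_parse(s: str) -> bool | None:
    s = s.strip().lower()
    if s in ("true", "false"):
        return s == "true"
    return None


def write_responses(responses: Iterable[QuestionResponse], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in responses:
            fh.write(
                json.dumps(
                    {
                        "respondent_id": r.respondent_id,
                        "record_id": r.record_id,
                        "sign": r.sign,
                        "verdict": _verdict_str(r.verdict),
                        "citation_raw": r.citation_raw,
                        "run_index": r.run_index,
                        "temperature": r.temperature,
                    }
                )
                + "\n"
            )


def read_responses(path: str | Path) -> list[QuestionResponse]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            row = json.loads(line)
            out.append(
                QuestionResponse(
                    respondent_id=row["respondent_id"],
                    record_id=row["record_id"],
                    sign=row["sign"],
                    verdict=_verdict_parse(str(row.get("verdict", "NA"))),
                    citation_raw=row.get("citation_raw", "") or "",
                    run_index=row.get("run_index"),
                    temperature=row.get("temperature"),
                )
            )
    return out


def write_exclusion_log(log: ExclusionLog, path: str | Path) -> None:
    pd.DataFrame(log.entries, columns=["record_id", "reason"]).to_csv(path, index=False)


def read_ambiguity_labels(path: str | Path) -> dict[tuple[str, str], str]:
    df = pd.read_csv(path, dtype=str)
    return {(row.record_id, row.sign): row.ambiguity for row in df.itertuples()}


def write_metrics_csv(
    per_sign: Mapping[str, Mapping[str, MetricEstimate]], path: str | Path
) -> None:
    rows = []
    for sign, metrics in per_sign.items():
        for est in metrics.values():
            rows.append(
                {
                    "sign": sign,
                    "metric": est.name,
                    "value": est.value,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "k": est.k,
                    "n": est.n,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary_csv(summary: Mapping[str, PanelSummary], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "metric": s.metric,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "n_defined": s.n_defined,
                "n_undefined": s.n_undefined,
            }
            for s in summary.values()
        ]
    ).to_csv(path, index=False)


def write_ledger(ledger: ErrorLedger, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    pd.DataFrame(
        [
            {
                "record_id": c.record_id,
                "sign": c.sign,
                "error_type": c.error_type,
                "dissent_count": c.dissent_count,
                "discrepancy": c.discrepancy,
                "ambiguity": c.ambiguity,
            }
            for c in ledger.cases
        ]
    ).to_csv(csv_path, index=False)
    if json_path:
        Path(json_path).write_text(
            json.dumps(
                {
                    "total_questions": ledger.total_questions,
                    "n_errors": ledger.n_errors,
                    "counts": ledger.counts,
                    "pct": ledger.pct,
                },
                indent=2,
            )
        )


def write_events(events: Iterable[ComplianceEvent], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for ev in events:
            fh.write(
                json.dumps(
                    {"record_id": ev.record_id, "run_key": ev.run_key, "kind": ev.kind, "detail": ev.detail}
                )
                + "\n"
            )
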