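"""Corpus ingestion, exclusion rules, and study-design sample size.

A corpus is a list of :class:`EHRecord` — one veterinary visit reduced to
the three fields shown to respondents: admission date, presenting
complaint, and the free-text pertinent history. Records with an empty
history carry no classifiable text and are excluded; a patient may
contribute at most one record so that questions are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Iterator

from scipy.stats import norm

__all__ = [
    "EHRecord",
    "StudyDesignParams",
    "ExclusionLog",
    "CorpusSummary",
    "required_sample_size",
    "load_and_filter_corpus",
    "corpus_summary",
]


@dataclass(frozen=True)
class EHRecord:
    """One clinical record: identifiers plus the three respondent-visible fields."""

    record_id: str
    patient_id: str
    admission_date: date | None
    presenting_complaint: str
    pertinent_history: str

    @property
    def visible_text(self) -> str:
        """Concatenation of the fields respondents may quote from."""
        return f"{self.presenting_complaint}\n{self.pertinent_history}"


@dataclass(frozen=True)
class StudyDesignParams:
    """Inputs to the sensitivity-precision sample-size calculation.

    Parameters
    ----------
    sensitivity
        Expected sensitivity of the test under evaluation, in (0, 1).
    margin
        Acceptable half-width of the confidence interval (margin of
        error), in (0, 1).
    prevalence
        Expected prevalence of the condition, in (0, 1]. The required
        number of condition-positive records is inflated by 1/prevalence
        to obtain a total corpus size.
    confidence
        Two-sided confidence level, in (0, 1); mapped to the standard
        normal critical value z.
    """

    sensitivity: float
    margin: float
    prevalence: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        for name, value, closed_top in (
            ("sensitivity", self.sensitivity, False),
            ("margin", self.margin, False),
            ("prevalence", self.prevalence, True),
            ("confidence", self.confidence, False),
        ):
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            hi_ok = value <= 1.0 if closed_top else value < 1.0
            if not (0.0 < value and hi_ok):
                bound = "(0, 1]" if closed_top else "(0, 1)"
                raise ValueError(f"{name} must lie in {bound}, got {value!r}")

    @property
    def z(self) -> float:
        """Standard-normal critical value for the two-sided confidence level."""
        return float(norm.ppf(1.0 - (1.0 - self.confidence) / 2.0))


def required_sample_size(params: StudyDesignParams) -> int:
    """Total records needed to estimate sensitivity to the stated precision.

    Uses the standard precision formula for a single diagnostic test:
    the number of condition-positive records is

        n_pos = z^2 * Se * (1 - Se) / d^2

    and the total is n_pos / prevalence, with the ceiling applied once,
    at the end. With the defaults of a 95% confidence level, expected
    sensitivity 0.95, margin 0.07 and prevalence 0.15 this yields 249.
    """
    z = params.z
    n_pos = z * z * params.sensitivity * (1.0 - params.sensitivity) / params.margin**2
    return math.ceil(n_pos / params.prevalence)


@dataclass
class ExclusionLog:
    """Per-record exclusion reasons accumulated during filtering."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, record_id: str, reason: str) -> None:
        self.entries.append((record_id, reason))

    def __len__(self) -> int:
        return len(self.entries)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.entries:
            out[reason] = out.get(reason, 0) + 1
        return out


def load_and_filter_corpus(
    source: Iterable[EHRecord | dict],
) -> tuple[list[EHRecord], ExclusionLog]:
    """Apply the corpus exclusion rules to a stream of records.

    Rules, in order per record: unparseable rows are logged as
    ``malformed``; records whose pertinent history is empty or
    whitespace-only are logged as ``empty_history``; a second record for
    an already-seen patient is logged as ``duplicate_patient`` (the
    earliest-sampled record is kept — resampling a replacement is the
    caller's loop). Nothing is dropped silently: kept + excluded always
    equals the input size.
    """
    kept: list[EHRecord] = []
    log = ExclusionLog()
    seen_patients: set[str] = set()
    for i, raw in enumerate(source):
        try:
            rec = raw if isinstance(raw, EHRecord) else _coerce_record(raw)
        except Exception as exc:  # noqa: BLE001 - logged, never silent
            rid = raw.get("record_id", f"<row {i}>") if isinstance(raw, dict) else f"<row {i}>"
            log.add(str(rid), f"malformed: {exc}")
            continue
        if not rec.pertinent_history.strip():
            log.add(rec.record_id, "empty_history")
            continue
        if rec.patient_id in seen_patients:
            log.add(rec.record_id, "duplicate_patient")
            continue
        seen_patients.add(rec.patient_id)
        kept.append(rec)
    return kept, log


def _coerce_record(row: dict) -> EHRecord:
    missing = [k for k in ("record_id", "patient_id", "pertinent_history") if k not in row]
    if missing:
        raise ValueError(f"missing fields: {', '.join(missing)}")
    adm = row.get("admission_date")
    if isinstance(adm, str) and adm:
        adm = date.fromisoformat(adm)
    elif not isinstance(adm, date):
        adm = None
    return EHRecord(
        record_id=str(row["record_id"]),
        patient_id=str(row["patient_id"]),
        admission_date=adm,
        presenting_complaint=str(row.get("presenting_complaint", "") or ""),
        pertinent_history=str(row["pertinent_history"]),
    )


@dataclass(frozen=True)
class CorpusSummary:
    n: int
    word_length_min: int
    word_length_max: int
    word_length_median: float
    date_range: tuple[date, date] | None


def corpus_summary(records: list[EHRecord]) -> CorpusSummary:
    """Summary statistics over a corpus: size, history word lengths, date span.

    Word length is the count of whitespace-delimited tokens of the
    pertinent history only.
    """
    if not records:
        raise ValueError("corpus is empty")
    lengths = sorted(len(r.pertinent_history.split()) for r in records)
    n = len(lengths)
    mid = n // 2
    median = float(lengths[mid]) if n % 2 else (lengths[mid - 1] + lengths[mid]) / 2.0
    dates = [r.admission_date for r in records if r.admission_date is not None]
    return CorpusSummary(
        n=n,
        word_length_min=lengths[0],
        word_length_max=lengths[-1],
        word_length_median=median,
        date_range=(min(dates), max(dates)) if dates else None,
    )


def iter_questions(records: list[EHRecord], signs: list[str]) -> Iterator[tuple[str, str]]:
    """All (record_id, sign) question keys for a corpus, in corpus order."""
    for rec in records:
        for sign in signs:
            yield rec.record_id, sign
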