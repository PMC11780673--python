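"""Citation parsing and verbatim verification against the EHR text.

Respondents were instructed to support each verdict with copy-pasted
text: each section enclosed in quotation marks, sections separated by
whitespace, no ellipses. This module extracts the quoted segments,
checks the format rules, and classifies how faithfully each segment
reproduces the source through an ordered normalization ladder::

    exact > case_only > punct_space > shortened > scaffold_included
          > paraphrase > unmatched

The first level that fires is returned. ``exact`` means the citation is
a contiguous substring of the EHR text; ``unmatched`` segments are
hallucination candidates (text not present in the record at any
normalization level). A response is citation-compliant only when it has
zero format violations and every segment matches at level ``exact``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .corpus import EHRecord
from .prompting import QuestionResponse

LADDER_LEVELS = (
    "exact",
    "case_only",
    "punct_space",
    "shortened",
    "scaffold_included",
    "paraphrase",
    "unmatched",
)

DEFAULT_SCAFFOLD_STRINGS = (
    "pertinent history:",
    "presenting complaint:",
    "admission date:",
    "citation:",
)

_ELLIPSIS_RE = re.compile(r"\.\.\.|…")
_TYPOGRAPHIC = {"“": '"', "”": '"', "‘": "'", "’": "'"}

__all__ = [
    "CitationSet",
    "MatchVerdict",
    "MatchThresholds",
    "AuditResult",
    "extract_citations",
    "match_citation",
    "audit_panel",
]


@dataclass(frozen=True)
class MatchThresholds:
    """Tunable knobs of the matching ladder.

    ``paraphrase_similarity`` is the minimum token containment
    (shared normalized tokens / segment tokens) for the paraphrase
    level; scaffold strings are question/field-name fragments that are
    stripped before re-trying an exact match.
    """

    paraphrase_similarity: float = 0.5
    scaffold_strings: tuple[str, ...] = DEFAULT_SCAFFOLD_STRINGS


@dataclass
class CitationSet:
    """Quoted segments parsed from one citation field, plus format violations."""

    raw: str
    segments: list[str] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)  # subset of {unquoted, no_whitespace_separation, ellipsis_used}


@dataclass(frozen=True)
class MatchVerdict:
    level: str
    interval: tuple[int, int] | None = None
    detail: str = ""


def _normalize_quotes(text: str) -> str:
    for src, dst in _TYPOGRAPHIC.items():
        text = text.replace(src, dst)
    return text


def extract_citations(raw: str) -> CitationSet:
    """Parse quote-delimited segments and flag format violations.

    An empty field is compliant by vacuity (no segments, no
    violations). Text outside quotes, adjacent quotes without
    whitespace separation, ellipses inside a segment, and unbalanced
    quotes each raise a violation; extraction is best-effort throughout.
    """
    cs = CitationSet(raw=raw)
    if not raw or not raw.strip():
        return cs
    text = _normalize_quotes(raw)
    parts = text.split('"')
    balanced = len(parts) % 2 == 1
    if not balanced:
        cs.violations.append("unquoted")  # unbalanced quotes: best-effort extraction
    for i, part in enumerate(parts):
        inside = i % 2 == 1
        if inside:
            if part.strip():
                cs.segments.append(part)
            if _ELLIPSIS_RE.search(part):
                if "ellipsis_used" not in cs.violations:
                    cs.violations.append("ellipsis_used")
        else:
            if part.strip():
                if "unquoted" not in cs.violations:
                    cs.violations.append("unquoted")
            elif part == "" and 0 < i < len(parts) - 1:
                # two quoted segments back-to-back with no separator
                if "no_whitespace_separation" not in cs.violations:
                    cs.violations.append("no_whitespace_separation")
    return cs


_WORD_RE = re.compile(r"\S+")
_STRIP_RE = re.compile(r"[^0-9a-z]+")


def _norm_token(tok: str) -> str:
    return _STRIP_RE.sub("", tok.casefold())


def _tokens_with_offsets(text: str) -> list[tuple[str, int, int]]:
    out = []
    for m in _WORD_RE.finditer(text):
        norm = _norm_token(m.group())
        if norm:
            out.append((norm, m.start(), m.end()))
    return out


def _subsequence_match(
    needle: list[str], hay: list[tuple[str, int, int]]
) -> tuple[list[int], bool] | None:
    """Greedy ordered-subsequence match; returns matched hay indices and contiguity."""
    idxs: list[int] = []
    pos = 0
    for tok in needle:
        while pos < len(hay) and hay[pos][0] != tok:
            pos += 1
        if pos == len(hay):
            return None
        idxs.append(pos)
        pos += 1
    contiguous = all(b - a == 1 for a, b in zip(idxs, idxs[1:]))
    return idxs, contiguous


def _find_contiguous(needle: list[str], hay: list[tuple[str, int, int]]) -> tuple[int, int] | None:
    n = len(needle)
    for start in range(len(hay) - n + 1):
        if all(hay[start + j][0] == needle[j] for j in range(n)):
            return hay[start][1], hay[start + n - 1][2]
    return None


def match_citation(
    segment: str,
    ehr_text: str,
    thresholds: MatchThresholds = MatchThresholds(),
) -> MatchVerdict:
    """Classify one quoted segment against the EHR text via the ladder.

    Levels are tried in order and the first that fires wins; an exact
    substring therefore never reports a weaker level. Matched character
    intervals (in ``ehr_text``) are returned where the level pins one
    down; paraphrase and unmatched carry no interval.
    """
    if not segment.strip():
        raise ValueError("empty citation segment")
    seg = _normalize_quotes(segment).strip()

    idx = ehr_text.find(seg)
    if idx != -1:
        return MatchVerdict("exact", (idx, idx + len(seg)))

    idx = ehr_text.lower().find(seg.lower())
    if idx != -1:
        return MatchVerdict("case_only", (idx, idx + len(seg)))

    seg_tokens = [t for t, _, _ in _tokens_with_offsets(seg)]
    ehr_tokens = _tokens_with_offsets(ehr_text)
    if seg_tokens:
        interval = _find_contiguous(seg_tokens, ehr_tokens)
        if interval is not None:
            return MatchVerdict("punct_space", interval)
        sub = _subsequence_match(seg_tokens, ehr_tokens)
        if sub is not None:
            idxs, _ = sub
            return MatchVerdict(
                "shortened",
                (ehr_tokens[idxs[0]][1], ehr_tokens[idxs[-1]][2]),
                detail=f"{len(seg_tokens)} of {idxs[-1] - idxs[0] + 1} source tokens",
            )

    stripped = seg
    for scaffold in thresholds.scaffold_strings:
        stripped = re.sub(re.escape(scaffold), " ", stripped, flags=re.IGNORECASE)
    stripped = stripped.strip(" :;-\t\n")
    if stripped and stripped != seg:
        idx = ehr_text.find(stripped)
        if idx == -1:
            idx = ehr_text.lower().find(stripped.lower())
        if idx != -1:
            return MatchVerdict("scaffold_included", (idx, idx + len(stripped)))

    if seg_tokens:
        ehr_set = {t for t, _, _ in ehr_tokens}
        shared = sum(1 for t in set(seg_tokens) if t in ehr_set)
        similarity = shared / len(set(seg_tokens))
        if similarity >= thresholds.paraphrase_similarity:
            return MatchVerdict("paraphrase", None, detail=f"token containment {similarity:.2f}")

    return MatchVerdict("unmatched")


@dataclass
class AuditResult:
    """Panel-wide citation audit: per-cell rates, ladder histogram, hallucinations."""

    table: pd.DataFrame  # respondent, temperature, n_responses, compliance_rate, per-level counts
    hallucinations: list[dict] = field(default_factory=list)
    per_response: pd.DataFrame | None = None


def audit_panel(
    responses: Iterable[QuestionResponse],
    records: Mapping[str, EHRecord],
    thresholds: MatchThresholds = MatchThresholds(),
) -> AuditResult:
    """Audit every response's citations against its record.

    A response is compliant iff its citation field has zero format
    violations and every segment matches at level ``exact``; a response
    with no citation commits no violation and counts as compliant.
    Responses containing any ``unmatched`` segment are collected as
    hallucination candidates.
    """
    rows = []
    hallucinations = []
    for resp in responses:
        if resp.record_id not in records:
            raise KeyError(f"response references unknown record {resp.record_id!r}")
        text = records[resp.record_id].visible_text
        cs = extract_citations(resp.citation_raw)
        verdicts = [match_citation(seg, text, thresholds) for seg in cs.segments]
        levels = [v.level for v in verdicts]
        compliant = not cs.violations and all(lv == "exact" for lv in levels)
        row = {
            "respondent_id": resp.respondent_id,
            "temperature": resp.temperature,
            "record_id": resp.record_id,
            "sign": resp.sign,
            "n_segments": len(cs.segments),
            "violations": ";".join(cs.violations),
            "compliant": compliant,
        }
        for lv in LADDER_LEVELS:
            row[lv] = levels.count(lv)
        rows.append(row)
        if "unmatched" in levels:
            hallucinations.append(
                {
                    "respondent_id": resp.respondent_id,
                    "temperature": resp.temperature,
                    "record_id": resp.record_id,
                    "sign": resp.sign,
                    "segments": [s for s, v in zip(cs.segments, verdicts) if v.level == "unmatched"],
                }
            )
    per_response = pd.DataFrame(rows)
    if per_response.empty:
        raise ValueError("no responses to audit")
    grouped = (
        per_response.assign(
            temperature=pd.to_numeric(per_response["temperature"], errors="coerce").fillna(-1.0)
        )
        .groupby(["respondent_id", "temperature"], as_index=False)
        .agg(
            n_responses=("compliant", "size"),
            compliance_rate=("compliant", "mean"),
            **{lv: (lv, "sum") for lv in LADDER_LEVELS},
        )
    )
    grouped["temperature"] = grouped["temperature"].replace(-1.0, float("nan"))
    return AuditResult(table=grouped, hallucinations=hallucinations, per_response=per_response)
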