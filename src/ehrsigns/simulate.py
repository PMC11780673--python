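"""Synthetic corpora, human panels, and machine-annotator runs.

The generator emulates the statistical structure the evaluation
pipeline assumes, without any language model: template-based record
text with exact gold citation spans; a five-human panel whose
disagreement is driven entirely by temporal/qualitative ambiguity; and
a machine annotator whose five runs per temperature share a per-question
base answer and diverge only through temperature-dependent run-level
flips — reproducing the observation that model self-agreement exceeds
human-human agreement even at high temperature.

All randomness flows from ``SimConfig.seed`` through a named generator
per stage (corpus / humans / machine), so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus import EHRecord
from .metrics import Verdict
from .prompting import DEFAULT_SIGNS, QuestionResponse

QuestionKey = tuple[str, str]

__all__ = [
    "SimConfig",
    "QuestionTruth",
    "LatentTruth",
    "generate_corpus",
    "simulate_human_panel",
    "simulate_llm_runs",
    "apply_deviation",
    "export_ground_truth",
    "ambiguity_labels",
]

# Sentence templates per sign. Three classes: a clear current sign, a
# temporally ambiguous (historic / dated) description, and a
# qualitatively equivocal description. A subset of absent signs gets an
# explicit negation. Tokens deliberately avoid the scaffold vocabulary
# ("pertinent", field names) and the reserved paraphrase words below so
# that every injected citation deviation resolves at its intended
# ladder level.
_CLEAR = {
    "decreased appetite": "the cat has been eating much less than usual this week.",
    "vomiting": "owner reports vomiting almost daily for the last five days.",
    "weight loss": "the cat has lost weight steadily over the past month.",
    "diarrhea": "liquid diarrhea noted in the litter box every morning.",
    "constipation": "straining with no feces produced for the last two days.",
    "polyphagia": "the cat is ravenous and begs for food constantly.",
}
_TEMPORAL = {
    "decreased appetite": "appetite was poor around the dental visit early last year.",
    "vomiting": "episodes of vomiting were noted at a visit two years ago.",
    "weight loss": "weight 6/30/01 16.5 lb, weight 11/00 20.5 lb.",
    "diarrhea": "diarrhea resolved after the diet change several months ago.",
    "constipation": "treated for constipation once in 2019 with no recurrence since.",
    "polyphagia": "was polyphagic at a previous visit but eating less after treatment.",
}
_QUALITATIVE = {
    "decreased appetite": "picky with dry food but finishes wet food most evenings.",
    "vomiting": "owner found a spit-up pill on the ground yesterday.",
    "weight loss": "feels a bit bonier along the spine per owner.",
    "diarrhea": "stool softer than normal at times, formed on most days.",
    "constipation": "one bowel movement of hard crusty feces covered with a softer outer layer.",
    "polyphagia": "finishes meals quickly and sometimes asks for more food.",
}
_NEGATION = {
    "decreased appetite": "appetite remains normal per owner.",
    "vomiting": "no vomiting reported at home.",
    "weight loss": "weight stable since last visit.",
    "diarrhea": "no diarrhea observed in the box.",
    "constipation": "stools normal in frequency and consistency.",
    "polyphagia": "no increase in hunger between meals.",
}
_FILLERS = (
    "indoor only cat with vaccinations current.",
    "drinking water as usual at home.",
    "lives with one other healthy cat.",
    "adopted from the local shelter in spring.",
    "no coughing or sneezing at home.",
    "grooming and activity unchanged per owner.",
)
_COMPLAINTS = ("recheck visit", "annual exam", "not doing well", "gi signs", "referral evaluation")

# Words guaranteed absent from all templates; used to fabricate
# paraphrase deviations whose replaced tokens cannot occur in a record.
RESERVED_PARAPHRASE_WORDS = ("seemingly", "intermittent", "perceived", "subjectively")

DEVIATION_LEVELS = ("case_only", "punct_space", "shortened", "paraphrase", "scaffold_included")


def _default_human_deviations() -> dict[str, float]:
    return {
        "case_only": 0.04,
        "punct_space": 0.04,
        "shortened": 0.02,
        "paraphrase": 0.01,
        "scaffold_included": 0.01,
    }


def _default_machine_deviations() -> dict[str, float]:
    return {
        "case_only": 0.01,
        "punct_space": 0.01,
        "shortened": 0.005,
        "paraphrase": 0.002,
        "scaffold_included": 0.002,
    }


def _default_flip_rates() -> dict[float, float]:
    # chosen so mean run-pair kappa lands near 0.98 / 0.96 / 0.93 at
    # temperatures 0 / 0.5 / 1 under the default base-rate structure
    return {0.0: 0.002, 0.5: 0.006, 1.0: 0.012}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic panels.

    Defaults mirror the evaluated study: 250 records, six signs at 15%
    per-sign prevalence, five human respondents, and five machine runs
    at each of temperatures 0 / 0.5 / 1 with a run-to-run flip rate
    non-decreasing in temperature. Ambiguity prevalences and error
    rates are illustrative magnitudes chosen so that machine-vs-human
    disagreement lands at a few percent of questions; they are knobs,
    not fitted quantities.
    """

    n_records: int = 250
    signs: tuple[str, ...] = DEFAULT_SIGNS
    prevalence: float = 0.15
    p_temporal: float = 0.15  # P(temporal ambiguity | sign signal)
    p_qualitative: float = 0.10  # P(qualitative ambiguity | sign signal)
    negation_rate: float = 0.3  # P(explicit negation | sign absent)
    # human panel
    n_humans: int = 5
    eps_human: float = 0.01  # error rate on unambiguous questions
    pi_human: float = 0.5  # P(true) on ambiguous questions, per respondent
    mu_human: float = 0.10  # P(no citation | true verdict with a gold span)
    human_deviation_probs: dict[str, float] = field(default_factory=_default_human_deviations)
    # machine annotator
    eps_machine: float = 0.01
    pi_machine: float = 0.8  # true-bias on ambiguous questions -> FP-dominated errors
    mu_machine: float = 0.02
    machine_deviation_probs: dict[str, float] = field(default_factory=_default_machine_deviations)
    flip_rates: dict[float, float] = field(default_factory=_default_flip_rates)
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.prevalence, self.p_temporal, self.p_qualitative, self.negation_rate,
            self.eps_human, self.pi_human, self.mu_human, self.eps_machine,
            self.pi_machine, self.mu_machine,
            *self.human_deviation_probs.values(), *self.machine_deviation_probs.values(),
            *self.flip_rates.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        temps = sorted(self.flip_rates)
        rates = [self.flip_rates[t] for t in temps]
        if any(b < a for a, b in zip(rates, rates[1:])):
            raise ValueError("run-to-run flip rate must be non-decreasing in temperature")
        if self.p_temporal + self.p_qualitative > 1.0:
            raise ValueError("ambiguity probabilities must sum to at most 1")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "SimConfig":
        """Load a config from a YAML mapping; keyword overrides win."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of SimConfig fields")
        if "signs" in data:
            data["signs"] = tuple(data["signs"])
        if "flip_rates" in data:
            data["flip_rates"] = {float(k): float(v) for k, v in data["flip_rates"].items()}
        data.update(overrides)
        return cls(**data)


@dataclass(frozen=True)
class QuestionTruth:
    status: str  # present | historic | absent
    ambiguity: str  # temporal | qualitative | none
    span: tuple[int, int] | None  # gold citation interval in the record's visible text


@dataclass
class LatentTruth:
    questions: dict[QuestionKey, QuestionTruth] = field(default_factory=dict)

    def expected_verdict(self, key: QuestionKey) -> Verdict:
        """Ground-truth verdict; None for ambiguous questions (no single truth)."""
        t = self.questions[key]
        if t.ambiguity != "none":
            return None
        return t.status == "present"


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def generate_corpus(config: SimConfig) -> tuple[list[EHRecord], LatentTruth]:
    """Template-assembled records with exact gold spans, determined by the seed.

    Per (record, sign): a sign signal is drawn at the configured
    prevalence; a signal is rendered as a clear-present, temporally
    ambiguous (historic/dated), or qualitatively equivocal sentence per
    the ambiguity probabilities. A subset of absent signs gets an
    explicit negation sentence (no gold span — negative verdicts cite
    nothing). Sentences are shuffled among filler text; spans are
    recorded in the record's visible text (complaint + history).
    """
    for sign in config.signs:
        if sign not in _CLEAR:
            raise ValueError(f"no sentence templates for sign {sign!r}")
    rng = _rng(config.seed, 0)
    records: list[EHRecord] = []
    truth = LatentTruth()
    for i in range(config.n_records):
        record_id = f"R{i:05d}"
        complaint = str(rng.choice(_COMPLAINTS))
        n_fill = int(rng.integers(1, 4))
        sentences = list(rng.choice(_FILLERS, size=n_fill, replace=False))
        drawn: dict[str, QuestionTruth] = {}
        sign_sentence: dict[str, str] = {}
        for sign in config.signs:
            if rng.random() < config.prevalence:
                u = rng.random()
                if u < config.p_temporal:
                    status, ambiguity, sentence = "historic", "temporal", _TEMPORAL[sign]
                elif u < config.p_temporal + config.p_qualitative:
                    status, ambiguity, sentence = "present", "qualitative", _QUALITATIVE[sign]
                else:
                    status, ambiguity, sentence = "present", "none", _CLEAR[sign]
                sentences.append(sentence)
                sign_sentence[sign] = sentence
                drawn[sign] = QuestionTruth(status, ambiguity, None)
            else:
                if rng.random() < config.negation_rate:
                    sentences.append(_NEGATION[sign])
                drawn[sign] = QuestionTruth("absent", "none", None)
        rng.shuffle(sentences)
        history = " ".join(sentences)
        adm = date(
            int(1991 + rng.integers(0, 33)), int(rng.integers(1, 13)), int(rng.integers(1, 29))
        )
        record = EHRecord(
            record_id=record_id,
            patient_id=f"P{i:05d}",
            admission_date=adm,
            presenting_complaint=complaint,
            pertinent_history=history,
        )
        records.append(record)
        offset = len(complaint) + 1  # complaint + "\n"
        for sign in config.signs:
            qt = drawn[sign]
            if sign in sign_sentence:
                start = offset + history.index(sign_sentence[sign])
                qt = QuestionTruth(qt.status, qt.ambiguity, (start, start + len(sign_sentence[sign])))
            truth.questions[(record_id, sign)] = qt
    return records, truth


def apply_deviation(
    span_text: str, level: str, ehr_text: str, rng: np.random.Generator
) -> str:
    """Perturb a gold span so it resolves at exactly the requested ladder level.

    ``exact`` returns the span unchanged. The constructions are chosen
    so that every earlier ladder level provably fails: e.g. a shortened
    citation drops an interior token (never the edges), a paraphrase
    replaces interior tokens with reserved words that occur in no
    template.
    """
    if level == "exact":
        return span_text
    if level == "case_only":
        for cand in (span_text.title(), span_text.upper(), span_text.swapcase()):
            if cand != span_text and cand not in ehr_text:
                return cand
        raise ValueError(f"cannot build case deviation for {span_text!r}")
    if level == "punct_space":
        # interior double spacing: exact and case-insensitive substring
        # checks fail, token-level normalization still matches contiguously
        if len(span_text.split()) < 2:
            raise ValueError("span too short for a spacing deviation")
        return "  ".join(span_text.split())
    toks = span_text.split()
    if level == "shortened":
        if len(toks) < 4:
            raise ValueError("span too short to shorten safely")
        drop = len(toks) // 2
        return " ".join(toks[:drop] + toks[drop + 1 :])
    if level == "paraphrase":
        if len(toks) < 5:
            raise ValueError("span too short to paraphrase safely")
        positions = [1, 3]
        words = rng.choice(RESERVED_PARAPHRASE_WORDS, size=2, replace=False)
        for pos, word in zip(positions, words):
            toks[pos] = str(word)
        return " ".join(toks)
    if level == "scaffold_included":
        return f"pertinent history: {span_text}"
    raise ValueError(f"unknown deviation level {level!r}")


def _draw_deviation(probs: Mapping[str, float], rng: np.random.Generator) -> str:
    u = rng.random()
    acc = 0.0
    for level in DEVIATION_LEVELS:
        acc += probs.get(level, 0.0)
        if u < acc:
            return level
    return "exact"


def _citation_for(
    verdict: Verdict,
    qt: QuestionTruth,
    ehr_text: str,
    miss_prob: float,
    deviation_probs: Mapping[str, float],
    rng: np.random.Generator,
) -> str:
    """True verdicts cite the gold span (possibly perturbed); false cite nothing."""
    if verdict is not True or qt.span is None:
        return ""
    if rng.random() < miss_prob:
        return ""
    span_text = ehr_text[qt.span[0] : qt.span[1]]
    level = _draw_deviation(deviation_probs, rng)
    return f'"{apply_deviation(span_text, level, ehr_text, rng)}"'


def simulate_human_panel(
    records: list[EHRecord],
    truth: LatentTruth,
    config: SimConfig,
    n_respondents: int | None = None,
) -> list[QuestionResponse]:
    """Five blinded humans: correct up to ε_h on clear questions, split on ambiguous ones.

    On unambiguous questions each respondent answers correctly with
    probability 1-ε_h; on ambiguous questions each independently
    answers true with probability π_h — this is the dissent engine that
    drives interobserver disagreement. True verdicts cite the gold span
    with probability 1-μ, with configured citation deviations.
    """
    n_resp = n_respondents or config.n_humans
    rng = _rng(config.seed, 1)
    responses: list[QuestionResponse] = []
    for r_idx in range(n_resp):
        respondent = f"human_{r_idx + 1}"
        for record in records:
            text = record.visible_text
            for sign in config.signs:
                qt = truth.questions[(record.record_id, sign)]
                if qt.ambiguity == "none":
                    correct = qt.status == "present"
                    verdict = correct if rng.random() >= config.eps_human else not correct
                else:
                    verdict = bool(rng.random() < config.pi_human)
                citation = _citation_for(
                    verdict, qt, text, config.mu_human, config.human_deviation_probs, rng
                )
                responses.append(
                    QuestionResponse(
                        respondent_id=respondent,
                        record_id=record.record_id,
                        sign=sign,
                        verdict=verdict,
                        citation_raw=citation,
                    )
                )
    return responses


def simulate_llm_runs(
    records: list[EHRecord], truth: LatentTruth, config: SimConfig
) -> list[QuestionResponse]:
    """Machine runs: one base answer per question, flipped per run at rate δ(T).

    The base answer is drawn once per question (error ε_m on
    unambiguous questions; true with probability π_m on ambiguous
    ones); each of the ``repeats`` runs at temperature T independently
    flips it with probability δ(T). Because runs share the base answer,
    run-pair agreement stays high even when the base answer is wrong —
    the within-model correlation the study observed.
    """
    rng = _rng(config.seed, 2)
    temperatures = sorted(config.flip_rates)
    responses: list[QuestionResponse] = []
    for record in records:
        text = record.visible_text
        for sign in config.signs:
            qt = truth.questions[(record.record_id, sign)]
            if qt.ambiguity == "none":
                correct = qt.status == "present"
                base = correct if rng.random() >= config.eps_machine else not correct
            else:
                base = bool(rng.random() < config.pi_machine)
            for temperature in temperatures:
                delta = config.flip_rates[temperature]
                for run in range(config.repeats):
                    verdict = (not base) if rng.random() < delta else base
                    citation = _citation_for(
                        verdict, qt, text, config.mu_machine, config.machine_deviation_probs, rng
                    )
                    responses.append(
                        QuestionResponse(
                            respondent_id="llm",
                            record_id=record.record_id,
                            sign=sign,
                            verdict=verdict,
                            citation_raw=citation,
                            run_index=run,
                            temperature=temperature,
                        )
                    )
    return responses


def ambiguity_labels(truth: LatentTruth) -> dict[QuestionKey, str]:
    """Adjudication-style labels for the ambiguous questions only."""
    return {k: t.ambiguity for k, t in truth.questions.items() if t.ambiguity != "none"}


def export_ground_truth(
    truth: LatentTruth,
    labels_path: str | None = None,
    truth_path: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ambiguity-label table (ambiguous questions only) and the full truth table."""
    labels = pd.DataFrame(
        [
            {"record_id": rid, "sign": sign, "ambiguity": t.ambiguity}
            for (rid, sign), t in truth.questions.items()
            if t.ambiguity != "none"
        ],
        columns=["record_id", "sign", "ambiguity"],
    )
    table = pd.DataFrame(
        [
            {
                "record_id": rid,
                "sign": sign,
                "status": t.status,
                "ambiguity": t.ambiguity,
                "span_start": t.span[0] if t.span else pd.NA,
                "span_end": t.span[1] if t.span else pd.NA,
            }
            for (rid, sign), t in truth.questions.items()
        ],
        columns=["record_id", "sign", "status", "ambiguity", "span_start", "span_end"],
    )
    if labels_path:
        labels.to_csv(labels_path, index=False)
    if truth_path:
        table.to_csv(truth_path, index=False)
    return labels, table
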