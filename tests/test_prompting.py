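"""Prompt rendering, structured-output parsing/repair, and the panel runner."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrsigns.backends import FailingBackend, MockBackend
from ehrsigns.prompting import (
    DEFAULT_SIGNS,
    PromptSpec,
    build_prompt,
    compliance_summary,
    parse_model_output,
)
from ehrsigns.runner import RunConfig, run_panel

from conftest import make_record

SPEC = PromptSpec()


def well_formed(verdicts, citation=""):
    return json.dumps(
        {sign: {"answer": v, "citation": citation} for sign, v in zip(SPEC.signs, verdicts)}
    )


class TestBuildPrompt:
    def test_deterministic(self, record):
        assert build_prompt(record, SPEC) == build_prompt(record, SPEC)

    def test_embeds_record_fields_verbatim(self):
        rec = make_record(history="vomiting daily")
        prompt = build_prompt(rec, SPEC)
        assert "vomiting daily" in prompt
        assert rec.presenting_complaint in prompt
        assert rec.admission_date.isoformat() in prompt

    def test_six_question_blocks_in_order(self, record):
        prompt = build_prompt(record, SPEC)
        positions = [prompt.index(f"Is {sign} present?") for sign in SPEC.signs]
        assert len(positions) == 6 and positions == sorted(positions)

    def test_citation_instructions_present(self, record):
        prompt = build_prompt(record, SPEC)
        for clause in ("quotation marks", "white space", "ellipses"):
            assert clause in prompt


class TestParseModelOutput:
    def test_well_formed_six_booleans_no_events(self):
        raw = well_formed([True, False, True, False, False, False])
        responses, events = parse_model_output(raw, SPEC, record_id="R1")
        assert [r.verdict for r in responses] == [True, False, True, False, False, False]
        assert events == []

    def test_trailing_separator_repaired_to_same_verdicts(self):
        clean = well_formed([True] * 6)
        broken = clean[:-1].rstrip() + ",}"
        ok_responses, _ = parse_model_output(clean, SPEC, record_id="R1")
        responses, events = parse_model_output(broken, SPEC, record_id="R1")
        assert [r.verdict for r in responses] == [r.verdict for r in ok_responses]
        assert [e.kind for e in events] == ["repaired_structure"]

    def test_code_fence_stripped_with_event(self):
        raw = "```json\n" + well_formed([False] * 6) + "\n```"
        responses, events = parse_model_output(raw, SPEC, record_id="R1")
        assert all(r.verdict is False for r in responses)
        assert [e.kind for e in events] == ["repaired_structure"]

    def test_na_answer_yields_na_verdict_and_event(self):
        """An explicit "NA" answer is not a boolean: NA verdict + event."""
        obj = json.loads(well_formed([True] * 6))
        obj["vomiting"]["answer"] = "NA"
        responses, events = parse_model_output(json.dumps(obj), SPEC, record_id="R1")
        byname = {r.sign: r for r in responses}
        assert byname["vomiting"].verdict is None
        assert [e.kind for e in events] == ["non_boolean_answer"]

    def test_missing_sign_yields_na_and_event(self):
        obj = json.loads(well_formed([True] * 6))
        del obj["diarrhea"]
        responses, events = parse_model_output(json.dumps(obj), SPEC, record_id="R1")
        byname = {r.sign: r for r in responses}
        assert byname["diarrhea"].verdict is None
        assert [e.kind for e in events] == ["missing_field"]
        assert len(responses) == 6

    def test_unrecoverable_garbage_all_na(self):
        responses, events = parse_model_output("sorry, I cannot help", SPEC, record_id="R1")
        assert all(r.verdict is None for r in responses)
        assert [e.kind for e in events] == ["invalid_structure"]

    def test_empty_output_event(self):
        responses, events = parse_model_output("  ", SPEC, record_id="R1")
        assert all(r.verdict is None for r in responses)
        assert [e.kind for e in events] == ["empty_output"]

    def test_string_booleans_accepted(self):
        raw = json.dumps({s: {"answer": "true", "citation": ""} for s in SPEC.signs})
        responses, events = parse_model_output(raw, SPEC)
        assert all(r.verdict is True for r in responses) and events == []

    @given(st.lists(st.booleans(), min_size=6, max_size=6))
    @settings(derandomize=True, max_examples=40)
    def test_compliant_output_round_trips_with_zero_events(self, verdicts):
        responses, events = parse_model_output(well_formed(verdicts), SPEC, record_id="R9")
        assert events == []
        assert [r.verdict for r in responses] == verdicts
        assert [r.sign for r in responses] == list(SPEC.signs)


class TestRunPanel:
    def test_cardinality_records_x_signs_x_repeats(self):
        records = [make_record("R1", "P1"), make_record("R2", "P2")]
        config = RunConfig(temperatures=(0.0,), repeats=5)
        result = run_panel(records, MockBackend(seed=1), SPEC, config)
        assert len(result.responses) == 2 * 6 * 5

    def test_same_seed_reproduces_bit_identically(self):
        records = [make_record("R1", "P1"), make_record("R2", "P2")]
        config = RunConfig(temperatures=(0.0, 1.0), repeats=3)
        r1 = run_panel(records, MockBackend(seed=7), SPEC, config)
        r2 = run_panel(records, MockBackend(seed=7), SPEC, config)
        assert r1.responses == r2.responses

    def test_backend_failure_logged_cardinality_preserved(self):
        records = [make_record("R1", "P1", history="all fine today."), make_record("R2", "P2")]
        backend = FailingBackend(MockBackend(seed=1), fail_if_contains="all fine today.")
        config = RunConfig(temperatures=(0.0,), repeats=2)
        result = run_panel(records, backend, SPEC, config)
        assert len(result.responses) == 2 * 6 * 2
        assert len(result.failures) == 2  # both repeats of R1
        failed = [r for r in result.responses if r.record_id == "R1"]
        assert all(r.verdict is None for r in failed)


class TestComplianceSummary:
    def test_all_well_formed_rates_one(self):
        records = [make_record(f"R{i}", f"P{i}") for i in range(3)]
        result = run_panel(records, MockBackend(seed=3), SPEC, RunConfig(temperatures=(0.0,), repeats=2))
        cells = compliance_summary(result.responses, result.events)
        assert len(cells) == 1
        cell = cells[0]
        assert cell.structure_valid_rate == 1.0
        assert cell.boolean_answer_rate == 1.0
        assert cell.na_rate == 0.0
        assert cell.n_questions == 3 * 6 * 2

    def test_single_na_among_questions_counted(self):
        obj = {s: {"answer": True, "citation": ""} for s in SPEC.signs}
        obj["vomiting"]["answer"] = "NA"
        responses, events = parse_model_output(json.dumps(obj), SPEC, record_id="R1", temperature=0.0, run_index=0)
        more, more_events = parse_model_output(well_formed([False] * 6), SPEC, record_id="R2", temperature=0.0, run_index=0)
        cells = compliance_summary(responses + more, events + more_events)
        cell = cells[0]
        assert cell.boolean_answer_rate == pytest.approx(11 / 12)
        assert cell.events == {"non_boolean_answer": 1}

    def test_all_invalid_structure_rate_zero(self):
        responses, events = parse_model_output("garbage", SPEC, record_id="R1", run_index=0, temperature=0.0)
        cell = compliance_summary(responses, events)[0]
        assert cell.structure_valid_rate == 0.0 and cell.na_rate == 1.0
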