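"""Panel execution: repeated runs per temperature against a pluggable backend.

The run protocol mirrors the study design: every record is analyzed
``repeats`` times at each temperature, and the response set always has
cardinality records x signs x repeats x temperatures — a backend failure
yields NA-verdict rows plus a failure entry rather than a hole.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .backends import Backend
from .corpus import EHRecord
from .prompting import ComplianceEvent, PromptSpec, QuestionResponse, build_prompt, parse_model_output

__all__ = ["RunConfig", "PanelResult", "run_panel"]


@dataclass(frozen=True)
class RunConfig:
    """Temperatures, repeats per temperature, and retry policy for one panel."""

    temperatures: tuple[float, ...] = (0.0, 0.5, 1.0)
    repeats: int = 5
    max_retries: int = 2
    respondent_id: str = "model"

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if any(t < 0 for t in self.temperatures):
            raise ValueError("temperatures must be non-negative")


@dataclass
class PanelResult:
    responses: list[QuestionResponse] = field(default_factory=list)
    events: list[ComplianceEvent] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)
    timings: list[dict] = field(default_factory=list)


def run_panel(
    records: list[EHRecord],
    backend: Backend,
    spec: PromptSpec = PromptSpec(),
    config: RunConfig = RunConfig(),
) -> PanelResult:
    """Run every record through the backend at each temperature, repeatedly.

    Transport failures are retried up to ``config.max_retries`` times;
    a record-run that still fails contributes NA verdicts for all signs
    and one failure entry, and the panel continues. Timings are
    informational only.
    """
    result = PanelResult()
    for temperature in config.temperatures:
        for run_index in range(config.repeats):
            for record in records:
                prompt = build_prompt(record, spec)
                raw: str | None = None
                err: Exception | None = None
                t0 = time.perf_counter()
                for _ in range(config.max_retries + 1):
                    try:
                        raw = backend.complete(prompt, temperature)
                        break
                    except Exception as exc:  # noqa: BLE001 - retried, then logged
                        err = exc
                elapsed = time.perf_counter() - t0
                if raw is None:
                    result.failures.append(
                        {
                            "record_id": record.record_id,
                            "temperature": temperature,
                            "run_index": run_index,
                            "error": repr(err),
                        }
                    )
                    raw = ""  # parses to NA verdicts + empty_output event
                responses, events = parse_model_output(
                    raw,
                    spec,
                    respondent_id=config.respondent_id,
                    record_id=record.record_id,
                    run_index=run_index,
                    temperature=temperature,
                )
                result.responses.extend(responses)
                result.events.extend(events)
                result.timings.append(
                    {
                        "record_id": record.record_id,
                        "temperature": temperature,
                        "run_index": run_index,
                        "seconds": elapsed,
                    }
                )
    return result
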