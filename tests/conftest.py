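from datetime import date

import pytest

from ehrsigns.corpus import EHRecord
from ehrsigns.simulate import SimConfig, generate_corpus


def make_record(
    record_id="R1",
    patient_id="P1",
    history="owner reports vomiting almost daily for the last five days.",
    complaint="recheck visit",
):
    return EHRecord(
        record_id=record_id,
        patient_id=patient_id,
        admission_date=date(2020, 3, 14),
        presenting_complaint=complaint,
        pertinent_history=history,
    )


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def small_corpus():
    """Deterministic 40-record synthetic corpus with its latent truth."""
    config = SimConfig(n_records=40, seed=11)
    records, truth = generate_corpus(config)
    return config, records, truth


def no_deviation_config(**overrides) -> SimConfig:
    """Simulator config with perfect citation behavior (no misses, no deviations)."""
    zero = {level: 0.0 for level in ("case_only", "punct_space", "shortened", "paraphrase", "scaffold_included")}
    defaults = dict(
        n_records=30,
        seed=5,
        mu_human=0.0,
        mu_machine=0.0,
        human_deviation_probs=dict(zero),
        machine_deviation_probs=dict(zero),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
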