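"""Generator determinism, calibration, and cross-module round trips."""

import numpy as np
import pytest

from ehrsigns.citations import audit_panel
from ehrsigns.metrics import wilson_ci
from ehrsigns.pipeline import (
    build_error_ledger,
    consensus,
    human_panel,
    llm_run_panels,
    reproducibility,
)
from ehrsigns.simulate import (
    SimConfig,
    ambiguity_labels,
    export_ground_truth,
    generate_corpus,
    simulate_human_panel,
    simulate_llm_runs,
)

from conftest import no_deviation_config


class TestGenerateCorpus:
    def test_seed_determinism(self):
        cfg = SimConfig(n_records=20, seed=9)
        r1, t1 = generate_corpus(cfg)
        r2, t2 = generate_corpus(cfg)
        assert r1 == r2 and t1.questions == t2.questions

    def test_zero_prevalence_all_absent(self):
        cfg = SimConfig(n_records=15, prevalence=0.0, seed=1)
        _, truth = generate_corpus(cfg)
        assert all(t.status == "absent" for t in truth.questions.values())

    def test_prevalence_within_wilson_band(self):
        """Signal fractions consistent with binomial sampling at the set prevalence.

        Six signs are checked simultaneously, so the per-sign band uses
        a multiplicity-adjusted z (99.5% intervals); the pooled count
        over all signs is checked at the plain 95% level.
        """
        from scipy.stats import norm

        cfg = SimConfig(n_records=500, seed=4)
        _, truth = generate_corpus(cfg)
        total = 0
        z_adj = float(norm.ppf(1 - 0.005 / 2))
        for sign in cfg.signs:
            k = sum(
                1 for (_, s), t in truth.questions.items() if s == sign and t.status != "absent"
            )
            total += k
            lo, hi = wilson_ci(k, 500, z=z_adj)
            assert lo <= cfg.prevalence <= hi
        lo, hi = wilson_ci(total, 500 * len(cfg.signs))
        assert lo <= cfg.prevalence <= hi

    def test_gold_spans_point_at_their_sentences(self, small_corpus):
        _, records, truth = small_corpus
        by_id = {r.record_id: r for r in records}
        n_spans = 0
        for (rid, sign), t in truth.questions.items():
            if t.span is not None:
                text = by_id[rid].visible_text[t.span[0] : t.span[1]]
                assert text.endswith(".") and len(text.split()) >= 4
                n_spans += 1
        assert n_spans > 20

    def test_ambiguity_status_pairing(self, small_corpus):
        """Temporal ambiguity only on historic signs; qualitative on present."""
        _, _, truth = small_corpus
        for t in truth.questions.values():
            if t.ambiguity == "temporal":
                assert t.status == "historic"
            if t.ambiguity == "qualitative":
                assert t.status == "present"

    def test_config_from_yaml(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("prevalence: 0.3\npi_machine: 0.9\nflip_rates:\n  0.0: 0.001\n  1.0: 0.01\n")
        cfg = SimConfig.from_yaml(str(path), seed=42)
        assert cfg.prevalence == 0.3 and cfg.pi_machine == 0.9 and cfg.seed == 42
        assert cfg.flip_rates == {0.0: 0.001, 1.0: 0.01}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(prevalence=1.5)
        with pytest.raises(ValueError):
            SimConfig(flip_rates={0.0: 0.1, 1.0: 0.05})
        with pytest.raises(ValueError):
            SimConfig(p_temporal=0.7, p_qualitative=0.6)


class TestHumanPanel:
    def test_errorless_unambiguous_panel_agrees_perfectly(self):
        cfg = SimConfig(n_records=25, seed=2, eps_human=0.0, p_temporal=0.0, p_qualitative=0.0)
        records, truth = generate_corpus(cfg)
        responses = simulate_human_panel(records, truth, cfg)
        _, mean_kappa = reproducibility(human_panel(responses))
        assert mean_kappa == 1.0
        ref = consensus(human_panel(responses))
        for key, verdict in ref.items():
            assert verdict == truth.expected_verdict(key)

    def test_ambiguous_split_drives_agreement_toward_half(self):
        """With pi_h=0.5 two respondents agree on an ambiguous question ~50%."""
        cfg = SimConfig(n_records=400, seed=6, prevalence=0.5, p_temporal=1.0, p_qualitative=0.0)
        records, truth = generate_corpus(cfg)
        responses = simulate_human_panel(records, truth, cfg, n_respondents=2)
        panel = human_panel(responses)
        amb = [k for k, t in truth.questions.items() if t.ambiguity != "none"]
        agree = np.mean([panel["human_1"][k] == panel["human_2"][k] for k in amb])
        assert agree == pytest.approx(0.5, abs=0.03)

    def test_mean_kappa_decreases_with_ambiguity_prevalence(self):
        means = []
        for p_amb in (0.0, 0.3, 0.6):
            cfg = SimConfig(n_records=150, seed=8, p_temporal=p_amb, p_qualitative=0.0)
            records, truth = generate_corpus(cfg)
            responses = simulate_human_panel(records, truth, cfg)
            _, mean_kappa = reproducibility(human_panel(responses))
            means.append(mean_kappa)
        assert means[0] > means[1] > means[2]

    def test_perfect_citations_fully_compliant(self):
        cfg = no_deviation_config()
        records, truth = generate_corpus(cfg)
        responses = simulate_human_panel(records, truth, cfg)
        audit = audit_panel(responses, {r.record_id: r for r in records})
        assert (audit.table["compliance_rate"] == 1.0).all()
        assert audit.hallucinations == []


class TestLlmRuns:
    def test_zero_flip_rate_runs_identical(self):
        cfg = SimConfig(n_records=20, seed=3, flip_rates={0.0: 0.0})
        records, truth = generate_corpus(cfg)
        responses = simulate_llm_runs(records, truth, cfg)
        _, mean_kappa = reproducibility(llm_run_panels(responses, 0.0))
        assert mean_kappa == 1.0

    def test_run_agreement_decreases_with_temperature(self):
        cfg = SimConfig(n_records=200, seed=12, flip_rates={0.0: 0.002, 0.5: 0.02, 1.0: 0.08})
        records, truth = generate_corpus(cfg)
        responses = simulate_llm_runs(records, truth, cfg)
        kappas = [reproducibility(llm_run_panels(responses, t))[1] for t in (0.0, 0.5, 1.0)]
        assert kappas[0] > kappas[1] > kappas[2]

    def test_errors_concentrate_on_ambiguous_questions_as_false_positives(self):
        """True-biased model vs split humans: ambiguity produces FP-dominated errors."""
        cfg = SimConfig(
            n_records=150, seed=13, eps_machine=0.0, pi_machine=1.0, pi_human=0.4
        )
        records, truth = generate_corpus(cfg)
        humans = simulate_human_panel(records, truth, cfg)
        llm = simulate_llm_runs(records, truth, cfg)
        ledger = build_error_ledger(
            llm, humans, {r.record_id: r for r in records},
            temperature=0.0, ambiguity=ambiguity_labels(truth),
        )
        assert ledger.n_errors > 0
        assert ledger.counts["false_positive"] > ledger.counts["false_negative"]
        on_ambiguous = sum(1 for c in ledger.cases if c.ambiguity in ("temporal", "qualitative"))
        assert on_ambiguous >= ledger.n_errors - on_ambiguous

    def test_ledger_marginal_identities_on_simulator_output(self):
        cfg = SimConfig(n_records=80, seed=21)
        records, truth = generate_corpus(cfg)
        humans = simulate_human_panel(records, truth, cfg)
        llm = simulate_llm_runs(records, truth, cfg)
        ledger = build_error_ledger(
            llm, humans, {r.record_id: r for r in records},
            temperature=0.0, ambiguity=ambiguity_labels(truth),
        )
        c = ledger.counts
        assert c["false_positive"] + c["false_negative"] == c["errors"]
        assert c["dissent_2"] + c["dissent_1"] + c["dissent_0"] == c["errors"]
        assert c["interpretation"] + c["citation"] == c["errors"]
        assert all(case.dissent_count <= 2 for case in ledger.cases)


class TestExportGroundTruth:
    def test_round_trip_and_label_count(self, tmp_path, small_corpus):
        _, _, truth = small_corpus
        labels_path = tmp_path / "labels.csv"
        truth_path = tmp_path / "truth.csv"
        labels, table = export_ground_truth(truth, labels_path, truth_path)
        assert list(labels.columns) == ["record_id", "sign", "ambiguity"]
        n_ambiguous = sum(1 for t in truth.questions.values() if t.ambiguity != "none")
        assert len(labels) == n_ambiguous
        assert len(table) == len(truth.questions)

        from ehrsigns.io import read_ambiguity_labels

        recovered = read_ambiguity_labels(labels_path)
        assert recovered == ambiguity_labels(truth)
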