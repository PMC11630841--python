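import math

import numpy as np
import pytest

from famrescue import (
    CohortEntry,
    MockBackend,
    MockResponseSpec,
    PipelineConfig,
    PredictionRequest,
    PredictionResult,
    RescueConfig,
    StructureModel,
    TemplateBank,
    best_pick,
    build_template_bank,
    generate_study,
    run_pipeline,
    run_rescue,
    summarize,
    write_report,
)
from famrescue.exceptions import ValidationError


def _model(pid, value, length=10):
    return StructureModel(pid, "A" * length, np.full(length, float(value)))


def _baseline_result(pid, value):
    m = _model(pid, value)
    return PredictionResult(pid, "no_template_msa", m, float(value), float(value))


class TestTemplateBank:
    def test_threshold_is_inclusive(self):
        results = [
            _baseline_result("a", 65.0),
            _baseline_result("b", 70.0),
            _baseline_result("c", 90.2),
        ]
        bank = build_template_bank(results, "F")
        assert [t.protein_id for t in bank.templates] == ["c", "b"]

    def test_all_below_threshold_gives_empty_bank(self):
        bank = build_template_bank([_baseline_result("a", 60.0)], "F")
        assert len(bank) == 0

    def test_matches_filter_and_sort_oracle(self, rng):
        values = rng.uniform(40, 100, size=30)
        results = [_baseline_result(f"p{i:02d}", v) for i, v in enumerate(values)]
        bank = build_template_bank(results, "F")
        expected = sorted(
            (f"p{i:02d}" for i, v in enumerate(values) if v >= 70.0),
            key=lambda pid: (-values[int(pid[1:])], pid),
        )
        assert [t.protein_id for t in bank.templates] == expected

    def test_rejects_non_baseline_results(self):
        m = _model("a", 80.0)
        res = PredictionResult("a", "template_msa", m, 80.0, 80.0)
        with pytest.raises(ValidationError):
            build_template_bank([res], "F")


class TestBestPick:
    def test_max_selected(self):
        assert best_pick(68.0, 75.0) == ("template_single", 75.0)

    def test_tie_goes_to_msa(self):
        assert best_pick(70.0, 70.0) == ("template_msa", 70.0)

    def test_matches_max_oracle(self, rng):
        for _ in range(1000):
            a, b = rng.uniform(0, 100, 2)
            mode, value = best_pick(a, b)
            assert value == max(a, b)


class _ScriptedBackend:
    """Backend returning scripted mean plDDTs per mode."""

    def __init__(self, baseline, msa, single):
        self._values = {
            "no_template_msa": baseline,
            "template_msa": msa,
            "template_single": single,
        }

    def predict(self, request):
        v = self._values[request.mode]
        m = _model(request.protein_id, v, len(request.sequence))
        return PredictionResult(request.protein_id, request.mode, m, v, v)


def _run_scripted(baseline, msa, single):
    backend = _ScriptedBackend(baseline, msa, single)
    bank = TemplateBank("F", [_model("tmpl", 90.0)])
    entry = CohortEntry("query", "F", "low", baseline, False)
    return run_rescue(entry, "A" * 10, bank, backend, seed=0)


class TestRunRescue:
    def test_single_mode_rescue(self):
        rec = _run_scripted(60.0, 68.0, 75.0)
        assert rec.best_pick_mode == "template_single"
        assert rec.best_pick_plddt == 75.0
        assert rec.rescued

    def test_below_threshold_not_rescued(self):
        rec = _run_scripted(60.0, 69.0, 64.0)
        assert rec.best_pick_plddt == 69.0
        assert not rec.rescued

    def test_confident_baseline_never_rescued(self):
        rec = _run_scripted(72.0, 80.0, 85.0)
        assert not rec.rescued

    def test_three_modes_recorded(self):
        rec = _run_scripted(60.0, 68.0, 75.0)
        assert (rec.baseline_plddt, rec.template_msa_plddt,
                rec.template_single_plddt) == (60.0, 68.0, 75.0)
        assert rec.closest_template_id == "tmpl"

    def test_empty_bank_rejected(self):
        entry = CohortEntry("q", "F", "low", 60.0, False)
        with pytest.raises(ValidationError):
            run_rescue(entry, "A" * 10, TemplateBank("F", []),
                       _ScriptedBackend(60, 65, 65), seed=0)


class TestPredictionRequest:
    def test_no_template_mode_forbids_templates(self):
        with pytest.raises(ValidationError):
            PredictionRequest("p", "ACD", "no_template_msa",
                              templates=(_model("t", 80.0),))

    def test_single_mode_disables_msa(self):
        req = PredictionRequest("p", "ACD", "template_single",
                                templates=(_model("t", 80.0),))
        assert not req.msa_enabled


def _study(seed, n_families=3, members=30, response=None):
    mbf, anns, _ = generate_study(n_families, members, seed=seed)
    spans = {a.protein_id: a.span for a in anns}
    allm = [m for ms in mbf.values() for m in ms]
    backend = MockBackend(allm, spans, response or MockResponseSpec(seed=seed))
    config = PipelineConfig(min_members=20)
    return run_pipeline(mbf, anns, backend, seed=seed, config=config)


class TestPipeline:
    def test_best_pick_dominates_each_mode(self):
        records, _ = _study(11)
        for r in records:
            assert r.best_pick_plddt >= r.template_msa_plddt - 1e-9
            assert r.best_pick_plddt >= r.template_single_plddt - 1e-9

    def test_rescued_implies_threshold_crossing(self):
        records, _ = _study(12)
        assert records
        for r in records:
            if r.rescued:
                assert r.baseline_plddt < 70.0 <= r.best_pick_plddt

    def test_null_backend_rescues_nothing(self):
        null = MockResponseSpec(
            gain_at_full_identity=0.0, sd_single=0.0, sd_msa=0.0,
            msa_ignore_prob=0.0, seed=0,
        )
        records, _ = _study(13, response=null)
        summary = summarize(records)
        assert summary.n_rescued == 0
        assert summary.mean_delta["best_pick"] == 0.0

    def test_identical_seed_gives_byte_identical_report(self, tmp_path):
        r1, _ = _study(14)
        r2, _ = _study(14)
        p1 = write_report(r1, tmp_path / "a.csv")
        p2 = write_report(r2, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()


def test_pipeline_config_from_yaml(tmp_path):
    path = tmp_path / "config.yaml"
    path.write_text(
        "min_members: 20\nper_stratum: 5\n"
        "peaks:\n  min_height: 0.05\n"
        "rescue:\n  max_templates: 2\n  exclude_self_template: true\n"
    )
    config = PipelineConfig.from_yaml(path)
    assert config.min_members == 20
    assert config.per_stratum == 5
    assert config.peak_params.min_height == 0.05
    assert config.rescue.max_templates == 2
    assert config.rescue.exclude_self_template
    # empty file keeps every default
    empty = tmp_path / "empty.yaml"
    empty.write_text("")
    assert PipelineConfig.from_yaml(empty) == PipelineConfig()
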