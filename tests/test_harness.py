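"""Simulation protocol, metrics and the repeated-run comparison harness."""

import json

import numpy as np
import pytest

from t2soflc.cli import main as cli_main
from t2soflc.harness import (
    SimulationConfig,
    SimulationTrace,
    compute_metrics,
    control_stability,
    repeat_and_compare,
    run_closed_loop,
    steady_state_error,
    _wilcoxon_less,
)
from t2soflc.patient_model import NoiseConfig

QUIET = NoiseConfig(param_fraction=0.0, meas_fraction=0.0)
SHORT = dict(duration=110.0, stage_switch=55.0)


def synthetic_trace(bp_offset=0.0, u2=None, duration=110.0, dt=0.01):
    n = int(duration / dt)
    t = np.arange(n) * dt
    zeros = np.zeros(n)
    return SimulationTrace(
        time_min=t,
        mr_set=np.full(n, 0.8),
        mr_clean=np.full(n, 0.8),
        mr_meas=np.full(n, 0.8),
        bp_set=np.full(n, 100.0),
        bp_clean=np.full(n, 100.0 + bp_offset),
        bp_meas=np.full(n, 100.0 + bp_offset),
        u_atracurium=zeros if u2 is None else u2,
        u_isoflurane=zeros if u2 is None else u2,
        n_rules_fired=zeros,
        n_rules_added=zeros,
    )


class TestMetrics:
    cfg = SimulationConfig(**SHORT, noise=QUIET)

    def test_exact_setpoint_gives_zero_error(self):
        tr = synthetic_trace()
        assert steady_state_error(tr, 1, "bp", self.cfg) == 0.0

    def test_constant_offset_recovered(self):
        tr = synthetic_trace(bp_offset=0.05)
        assert steady_state_error(tr, 2, "bp", self.cfg) == pytest.approx(0.05)

    def test_zero_mean_oscillation_averages_out(self):
        tr = synthetic_trace()
        tr.bp_clean = tr.bp_set + 3.0 * np.sin(2 * np.pi * tr.time_min / 5.0)
        assert steady_state_error(tr, 1, "bp", self.cfg) < 1e-2

    def test_window_longer_than_stage_rejected(self):
        tr = synthetic_trace()
        with pytest.raises(ValueError):
            steady_state_error(tr, 1, "bp", self.cfg, window=60.0)

    def test_constant_control_stability_zero(self):
        tr = synthetic_trace(u2=np.full(11000, 1.3))
        assert control_stability(tr, "iso", self.cfg, stage=1) == 0.0

    def test_alternating_control_stability(self):
        u = np.full(11000, 1.0)
        u[::2] += 0.2
        u[1::2] -= 0.2
        tr = synthetic_trace(u2=u)
        assert control_stability(tr, "iso", self.cfg, stage=2) == pytest.approx(0.2)

    def test_white_noise_control_sd_recovered(self, rng):
        u = 1.0 + 0.05 * rng.standard_normal(11000)
        tr = synthetic_trace(u2=u)
        est = control_stability(tr, "iso", self.cfg, stage=1)
        assert est == pytest.approx(0.05, rel=0.03)


@pytest.fixture(scope="module")
def short_trace():
    cfg = SimulationConfig(duration=40.0, stage_switch=25.0, noise=QUIET)
    return run_closed_loop(cfg, seed=5), cfg


class TestProtocol:

    def test_bolus_phase(self, short_trace):
        tr, _ = short_trace
        bolus = tr.u_atracurium[tr.time_min < 5.0]
        assert np.all(bolus == 5.0)

    def test_settle_phase_no_drugs(self, short_trace):
        tr, _ = short_trace
        m = (tr.time_min >= 5.0) & (tr.time_min < 15.0)
        assert np.all(tr.u_atracurium[m] == 0.0)
        assert np.all(tr.u_isoflurane[m] == 0.0)

    def test_map_constant_120_first_15_minutes(self, short_trace):
        tr, _ = short_trace
        assert np.all(tr.bp_clean[tr.time_min < 15.0] == 120.0)

    def test_drugs_never_negative(self, short_trace):
        tr, _ = short_trace
        assert tr.u_atracurium.min() >= 0.0 and tr.u_isoflurane.min() >= 0.0

    def test_setpoints_switch_at_stage_boundary(self, short_trace):
        tr, cfg = short_trace
        assert np.all(tr.mr_set[tr.time_min < 25.0] == 0.8)
        assert np.all(tr.mr_set[tr.time_min >= 25.0] == 0.9)
        assert np.all(tr.bp_set[tr.time_min >= 25.0] == 90.0)

    def test_trace_columns_equal_length(self, short_trace):
        tr, _ = short_trace
        df = tr.to_dataframe()
        assert len(df) == 4000 and not df.isna().any().any()

    def test_determinism(self):
        cfg = SimulationConfig(
            duration=30.0, stage_switch=20.0,
            noise=NoiseConfig(param_fraction=0.01, meas_fraction=0.2),
        )
        a = run_closed_loop(cfg, seed=11)
        b = run_closed_loop(cfg, seed=11)
        assert np.array_equal(a.mr_meas, b.mr_meas)
        assert np.array_equal(a.u_isoflurane, b.u_isoflurane)

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(
            duration=30.0, stage_switch=20.0,
            noise=NoiseConfig(param_fraction=0.01, meas_fraction=0.2),
        )
        a = run_closed_loop(cfg, seed=11)
        b = run_closed_loop(cfg, seed=12)
        assert not np.array_equal(a.u_isoflurane, b.u_isoflurane)


class TestClosedLoopConvergence:
    def test_type1_expert_noise_free_converges(self):
        """Noise-free type-1 run with expert rules settles near both
        set points in each stage's final window."""
        cfg = SimulationConfig(controller_kind="type1", noise=QUIET)
        tr = run_closed_loop(cfg, seed=1)
        m = compute_metrics(tr, cfg)
        for stage in (0, 1):
            assert m.sse_mr[stage] < 0.03
            assert m.sse_bp[stage] < 0.5
        for stage in (1, 2):
            w = (tr.time_min >= (100 if stage == 1 else 250)) & (
                tr.time_min < (150 if stage == 1 else 300)
            )
            assert np.abs(tr.mr_clean[w] - tr.mr_set[w]).max() < 0.12
            assert np.abs(tr.bp_clean[w] - tr.bp_set[w]).max() < 2.5


class TestComparison:
    def test_wilcoxon_identical_vectors_no_rejection(self):
        a = np.full(10, 0.5)
        assert _wilcoxon_less(a, a) == 1.0

    def test_wilcoxon_strict_dominance_rejects(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(1, 2, 10)
        a = b - 0.5
        p = _wilcoxon_less(a, b)
        assert p == pytest.approx(1 / 1024, rel=1e-6)
        assert p < 0.05

    def test_repeat_and_compare_report_shape(self):
        base = SimulationConfig(**SHORT, noise=NoiseConfig(meas_fraction=0.1), reps=2)
        configs = {
            "type1": base,
            "interval_t2": SimulationConfig(
                **SHORT, noise=NoiseConfig(meas_fraction=0.1),
                reps=2, controller_kind="interval_t2",
            ),
        }
        report = repeat_and_compare(
            configs, reps=2, base_seed=7, hypotheses=[("interval_t2", "type1")]
        )
        assert report["reps"] == 2
        for metric, entry in report["tests"].items():
            assert 0.0 <= entry["kruskal_wallis_p"] <= 1.0
            pw = entry["pairwise"]["interval_t2<type1"]
            assert 0.0 <= pw["p"] <= 1.0 and isinstance(pw["accept"], bool)
        assert len(report["metrics"]["type1"]["sse_bp_stage1"]) == 2

    def test_single_config_rejected(self):
        with pytest.raises(ValueError):
            repeat_and_compare({"only": SimulationConfig(**SHORT)})


class TestConfigSerialization:
    def test_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(
            controller_kind="zslice_t2",
            noise=NoiseConfig(meas_fraction=0.2, seed=3),
            stage_switch=120.0,
        )
        path = tmp_path / "config.json"
        cfg.to_json(path)
        assert SimulationConfig.from_json(path) == cfg

    def test_invalid_stage_switch_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(stage_switch=400.0)

    def test_unknown_controller_kind_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(controller_kind="pid")


class TestCli:
    def test_simulate_writes_outputs_and_is_deterministic(self, tmp_path):
        args = [
            "simulate", "--controller", "type1", "--noise", "0.1",
            "--seed", "1", "--duration", "110", "--stage-switch", "55",
        ]
        out1, out2 = tmp_path / "a", tmp_path / "b"
        assert cli_main(args + ["--out", str(out1)]) == 0
        assert cli_main(args + ["--out", str(out2)]) == 0
        m1 = (out1 / "metrics.json").read_bytes()
        assert m1 == (out2 / "metrics.json").read_bytes()
        assert (out1 / "trace.csv").exists()
        assert (out1 / "firing_stats.csv").exists()
        metrics = json.loads(m1)
        assert set(metrics) >= {"sse_mr_stage1", "stability_iso_stage2"}

    def test_extract_rules_writes_reduced_bases(self, tmp_path):
        rc = cli_main(
            [
                "extract-rules", "--controller", "type1", "--threshold", "1.0",
                "--seed", "2", "--duration", "110", "--stage-switch", "55",
                "--out", str(tmp_path),
            ]
        )
        assert rc == 0
        assert (tmp_path / "extracted_atracurium.csv").exists()
        assert (tmp_path / "extracted_isoflurane.csv").exists()

    def test_open_loop_subcommand(self, tmp_path):
        rc = cli_main(
            ["open-loop", "--u2", "2.0", "--horizon", "30", "--out", str(tmp_path)]
        )
        assert rc == 0
        assert (tmp_path / "open_loop.csv").exists()

    def test_bad_flags_nonzero_exit(self, capsys):
        with pytest.raises(SystemExit):
            cli_main(["simulate", "--controller", "type9"])
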