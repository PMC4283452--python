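"""Closed-loop surgical simulation protocol, metrics and repeated-run
statistical comparison.

The protocol simulates a 300-minute, two-stage procedure at 0.01-minute
resolution (30,000 intervals).  An atracurium bolus of 5 normalized
units runs for the first 5 minutes; the block then settles until minute
15 with both drugs off, after which the self-organizing fuzzy controller
takes over.  Set points switch between the two surgical stages (default
at minute 150): muscle relaxation 0.8 then 0.9 of full block, MAP 100
then 90 mmHg.  Measured signals carry additive white noise at 10% or 20%
of a per-channel reference SD, and the plant itself is "nonfixed" (1%
parametric white noise).

Performance is summarized per stage by the steady-state error (absolute
deviation of the average response over the stage's last 50 minutes from
the set point) and per run by the control stability (standard deviation
of each drug signal while the controller is active).  Repeated matched-
seed runs are compared with Kruskal-Wallis and one-tailed Wilcoxon
signed-rank tests at significance level 0.05.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fuzzy_core.rules import RuleBase, read_rulebase
from .patient_model import NoiseConfig, Plant, PlantParameters
from .soflc import ControllerGains, SelfOrganizingController, fixture_path

__all__ = [
    "SimulationConfig",
    "SimulationTrace",
    "Metrics",
    "run_closed_loop",
    "steady_state_error",
    "control_stability",
    "compute_metrics",
    "repeat_and_compare",
    "ALPHA",
]

ALPHA = 0.05

CONTROLLER_KINDS = ("type1", "interval_t2", "zslice_t2")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one closed-loop run."""

    duration: float = 300.0  # minutes
    dt: float = 0.01  # plant sampling interval, minutes
    stage_switch: float = 150.0  # minutes
    mr_setpoints: tuple[float, float] = (0.8, 0.9)  # normalized block
    bp_setpoints: tuple[float, float] = (100.0, 90.0)  # mmHg
    bolus_amplitude: float = 5.0  # normalized units
    bolus_duration: float = 5.0  # minutes
    settle_until: float = 15.0  # minutes; controller starts here
    controller_kind: str = "interval_t2"
    rulebase_atr: str | None = None  # None -> packaged expert fixture
    rulebase_iso: str | None = None
    fou_width: float = 0.05  # fraction of universe span
    n_zslices: int = 5
    control_period: float = 0.1  # minutes between controller updates
    adapt: bool = True
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    gains: ControllerGains = field(default_factory=ControllerGains)
    plant: PlantParameters = field(default_factory=PlantParameters)
    seed: int = 0
    reps: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.stage_switch < self.duration:
            raise ValueError("stage_switch must lie inside the run")
        if self.controller_kind not in CONTROLLER_KINDS:
            raise ValueError(f"controller_kind must be one of {CONTROLLER_KINDS}")

    # ------------------------------------------------------------------
    def setpoints(self, t: float) -> tuple[float, float]:
        i = 0 if t < self.stage_switch else 1
        return self.mr_setpoints[i], self.bp_setpoints[i]

    def load_rulebases(self) -> tuple[RuleBase, RuleBase]:
        atr = self.rulebase_atr or str(fixture_path("expert_atracurium.csv"))
        iso = self.rulebase_iso or str(fixture_path("expert_isoflurane.csv"))
        return read_rulebase(atr), read_rulebase(iso)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        for key, sub in (
            ("noise", NoiseConfig),
            ("gains", ControllerGains),
            ("plant", PlantParameters),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = _build_nested(sub, raw[key])
        for key in ("mr_setpoints", "bp_setpoints"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _build_nested(cls, raw: dict):
    from .patient_model import HillParams, LinearBlockParams

    if cls is PlantParameters:
        kwargs = dict(raw)
        for key in ("g11", "g22", "g12", "pk"):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                for tup in ("pole_time_constants", "zero_time_constants"):
                    if tup in sub:
                        sub[tup] = tuple(sub[tup])
                kwargs[key] = LinearBlockParams(**sub)
        if "hill" in kwargs and isinstance(kwargs["hill"], dict):
            kwargs["hill"] = HillParams(**kwargs["hill"])
        return PlantParameters(**kwargs)
    return cls(**raw)


@dataclass
class SimulationTrace:
    """Per-step arrays of one closed-loop run."""

    time_min: np.ndarray
    mr_set: np.ndarray
    mr_clean: np.ndarray
    mr_meas: np.ndarray
    bp_set: np.ndarray
    bp_clean: np.ndarray
    bp_meas: np.ndarray
    u_atracurium: np.ndarray
    u_isoflurane: np.ndarray
    n_rules_fired: np.ndarray
    n_rules_added: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({k: getattr(self, k) for k in self.__dataclass_fields__})

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")


@dataclass
class Metrics:
    """Per-stage steady-state errors and control stabilities.

    Both families are evaluated over the final window of each surgical
    stage, mirroring the stage-resolved reporting of the protocol: the
    steady-state error as the absolute deviation of the average response
    from the set point, the control stability as the standard deviation
    of the drug signal (dosing smoothness)."""

    sse_mr: tuple[float, float]
    sse_bp: tuple[float, float]
    stability_atr: tuple[float, float]
    stability_iso: tuple[float, float]

    def as_flat_dict(self) -> dict[str, float]:
        return {
            "sse_mr_stage1": self.sse_mr[0],
            "sse_mr_stage2": self.sse_mr[1],
            "sse_bp_stage1": self.sse_bp[0],
            "sse_bp_stage2": self.sse_bp[1],
            "stability_atr_stage1": self.stability_atr[0],
            "stability_atr_stage2": self.stability_atr[1],
            "stability_iso_stage1": self.stability_iso[0],
            "stability_iso_stage2": self.stability_iso[1],
        }


def run_closed_loop(
    config: SimulationConfig,
    seed: int | None = None,
    controller: SelfOrganizingController | None = None,
) -> SimulationTrace:
    """Run the full two-stage protocol and return the trace.

    A ``controller`` may be passed in (e.g. pre-trained); otherwise one
    is built from the config.  ``seed`` overrides ``config.seed``.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_plant, rng_meas = (np.random.default_rng(s) for s in ss.spawn(2))

    plant = Plant(config.plant, config.noise.param_fraction, rng_plant)
    if controller is None:
        atr_rb, iso_rb = config.load_rulebases()
        controller = SelfOrganizingController(
            config.controller_kind,
            atr_rb,
            iso_rb,
            gains=config.gains,
            fou_width=config.fou_width,
            n_zslices=config.n_zslices,
            control_period=config.control_period,
            credit_delay_mr=config.plant.g11.dead_time,
            credit_delay_bp=config.plant.g22.dead_time,
            adapt=config.adapt,
        )

    n = int(round(config.duration / config.dt))
    control_every = max(int(round(config.control_period / config.dt)), 1)
    meas_sd_mr = config.noise.meas_fraction * config.noise.ref_sd_mr
    meas_sd_bp = config.noise.meas_fraction * config.noise.ref_sd_bp
    noise_mr = rng_meas.standard_normal(n) * meas_sd_mr if meas_sd_mr else np.zeros(n)
    noise_bp = rng_meas.standard_normal(n) * meas_sd_bp if meas_sd_bp else np.zeros(n)

    cols = {
        name: np.empty(n)
        for name in (
            "time_min mr_set mr_clean mr_meas bp_set bp_clean bp_meas "
            "u_atracurium u_isoflurane n_rules_fired n_rules_added".split()
        )
    }
    u1 = u2 = 0.0
    for i in range(n):
        t = i * config.dt
        mr_set, bp_set = config.setpoints(t)
        if t < config.bolus_duration:
            u1, u2 = config.bolus_amplitude, 0.0
        elif t < config.settle_until:
            u1, u2 = 0.0, 0.0
        mr, bp = plant.step(u1, u2)
        mr_meas = mr + noise_mr[i]
        bp_meas = bp + noise_bp[i]
        fired = added = 0
        if t >= config.settle_until and i % control_every == 0:
            u1, u2 = controller.step(mr_meas, bp_meas, mr_set, bp_set)
            fired, added = controller.last_fired, controller.last_added
        c = cols
        c["time_min"][i] = t
        c["mr_set"][i] = mr_set
        c["mr_clean"][i] = mr
        c["mr_meas"][i] = mr_meas
        c["bp_set"][i] = bp_set
        c["bp_clean"][i] = bp
        c["bp_meas"][i] = bp_meas
        c["u_atracurium"][i] = u1
        c["u_isoflurane"][i] = u2
        c["n_rules_fired"][i] = fired
        c["n_rules_added"][i] = added
    trace = SimulationTrace(**cols)
    trace.controller = controller  # type: ignore[attr-defined]
    trace.config = config  # type: ignore[attr-defined]
    return trace


def _stage_window(
    trace: SimulationTrace, config: SimulationConfig, stage: int, window: float = 50.0
) -> np.ndarray:
    start, end = (
        (0.0, config.stage_switch) if stage == 1 else (config.stage_switch, config.duration)
    )
    if end - start < window:
        raise ValueError(f"stage {stage} is shorter than the {window}-minute window")
    t = trace.time_min
    return (t >= end - window) & (t < end)


def steady_state_error(
    trace: SimulationTrace,
    stage: int,
    channel: str,
    config: SimulationConfig | None = None,
    window: float = 50.0,
) -> float:
    """Absolute deviation of the average response over the stage's final
    ``window`` minutes from the set point (clean signal)."""
    config = config or trace.config
    mask = _stage_window(trace, config, stage, window)
    if channel in ("mr", "paralysis", "muscle_relaxation"):
        y, sp = trace.mr_clean, trace.mr_set
    elif channel in ("bp", "map"):
        y, sp = trace.bp_clean, trace.bp_set
    else:
        raise KeyError(f"unknown channel {channel!r}")
    return float(abs(np.mean(y[mask]) - np.mean(sp[mask])))


def control_stability(
    trace: SimulationTrace,
    channel: str,
    config: SimulationConfig | None = None,
    stage: int | None = None,
    window: float = 50.0,
) -> float:
    """Population SD of a drug signal: dosing smoothness.

    With ``stage`` given, the SD is taken over that stage's final
    ``window`` minutes (the settled period, so the set-point transient
    common to every controller does not dominate); with ``stage=None``
    it covers the whole controller-active period.
    """
    config = config or trace.config
    u = trace.u_atracurium if channel in ("atr", "atracurium", "u1") else trace.u_isoflurane
    if stage is None:
        mask = trace.time_min >= config.settle_until
    else:
        mask = _stage_window(trace, config, stage, window)
    return float(np.std(u[mask]))


def compute_metrics(trace: SimulationTrace, config: SimulationConfig | None = None) -> Metrics:
    config = config or trace.config
    return Metrics(
        sse_mr=(
            steady_state_error(trace, 1, "mr", config),
            steady_state_error(trace, 2, "mr", config),
        ),
        sse_bp=(
            steady_state_error(trace, 1, "bp", config),
            steady_state_error(trace, 2, "bp", config),
        ),
        stability_atr=(
            control_stability(trace, "atr", config, stage=1),
            control_stability(trace, "atr", config, stage=2),
        ),
        stability_iso=(
            control_stability(trace, "iso", config, stage=1),
            control_stability(trace, "iso", config, stage=2),
        ),
    )


# ---------------------------------------------------------------------
# repeated runs and statistical comparison


def _wilcoxon_less(a: np.ndarray, b: np.ndarray) -> float:
    """One-tailed Wilcoxon signed-rank p-value for H1: a < b (paired)."""
    d = np.asarray(a) - np.asarray(b)
    if np.all(d == 0):
        return 1.0
    res = sps.wilcoxon(d, alternative="less")
    return float(res.pvalue)


def repeat_and_compare(
    configs: dict[str, SimulationConfig],
    reps: int | None = None,
    base_seed: int | None = None,
    hypotheses: list[tuple[str, str]] | None = None,
) -> dict:
    """Run each config ``reps`` times with matched seeds and compare.

    ``hypotheses`` lists ordered pairs (a, b) tested one-tailed as
    "a performs better (smaller metric) than b" per metric with the
    Wilcoxon signed-rank test; a Kruskal-Wallis test across all groups
    is reported per metric as well.  Returns a nested report dict with
    the raw metric vectors, p-values and accept/reject flags at 0.05.
    """
    if len(configs) < 2:
        raise ValueError("need at least two configurations to compare")
    first = next(iter(configs.values()))
    reps = first.reps if reps is None else reps
    if reps < 2:
        raise ValueError("need at least two repetitions")
    base_seed = first.seed if base_seed is None else base_seed

    metric_names = (
        "sse_mr_stage1 sse_mr_stage2 sse_bp_stage1 sse_bp_stage2 "
        "stability_atr_stage1 stability_atr_stage2 "
        "stability_iso_stage1 stability_iso_stage2".split()
    )
    values: dict[str, dict[str, list[float]]] = {
        name: {m: [] for m in metric_names} for name in configs
    }
    for name, cfg in configs.items():
        for r in range(reps):
            trace = run_closed_loop(cfg, seed=base_seed + r)
            flat = compute_metrics(trace, cfg).as_flat_dict()
            for m in metric_names:
                values[name][m].append(flat[m])

    report: dict = {"reps": reps, "alpha": ALPHA, "metrics": values, "tests": {}}
    for m in metric_names:
        groups = [values[name][m] for name in configs]
        if len(groups) >= 2 and any(
            np.ptp(np.concatenate(groups)) > 0 for _ in (0,)
        ):
            try:
                kw = float(sps.kruskal(*groups).pvalue)
            except ValueError:  # all values identical
                kw = 1.0
        else:
            kw = 1.0
        entry: dict = {"kruskal_wallis_p": kw, "pairwise": {}}
        for a, b in hypotheses or []:
            p = _wilcoxon_less(np.array(values[a][m]), np.array(values[b][m]))
            entry["pairwise"][f"{a}<{b}"] = {"p": p, "accept": bool(p < ALPHA)}
        report["tests"][m] = entry
    return report
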