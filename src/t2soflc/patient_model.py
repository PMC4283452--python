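"""Discrete-time multivariable anesthetic patient simulator.

Intravenous atracurium drives neuromuscular block (paralysis, normalized
0-1) through a third-order linear pharmacodynamic path with dead time
followed by a sigmoid Hill concentration-effect curve.  Inhaled
isoflurane lowers mean arterial pressure (MAP, mmHg) through a
first-order lag with dead time and additionally potentiates the
neuromuscular block through a second-order interaction path.  The
coupling matrix is triangular: atracurium has no effect on MAP.

The continuous-time blocks are stepped at a fixed sampling interval
``dt`` (default 0.01 min, i.e. 100 intervals per minute) using an exact
zero-order-hold discretization of a modal (parallel first-order)
realization; pure dead times are integer-step ring buffers.  A
"nonfixed" patient is obtained by perturbing every block gain, time
constant and Hill parameter with serially uncorrelated multiplicative
Gaussian noise at each sampling instant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LinearBlockParams",
    "HillParams",
    "PlantParameters",
    "NoiseConfig",
    "DiscreteBlock",
    "Plant",
    "hill_effect",
    "discretize",
    "perturb_parameters",
    "add_measurement_noise",
    "open_loop_response",
    "ATRACURIUM_PD",
    "ATRACURIUM_PK",
    "ISOFLURANE_BP",
    "ISOFLURANE_MR_INTERACTION",
]


@dataclass(frozen=True)
class LinearBlockParams:
    """A rational transfer-function block K * prod(1+Tz*s) / prod(1+Tp*s) * exp(-tau*s).

    Time constants are in minutes.  The block must be proper (at least as
    many poles as zeros) and all pole time constants strictly positive.
    """

    gain: float
    pole_time_constants: tuple[float, ...]
    zero_time_constants: tuple[float, ...] = ()
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.pole_time_constants:
            raise ValueError("a linear block needs at least one pole")
        if any(t <= 0 for t in self.pole_time_constants):
            raise ValueError("pole time constants must be > 0")
        if self.dead_time < 0:
            raise ValueError("dead time must be >= 0")
        if len(self.zero_time_constants) > len(self.pole_time_constants):
            raise ValueError("improper transfer function (more zeros than poles)")

    @property
    def dc_gain(self) -> float:
        return self.gain


#: Atracurium pharmacodynamic path (drug input -> effect-site concentration).
ATRACURIUM_PD = LinearBlockParams(
    gain=1.0,
    pole_time_constants=(4.81, 34.42, 3.08),
    zero_time_constants=(10.64,),
    dead_time=1.0,
)

#: Stand-alone atracurium pharmacokinetic block.  Not cascaded by default;
#: see :class:`PlantParameters.pk_cascade`.
ATRACURIUM_PK = LinearBlockParams(
    gain=9.94,
    pole_time_constants=(3.08, 34.42),
    zero_time_constants=(10.64,),
    dead_time=0.0,
)

#: Isoflurane -> change of mean arterial pressure (mmHg per percent).
ISOFLURANE_BP = LinearBlockParams(
    gain=-15.0,
    pole_time_constants=(2.0,),
    dead_time=0.42,
)

#: Isoflurane -> neuromuscular-block interaction (paralysis fraction per percent).
ISOFLURANE_MR_INTERACTION = LinearBlockParams(
    gain=0.27,
    pole_time_constants=(2.83, 1.25),
    dead_time=1.0,
)


@dataclass(frozen=True)
class HillParams:
    """Sigmoid Emax concentration-effect curve."""

    e_max: float = 100.0  # percent
    xe50: float = 0.404  # ug/mL, concentration at half effect
    alpha: float = 2.98  # slope exponent

    def __post_init__(self) -> None:
        if self.e_max <= 0 or self.xe50 <= 0 or self.alpha <= 0:
            raise ValueError("Hill parameters must be strictly positive")


def hill_effect(concentration, params: HillParams = HillParams()):
    """Drug effect (percent) at the given effect-site concentration.

    Accepts scalars or arrays; raises on negative concentrations.
    """
    x = np.asarray(concentration, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be >= 0")
    xa = np.power(x, params.alpha)
    eff = params.e_max * xa / (xa + params.xe50**params.alpha)
    return float(eff) if np.isscalar(concentration) or eff.ndim == 0 else eff


def _modal_coefficients(
    gain: float, zeros: Sequence[float], poles: Sequence[float]
) -> tuple[float, list[float]]:
    """Partial-fraction expansion H(s) = d + sum_i c_i / (1 + T_i s).

    Requires distinct pole time constants.  ``d`` is the direct
    feedthrough (nonzero only when pole and zero counts are equal).
    """
    if len(set(poles)) != len(poles):
        raise ValueError("pole time constants must be distinct")
    if len(zeros) == len(poles):
        d = gain * math.prod(zeros) / math.prod(poles)
    else:
        d = 0.0
    residues = []
    for i, ti in enumerate(poles):
        num = gain * math.prod(1.0 - tz / ti for tz in zeros)
        den = math.prod(1.0 - tj / ti for j, tj in enumerate(poles) if j != i)
        residues.append(num / den)
    return d, residues


class DiscreteBlock:
    """Exact zero-order-hold discretization of a :class:`LinearBlockParams`.

    The block is realized as a parallel bank of first-order sections
    (modal form), which makes the ZOH step exact: for a piecewise
    constant input each section obeys
    ``y <- exp(-dt/T) * y + c * (1 - exp(-dt/T)) * u``.
    The dead time is an input-side ring buffer of ``round(tau/dt)``
    steps whose length is fixed at construction.
    """

    def __init__(self, params: LinearBlockParams, dt: float):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if dt >= min(params.pole_time_constants):
            raise ValueError(
                f"dt={dt} must be smaller than the fastest time constant "
                f"{min(params.pole_time_constants)} for a faithful discretization"
            )
        self.params = params
        self.dt = dt
        self.delay_steps = int(round(params.dead_time / dt))
        self._buf = [0.0] * self.delay_steps
        self._head = 0
        self._state = [0.0] * len(params.pole_time_constants)
        self.retune(params.gain, params.zero_time_constants, params.pole_time_constants)

    def retune(
        self, gain: float, zeros: Sequence[float], poles: Sequence[float]
    ) -> None:
        """Recompute recursion coefficients for new continuous parameters.

        The filter state and the delay-buffer length are preserved, so
        this may be called at every step to realize a nonfixed plant.
        """
        if len(poles) != len(self._state):
            raise ValueError("pole count must not change after construction")
        d, residues = _modal_coefficients(gain, zeros, poles)
        self._direct = d
        self._decay = [math.exp(-self.dt / t) for t in poles]
        self._inject = [c * (1.0 - a) for c, a in zip(residues, self._decay)]

    @property
    def dc_gain(self) -> float:
        return self._direct + sum(
            inj / (1.0 - a) if a < 1.0 else 0.0
            for inj, a in zip(self._inject, self._decay)
        )

    def reset(self) -> None:
        self._buf = [0.0] * self.delay_steps
        self._head = 0
        self._state = [0.0] * len(self._state)

    def step(self, u: float) -> float:
        """Advance one sampling interval with input held at ``u``."""
        if self.delay_steps:
            buf = self._buf
            head = self._head
            u, buf[head] = buf[head], u
            self._head = (head + 1) % self.delay_steps
        y = self._direct * u
        state = self._state
        for i, (a, b) in enumerate(zip(self._decay, self._inject)):
            s = a * state[i] + b * u
            state[i] = s
            y += s
        return y


def discretize(params: LinearBlockParams, dt: float) -> DiscreteBlock:
    """Build the exact-ZOH discrete recursion for a linear block."""
    return DiscreteBlock(params, dt)


@dataclass(frozen=True)
class PlantParameters:
    """All parameters of the multivariable anesthetic patient model."""

    g11: LinearBlockParams = ATRACURIUM_PD
    hill: HillParams = HillParams()
    g22: LinearBlockParams = ISOFLURANE_BP
    g12: LinearBlockParams = ISOFLURANE_MR_INTERACTION
    baseline_bp: float = 120.0  # mmHg
    dt: float = 0.01  # minutes; 100 intervals per minute
    u1_scale: float = 1.0  # normalized infusion units -> effect-site ug/mL
    pk_cascade: bool = False  # optionally cascade the stand-alone PK block
    pk: LinearBlockParams = ATRACURIUM_PK

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.baseline_bp <= 0:
            raise ValueError("baseline_bp must be > 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Parametric (plant) and measurement (sensor) white-noise settings.

    ``param_fraction`` multiplies every plant parameter by
    ``1 + param_fraction * z`` with fresh standard-normal ``z`` at every
    sampling instant.  Measurement noise is additive,
    ``meas_fraction * reference_sd`` being the noise SD per channel.
    The reference SDs are fixed, clinically plausible signal-variability
    scales (muscle relaxation on a 0-1 scale, MAP in mmHg).
    """

    param_fraction: float = 0.01
    meas_fraction: float = 0.1
    ref_sd_mr: float = 0.1
    ref_sd_bp: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.param_fraction < 0 or self.meas_fraction < 0:
            raise ValueError("noise fractions must be >= 0")

    def reference_sd(self, channel: str) -> float:
        if channel in ("mr", "paralysis", "muscle_relaxation"):
            return self.ref_sd_mr
        if channel in ("bp", "map"):
            return self.ref_sd_bp
        raise KeyError(f"unknown channel {channel!r}")


_MIN_MULTIPLIER = 1e-3  # keeps perturbed parameters sign-preserving


def _perturb_block(
    block: LinearBlockParams, fraction: float, z: np.ndarray, k: int
) -> tuple[LinearBlockParams, int]:
    def mult() -> float:
        nonlocal k
        m = max(1.0 + fraction * float(z[k]), _MIN_MULTIPLIER)
        k += 1
        return m

    gain = block.gain * mult()
    zeros = tuple(t * mult() for t in block.zero_time_constants)
    poles = tuple(t * mult() for t in block.pole_time_constants)
    # Dead times are not perturbed: the delay-buffer length is fixed at
    # discretization time.
    return replace(
        block, gain=gain, zero_time_constants=zeros, pole_time_constants=poles
    ), k


def perturb_parameters(
    nominal: PlantParameters, fraction: float, rng: np.random.Generator
) -> PlantParameters:
    """One white-noise draw of the nonfixed patient parameters.

    Every gain, time constant and Hill parameter is multiplied by
    ``1 + fraction * z`` (independent standard-normal ``z``), with the
    multiplier clamped positive so that signs and pole stability are
    preserved.  Dead times are left at their nominal values because the
    discrete delay structure is fixed.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    if fraction == 0:
        return nominal
    z = rng.standard_normal(16)
    k = 0
    g11, k = _perturb_block(nominal.g11, fraction, z, k)
    g22, k = _perturb_block(nominal.g22, fraction, z, k)
    g12, k = _perturb_block(nominal.g12, fraction, z, k)
    m = [max(1.0 + fraction * float(z[k + i]), _MIN_MULTIPLIER) for i in range(3)]
    hill = HillParams(
        e_max=nominal.hill.e_max * m[0],
        xe50=nominal.hill.xe50 * m[1],
        alpha=nominal.hill.alpha * m[2],
    )
    return replace(nominal, g11=g11, g22=g22, g12=g12, hill=hill)


def add_measurement_noise(
    clean: float, channel: str, noise: NoiseConfig, rng: np.random.Generator
) -> float:
    """Additive zero-mean Gaussian sensor noise on one sample."""
    if noise.meas_fraction == 0:
        return clean
    sd = noise.reference_sd(channel)
    if sd <= 0:
        raise ValueError("reference SD must be > 0")
    return clean + noise.meas_fraction * sd * float(rng.standard_normal())


class Plant:
    """Steppable nonfixed multivariable patient model.

    ``step(u1, u2)`` advances one sampling interval and returns the
    clean ``(paralysis, map)`` pair.  ``u1`` is the atracurium infusion
    in normalized units, ``u2`` the inhaled isoflurane concentration in
    percent.  With ``param_fraction > 0`` every continuous parameter is
    redrawn around its nominal value at each step before the recursion
    coefficients are updated (white parametric noise, not a random
    walk).
    """

    def __init__(
        self,
        params: PlantParameters = PlantParameters(),
        param_fraction: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        self.params = params
        self.param_fraction = param_fraction
        self.rng = rng if rng is not None else np.random.default_rng()
        self.g11 = DiscreteBlock(params.g11, params.dt)
        self.g22 = DiscreteBlock(params.g22, params.dt)
        self.g12 = DiscreteBlock(params.g12, params.dt)
        self.pk = DiscreteBlock(params.pk, params.dt) if params.pk_cascade else None
        self._hill = params.hill
        self.paralysis = 0.0
        self.map = params.baseline_bp

    def reset(self) -> None:
        for blk in (self.g11, self.g22, self.g12, self.pk):
            if blk is not None:
                blk.reset()
        self.paralysis = 0.0
        self.map = self.params.baseline_bp

    def _redraw_parameters(self) -> None:
        # Hot path: equivalent to perturb_parameters + retune, but
        # without constructing the frozen parameter dataclasses.
        f = self.param_fraction
        z = self.rng.standard_normal(13)
        k = 0

        def mult() -> float:
            nonlocal k
            m = max(1.0 + f * float(z[k]), _MIN_MULTIPLIER)
            k += 1
            return m

        for blk, nom in ((self.g11, self.params.g11), (self.g22, self.params.g22),
                         (self.g12, self.params.g12)):
            gain = nom.gain * mult()
            zeros = tuple(t * mult() for t in nom.zero_time_constants)
            poles = tuple(t * mult() for t in nom.pole_time_constants)
            blk.retune(gain, zeros, poles)
        hill = self.params.hill
        self._hill = HillParams(
            e_max=hill.e_max * mult(), xe50=hill.xe50 * mult(), alpha=hill.alpha * mult()
        )

    def step(self, u1: float, u2: float) -> tuple[float, float]:
        if u1 < 0 or u2 < 0:
            raise ValueError("drug inputs must be >= 0")
        if self.param_fraction > 0:
            self._redraw_parameters()
        p = self.params
        drive = u1 * p.u1_scale
        if self.pk is not None:
            drive = self.pk.step(drive)
        conc = self.g11.step(drive)
        effect = hill_effect(max(conc, 0.0), self._hill)
        interaction = self.g12.step(u2)
        paralysis = min(max(effect / 100.0 + interaction, 0.0), 1.0)
        bp = p.baseline_bp + self.g22.step(u2)
        self.paralysis = paralysis
        self.map = bp
        return paralysis, bp


def open_loop_response(
    u1: float | Callable[[float], float],
    u2: float | Callable[[float], float],
    params: PlantParameters = PlantParameters(),
    horizon: float = 60.0,
) -> dict[str, np.ndarray]:
    """Noise-free trajectory under prescribed open-loop inputs.

    ``u1``/``u2`` may be constants or callables of time (minutes).
    Returns arrays ``time_min, u1, u2, paralysis, map`` at ``dt``
    resolution.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    n = int(round(horizon / params.dt))
    plant = Plant(params)
    f1 = u1 if callable(u1) else (lambda t, _v=float(u1): _v)
    f2 = u2 if callable(u2) else (lambda t, _v=float(u2): _v)
    t = np.arange(n) * params.dt
    out = {
        "time_min": t,
        "u1": np.empty(n),
        "u2": np.empty(n),
        "paralysis": np.empty(n),
        "map": np.empty(n),
    }
    for i, ti in enumerate(t):
        v1, v2 = f1(ti), f2(ti)
        mr, bp = plant.step(v1, v2)
        out["u1"][i] = v1
        out["u2"][i] = v2
        out["paralysis"][i] = mr
        out["map"][i] = bp
    return out
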