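"""Self-organizing layer of the fuzzy anesthesia controller.

The controller reads four inputs — the error and the integrated error of
muscle relaxation (MR) and of mean arterial pressure (BP) — and emits
two drug-adjustment signals (atracurium infusion, isoflurane
concentration).  The 4-input/2-output problem is decomposed into the six
2-input/1-output subsystems formed by the unordered input pairs; each
output channel carries its own rule-base over all six pairs, and the six
defuzzified subsystem outputs superpose (sum, saturating at full scale)
into one crisp adjustment magnitude per channel.

Rule consequents are magnitude labels (ZE..PB).  The *direction* of an
adjustment is the sign that reduces the channel's own error: atracurium
is raised while paralysis is below its set point, isoflurane while MAP
is above its set point.  The self-organizing (SO) mechanism scores the
controller at each step through a 7x7 linguistic performance-index
matrix on the channel's (error, integrated-error) labels, and — after a
credit-assignment delay matched to the channel's plant dead time —
shifts the consequent of the maximally firing rule of each subsystem by
the correction's signed label offset, generating new rules for
antecedent combinations that had none.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fuzzy_core.inference import defuzzify_zslices, km_type_reduce, output_grid
from .fuzzy_core.rules import Rule, RuleBase
from .fuzzy_core.sets import (
    INPUT_LABELS,
    OUTPUT_LABELS,
    IntervalType2Set,
    LinguisticVariable,
    TriangularMF,
    ZSliceSet,
    _blurred_triangle,
    as_slices,
    build_partition,
)

__all__ = [
    "PAIRS",
    "ControllerInputs",
    "ControllerGains",
    "PerformanceIndexMatrix",
    "FiringStats",
    "RuleHistoryBuffer",
    "StepRecord",
    "SelfOrganizingController",
    "decompose",
    "pi_lookup",
    "label_inputs",
    "label_offset",
    "offset_to_correction",
    "so_update",
    "record_firing",
    "firing_percentages",
    "extract_rules",
    "fixture_path",
]

#: The six decomposed 2-input subsystems, in their fixed reporting order.
PAIRS = (
    ("E_MR", "IE_MR"),
    ("E_MR", "E_BP"),
    ("E_MR", "IE_BP"),
    ("IE_MR", "E_BP"),
    ("IE_MR", "IE_BP"),
    ("E_BP", "IE_BP"),
)

_DATA_DIR = Path(__file__).parent / "data"


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture (rule-bases, PI matrix)."""
    return _DATA_DIR / name


@dataclass
class ControllerInputs:
    """The four controller inputs, each scaled to its [-1, 1] universe."""

    e_mr: float
    ie_mr: float
    e_bp: float
    ie_bp: float

    def as_dict(self) -> dict[str, float]:
        return {
            "E_MR": self.e_mr,
            "IE_MR": self.ie_mr,
            "E_BP": self.e_bp,
            "IE_BP": self.ie_bp,
        }


def decompose(inputs: ControllerInputs) -> list[tuple[tuple[str, str], tuple[float, float]]]:
    """The six ordered (variable-pair, value-pair) subsystem inputs."""
    values = inputs.as_dict()
    return [(pair, (values[pair[0]], values[pair[1]])) for pair in PAIRS]


def label_offset(label: str) -> int:
    """Signed index offset of a linguistic label (ZE -> 0, PB -> +3, NB -> -3)."""
    return INPUT_LABELS.index(label) - INPUT_LABELS.index("ZE")


def offset_to_correction(offset: int) -> str:
    """Label for a signed offset, saturating at NB/PB."""
    return INPUT_LABELS[min(max(offset, -3), 3) + INPUT_LABELS.index("ZE")]


class PerformanceIndexMatrix:
    """7x7 lookup from (error label, integration-error label) to a
    correction label; rows and columns are nondecreasing in the label
    order, which is asserted at load."""

    def __init__(self, table: dict[tuple[str, str], str]):
        for e in INPUT_LABELS:
            for ie in INPUT_LABELS:
                if (e, ie) not in table:
                    raise ValueError(f"missing PI cell ({e}, {ie})")
        self.table = dict(table)
        self._validate_monotone()

    def _validate_monotone(self) -> None:
        order = {lab: i for i, lab in enumerate(INPUT_LABELS)}
        for e in INPUT_LABELS:
            row = [order[self.table[e, ie]] for ie in INPUT_LABELS]
            if any(b < a for a, b in zip(row, row[1:])):
                raise ValueError(f"PI row {e} is not nondecreasing")
        for ie in INPUT_LABELS:
            col = [order[self.table[e, ie]] for e in INPUT_LABELS]
            if any(b < a for a, b in zip(col, col[1:])):
                raise ValueError(f"PI column {ie} is not nondecreasing")

    @classmethod
    def from_csv(cls, path: str | Path | None = None) -> "PerformanceIndexMatrix":
        path = Path(path) if path is not None else fixture_path("pi_matrix.csv")
        table: dict[tuple[str, str], str] = {}
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                e = row["error"]
                for ie in INPUT_LABELS:
                    table[e, ie] = row[ie]
        return cls(table)

    def lookup(self, e_label: str, ie_label: str) -> str:
        if e_label not in INPUT_LABELS or ie_label not in INPUT_LABELS:
            raise KeyError(f"unknown label ({e_label}, {ie_label})")
        return self.table[e_label, ie_label]


def pi_lookup(matrix: PerformanceIndexMatrix, e_label: str, ie_label: str) -> str:
    return matrix.lookup(e_label, ie_label)


def label_inputs(x: float, variable) -> str:
    """Best-matching label of a crisp input: maximal upper-MF membership,
    ties resolved toward ZE."""
    x = variable.clamp(x)
    ze = variable.labels.index("ZE") if "ZE" in variable.labels else 0
    best_mu = -1.0
    best_key: tuple[int, int] | None = None
    best_lab = variable.labels[0]
    for i, lab in enumerate(variable.labels):
        _, slices = as_slices(variable.sets[lab])
        mu = float(slices[0].upper(x))
        key = (abs(i - ze), i)
        if mu > best_mu + 1e-9 or (mu > best_mu - 1e-9 and key < best_key):
            best_mu, best_key, best_lab = mu, key, lab
    return best_lab


class FiringStats:
    """Per-rule fire counts over the total number of inference operations."""

    def __init__(self) -> None:
        self.counts: dict[tuple[str, str, str, str], int] = {}
        self.total = 0

    def record(self, fired: list[tuple[str, str, str, str]]) -> None:
        """Count one inference operation and the rules it fired."""
        self.total += 1
        for sig in fired:
            self.counts[sig] = self.counts.get(sig, 0) + 1

    def percentages(self) -> dict[tuple[str, str, str, str], float]:
        if self.total == 0:
            raise ZeroDivisionError("no inference operations recorded")
        return {sig: 100.0 * n / self.total for sig, n in self.counts.items()}

    def percentage(self, sig: tuple[str, str, str, str]) -> float:
        if self.total == 0:
            raise ZeroDivisionError("no inference operations recorded")
        return 100.0 * self.counts.get(sig, 0) / self.total


def record_firing(stats: FiringStats, fired: list[tuple[str, str, str, str]]) -> None:
    stats.record(fired)


def firing_percentages(stats: FiringStats) -> dict[tuple[str, str, str, str], float]:
    return stats.percentages()


def extract_rules(
    rulebase: RuleBase, stats: FiringStats, threshold: float = 1.0
) -> RuleBase:
    """Drop trivial rules: those fired in less than ``threshold`` percent
    of the inference operations (never-fired rules included)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0:
        return rulebase.copy()
    pct = stats.percentages()
    kept = [r for r in rulebase.rules() if pct.get(r.signature, 0.0) >= threshold]
    if not kept:
        import warnings

        warnings.warn("rule extraction removed every rule; controller would be inert")
    return RuleBase(rulebase.output_var, kept)


@dataclass
class StepRecord:
    """What the SO mechanism needs to assign delayed credit for one step."""

    labels: dict[str, str]  # crisp best label per input variable
    max_rule: dict[tuple[str, str], tuple[str, str, str, str] | None]
    direction: int = 0  # sign of the drug adjustment applied at this step
    demand: tuple[float, float] = (0.0, 0.0)  # channel (error, int-error), drug-demand sign


class RuleHistoryBuffer:
    """FIFO of recent step records, sized to the credit-assignment delay."""

    def __init__(self, delay_steps: int):
        if delay_steps < 0:
            raise ValueError("delay must be >= 0")
        self.delay_steps = delay_steps
        self._buf: deque[StepRecord] = deque(maxlen=delay_steps + 1)

    def push(self, record: StepRecord) -> StepRecord | None:
        """Append the newest record; return the responsible record
        (``delay_steps`` ago) once the buffer has filled."""
        self._buf.append(record)
        if len(self._buf) == self._buf.maxlen:
            return self._buf[0]
        return None

    def __len__(self) -> int:
        return len(self._buf)


def so_update(
    rulebase: RuleBase, record: StepRecord, correction: str
) -> list[tuple[str, tuple[str, str, str, str], str, str]]:
    """Apply one SO correction to the rules responsible at ``record``.

    For each decomposed subsystem the maximally firing rule's consequent
    is shifted by the correction's signed label offset, saturating at
    the output label range; a subsystem whose antecedent signature had
    no rule gets a new rule with consequent ``saturate(ZE + offset)``.
    A ZE correction leaves the rule-base untouched.  Returns a change
    log of (action, signature, old, new) tuples.
    """
    off = label_offset(correction)
    if off == 0:
        return []
    lo, hi = 0, len(OUTPUT_LABELS) - 1
    changes: list[tuple[str, tuple[str, str, str, str], str, str]] = []
    for pair in PAIRS:
        sig = record.max_rule.get(pair)
        if sig is not None:
            rule = rulebase.get(sig)
            if rule is None:
                continue
            idx = OUTPUT_LABELS.index(rule.consequent)
            new = OUTPUT_LABELS[min(max(idx + off, lo), hi)]
            if new != rule.consequent:
                changes.append(("modify", sig, rule.consequent, new))
                rulebase.put(Rule(rule.in1, rule.in2, new))
        else:
            v1, v2 = pair
            new_sig = (v1, record.labels[v1], v2, record.labels[v2])
            if new_sig not in rulebase:
                cons = OUTPUT_LABELS[min(max(off, lo), hi)]
                changes.append(("add", new_sig, "", cons))
                rulebase.put(
                    Rule.make((v1, record.labels[v1]), (v2, record.labels[v2]), cons)
                )
    return changes


@dataclass(frozen=True)
class ControllerGains:
    """Input/output scaling of the controller.

    Errors are scaled so the expected operating excursions (0.2 of
    full paralysis, 30 mmHg of MAP) map onto the [-1, 1] input
    universes.  Integrated errors leak with a 20-minute forgetting time
    constant (anti-windup) and are clamped to their universe.  The
    defuzzified output magnitude (0..1) is an adjustment *rate*: at
    full strength (PB) a drug signal moves by ``rate_per_min`` of its
    full scale ``u_max`` per minute.  The atracurium rate is much
    slower than the isoflurane rate because its plant settles over
    tens of minutes rather than a couple of minutes.
    """

    e_scale_mr: float = 0.2  # paralysis fraction mapping to |e| = 1
    e_scale_bp: float = 30.0  # mmHg mapping to |e| = 1
    ie_scale_mr: float = 2.0  # paralysis * min
    ie_scale_bp: float = 300.0  # mmHg * min
    ie_leak_minutes: float = 20.0  # integrated-error forgetting time constant
    u1_max: float = 2.0  # normalized atracurium units (full scale)
    u2_max: float = 4.0  # percent isoflurane (full scale)
    rate_atr_per_min: float = 0.005  # full-scale fraction per minute at PB
    rate_iso_per_min: float = 0.02


_KINDS = ("type1", "interval_t2", "zslice_t2")


def magnitude_partition(
    fou_width: float = 0.0, n_zslices: int | None = None
) -> LinguisticVariable:
    """Output partition for drug-adjustment magnitudes.

    ZE peaks at zero magnitude (its symmetric triangle extends to -1/3
    so that an all-ZE inference defuzzifies to exactly zero); PS, PM and
    PB peak at 1/3, 2/3 and 1.  The crisp controller magnitude is the
    defuzzified value clamped to [0, 1].
    """
    peaks = {"ZE": 0.0, "PS": 1 / 3, "PM": 2 / 3, "PB": 1.0}
    sets: dict[str, object] = {}
    for lab, p in peaks.items():
        left, right = p - 1 / 3, min(p + 1 / 3, 1.0)
        if fou_width == 0:
            sets[lab] = TriangularMF(left, p, right)
        elif not n_zslices:
            sets[lab] = _blurred_triangle(left, p, right, fou_width)
        else:
            z = tuple((k + 1) / n_zslices for k in range(n_zslices))
            widths = [fou_width * (1 - k / n_zslices) for k in range(n_zslices)]
            sets[lab] = ZSliceSet(
                z, tuple(_blurred_triangle(left, p, right, w) for w in widths)
            )
    return LinguisticVariable(
        name="magnitude", universe=(-1 / 3, 1.0), sets=sets, labels=OUTPUT_LABELS
    )


class SelfOrganizingController:
    """Complete SOFLC: fuzzifier, Mamdani inference, KM type reduction,
    defuzzifier, plus the self-organizing rule-adaptation layer.

    ``kind`` selects the fuzzy machinery: plain type-1 sets,
    interval type-2 sets (triangles blurred by ``fou_width`` into a
    footprint of uncertainty), or a zSlices general type-2 stack of
    ``n_zslices`` nested FOUs.  ``fou_width`` is expressed as a fraction
    of the universe span.
    """

    def __init__(
        self,
        kind: str,
        atr_rules: RuleBase,
        iso_rules: RuleBase,
        *,
        gains: ControllerGains | None = None,
        pi_matrix: PerformanceIndexMatrix | None = None,
        fou_width: float = 0.05,
        n_zslices: int = 5,
        control_period: float = 0.1,  # minutes between controller updates
        credit_delay_mr: float = 1.0,  # minutes; atracurium path dead time
        credit_delay_bp: float = 0.42,  # minutes; isoflurane path dead time
        adapt: bool = True,
        track_firing: bool = True,
        so_cooldown: bool = False,
        grid_points: int = 1001,
    ):
        if kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        self.kind = kind
        self.so_cooldown = so_cooldown
        self.gains = gains or ControllerGains()
        self.pi = pi_matrix or PerformanceIndexMatrix.from_csv()
        self.adapt = adapt
        self.track_firing = track_firing
        self.control_period = control_period
        self.rulebases = {"atracurium": atr_rules, "isoflurane": iso_rules}

        width = 0.0 if kind == "type1" else fou_width
        slices = n_zslices if kind == "zslice_t2" else None
        in_span, out_span = 2.0, 4.0 / 3.0
        self.input_var = build_partition(
            (-1.0, 1.0), INPUT_LABELS, width * in_span, slices, name="input"
        )
        self.output_var = magnitude_partition(width * out_span, slices)
        # Crisp labelling (for the PI lookup) always uses the type-1 geometry.
        self._label_var = build_partition((-1.0, 1.0), INPUT_LABELS, 0.0, name="crisp")

        # Pre-evaluated machinery: per slice, per label, the input
        # triangle coefficients and the output membership grids.
        self._grid = output_grid(self.output_var.universe, grid_points)
        self._in_slices: list[dict[str, IntervalType2Set]] = []
        self._out_lo: list[dict[str, np.ndarray]] = []
        self._out_hi: list[dict[str, np.ndarray]] = []
        self.z_levels: tuple[float, ...] = (1.0,)
        for lab in INPUT_LABELS:
            z, sl = as_slices(self.input_var.sets[lab])
            self.z_levels = z
            for k, s in enumerate(sl):
                if len(self._in_slices) <= k:
                    self._in_slices.append({})
                self._in_slices[k][lab] = s
        for lab in OUTPUT_LABELS:
            _, sl = as_slices(self.output_var.sets[lab])
            for k, s in enumerate(sl):
                if len(self._out_lo) <= k:
                    self._out_lo.append({})
                    self._out_hi.append({})
                self._out_lo[k][lab] = np.asarray(s.lower(self._grid))
                self._out_hi[k][lab] = np.asarray(s.upper(self._grid))

        self._delay = {
            "atracurium": max(int(round(credit_delay_mr / control_period)), 0),
            "isoflurane": max(int(round(credit_delay_bp / control_period)), 0),
        }
        self.stats = {"atracurium": FiringStats(), "isoflurane": FiringStats()}
        self.change_log: list[tuple[float, str, str, tuple, str, str]] = []
        self.reset()

    def reset(self) -> None:
        self.u1 = 0.0
        self.u2 = 0.0
        self._ie_mr = 0.0
        self._ie_bp = 0.0
        self._t = 0.0
        self.history = {
            ch: RuleHistoryBuffer(self._delay[ch]) for ch in self.rulebases
        }
        self._last_modified = {ch: {} for ch in self.rulebases}
        self._step_count = 0
        self.last_fired = 0
        self.last_added = 0

    # -- fuzzification ------------------------------------------------

    def _memberships(self, x: float, k: int) -> dict[str, tuple[float, float]]:
        """(lower, upper) membership of ``x`` in every input label, slice k."""
        out = {}
        for lab, s in self._in_slices[k].items():
            hi = float(s.upper(x))
            if hi > 0.0:
                out[lab] = (float(s.lower(x)), hi)
        return out

    # -- one subsystem inference --------------------------------------

    def _infer_pair(
        self,
        rules: dict[tuple[str, str], str],
        mu1: list[dict[str, tuple[float, float]]],
        mu2: list[dict[str, tuple[float, float]]],
    ) -> tuple[float | None, list[tuple[str, str]]]:
        """Crisp magnitude of one 2-input subsystem, or None if no rule
        fires; also returns the fired label-pairs (widest slice)."""
        per_slice: list[tuple[float, float]] = []
        fired_widest: list[tuple[str, str]] = []
        for k, z in enumerate(self.z_levels):
            m1, m2 = mu1[k], mu2[k]
            # max firing per consequent label (min t-norm, max aggregation)
            f_lo: dict[str, float] = {}
            f_hi: dict[str, float] = {}
            fired_here = []
            for l1, (lo1, hi1) in m1.items():
                for l2, (lo2, hi2) in m2.items():
                    cons = rules.get((l1, l2))
                    if cons is None:
                        continue
                    fl, fh = min(lo1, lo2), min(hi1, hi2)
                    if fh <= 0.0:
                        continue
                    fired_here.append((l1, l2))
                    if fl > f_lo.get(cons, -1.0):
                        f_lo[cons] = fl
                    if fh > f_hi.get(cons, -1.0):
                        f_hi[cons] = fh
            if k == 0:
                fired_widest = fired_here
            if not f_hi:
                # A narrower slice may fail to fire even when a wider one
                # did; it then contributes nothing.
                continue
            env_lo = None
            env_hi = None
            out_lo, out_hi = self._out_lo[k], self._out_hi[k]
            for cons, fh in f_hi.items():
                t_hi = np.minimum(out_hi[cons], fh)
                t_lo = np.minimum(out_lo[cons], f_lo.get(cons, 0.0))
                env_hi = t_hi if env_hi is None else np.maximum(env_hi, t_hi)
                env_lo = t_lo if env_lo is None else np.maximum(env_lo, t_lo)
            yl, yr = km_type_reduce(self._grid, env_lo, env_hi)
            per_slice.append((z, (yl, yr)))
        if not per_slice:
            return None, fired_widest
        y = defuzzify_zslices(
            [z for z, _ in per_slice], [iv for _, iv in per_slice]
        )
        return y, fired_widest

    # -- the control step ---------------------------------------------

    def step(
        self, mr_meas: float, bp_meas: float, mr_set: float, bp_set: float
    ) -> tuple[float, float]:
        """One controller update; returns the new (u1, u2) drug signals."""
        g = self.gains
        h = self.control_period
        e_mr = mr_meas - mr_set
        e_bp = bp_meas - bp_set
        self._ie_mr += (e_mr - self._ie_mr / g.ie_leak_minutes) * h
        self._ie_bp += (e_bp - self._ie_bp / g.ie_leak_minutes) * h

        clamp = self.input_var.clamp
        inputs = ControllerInputs(
            e_mr=clamp(e_mr / g.e_scale_mr),
            ie_mr=clamp(self._ie_mr / g.ie_scale_mr),
            e_bp=clamp(e_bp / g.e_scale_bp),
            ie_bp=clamp(self._ie_bp / g.ie_scale_bp),
        )
        values = inputs.as_dict()
        mu = {
            var: [self._memberships(x, k) for k in range(len(self.z_levels))]
            for var, x in values.items()
        }
        crisp_labels = {
            var: label_inputs(x, self._label_var) for var, x in values.items()
        }

        # Direction that reduces each channel's own error: atracurium is
        # raised while paralysis is below its set point, isoflurane while
        # MAP is above its set point.
        directions = {
            "atracurium": int(e_mr < 0) - int(e_mr > 0),
            "isoflurane": int(e_bp > 0) - int(e_bp < 0),
        }
        # Channel-oriented "drug demand" errors: positive when the channel
        # needs more drug (atracurium raises paralysis, so its demand is
        # the negated error; isoflurane lowers MAP, so demand follows the
        # raw error).
        demand = {
            "atracurium": (-inputs.e_mr, -inputs.ie_mr),
            "isoflurane": (inputs.e_bp, inputs.ie_bp),
        }

        self.last_fired = 0
        self.last_added = 0
        magnitudes: dict[str, float] = {}
        for channel, rb in self.rulebases.items():
            ys = []
            max_rule: dict[tuple[str, str], tuple | None] = {}
            for pair in PAIRS:
                rules = rb.pair_rules(pair)
                y, fired = self._infer_pair(rules, mu[pair[0]], mu[pair[1]])
                sigs = [(pair[0], l1, pair[1], l2) for l1, l2 in fired]
                if self.track_firing:
                    self.stats[channel].record(sigs)
                self.last_fired += len(sigs)
                if y is not None:
                    ys.append(y)
                    # blame the maximally firing rule (by upper firing bound)
                    best = max(
                        fired,
                        key=lambda p: min(
                            mu[pair[0]][0][p[0]][1], mu[pair[1]][0][p[1]][1]
                        ),
                    )
                    max_rule[pair] = (pair[0], best[0], pair[1], best[1])
                else:
                    max_rule[pair] = None
                    if self.adapt and not rules.get(
                        (crisp_labels[pair[0]], crisp_labels[pair[1]])
                    ):
                        # keep a reduced rule-base alive: seed a neutral rule
                        sig = (
                            pair[0],
                            crisp_labels[pair[0]],
                            pair[1],
                            crisp_labels[pair[1]],
                        )
                        if sig not in rb:
                            rb.put(
                                Rule.make(
                                    (pair[0], crisp_labels[pair[0]]),
                                    (pair[1], crisp_labels[pair[1]]),
                                    "ZE",
                                )
                            )
                            self.last_added += 1
            # Superpose the decomposed subsystems: each contributes its own
            # share of the demanded drug level; the sum saturates at full
            # scale.  (Subsystems with no fired rule contribute nothing.)
            magnitudes[channel] = min(max(float(np.sum(ys)), 0.0), 1.0) if ys else 0.0

            if self.adapt:
                record = StepRecord(
                    labels=crisp_labels,
                    max_rule=max_rule,
                    direction=directions[channel],
                    demand=demand[channel],
                )
                responsible = self.history[channel].push(record)
                if responsible is not None:
                    self._apply_so(channel, responsible, demand[channel])

        # The crisp magnitudes are adjustment rates; the drug signals
        # integrate them (velocity-form control) and clamp at the
        # physical range.
        self.u1 += (
            directions["atracurium"] * magnitudes["atracurium"]
            * g.rate_atr_per_min * g.u1_max * h
        )
        self.u1 = min(max(self.u1, 0.0), g.u1_max)
        self.u2 += (
            directions["isoflurane"] * magnitudes["isoflurane"]
            * g.rate_iso_per_min * g.u2_max * h
        )
        self.u2 = min(max(self.u2, 0.0), g.u2_max)
        self._t += h
        self._step_count += 1
        return self.u1, self.u2

    def _apply_so(
        self, channel: str, responsible: StepRecord, demand_now: tuple[float, float]
    ) -> None:
        """Delayed credit assignment: the performance index is read off the
        *current* deviation (which reflects the action taken one plant
        dead time ago), and applied to the rules fired at the responsible
        step."""
        e_dem, ie_dem = demand_now
        e_lab = label_inputs(e_dem, self._label_var)
        ie_lab = label_inputs(ie_dem, self._label_var)
        corr = self.pi.lookup(e_lab, ie_lab)
        # The correction is a signed change of drug demand; rule
        # consequents are unsigned adjustment magnitudes that were
        # applied with the responsible step's direction, so that sign is
        # folded into the label shift.
        off = label_offset(corr) * responsible.direction
        if off == 0:
            return
        # Optionally, a freshly modified rule is immune for one credit-
        # assignment delay, so its effect can be observed before it is
        # judged again.
        cooldown = (self._delay[channel] + 1) if self.so_cooldown else 0
        record = StepRecord(
            labels=responsible.labels,
            max_rule={
                pair: sig
                for pair, sig in responsible.max_rule.items()
                if sig is None
                or self._step_count - self._last_modified[channel].get(sig, -cooldown)
                >= cooldown
            },
            direction=responsible.direction,
            demand=responsible.demand,
        )
        changes = so_update(
            self.rulebases[channel], record, offset_to_correction(off)
        )
        for action, sig, old, new in changes:
            self._last_modified[channel][sig] = self._step_count
            self.change_log.append((self._t, channel, action, sig, old, new))
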