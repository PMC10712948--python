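"""Paced action potentials of phenotypically scaled ventricular myocytes.

The production model is the O'Hara-Rudy (2011) endocardial myocyte with a
fixed baseline rescaling of six maximal conductances/permeabilities
(:data:`BASELINE_RESCALING`) that biases the model toward long-QT-like
behaviour, so that early afterdepolarizations are reachable within the
study's parameter domain. On top of that baseline, each virtual cell
carries four dimensionless multipliers (gCaL, gKr, gNaL, gKs) whose natural
logs are the coordinates of the analysis space.

Cells are paced at 1 Hz with a -70 uA/uF, 0.5 ms stimulus current,
equilibrated for 1000 beats, and the final four beats are recorded at 1 ms
resolution for ectopy classification.

Two solvers are available: ``"lsoda"`` (adaptive stiff integration through
scipy, honouring the configured tolerances) and ``"rush-larsen"`` (fixed
step, exponential integration of the gating variables), which is roughly an
order of magnitude faster and is the default for population runs.

A cheap surrogate generator (:func:`surrogate_simulate`) produces template
action potentials, with an EAD bump inserted according to a configurable
linear rule in log-multiplier space, so the downstream pipeline can be
exercised without integrating the biophysical model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import _ord

#: Fixed multipliers applied once to the published ORd endocardial values,
#: before any cell-specific scaling.
BASELINE_RESCALING = {
    "GKs": 8.09,
    "GKr": 1.17,
    "PCa": 3.57,   # GCaL permeability
    "Gncx": 3.05,  # PNaCa
    "Pnak": 1.91,  # PNaK
    "GNaL": 1.7,
}

_RESCALE_INDEX = {
    "GKs": _ord.P_GKS,
    "GKr": _ord.P_GKR,
    "PCa": _ord.P_PCA,
    "Gncx": _ord.P_GNCX,
    "Pnak": _ord.P_PNAK,
    "GNaL": _ord.P_GNAL,
}


class SimulationError(RuntimeError):
    """ODE integration failed; carries the offending multipliers."""

    def __init__(self, message: str, multipliers: "ConductanceMultipliers | None" = None):
        super().__init__(message)
        self.multipliers = multipliers


@dataclass(frozen=True)
class ConductanceMultipliers:
    """Cell-specific scale factors for the four analysis channels."""

    gCaL: float = 1.0
    gKr: float = 1.0
    gNaL: float = 1.0
    gKs: float = 1.0

    def __post_init__(self) -> None:
        for name, g in zip(("gCaL", "gKr", "gNaL", "gKs"), self.as_tuple()):
            if not (g > 0 and math.isfinite(g)):
                raise ValueError(f"{name} must be a positive finite number, got {g}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.gCaL, self.gKr, self.gNaL, self.gKs)

    def log(self) -> np.ndarray:
        """Coordinates X = ln(G) in the analysis space (CaL, Kr, NaL, Ks)."""
        return np.log(np.asarray(self.as_tuple()))

    @classmethod
    def from_log(cls, X: Sequence[float]) -> "ConductanceMultipliers":
        X = np.asarray(X, dtype=float)
        if X.shape != (4,):
            raise ValueError("log-multiplier vector must have 4 components")
        g = np.exp(X)
        return cls(gCaL=g[0], gKr=g[1], gNaL=g[2], gKs=g[3])


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic current-pulse pacing.

    ``stim_amplitude`` is in the model's stimulus-current units (uA/uF);
    the default -70 for 0.5 ms at a 1000 ms cycle length reproduces the
    study protocol. ``equilibration_beats`` are integrated without
    recording; the final ``recorded_beats`` are kept for classification.
    """

    cycle_length: float = 1000.0  # ms
    stim_amplitude: float = -70.0  # uA/uF
    stim_duration: float = 0.5  # ms
    equilibration_beats: int = 1000
    recorded_beats: int = 4

    def __post_init__(self) -> None:
        if not (self.cycle_length > self.stim_duration > 0):
            raise ValueError("need cycle_length > stim_duration > 0")
        if self.equilibration_beats < 0:
            raise ValueError("equilibration_beats must be >= 0")
        if self.recorded_beats < 1:
            raise ValueError("recorded_beats must be >= 1")


@dataclass(frozen=True)
class SolverSettings:
    """Integration settings.

    ``method`` is ``"rush-larsen"`` (fixed-step hybrid integrator) or
    ``"lsoda"`` (adaptive stiff solver with the configured tolerances,
    AbsTol 1e-3 / RelTol 1e-6 by default). ``sample_dt`` is the recording
    resolution in ms; peak classification needs <= 1 ms.
    """

    method: str = "rush-larsen"
    abs_tol: float = 1e-3
    rel_tol: float = 1e-6
    max_step: float = np.inf
    sample_dt: float = 1.0
    dt_fine: float = 0.005   # ms, during stimulus/upstroke window
    dt_coarse: float = 0.02  # ms, remainder of the beat
    fine_window: float = 20.0  # ms

    def __post_init__(self) -> None:
        if self.abs_tol <= 0 or self.rel_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.method not in ("rush-larsen", "lsoda"):
            raise ValueError(f"unknown solver method {self.method!r}")
        if not (0 < self.sample_dt <= 1.0):
            raise ValueError("sample_dt must be in (0, 1] ms")


@dataclass
class APTrace:
    """Recorded membrane-voltage trace over the final paced beats."""

    time: np.ndarray  # ms, strictly increasing, 0 at first recorded beat
    vm: np.ndarray    # mV
    protocol: PacingProtocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.vm.shape:
            raise ValueError("time and vm must be matching 1-D arrays")
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(np.ceil((self.time[-1] + 1e-9) / self.protocol.cycle_length))

    def beat_slices(self) -> list[np.ndarray]:
        """Boolean masks for half-open beat windows [k*CL, (k+1)*CL)."""
        cl = self.protocol.cycle_length
        return [
            (self.time >= k * cl) & (self.time < (k + 1) * cl)
            for k in range(self.n_beats)
        ]

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV (time_ms, vm_mV) with '#'-prefixed metadata."""
        lines = [
            f"# cycle_length_ms={self.protocol.cycle_length}",
            f"# stim_amplitude={self.protocol.stim_amplitude}",
            f"# stim_duration_ms={self.protocol.stim_duration}",
        ]
        lines += [f"# {k}={v}" for k, v in self.meta.items()]
        lines.append("time_ms,vm_mV")
        lines += [f"{t:.6g},{v:.8g}" for t, v in zip(self.time, self.vm)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "APTrace":
        meta: dict = {}
        rows = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v.strip()
            elif line and not line.startswith("time_ms"):
                t, v = line.split(",")
                rows.append((float(t), float(v)))
        protocol = PacingProtocol(
            cycle_length=float(meta.pop("cycle_length_ms", 1000.0)),
            stim_amplitude=float(meta.pop("stim_amplitude", -70.0)),
            stim_duration=float(meta.pop("stim_duration_ms", 0.5)),
        )
        arr = np.asarray(rows)
        return cls(time=arr[:, 0], vm=arr[:, 1], protocol=protocol, meta=meta)


def build_scaled_parameters(
    multipliers: ConductanceMultipliers | Sequence[float],
) -> np.ndarray:
    """Full ORd parameter vector with baseline rescaling then cell multipliers.

    The published endocardial values are first multiplied by
    :data:`BASELINE_RESCALING` and then gCaL, gKr, gNaL, gKs scale PCa, GKr,
    GNaL, GKs respectively. All other parameters are untouched.
    """
    if not isinstance(multipliers, ConductanceMultipliers):
        multipliers = ConductanceMultipliers(*multipliers)
    p = _ord.BASE_PARAMS.copy()
    for name, factor in BASELINE_RESCALING.items():
        p[_RESCALE_INDEX[name]] *= factor
    p[_ord.P_PCA] *= multipliers.gCaL
    p[_ord.P_GKR] *= multipliers.gKr
    p[_ord.P_GNAL] *= multipliers.gNaL
    p[_ord.P_GKS] *= multipliers.gKs
    return p


def _simulate_lsoda(y, p, protocol, solver):
    """Beat-by-beat adaptive integration; returns recorded (t, vm)."""
    cl, dur, amp = protocol.cycle_length, protocol.stim_duration, protocol.stim_amplitude

    def run(t0, t1, ist, t_eval=None):
        sol = solve_ivp(
            _ord.rhs,
            (t0, t1),
            y,
            method="LSODA",
            t_eval=t_eval,
            args=(p, ist),
            atol=solver.abs_tol,
            rtol=solver.rel_tol,
            max_step=solver.max_step,
        )
        if not sol.success:
            raise SimulationError(f"LSODA failed: {sol.message}")
        y[:] = sol.y[:, -1]
        return sol

    for _ in range(protocol.equilibration_beats):
        run(0.0, dur, amp)
        run(dur, cl, 0.0)
    times, vms = [], []
    for b in range(protocol.recorded_beats):
        grid1 = np.arange(0.0, dur, solver.sample_dt)
        sol1 = run(0.0, dur, amp, t_eval=np.concatenate((grid1, [dur])))
        grid2 = np.arange(
            math.ceil(dur / solver.sample_dt) * solver.sample_dt, cl, solver.sample_dt
        )
        sol2 = run(dur, cl, 0.0, t_eval=grid2)
        t = np.concatenate((sol1.t[:-1], sol2.t)) + b * cl
        v = np.concatenate((sol1.y[0, :-1], sol2.y[0, :]))
        times.append(t)
        vms.append(v)
    return np.concatenate(times), np.concatenate(vms)


def _simulate_rl(y, p, protocol, solver):
    cl, dur, amp = protocol.cycle_length, protocol.stim_duration, protocol.stim_amplitude
    if protocol.equilibration_beats:
        _ord.paced_beats(
            y, p, protocol.equilibration_beats, cl, amp, dur,
            solver.dt_fine, solver.dt_coarse, solver.fine_window,
            solver.sample_dt, False,
        )
        if not np.all(np.isfinite(y)):
            raise SimulationError("state became non-finite during equilibration")
    t, v = _ord.paced_beats(
        y, p, protocol.recorded_beats, cl, amp, dur,
        solver.dt_fine, solver.dt_coarse, solver.fine_window,
        solver.sample_dt, True,
    )
    expected = protocol.recorded_beats * int(round(cl / solver.sample_dt))
    if len(t) < expected or not np.all(np.isfinite(v)):
        raise SimulationError("state became non-finite during recording")
    return t, v


def simulate_ap(
    multipliers: ConductanceMultipliers | Sequence[float],
    protocol: PacingProtocol = PacingProtocol(),
    solver: SolverSettings = SolverSettings(),
    initial_state: np.ndarray | None = None,
) -> APTrace:
    """Equilibrate and record the paced AP of one scaled ORd myocyte.

    Deterministic for fixed inputs and solver settings. Raises
    :class:`SimulationError` (carrying the multipliers) if the state
    becomes non-finite, which can happen for extreme conductance
    combinations.
    """
    if not isinstance(multipliers, ConductanceMultipliers):
        multipliers = ConductanceMultipliers(*multipliers)
    p = build_scaled_parameters(multipliers)
    y = (initial_state if initial_state is not None else _ord.Y0).copy()
    try:
        if solver.method == "lsoda":
            t, v = _simulate_lsoda(y, p, protocol, solver)
        else:
            t, v = _simulate_rl(y, p, protocol, solver)
    except SimulationError as exc:
        raise SimulationError(str(exc), multipliers) from None
    meta = {
        "model": "ord-endo",
        "solver": solver.method,
        "multipliers": multipliers.as_tuple(),
    }
    return APTrace(time=t, vm=v, protocol=protocol, meta=meta)


_PROTOCOL_KEYS = {
    "cycle_length": float,
    "stim_amplitude": float,
    "stim_duration": float,
    "equilibration_beats": int,
    "recorded_beats": int,
}
_SOLVER_KEYS = {
    "method": str,
    "abs_tol": float,
    "rel_tol": float,
    "max_step": float,
    "sample_dt": float,
    "dt_fine": float,
    "dt_coarse": float,
    "fine_window": float,
}


def load_protocol_config(path: str | Path) -> tuple[PacingProtocol, SolverSettings]:
    """Read pacing/solver settings from a key=value text file.

    Lines are ``key = value``; '#' starts a comment. Unknown keys raise
    ``ValueError``. Keys: cycle_length, stim_amplitude, stim_duration,
    equilibration_beats, recorded_beats; method, abs_tol, rel_tol,
    max_step, sample_dt, dt_fine, dt_coarse, fine_window.
    """
    proto_kw: dict = {}
    solver_kw: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, sep, value = (s.strip() for s in line.partition("="))
        if not sep:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        if key in _PROTOCOL_KEYS:
            proto_kw[key] = _PROTOCOL_KEYS[key](value)
        elif key in _SOLVER_KEYS:
            solver_kw[key] = _SOLVER_KEYS[key](value)
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return PacingProtocol(**proto_kw), SolverSettings(**solver_kw)


# ---------------------------------------------------------------------------
# Surrogate model


@dataclass(frozen=True)
class SurrogateSpec:
    """Configuration of the surrogate AP generator.

    A cell is ectopic when the logit ``b0 + b . X`` is positive (X being the
    log-multipliers); with ``temperature > 0`` the label is instead drawn
    Bernoulli(logistic(logit / temperature)) from the supplied RNG, which
    mimics the soft boundary of the biophysical model and keeps logistic
    refits well-posed. Defaults reproduce the published axis, so refitting a
    large surrogate population recovers those coefficients.

    Trace geometry: a stereotyped AP (rest -88 mV, peak +34 mV, APD about
    ``apd`` ms) with, when ectopic, a Gaussian depolarizing bump of
    ``ead_amplitude`` mV at ``ead_time`` ms — above -50 mV and more than
    100 ms from the upstroke, satisfying the detector's definition.
    """

    b0: float = -6.416
    b: tuple[float, float, float, float] = (2.509, -2.471, 0.847, -1.724)
    temperature: float = 0.0
    rest: float = -88.0
    peak: float = 34.0
    apd: float = 300.0
    ead_amplitude: float = 12.0
    ead_time: float = 240.0
    ead_width: float = 18.0


def _surrogate_beat(t: np.ndarray, spec: SurrogateSpec, ead: bool) -> np.ndarray:
    """Template AP over one beat; single upstroke peak, optional EAD bump."""
    up = np.clip(t / 1.0, 0.0, 1.0)  # 1 ms linear upstroke
    envelope = np.exp(-t / 600.0) / (1.0 + np.exp((t - spec.apd) / 12.0))
    v = spec.rest + (spec.peak - spec.rest) * up * envelope
    if ead:
        v = v + spec.ead_amplitude * np.exp(-(((t - spec.ead_time) / spec.ead_width) ** 2))
    return v


def surrogate_logit(X: Sequence[float], spec: SurrogateSpec) -> float:
    X = np.asarray(X, dtype=float)
    return float(spec.b0 + X @ np.asarray(spec.b))


def surrogate_label(
    X: Sequence[float],
    spec: SurrogateSpec,
    rng: np.random.Generator | None = None,
) -> bool:
    """Ectopic/benign decision of the surrogate rule for log-multipliers X."""
    logit = surrogate_logit(X, spec)
    if spec.temperature > 0 and rng is not None:
        p = 1.0 / (1.0 + math.exp(-logit / spec.temperature))
        return bool(rng.random() < p)
    return logit > 0


def surrogate_simulate(
    multipliers: ConductanceMultipliers | Sequence[float],
    protocol: PacingProtocol = PacingProtocol(),
    spec: SurrogateSpec = SurrogateSpec(),
    rng: np.random.Generator | None = None,
) -> APTrace:
    """Synthetic paced trace whose EAD content follows the surrogate rule."""
    if not isinstance(multipliers, ConductanceMultipliers):
        multipliers = ConductanceMultipliers(*multipliers)
    ead = surrogate_label(multipliers.log(), spec, rng)
    cl = protocol.cycle_length
    tb = np.arange(0.0, cl, 1.0)
    beats = [_surrogate_beat(tb, spec, ead) for _ in range(protocol.recorded_beats)]
    t = np.concatenate([tb + k * cl for k in range(protocol.recorded_beats)])
    v = np.concatenate(beats)
    meta = {
        "model": "surrogate",
        "multipliers": multipliers.as_tuple(),
        "ead": ead,
    }
    return APTrace(time=t, vm=v, protocol=protocol, meta=meta)
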