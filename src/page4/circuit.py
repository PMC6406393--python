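"""PAGE4 phosphorylation-circuit ODE model.

The circuit tracks five dynamical species, all in dimensionless
concentration units with time in hours:

* ``W`` — wild-type PAGE4, produced at a constant rate and converted to
  the HIPK1 phospho-form by the HIPK1 kinase (a constant activity folded
  into the rate constant ``k_H``).
* ``H`` — HIPK1-PAGE4 (double-phosphorylated), converted to the CLK2
  phospho-form by the CLK2 kinase ``K`` via mass action (``k_C * K * H``).
* ``C`` — CLK2-PAGE4 (hyper-phosphorylated), degraded only.
* ``A`` — androgen-receptor (AR) activity, produced under Hill-type
  repression by ``H`` (HIPK1-PAGE4 potentiates c-Jun/AP-1, a negative AR
  regulator; c-Jun is lumped into the repression term).
* ``K`` — CLK2 kinase, produced under Hill-type repression by AR.

The loop H ⊣ A ⊣ K, closed by K consuming H, is a three-stage negative
feedback. With the long WT-PAGE4 half-life (~150 h) as the slow anchor it
relaxes into a limit cycle with a period of roughly one week, alternating
an androgen-dependent phenotype (high H, low C) with an
androgen-independent one (low H, high C).

Treatment enters through a :class:`~page4.protocols.Protocol`: androgen
deprivation (ADT) multiplies AR production by ``1 - u_ADT``; bipolar
androgen treatment drives AR with an additive term ``beta_OE * u_OE``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .protocols import Protocol, no_treatment

__all__ = [
    "SPECIES",
    "CircuitParams",
    "CircuitState",
    "Trajectory",
    "hill_inhibition",
    "derivatives",
    "simulate",
]

#: canonical species order used by every array-valued interface
SPECIES = ("W", "H", "C", "K", "A")

#: default WT-PAGE4 half-life in hours (the slow timescale of the circuit)
WT_HALF_LIFE_H = 150.0


class CircuitError(ValueError):
    """Invalid circuit parameters or states."""


class IntegrationError(RuntimeError):
    """Adaptive integration failed; carries the failure time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g} h)")
        self.t_fail = t_fail


@dataclass(frozen=True)
class CircuitParams:
    """Rate constants and Hill parameters of the phospho-circuit.

    Units: production rates conc/h, conversion/degradation rates 1/h
    (``k_C`` is 1/(conc·h)), thresholds conc, Hill coefficients
    dimensionless. Concentrations themselves are dimensionless.
    """

    g_W: float        # WT-PAGE4 production
    k_H: float        # HIPK1-catalysed conversion W -> H
    k_C: float        # CLK2-catalysed conversion H -> C (bilinear in K, H)
    delta_W: float    # degradation rates
    delta_H: float
    delta_C: float
    delta_K: float
    delta_A: float
    g_A: float        # AR activity production scale
    g_K: float        # CLK2 production scale
    H0: float         # Hill threshold, HIPK1-PAGE4 -| AR
    n_H: float        # Hill coefficient, HIPK1-PAGE4 -| AR
    A0: float         # Hill threshold, AR -| CLK2
    n_A: float        # Hill coefficient, AR -| CLK2
    beta_OE: float = 0.0  # AR overexpression drive (BAT)

    def __post_init__(self):
        positive = ("g_W", "k_H", "k_C", "delta_W", "delta_H", "delta_C",
                    "delta_K", "delta_A", "g_A", "g_K", "H0", "A0")
        for name in positive:
            if not getattr(self, name) > 0:
                raise CircuitError(f"parameter {name} must be strictly positive")
        if self.n_H < 1 or self.n_A < 1:
            raise CircuitError("Hill coefficients must be >= 1")
        if self.beta_OE < 0:
            raise CircuitError("beta_OE must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        return cls(**d)

    def replace(self, **kw) -> "CircuitParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CircuitState:
    """Levels of the five species (dimensionless concentrations)."""

    W: float
    H: float
    C: float
    K: float
    A: float

    def as_array(self) -> np.ndarray:
        return np.array([self.W, self.H, self.C, self.K, self.A], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "CircuitState":
        W, H, C, K, A = (float(v) for v in y)
        return cls(W, H, C, K, A)


@dataclass
class Trajectory:
    """Single-cell time series on a uniform output grid.

    ``states`` has shape (n_times, 5) in :data:`SPECIES` order.
    """

    times: np.ndarray
    states: np.ndarray
    params_id: str = ""
    protocol_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise CircuitError("trajectory times must be strictly increasing")
        if self.states.shape != (self.times.size, len(SPECIES)):
            raise CircuitError("states must be (n_times, 5)")
        if not np.all(np.isfinite(self.states)):
            raise CircuitError("trajectory contains non-finite states")

    def species(self, name: str) -> np.ndarray:
        try:
            return self.states[:, SPECIES.index(name)]
        except ValueError:
            raise KeyError(f"unknown species {name!r}; expected one of {SPECIES}")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=[*SPECIES])
        df.insert(0, "time_h", self.times)
        return df


def hill_inhibition(x: float, x0: float, n: float) -> float:
    """Repressive Hill function ``1 / (1 + (x/x0)^n)``.

    Monotone non-increasing in ``x``; equals 1 at ``x = 0`` and 1/2 at
    ``x = x0``. ``x0`` must be positive and ``n >= 1``.
    """
    if x0 <= 0:
        raise CircuitError("Hill threshold x0 must be strictly positive")
    if n < 1:
        raise CircuitError("Hill coefficient n must be >= 1")
    x = np.maximum(x, 0.0)  # guard against solver round-off below zero
    return 1.0 / (1.0 + (x / x0) ** n)


def _rhs(t: float, y: np.ndarray, p: CircuitParams, u_adt: float, u_oe: float,
         clamp_K: float | None = None) -> np.ndarray:
    """Vector field; vectorised over trailing axes of ``y`` (shape (5, ...))."""
    W, H, C, K, A = y
    if clamp_K is not None:
        K = clamp_K
    dW = p.g_W - p.k_H * W - p.delta_W * W
    dH = p.k_H * W - p.k_C * K * H - p.delta_H * H
    dC = p.k_C * K * H - p.delta_C * C
    dK = p.g_K * hill_inhibition(A, p.A0, p.n_A) - p.delta_K * K
    dA = (p.g_A * hill_inhibition(H, p.H0, p.n_H) * (1.0 - u_adt)
          + p.beta_OE * u_oe - p.delta_A * A)
    if clamp_K is not None:
        dK = np.zeros_like(dC)
    return np.array([dW, dH, dC, dK, dA])


def derivatives(state: CircuitState, t: float, params: CircuitParams,
                protocol: Protocol | None = None) -> CircuitState:
    """Instantaneous rates of change at ``state`` under ``protocol``.

    Raises on negative state components; the integrator uses an internal
    unchecked path, so this surface is for inspection and testing.
    """
    y = state.as_array()
    if np.any(y < 0):
        raise CircuitError("state components must be non-negative")
    protocol = protocol if protocol is not None else no_treatment()
    u_adt, u_oe = protocol.u_at(t)
    return CircuitState.from_array(_rhs(t, y, params, u_adt, u_oe))


def simulate(params: CircuitParams, protocol: Protocol | None,
             initial: CircuitState, t_span: tuple[float, float],
             output_dt: float = 0.5, *, rtol: float = 1e-8,
             atol: float = 1e-10, clamp_K: float | None = None) -> Trajectory:
    """Integrate the circuit over ``t_span`` and sample every ``output_dt`` h.

    Integration is piecewise over the protocol's constant segments with an
    adaptive stiff-capable solver (LSODA). Non-negativity of the state is a
    property of the vector field (all flows into a species vanish no faster
    than linearly at zero); no clipping is applied.

    ``clamp_K`` freezes the CLK2 kinase at a constant value, severing the
    feedback loop — an ablation control, not a physiological scenario.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise CircuitError("t_span must satisfy t_end > t_start")
    if output_dt <= 0:
        raise CircuitError("output_dt must be positive")
    protocol = protocol if protocol is not None else no_treatment()

    times = np.arange(t0, t1 + output_dt * 0.5, output_dt)
    out = np.empty((times.size, len(SPECIES)))
    y = initial.as_array()
    if np.any(y < 0):
        raise CircuitError("initial state must be non-negative")

    segments = list(protocol.iter_segments(t0, t1))
    for idx, (seg_start, seg_end, u_adt, u_oe) in enumerate(segments):
        last = idx == len(segments) - 1
        # grid points inside the half-open segment [start, end); the final
        # segment keeps its right endpoint so the last sample is covered
        mask = (times >= seg_start - 1e-9) & (
            (times <= seg_end + 1e-9) if last else (times < seg_end - 1e-9))
        grid = np.clip(times[mask], seg_start, seg_end)
        # always integrate through seg_end so the carried state is exact
        t_eval = np.unique(np.append(grid, seg_end))
        sol = solve_ivp(
            _rhs, (seg_start, seg_end), y, method="LSODA", t_eval=t_eval,
            args=(params, u_adt, u_oe, clamp_K), rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else seg_start)
        if grid.size:
            out[mask] = sol.y[:, :grid.size].T if t_eval.size > grid.size else sol.y.T
        y = sol.y[:, -1]

    return Trajectory(times=times, states=out,
                      params_id=params_fingerprint(params),
                      protocol_id=protocol.label)


def params_fingerprint(params: CircuitParams) -> str:
    """Short stable hash of a parameter set, for provenance tags."""
    import hashlib

    payload = ",".join(f"{k}={v!r}" for k, v in sorted(params.to_dict().items()))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
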