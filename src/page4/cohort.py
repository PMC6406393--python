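"""Cell-cohort simulation: heterogeneity, synchronization, phenotypes.

Cells are identical and non-interacting; the only source of population
heterogeneity is the phase of each cell along the no-treatment limit
cycle. Initial conditions are therefore drawn by placing cells at
uniform-random phases of the cycle, which reproduces the broad untreated
CLK2 distribution, and treatment protocols then act on all cells
simultaneously.

Synchrony is quantified by the Kuramoto-style order parameter
``R = |<exp(i φ_j)>|`` with the per-cell phase ``φ_j`` defined
geometrically as the angle of ``(H_j - H̄, C_j - C̄)`` around the limit
cycle's centroid in the (HIPK1-PAGE4, CLK2-PAGE4) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import (SPECIES, CircuitParams, CircuitState, Trajectory,
                      IntegrationError, _rhs, params_fingerprint, simulate)
from .oscillation import detect_period
from .protocols import Protocol, no_treatment

__all__ = [
    "LimitCycle", "NoLimitCycleError", "limit_cycle", "CohortResult",
    "sample_initial_conditions", "simulate_cohort", "population_cv",
    "sync_order_parameter", "classify_phenotype", "phenotype_fractions",
]


class NoLimitCycleError(RuntimeError):
    """The dynamics settle on a fixed point; phase sampling is undefined."""


@dataclass(frozen=True)
class LimitCycle:
    """One period of the no-treatment attractor, densely sampled."""

    period: float                 # h
    times: np.ndarray             # h, from 0 to period
    states: np.ndarray            # (n_samples, 5) in SPECIES order
    centroid: dict = field(default_factory=dict)   # cycle-mean per species
    midrange: dict = field(default_factory=dict)   # (min+max)/2 per species

    def state_at_phase(self, phase: np.ndarray) -> np.ndarray:
        """Interpolate cycle states at fractional phases in [0, 1)."""
        phase = np.atleast_1d(np.asarray(phase, dtype=float)) % 1.0
        t = phase * self.period
        out = np.empty((t.size, len(SPECIES)))
        for k in range(len(SPECIES)):
            out[:, k] = np.interp(t, self.times, self.states[:, k])
        return out


_CYCLE_CACHE: dict[str, LimitCycle] = {}

_BURN_IN_H = 2000.0
_SIM_END_H = 5000.0
_IC = CircuitState(W=1.0, H=0.5, C=0.1, K=0.1, A=0.5)


def limit_cycle(params: CircuitParams, output_dt: float = 0.25) -> LimitCycle:
    """Compute (and cache) the no-treatment limit cycle for ``params``.

    The system is integrated well past its transient, the HIPK1-PAGE4
    peaks are located, and the states between the last two peaks are
    taken as one period of the attractor.
    """
    key = params_fingerprint(params) + f":{output_dt:g}"
    if key in _CYCLE_CACHE:
        return _CYCLE_CACHE[key]
    traj = simulate(params, None, _IC, (0.0, _SIM_END_H), output_dt=output_dt)
    summary = detect_period(traj, "H", burn_in=_BURN_IN_H)
    if not summary.is_oscillating:
        raise NoLimitCycleError("no sustained oscillation for these parameters")
    t_a, t_b = summary.peak_times[-2], summary.peak_times[-1]
    m = (traj.times >= t_a) & (traj.times <= t_b)
    times = traj.times[m] - t_a
    states = traj.states[m]
    centroid = {s: float(states[:, i].mean()) for i, s in enumerate(SPECIES)}
    midrange = {s: float(0.5 * (states[:, i].min() + states[:, i].max()))
                for i, s in enumerate(SPECIES)}
    cyc = LimitCycle(period=float(t_b - t_a), times=times, states=states,
                     centroid=centroid, midrange=midrange)
    _CYCLE_CACHE[key] = cyc
    return cyc


@dataclass
class CohortResult:
    """Trajectories of a non-interacting cell population.

    ``per_cell_states`` has shape (n_cells, n_times, 5).
    """

    n_cells: int
    seed: int
    times: np.ndarray
    per_cell_states: np.ndarray
    protocol_id: str = ""
    params_id: str = ""
    cycle_centroid: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.per_cell_states = np.asarray(self.per_cell_states, dtype=float)
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.per_cell_states.shape != (self.n_cells, self.times.size, len(SPECIES)):
            raise ValueError("per_cell_states must be (n_cells, n_times, 5)")

    def species_at(self, species: str, t: float) -> np.ndarray:
        """Per-cell values of one species at the grid time nearest ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > (self.times[1] - self.times[0]):
            raise ValueError(f"t={t} outside cohort time grid")
        return self.per_cell_states[:, i, SPECIES.index(species)]

    def cell_trajectory(self, j: int) -> Trajectory:
        return Trajectory(times=self.times, states=self.per_cell_states[j],
                          params_id=self.params_id, protocol_id=self.protocol_id)


def sample_initial_conditions(params: CircuitParams, n_cells: int,
                              seed: int = 42) -> list[CircuitState]:
    """Draw cells at uniform-random phases along the no-treatment cycle.

    Deterministic given ``seed``; raises :class:`NoLimitCycleError` when
    the dynamics admit no cycle.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    cyc = limit_cycle(params)
    rng = np.random.default_rng(seed)
    phases = rng.random(n_cells)
    states = cyc.state_at_phase(phases)
    return [CircuitState.from_array(row) for row in states]


def simulate_cohort(params: CircuitParams, protocol: Protocol | None,
                    n_cells: int, seed: int, t_span: tuple[float, float],
                    output_dt: float = 1.0, *, rtol: float = 1e-6,
                    atol: float = 1e-9,
                    initial_states: list[CircuitState] | None = None
                    ) -> CohortResult:
    """Integrate every cell of a phase-randomized cohort under one protocol.

    All cells are advanced together as one stacked ODE system (the cells
    are independent, so the stacked system is block-diagonal and a single
    adaptive non-stiff integration covers the whole population).
    """
    protocol = protocol if protocol is not None else no_treatment()
    cyc = limit_cycle(params)
    if initial_states is None:
        initial_states = sample_initial_conditions(params, n_cells, seed)
    if len(initial_states) != n_cells:
        raise ValueError("initial_states length must equal n_cells")

    t0, t1 = float(t_span[0]), float(t_span[1])
    times = np.arange(t0, t1 + output_dt * 0.5, output_dt)
    y = np.stack([s.as_array() for s in initial_states])  # (n, 5)
    out = np.empty((n_cells, times.size, len(SPECIES)))

    def stacked_rhs(t, yflat, u_adt, u_oe):
        dy = _rhs(t, yflat.reshape(n_cells, 5).T, params, u_adt, u_oe)
        return dy.T.ravel()

    segments = list(protocol.iter_segments(t0, t1))
    for idx, (seg_start, seg_end, u_adt, u_oe) in enumerate(segments):
        last = idx == len(segments) - 1
        mask = (times >= seg_start - 1e-9) & (
            (times <= seg_end + 1e-9) if last else (times < seg_end - 1e-9))
        grid = np.clip(times[mask], seg_start, seg_end)
        t_eval = np.unique(np.append(grid, seg_end))
        sol = solve_ivp(stacked_rhs, (seg_start, seg_end), y.ravel(),
                        method="RK45", t_eval=t_eval, args=(u_adt, u_oe),
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"cohort integration failed: {sol.message}",
                                   sol.t[-1] if sol.t.size else seg_start)
        vals = sol.y.T.reshape(t_eval.size, n_cells, 5)
        if grid.size:
            out[:, mask, :] = vals[:grid.size].transpose(1, 0, 2)
        y = vals[-1]

    return CohortResult(
        n_cells=n_cells, seed=seed, times=times, per_cell_states=out,
        protocol_id=protocol.label, params_id=params_fingerprint(params),
        cycle_centroid={"H": cyc.centroid["H"], "C": cyc.centroid["C"]},
    )


def population_cv(cohort: CohortResult, species: str, t: float) -> float:
    """Coefficient of variation across cells at time ``t``.

    Population (not sample) standard deviation divided by the mean.
    """
    vals = cohort.species_at(species, t)
    mean = float(vals.mean())
    if mean == 0.0:
        raise ZeroDivisionError("population mean is zero; CV undefined")
    return float(vals.std(ddof=0) / mean)


def sync_order_parameter(cohort: CohortResult, t: float) -> float:
    """Kuramoto order parameter R in [0, 1] of the cohort at time ``t``.

    Phase of each cell is the angle of (H - H̄, C - C̄) around the limit
    cycle centroid; R = 1 means perfect phase alignment, R ~ 0 a uniform
    phase distribution.
    """
    if cohort.n_cells < 2:
        raise ValueError("order parameter needs at least two cells")
    h = cohort.species_at("H", t) - cohort.cycle_centroid["H"]
    c = cohort.species_at("C", t) - cohort.cycle_centroid["C"]
    r = np.hypot(h, c)
    if np.all(r < 1e-12):
        raise ValueError("all cells at the cycle centroid; phase undefined")
    phi = np.arctan2(c, h)
    return float(np.abs(np.mean(np.exp(1j * phi))))


def classify_phenotype(state: CircuitState, h_mid: float, c_mid: float) -> str:
    """Androgen-dependence label from HIPK1- and CLK2-PAGE4 levels.

    ``AD`` (androgen-dependent): high HIPK1-PAGE4, low CLK2-PAGE4.
    ``AI`` (androgen-independent): low HIPK1-PAGE4, high CLK2-PAGE4.
    Anything else — including exact threshold hits — is ``indeterminate``.
    """
    if state.H > h_mid and state.C < c_mid:
        return "AD"
    if state.H < h_mid and state.C > c_mid:
        return "AI"
    return "indeterminate"


def phenotype_fractions(cohort: CohortResult, t: float, h_mid: float,
                        c_mid: float) -> dict[str, float]:
    """Fraction of cells per phenotype label at time ``t``."""
    H = cohort.species_at("H", t)
    C = cohort.species_at("C", t)
    ad = np.mean((H > h_mid) & (C < c_mid))
    ai = np.mean((H < h_mid) & (C > c_mid))
    return {"AD": float(ad), "AI": float(ai),
            "indeterminate": float(1.0 - ad - ai)}
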