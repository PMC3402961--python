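"""Stiff ODE integration of kinetic models with blow-up diagnostics.

The integrator is the BDF (Gear-family) implicit multistep method, which
handles the wide timescale separation typical of metabolic rate laws.
Output is sampled on a fixed uniform grid anchored at t=0 so that wild-type
and knockout trajectories of the same horizon share their time points,
which the state-fluctuation norms require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .model import KineticModel

__all__ = ["IntegrationOptions", "Trajectory", "integrate", "trajectory_fluxes", "perturb_initial"]

Status = Literal["completed", "blew_up", "solver_failed"]


@dataclass(frozen=True)
class IntegrationOptions:
    """Solver configuration.

    ``ceiling`` is the blow-up threshold: concentrations soaring past it
    are taken as leaving the physically meaningful range (default 1e6 mM).
    ``floor`` is the negativity tolerance below which states are clipped to
    zero before rate evaluation.
    """

    t_end: float = 2000.0  # s
    n_grid: int = 400
    method: str = "BDF"
    rtol: float = 1e-8
    atol: float = 1e-10
    ceiling: float = 1e6  # mM
    floor: float = -1e-6  # mM


@dataclass
class Trajectory:
    """A solution of the model ODE sampled on a uniform grid."""

    times: np.ndarray  # (T,), s
    states: np.ndarray  # (T, n_dynamic), mM
    status: Status
    columns: list[str]
    blowup_time: float | None = None
    fluxes: np.ndarray | None = None  # (T, n_reactions), mM/s
    solver_meta: dict = field(default_factory=dict)

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def column(self, metabolite_id: str) -> np.ndarray:
        return self.states[:, self.columns.index(metabolite_id)]


def integrate(
    model: KineticModel,
    x0: np.ndarray | None = None,
    options: IntegrationOptions | None = None,
) -> Trajectory:
    """Integrate ``dX/dt = A.R(X,P) + B(X,P)`` from ``x0``.

    Solver failure and blow-up are reported in ``Trajectory.status``, never
    raised. A blow-up truncates the trajectory at the last grid point
    before the ceiling crossing.
    """
    opts = options or IntegrationOptions()
    if x0 is None:
        x0 = model.x0
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (model.n_dynamic,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({model.n_dynamic},)")
    if model.nonnegative and np.any(x0 < 0):
        raise ValueError("initial state has negative concentrations")

    clip = model.nonnegative

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        if clip:
            x = np.maximum(x, 0.0)
        return model.rhs(x, t)

    def blowup(t: float, x: np.ndarray) -> float:
        return opts.ceiling - float(np.max(np.abs(x)))

    blowup.terminal = True  # type: ignore[attr-defined]
    blowup.direction = -1  # type: ignore[attr-defined]

    t_eval = np.linspace(0.0, opts.t_end, opts.n_grid + 1)
    try:
        sol = solve_ivp(
            rhs, (0.0, opts.t_end), x0, method=opts.method,
            t_eval=t_eval, rtol=opts.rtol, atol=opts.atol, events=[blowup],
        )
    except Exception as exc:  # rate-law domain errors etc.
        return Trajectory(
            times=np.array([0.0]), states=x0[None, :], status="solver_failed",
            columns=list(model.dynamic_ids),
            solver_meta={"method": opts.method, "error": str(exc)},
        )

    meta = {
        "method": opts.method, "rtol": opts.rtol, "atol": opts.atol,
        "nfev": int(sol.nfev), "message": str(sol.message),
    }
    states = sol.y.T
    times = sol.t
    if clip:
        states = np.where(states > opts.floor, np.maximum(states, 0.0), states)
    if sol.status == 1:  # terminated by the blow-up event
        t_blow = float(sol.t_events[0][0])
        if times.size == 0 or times[0] > 0.0:
            times = np.concatenate([[0.0], times])
            states = np.vstack([x0, states])
        return Trajectory(
            times=times, states=states, status="blew_up",
            columns=list(model.dynamic_ids), blowup_time=t_blow, solver_meta=meta,
        )
    if not sol.success:
        return Trajectory(
            times=times if times.size else np.array([0.0]),
            states=states if times.size else x0[None, :],
            status="solver_failed", columns=list(model.dynamic_ids), solver_meta=meta,
        )
    bad = ~np.isfinite(states)
    if bad.any():
        return Trajectory(
            times=times, states=states, status="solver_failed",
            columns=list(model.dynamic_ids), solver_meta={**meta, "nonfinite": True},
        )
    return Trajectory(
        times=times, states=states, status="completed",
        columns=list(model.dynamic_ids), solver_meta=meta,
    )


def trajectory_fluxes(model: KineticModel, traj: Trajectory) -> np.ndarray:
    """Evaluate every reaction rate at every stored time point (mM/s)."""
    fluxes = np.empty((len(traj.times), len(model.reactions)))
    for i, (t, x) in enumerate(zip(traj.times, traj.states)):
        xi = np.maximum(x, 0.0) if model.nonnegative else x
        fluxes[i] = model.evaluate_rates(xi, float(t))
    traj.fluxes = fluxes
    return fluxes


def perturb_initial(
    x0: np.ndarray,
    fraction: float,
    direction: str = "+",
    seed: int | None = None,
) -> np.ndarray:
    """Scale an initial state elementwise by ``1 +/- fraction``.

    ``direction`` is ``"+"``, ``"-"`` or ``"random"`` (independent signs
    per element, reproducible under ``seed``).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    x0 = np.asarray(x0, dtype=float)
    if direction == "+":
        return x0 * (1.0 + fraction)
    if direction == "-":
        return x0 * (1.0 - fraction)
    if direction == "random":
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=x0.shape)
        return x0 * (1.0 + fraction * signs)
    raise ValueError(f"unknown direction {direction!r}")
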