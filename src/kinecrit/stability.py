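"""Equilibria, Lyapunov stability, normal-form signatures and limit cycles.

Equilibria of ``dX/dt = A.R(X,P) + B(X,P)`` are located with a trust-region
nonlinear least-squares solve of ``rhs(x) = 0`` seeded at the endpoint of a
long simulation (plus random restarts). Stability follows the eigenvalues
of the Jacobian at the equilibrium: all real parts negative means
asymptotically stable; any positive real part means unstable; a pair of
(numerically) purely imaginary conjugate eigenvalues flags a likely limit
cycle bifurcating from the equilibrium.

Near a hyperbolic (or center-pair) equilibrium the orbit structure is
topologically conjugate to the reduced normal form

    dy1/dt = b*y1 - y2 + s*y1*(y1^2 + y2^2)
    dy2/dt = y1 + b*y2 + s*y2*(y1^2 + y2^2)
    ds_i/dt = -s_i   (N_s contracting coordinates)
    du_j/dt = +u_j   (N_u expanding coordinates)

so the qualitative dynamics is summarized by the signature
(N_s, N_u, center pairs, s, b). With s = +1 and b < 0 the planar block
carries an unstable limit cycle of radius sqrt(-b).

"No equilibrium" is operationalized as: every solver start fails to reach
the residual tolerance AND the long trajectory is divergent (blown up or
still drifting at the horizon). Solver failure alone, with a bounded
settled trajectory, yields ``indeterminate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import KineticModel
from .simulation import IntegrationOptions, integrate

__all__ = [
    "StabilityThresholds",
    "NormalFormSignature",
    "EquilibriumReport",
    "OrbitStructure",
    "DynamicsReport",
    "find_equilibrium",
    "jacobian_at",
    "classify_stability",
    "orbit_structure",
    "probe_limit_cycle",
    "estimate_cycle_radius",
    "characterize_dynamics",
]


@dataclass(frozen=True)
class StabilityThresholds:
    """Numerical cuts for equilibrium search and classification.

    ``near_frac``/``extreme_frac`` are relative to ||X_eq||: a relocated
    equilibrium within ``near_frac`` of the reference norm counts as near;
    beyond ``extreme_frac`` (or outside the ordinary-range box of
    ``box_factor`` times the reference, componentwise) it counts as an
    extreme deviation.
    """

    residual_tol: float = 1e-6  # mM/s
    imag_tol: float = 1e-6  # relative real-part tolerance for "purely imaginary"
    near_frac: float = 0.5
    extreme_frac: float = 1.0
    box_factor: float = 100.0
    ceiling: float = 1e6  # mM
    n_starts: int = 10
    settled_tol: float = 1e-4  # mM/s; endpoint drift above this = not settled


@dataclass
class NormalFormSignature:
    """Spectral decomposition counts mapped onto the reduced normal form."""

    N_s: int
    N_u: int
    center_pairs: int
    sigma: int = +1
    beta: float | None = None

    @property
    def dimension(self) -> int:
        return self.N_s + self.N_u + 2 * self.center_pairs


@dataclass
class EquilibriumReport:
    """Location, stability and deviation record of one equilibrium search."""

    found: bool
    x_eq: np.ndarray | None = None
    residual_norm: float = np.inf
    in_ordinary_range: bool = False
    eigenvalues: np.ndarray | None = None
    stability: str | None = None  # asymptotically_stable | unstable | center_candidate
    signature: NormalFormSignature | None = None
    deviation: float = np.inf  # Euclid distance from the reference equilibrium
    diagnostics: dict = field(default_factory=dict)


def find_equilibrium(
    model: KineticModel,
    guess: np.ndarray,
    thresholds: StabilityThresholds | None = None,
) -> EquilibriumReport:
    """Solve rhs(x) = 0 by trust-region least squares seeded at ``guess``."""
    th = thresholds or StabilityThresholds()
    guess = np.asarray(guess, dtype=float)
    if not np.all(np.isfinite(guess)):
        raise ValueError("guess must be finite")
    lower = 0.0 if model.nonnegative else -np.inf
    try:
        res = least_squares(
            lambda x: model.rhs(x), np.maximum(guess, 0.0) if model.nonnegative else guess,
            method="trf", bounds=(lower, np.inf), xtol=1e-14, ftol=1e-14, gtol=1e-12,
            max_nfev=400,  # enough for quadratic convergence from a good seed;
            #               bounds the cost of hopeless starts on rootless systems
        )
    except Exception as exc:
        return EquilibriumReport(found=False, diagnostics={"error": str(exc)})
    x = res.x
    resid = float(np.linalg.norm(model.rhs(x)))
    within = bool(np.all(np.isfinite(x)) and np.max(np.abs(x)) < th.ceiling)
    found = resid < th.residual_tol and within
    return EquilibriumReport(
        found=found,
        x_eq=x if found else None,
        residual_norm=resid,
        diagnostics={"solver_status": int(res.status), "cost": float(res.cost)},
    )


def jacobian_at(model: KineticModel, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the full rhs (A.R + B) at x."""
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        if model.nonnegative and xm[j] < 0:
            xm[j] = 0.0
            h = (xp[j] - xm[j]) / 2.0
        J[:, j] = (model.rhs(xp) - model.rhs(xm)) / (xp[j] - xm[j])
    return J


def classify_stability(
    eigenvalues: np.ndarray,
    imag_tol: float = 1e-6,
    sigma: int = +1,
    beta: float | None = None,
) -> tuple[str, NormalFormSignature]:
    """Stability label and normal-form signature from a Jacobian spectrum.

    "Purely imaginary" uses the relative cut |Re(l)| < imag_tol * max(1, |l|),
    since numerical spectra never land exactly on the axis.
    """
    ev = np.asarray(eigenvalues, dtype=complex)
    tol = imag_tol * np.maximum(1.0, np.abs(ev))
    on_axis = np.abs(ev.real) < tol
    center = on_axis & (np.abs(ev.imag) >= tol)
    n_s = int(np.sum(~center & (ev.real < 0)))
    n_u = int(np.sum(~center & (ev.real >= 0) & ~on_axis))
    # degenerate (numerically zero) eigenvalues land in neither block
    pairs = int(np.sum(center & (ev.imag > 0)))
    sig = NormalFormSignature(N_s=n_s, N_u=n_u, center_pairs=pairs, sigma=sigma, beta=beta)
    if pairs > 0:
        return "center_candidate", sig
    if n_u > 0:
        return "unstable", sig
    if n_s == len(ev):
        return "asymptotically_stable", sig
    return "center_candidate", sig  # zero eigenvalue: marginal case


@dataclass
class OrbitStructure:
    """Qualitative description of the local orbit structure."""

    signature: NormalFormSignature
    reduced_system: list[str]
    contracting_dims: int
    expanding_dims: int
    has_planar_block: bool
    limit_cycle: str  # "unstable" | "stable" | "none" | "undetermined"
    cycle_radius: float | None
    description: str


def orbit_structure(signature: NormalFormSignature) -> OrbitStructure:
    """Map a spectral signature onto the reduced normal-form system."""
    eqs: list[str] = []
    has_plane = signature.center_pairs > 0
    if has_plane:
        s = "+" if signature.sigma > 0 else "-"
        eqs += [
            f"dy1/dt = b*y1 - y2 {s} y1*(y1^2 + y2^2)",
            f"dy2/dt = y1 + b*y2 {s} y2*(y1^2 + y2^2)",
        ]
    if signature.N_s:
        eqs.append(f"ds_i/dt = -s_i  (i = 1..{signature.N_s})")
    if signature.N_u:
        eqs.append(f"du_j/dt = +u_j  (j = 1..{signature.N_u})")

    cycle = "none"
    radius = None
    if has_plane:
        if signature.beta is None:
            cycle = "undetermined"
        elif signature.sigma > 0 and signature.beta < 0:
            cycle, radius = "unstable", float(np.sqrt(-signature.beta))
        elif signature.sigma < 0 and signature.beta > 0:
            cycle, radius = "stable", float(np.sqrt(signature.beta))

    bits = []
    if signature.N_u:
        bits.append(f"{signature.N_u} divergent dimension(s)")
    if has_plane:
        bits.append(
            f"{signature.center_pairs} planar center block(s) "
            f"(limit cycle: {cycle}"
            + (f", radius ~ {radius:.4g}" if radius is not None else "")
            + ")"
        )
    if signature.N_s:
        bits.append(f"{signature.N_s} contracting dimension(s)")
    desc = "; ".join(bits) if bits else "empty signature"
    if signature.N_u == 0 and not has_plane:
        desc = f"all {signature.N_s} dimensions contract (asymptotic stability)"
    return OrbitStructure(
        signature=signature,
        reduced_system=eqs,
        contracting_dims=signature.N_s,
        expanding_dims=signature.N_u,
        has_planar_block=has_plane,
        limit_cycle=cycle,
        cycle_radius=radius,
        description=desc,
    )


def probe_limit_cycle(
    model: KineticModel,
    eq: np.ndarray,
    plane: tuple[int, int],
    radii: list[float],
    t_end: float = 20.0,
    options: IntegrationOptions | None = None,
    conv_frac: float = 0.25,
    cycle_frac: float = 0.1,
) -> dict[float, str]:
    """Launch trajectories on a 2-D plane around ``eq`` and classify them.

    Each radius gets an outcome in {converged, cycling, diverged}: the
    planar distance from the equilibrium at the horizon shrinks below
    ``conv_frac`` of the start, stays within ``cycle_frac`` of it, or grows
    beyond it (blow-up counts as diverged). A converged -> diverged sign
    change across radii evidences an unstable limit cycle in between.
    """
    i, j = plane
    if i == j:
        raise ValueError("plane indices must be distinct")
    eq = np.asarray(eq, dtype=float)
    opts = options or IntegrationOptions(t_end=t_end, n_grid=200, rtol=1e-10, atol=1e-12)
    outcomes: dict[float, str] = {}
    for r in radii:
        x0 = eq.copy()
        x0[i] += r
        traj = integrate(model, x0, opts)
        if traj.status != "completed":
            outcomes[r] = "diverged"
            continue
        end = traj.endpoint
        r_end = float(np.hypot(end[i] - eq[i], end[j] - eq[j]))
        if r_end < conv_frac * r:
            outcomes[r] = "converged"
        elif abs(r_end - r) <= cycle_frac * r:
            outcomes[r] = "cycling"
        else:
            outcomes[r] = "diverged"
    return outcomes


def estimate_cycle_radius(
    model: KineticModel,
    eq: np.ndarray,
    plane: tuple[int, int],
    r_lo: float,
    r_hi: float,
    n_iter: int = 20,
    t_probe: float = 2.0,
) -> float:
    """Bisect for an unstable cycle radius between a converging and a
    diverging start, using the sign of the short-horizon radial drift."""
    i, j = plane
    opts = IntegrationOptions(t_end=t_probe, n_grid=20, rtol=1e-10, atol=1e-12)

    def drift(r: float) -> float:
        x0 = np.asarray(eq, dtype=float).copy()
        x0[i] += r
        traj = integrate(model, x0, opts)
        if traj.status != "completed":
            return +1.0
        end = traj.endpoint
        return float(np.hypot(end[i] - eq[i], end[j] - eq[j])) - r

    lo, hi = r_lo, r_hi
    if drift(lo) > 0 or drift(hi) < 0:
        raise ValueError("bracket does not straddle the cycle (drift signs equal)")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if drift(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class DynamicsReport:
    """Outcome of the knockout bifurcation checklist for one enzyme."""

    enzyme: str
    category: str  # no_equilibrium | extreme_deviation |
    #               relocated_with_stability_change | relocated_stable |
    #               near_stable | indeterminate
    equilibria: list[EquilibriumReport] = field(default_factory=list)
    trajectory_status: str = ""
    diagnostics: dict = field(default_factory=dict)


_SEVERITY = {
    "near_stable": 0,
    "relocated_stable": 1,
    "relocated_with_stability_change": 2,
    "extreme_deviation": 3,
}


def equilibrium_report(
    model: KineticModel,
    guess: np.ndarray,
    reference_x: np.ndarray | None = None,
    thresholds: StabilityThresholds | None = None,
) -> EquilibriumReport:
    """Full equilibrium report: location + spectrum + stability + deviation."""
    th = thresholds or StabilityThresholds()
    rep = find_equilibrium(model, guess, th)
    if not rep.found:
        return rep
    J = jacobian_at(model, rep.x_eq)
    rep.eigenvalues = np.linalg.eigvals(J)
    rep.stability, rep.signature = classify_stability(rep.eigenvalues, th.imag_tol)
    if reference_x is not None:
        rep.deviation = float(np.linalg.norm(rep.x_eq - reference_x))
        box_hi = th.box_factor * np.maximum(np.asarray(reference_x), 1e-12)
        rep.in_ordinary_range = bool(np.all(rep.x_eq <= box_hi))
    else:
        rep.deviation = 0.0
        rep.in_ordinary_range = True
    return rep


def _categorize(rep: EquilibriumReport, ref_norm: float, th: StabilityThresholds) -> str:
    if not rep.in_ordinary_range or rep.deviation > th.extreme_frac * ref_norm:
        return "extreme_deviation"
    if rep.stability != "asymptotically_stable":
        return "relocated_with_stability_change"
    if rep.deviation < th.near_frac * ref_norm:
        return "near_stable"
    return "relocated_stable"


def characterize_dynamics(
    model: KineticModel,
    enzyme_id: str,
    reference_eq: np.ndarray,
    thresholds: StabilityThresholds | None = None,
    seed: int = 0,
    options: IntegrationOptions | None = None,
) -> DynamicsReport:
    """Run the knockout bifurcation checklist for one enzyme.

    Knocks out the enzyme, simulates long, searches for residual equilibria
    from the trajectory endpoint plus seeded log-uniform random starts in
    the ordinary-range box, and classifies the outcome. When several
    distinct equilibria are found, the reported category is the most severe
    one (a single qualitatively changed equilibrium already counts as a
    large impact on dynamical stability).
    """
    th = thresholds or StabilityThresholds()
    opts = options or IntegrationOptions()
    reference_eq = np.asarray(reference_eq, dtype=float)
    knocked = model.knockout(enzyme_id)

    traj = integrate(knocked, model.x0, opts)
    divergent = traj.status == "blew_up"
    if traj.status == "completed":
        drift = float(np.linalg.norm(knocked.rhs(np.maximum(traj.endpoint, 0.0))))
        divergent = drift > th.settled_tol

    rng = np.random.default_rng(seed)
    starts = [np.maximum(traj.endpoint, 0.0)] if traj.times.size else []
    lo = np.maximum(reference_eq, 1e-12) * 1e-2
    hi = np.maximum(reference_eq, 1e-12) * th.box_factor
    for _ in range(th.n_starts):
        starts.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    found: list[EquilibriumReport] = []
    failures = 0
    for guess in starts:
        rep = equilibrium_report(knocked, guess, reference_x=reference_eq, thresholds=th)
        if rep.found:
            if not any(
                np.allclose(rep.x_eq, other.x_eq, rtol=1e-4, atol=1e-6) for other in found
            ):
                found.append(rep)
        else:
            failures += 1

    diag = {"starts": len(starts), "failures": failures, "trajectory": traj.status}
    if not found:
        category = "no_equilibrium" if divergent else "indeterminate"
        return DynamicsReport(
            enzyme=enzyme_id, category=category, equilibria=[],
            trajectory_status=traj.status, diagnostics=diag,
        )
    categories = [_categorize(rep, float(np.linalg.norm(reference_eq)), th) for rep in found]
    worst = max(categories, key=lambda c: _SEVERITY[c])
    return DynamicsReport(
        enzyme=enzyme_id, category=worst, equilibria=found,
        trajectory_status=traj.status, diagnostics={**diag, "categories": categories},
    )
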