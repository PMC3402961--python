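"""Per-enzyme criticality verdicts: fluctuation evidence + stability evidence.

An enzyme is *critical* when its deletion both (a) causes a large impact on
system states (impact measure above threshold) and (b) qualitatively
changes the system's dynamical stability (no residual equilibrium, an
extreme equilibrium relocation, or a relocation with a stability change).
It is *uncritical* when the residual system keeps a nearby asymptotically
stable equilibrium and the state impact is small. Mixed evidence yields
``indeterminate`` rather than a forced call.

The state-impact threshold is self-calibrating: knockouts whose residual
system keeps a *nearby stable* equilibrium are the sweep's own reference
for what a small state impact looks like, so the cut is placed a factor-two
margin above the largest M(n=1) in that reference group. When no knockout
is near-stable (e.g. a linear chain, where every deletion is equally
catastrophic) an absolute default applies; an explicit override is
available everywhere.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluctuation import FluctuationProfile, fluctuation_profile
from .model import KineticModel
from .simulation import IntegrationOptions, integrate
from .stability import (
    DynamicsReport,
    StabilityThresholds,
    characterize_dynamics,
    equilibrium_report,
)

__all__ = ["SweepConfig", "CriticalityVerdict", "classify_enzyme", "run_all", "SweepResult"]

#: absolute fallback impact threshold. M(1) sums relative trajectory
#: deviations over all entities: values of order 1 mean the system barely
#: moved, values of order 10+ mean aggregate state changes comparable to
#: many baseline magnitudes
DEFAULT_IMPACT_THRESHOLD = 10.0

#: margin factor above the small-impact reference group
IMPACT_MARGIN = 2.0


def sweep_impact_threshold(m1_by_dynamics: list[tuple[float, str]]) -> float:
    """Self-calibrated impact cut from the sweep's own evidence.

    Knockouts classified ``near_stable`` by the bifurcation checklist are
    the internal reference for "small" state impact; the threshold sits
    :data:`IMPACT_MARGIN` times above the largest M(1) among them. Without
    any near-stable knockout the absolute
    :data:`DEFAULT_IMPACT_THRESHOLD` applies.
    """
    reference = [
        m1 for m1, cat in m1_by_dynamics
        if cat == "near_stable" and np.isfinite(m1)
    ]
    if reference:
        return IMPACT_MARGIN * float(max(reference))
    return DEFAULT_IMPACT_THRESHOLD

_QUALITATIVE_CHANGE = {
    "no_equilibrium",
    "extreme_deviation",
    "relocated_with_stability_change",
}


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a full-model criticality sweep."""

    integration: IntegrationOptions = field(default_factory=IntegrationOptions)
    thresholds: StabilityThresholds = field(default_factory=StabilityThresholds)
    impact_exponents: tuple[int, ...] = (1, 2)
    impact_threshold: float | None = None  # None -> sweep median of M(1)
    view: str = "metabolite"
    seed: int = 0


@dataclass
class CriticalityVerdict:
    """The combined evidence record and label for one enzyme."""

    enzyme: str
    label: str  # critical | uncritical | indeterminate
    dynamics: str  # category from the bifurcation checklist
    M: dict[int, float]
    max_amplitude: float
    distance_of_max: int | None
    truncated: bool
    impact_threshold: float
    rationale: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "enzyme": self.enzyme,
            "label": self.label,
            "dynamics": self.dynamics,
            "M": {str(k): v for k, v in self.M.items()},
            "max_amplitude": self.max_amplitude,
            "distance_of_max": self.distance_of_max,
            "truncated": self.truncated,
            "impact_threshold": self.impact_threshold,
            "rationale": self.rationale,
        }


def _verdict_from_evidence(
    profile: FluctuationProfile,
    dynamics: DynamicsReport,
    impact_threshold: float,
) -> CriticalityVerdict:
    m1 = profile.M.get(1, 0.0)
    large_impact = m1 >= impact_threshold
    qualitative = dynamics.category in _QUALITATIVE_CHANGE
    if qualitative and large_impact:
        label = "critical"
    elif dynamics.category == "near_stable" and not large_impact:
        label = "uncritical"
    else:
        label = "indeterminate"
    return CriticalityVerdict(
        enzyme=profile.enzyme,
        label=label,
        dynamics=dynamics.category,
        M=dict(profile.M),
        max_amplitude=profile.max_amplitude,
        distance_of_max=profile.distance_of_max,
        truncated=profile.truncated,
        impact_threshold=impact_threshold,
        rationale={
            "large_state_impact": bool(large_impact),
            "qualitative_stability_change": bool(qualitative),
            "trajectory": dynamics.trajectory_status,
            "n_equilibria": len(dynamics.equilibria),
        },
    )


def classify_enzyme(
    model: KineticModel,
    enzyme_id: str,
    reference_eq: np.ndarray | None = None,
    config: SweepConfig | None = None,
    impact_threshold: float | None = None,
) -> CriticalityVerdict:
    """Classify a single enzyme with the conjunction rule."""
    cfg = config or SweepConfig()
    if reference_eq is None:
        ref = _reference_equilibrium(model, cfg)
        reference_eq = ref.x_eq
    threshold = (
        impact_threshold
        if impact_threshold is not None
        else (cfg.impact_threshold if cfg.impact_threshold is not None else DEFAULT_IMPACT_THRESHOLD)
    )
    profile = fluctuation_profile(
        model, enzyme_id, view=cfg.view, options=cfg.integration,
        n_values=cfg.impact_exponents,
    )
    dynamics = characterize_dynamics(
        model, enzyme_id, reference_eq, thresholds=cfg.thresholds,
        seed=cfg.seed, options=cfg.integration,
    )
    return _verdict_from_evidence(profile, dynamics, threshold)


def _reference_equilibrium(model: KineticModel, cfg: SweepConfig):
    traj = integrate(model, model.x0, cfg.integration)
    rep = equilibrium_report(model, traj.endpoint, reference_x=None, thresholds=cfg.thresholds)
    if not rep.found:
        raise RuntimeError(
            "could not locate the reference equilibrium of the original model"
        )
    return rep


@dataclass
class SweepResult:
    """All verdicts of a model sweep plus the reference equilibrium."""

    verdicts: list[CriticalityVerdict]
    reference: object  # EquilibriumReport of the original system
    impact_threshold: float
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def critical(self) -> list[str]:
        return [v.enzyme for v in self.verdicts if v.label == "critical"]

    @property
    def uncritical(self) -> list[str]:
        return [v.enzyme for v in self.verdicts if v.label == "uncritical"]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "enzyme": v.enzyme,
                    "label": v.label,
                    "dynamics": v.dynamics,
                    "M1": v.M.get(1, np.nan),
                    "M2": v.M.get(2, np.nan),
                    "max_amplitude": v.max_amplitude,
                    "distance_of_max": v.distance_of_max,
                    "truncated": v.truncated,
                }
                for v in self.verdicts
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "impact_threshold": self.impact_threshold,
                "verdicts": [v.to_dict() for v in self.verdicts],
            },
            indent=2,
            sort_keys=True,
        )


def run_all(model: KineticModel, config: SweepConfig | None = None) -> SweepResult:
    """Sweep every knockout-eligible enzyme and return all verdicts.

    One enzyme's failure never aborts the sweep: failures are reported as
    ``indeterminate`` verdicts carrying the error text.
    """
    cfg = config or SweepConfig()
    reference = _reference_equilibrium(model, cfg)
    traj0 = integrate(model, model.x0, cfg.integration)

    profiles: dict[str, FluctuationProfile] = {}
    dynamics: dict[str, DynamicsReport] = {}
    errors: dict[str, str] = {}
    timings: dict[str, float] = {}
    for enz in model.enzyme_ids:
        t0 = time.perf_counter()
        try:
            profiles[enz] = fluctuation_profile(
                model, enz, view=cfg.view, options=cfg.integration,
                n_values=cfg.impact_exponents, traj0=traj0,
            )
            dynamics[enz] = characterize_dynamics(
                model, enz, reference.x_eq, thresholds=cfg.thresholds,
                seed=cfg.seed, options=cfg.integration,
            )
        except Exception as exc:  # isolate per-enzyme crashes
            errors[enz] = f"{type(exc).__name__}: {exc}"
        timings[enz] = time.perf_counter() - t0

    if cfg.impact_threshold is not None:
        threshold = cfg.impact_threshold
    else:
        threshold = sweep_impact_threshold(
            [
                (profiles[e].M.get(1, 0.0), dynamics[e].category)
                for e in profiles
                if e in dynamics
            ]
        )

    verdicts: list[CriticalityVerdict] = []
    for enz in model.enzyme_ids:  # deterministic model order
        if enz in errors:
            verdicts.append(
                CriticalityVerdict(
                    enzyme=enz, label="indeterminate", dynamics="error",
                    M={}, max_amplitude=np.nan, distance_of_max=None,
                    truncated=False, impact_threshold=threshold,
                    rationale={"error": errors[enz]},
                )
            )
            continue
        verdicts.append(_verdict_from_evidence(profiles[enz], dynamics[enz], threshold))
    return SweepResult(
        verdicts=verdicts, reference=reference,
        impact_threshold=threshold, timings=timings,
    )
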