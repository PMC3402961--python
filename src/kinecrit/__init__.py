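"""kinecrit: criticality characterization of enzymes in kinetic metabolic models.

The workflow mirrors systems-dynamics criticality analysis: simulate a
kinetic ODE model, delete an enzyme in silico, quantify the distance-resolved
state fluctuations it causes, test whether the residual system keeps a
(nearby, stable) equilibrium, and validate the resulting critical/uncritical
split against flux-sums of essential metabolites under minimization of
metabolic adjustment.
"""

from .fixtures import (
    FixtureSpec,
    make_branched_compensation,
    make_central_carbon,
    make_fixture,
    make_linear_chain,
    make_normal_form_oscillator,
)
from .fluctuation import FluctuationProfile, amplitude, fluctuation_profile, impact_measure
from .model import (
    KineticModel,
    Metabolite,
    ModelParseError,
    ModelValidationError,
    Reaction,
    knockout,
    load_model,
    save_model,
)
from .moma import FluxSumTable, GAConfig, MomaResult, flux_sum, fluxsum_report, moma_adjust
from .network import DistanceMap, enzyme_distances, enzyme_graph, metabolite_distances
from .criticality import CriticalityVerdict, SweepConfig, SweepResult, classify_enzyme, run_all
from .simulation import (
    IntegrationOptions,
    Trajectory,
    integrate,
    perturb_initial,
    trajectory_fluxes,
)
from .stability import (
    DynamicsReport,
    EquilibriumReport,
    NormalFormSignature,
    OrbitStructure,
    StabilityThresholds,
    characterize_dynamics,
    classify_stability,
    equilibrium_report,
    estimate_cycle_radius,
    find_equilibrium,
    jacobian_at,
    orbit_structure,
    probe_limit_cycle,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def bundled_model_path(name: str = "central_carbon_synthetic"):
    """Path to a bundled model-definition file shipped with the package."""
    from importlib.resources import files

    return files("kinecrit").joinpath("data", f"{name}.yaml")
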