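"""Synthetic kinetic models with analytically known behavior.

Three programmatic fixture families cover the oracle needs of every other
module:

* linear chains (closed-form steady state ``Xi* = v0/ki`` and triangular
  Jacobian ``diag(-k)``),
* a branched compensation motif (two parallel routes from a source to a
  target; deleting one raises the steady-state flux through the other),
* the planar normal-form system with ``N_s`` contracting and ``N_u``
  expanding extra dimensions, whose unstable limit cycle has radius
  ``sqrt(-beta)`` for ``sigma = +1, beta < 0``.

In addition, :func:`make_central_carbon` builds a *synthetic*, scaled-down
central-carbon-style network (glycolysis + pentose phosphate pathway,
Michaelis-Menten kinetics) whose reference state is an exact flux-balanced
equilibrium by construction. It is a stand-in constructed for this package
— its topology follows E. coli central carbon metabolism but its rate laws
and parameters are designed, not measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import KineticModel, Metabolite, ModelValidationError, Reaction

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_linear_chain",
    "make_branched_compensation",
    "make_normal_form_oscillator",
    "make_central_carbon",
    "CENTRAL_CARBON_STEADY_STATE",
    "CENTRAL_CARBON_FLUXES",
    "ESSENTIAL_METABOLITES",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic model.

    Identical specs produce identical serialized models (byte-stable):
    random draws use ``numpy.random.default_rng(seed)`` and nothing else.
    """

    kind: str  # linear_chain | branched_compensation | normal_form_oscillator
    size: int = 2
    kinetics: str = "mass_action"
    k_range: tuple[float, float] = (0.5, 5.0)
    seed: int = 0


def make_fixture(spec: FixtureSpec) -> KineticModel:
    if spec.kind == "linear_chain":
        return make_linear_chain(spec.size, seed=spec.seed, k_range=spec.k_range)
    if spec.kind == "branched_compensation":
        return make_branched_compensation(seed=spec.seed)
    if spec.kind == "normal_form_oscillator":
        return make_normal_form_oscillator(beta=-1.0, sigma=+1, n_stable=spec.size, n_unstable=0)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def make_linear_chain(
    n: int,
    v0: float = 1.0,
    k: "np.ndarray | list[float] | None" = None,
    seed: int | None = None,
    k_range: tuple[float, float] = (0.5, 5.0),
) -> KineticModel:
    """Constant inflow -> X1 -> ... -> Xn -> outflow with mass-action steps.

    Enzyme ``ei`` consumes ``Xi`` at rate ``ki * Xi``; the analytic steady
    state is ``Xi* = v0 / ki`` and the Jacobian is lower-bidiagonal with
    ``-ki`` on the diagonal.
    """
    if n < 1:
        raise ModelValidationError("chain length must be >= 1")
    if v0 <= 0:
        raise ModelValidationError("inflow v0 must be > 0")
    if k is None:
        rng = np.random.default_rng(seed)
        k = rng.uniform(*k_range, size=n)
    k = np.asarray(k, dtype=float)
    if k.shape != (n,) or np.any(k <= 0):
        raise ModelValidationError("rate constants k must be strictly positive, one per step")

    mets = [Metabolite(id=f"X{i+1}", name=f"chain species {i+1}") for i in range(n)]
    params: dict[str, float] = {"v0": float(v0)}
    rxns = [
        Reaction(
            id="inflow",
            enzyme_name="constant source",
            products=[("X1", 1.0)],
            rate_law="v0",
            vmax_params=["v0"],
            is_lumped=True,
        )
    ]
    for i in range(n):
        params[f"k{i+1}"] = float(k[i])
        products = [(f"X{i+2}", 1.0)] if i + 1 < n else []
        rxns.append(
            Reaction(
                id=f"e{i+1}",
                enzyme_name=f"chain enzyme {i+1}",
                substrates=[(f"X{i+1}", 1.0)],
                products=products,
                rate_law=f"k{i+1} * X{i+1}",
                vmax_params=[f"k{i+1}"],
            )
        )
    x0 = {f"X{i+1}": float(v0 / k[i]) for i in range(n)}
    return KineticModel(mets, rxns, params, initial_state=x0, name=f"linear_chain_{n}")


def make_branched_compensation(seed: int = 0) -> KineticModel:
    """One source S feeding a target T through two parallel routes.

    The high-capacity branch carries most of the inflow at baseline; both
    branches alone can carry the full inflow, so deleting either one raises
    the steady-state flux through the survivor (local flux compensation).
    """
    del seed  # parameterization is fixed; kept for the FixtureSpec contract
    mets = [Metabolite(id="S", name="source"), Metabolite(id="T", name="target")]
    params = {
        "v0": 1.0,
        "Vh": 3.0,
        "Kh": 1.0,
        "Vl": 1.5,
        "Kl": 4.0,
        "kout": 2.0,
    }
    rxns = [
        Reaction(id="inflow", products=[("S", 1.0)], rate_law="v0",
                 vmax_params=["v0"], is_lumped=True),
        Reaction(id="bHigh", enzyme_name="high-capacity branch",
                 substrates=[("S", 1.0)], products=[("T", 1.0)],
                 rate_law="Vh * S / (Kh + S)", vmax_params=["Vh"]),
        Reaction(id="bLow", enzyme_name="low-capacity branch",
                 substrates=[("S", 1.0)], products=[("T", 1.0)],
                 rate_law="Vl * S / (Kl + S)", vmax_params=["Vl"]),
        Reaction(id="outflow", substrates=[("T", 1.0)], rate_law="kout * T",
                 vmax_params=["kout"], is_lumped=True),
    ]
    return KineticModel(
        mets, rxns, params, initial_state={"S": 0.4, "T": 0.5},
        name="branched_compensation",
    )


def make_normal_form_oscillator(
    beta: float,
    sigma: int = +1,
    n_stable: int = 0,
    n_unstable: int = 0,
) -> KineticModel:
    """The reduced normal-form ODE used as a stability-analysis oracle.

    Planar block::

        dy1/dt = beta*y1 - y2 + sigma*y1*(y1^2 + y2^2)
        dy2/dt = y1 + beta*y2 + sigma*y2*(y1^2 + y2^2)

    plus ``n_stable`` coordinates decaying as ``exp(-t)`` and
    ``n_unstable`` growing as ``exp(+t)``. In polar coordinates the radial
    drift is ``dr/dt = beta*r + sigma*r^3``: for ``sigma=+1, beta<0`` an
    unstable limit cycle of radius ``sqrt(-beta)`` surrounds a locally
    stable origin. Not a metabolic network; states may go negative.
    """
    if sigma not in (-1, +1):
        raise ModelValidationError("sigma must be -1 or +1")
    mets = [Metabolite(id="y1", name="planar coordinate 1"),
            Metabolite(id="y2", name="planar coordinate 2")]
    ext = {
        "y1": "beta*y1 - y2 + sigma*y1*(y1*y1 + y2*y2)",
        "y2": "y1 + beta*y2 + sigma*y2*(y1*y1 + y2*y2)",
    }
    x0 = {"y1": 0.1, "y2": 0.0}
    for i in range(n_stable):
        mets.append(Metabolite(id=f"s{i+1}", name=f"contracting coordinate {i+1}"))
        ext[f"s{i+1}"] = f"-s{i+1}"
        x0[f"s{i+1}"] = 1.0
    for i in range(n_unstable):
        mets.append(Metabolite(id=f"u{i+1}", name=f"expanding coordinate {i+1}"))
        ext[f"u{i+1}"] = f"u{i+1}"
        x0[f"u{i+1}"] = 0.0
    return KineticModel(
        mets, [], {"beta": float(beta), "sigma": float(sigma)},
        external_terms=ext, initial_state=x0,
        name="normal_form_oscillator", nonnegative=False,
    )


# --------------------------------------------------------------------------
# Synthetic central-carbon-style model
# --------------------------------------------------------------------------

#: designed reference steady state (mM); an exact equilibrium by construction
CENTRAL_CARBON_STEADY_STATE: dict[str, float] = {
    "g6p": 3.5, "f6p": 0.6, "fdp": 0.27, "dhap": 0.17, "gap": 0.22,
    "pgp": 0.01, "pg3": 2.1, "pg2": 0.4, "pep": 2.7, "pyr": 2.7,
    "oaa": 0.2, "pg6": 0.5, "ribu5p": 0.11, "xyl5p": 0.14, "rib5p": 0.2,
    "sed7p": 0.15, "e4p": 0.1, "g1p": 0.65,
}

#: designed reference fluxes (mM/s) at the steady state
CENTRAL_CARBON_FLUXES: dict[str, float] = {
    "PTS": 0.95, "NonPTS": 0.05, "PGI": 0.53, "PFK": 0.80, "ALDO": 0.80,
    "TIS": 0.80, "GAPDH": 1.71, "PGK": 1.71, "PGluMu": 1.65, "ENO": 1.65,
    "PK": 0.25, "PDH": 1.20, "PEPCx": 0.40, "TCA": 0.40, "G6PDH": 0.45,
    "PGDH": 0.45, "Ru5P": 0.27, "R5PI": 0.18, "TKa": 0.16, "TKb": 0.11,
    "TA": 0.16, "RPPK": 0.02, "DAHPS": 0.05, "SerSynth": 0.06,
    "PGM": 0.02, "G1PAT": 0.015, "G1PUtil": 0.005,
}

#: biosynthetic-precursor metabolites carrying the synthetic "essential"
#: annotation used by the flux-sum essentiality validation
ESSENTIAL_METABOLITES: tuple[str, ...] = (
    "g6p", "f6p", "gap", "pg3", "pep", "pyr", "e4p", "rib5p",
)

_CCM_NAMES = {
    "g6p": "glucose-6-phosphate", "f6p": "fructose-6-phosphate",
    "fdp": "fructose-1,6-bisphosphate", "dhap": "dihydroxyacetone phosphate",
    "gap": "glyceraldehyde-3-phosphate", "pgp": "1,3-diphosphoglycerate",
    "pg3": "3-phosphoglycerate", "pg2": "2-phosphoglycerate",
    "pep": "phosphoenolpyruvate", "pyr": "pyruvate", "oaa": "oxaloacetate",
    "pg6": "6-phosphogluconate", "ribu5p": "ribulose-5-phosphate",
    "xyl5p": "xylulose-5-phosphate", "rib5p": "ribose-5-phosphate",
    "sed7p": "sedoheptulose-7-phosphate", "e4p": "erythrose-4-phosphate",
    "g1p": "glucose-1-phosphate",
}


def make_central_carbon() -> KineticModel:
    """Synthetic scaled-down E. coli central-carbon-style kinetic model.

    18 dynamic metabolites (glycolysis, pentose phosphate pathway, a
    glycogen branch and an anaplerotic drain), one external boundary
    species (extracellular glucose), 19 enzymatic reactions and 8 lumped
    transport/biosynthesis steps. The phosphotransferase uptake couples
    inflow to phosphoenolpyruvate, so a collapse of lower glycolysis shuts
    down uptake; a small pep-independent uptake keeps a trickle of carbon
    flowing, which makes blocked linear segments accumulate without bound
    (no residual equilibrium) rather than freeze. Parameters are chosen so
    the tabulated reference state is an exact equilibrium.
    """
    mets = [
        Metabolite(id=mid, name=_CCM_NAMES[mid],
                   role_tags={"essential"} if mid in ESSENTIAL_METABOLITES else set())
        for mid in CENTRAL_CARBON_STEADY_STATE
    ]
    mets.append(Metabolite(id="glcex", name="extracellular glucose",
                           dynamic=False, external=True, value=10.0))

    params = {
        "PTS_Vmax": 1.2454851851851854, "PTS_Kglc": 1.0, "PTS_Kpep": 0.3,
        "PTS_Kisp": 15.0,
        "NPTS_v": 0.05,
        "PGI_Vmax": 1.9875, "PGI_Km": 7.0, "PGI_Ki6pg": 2.0,
        "PFK_Vmax": 1.60, "PFK_Km": 0.6,
        "ALDO_Vmax": 1.60, "ALDO_Km": 0.27,
        "TIS_Vmax": 1.60, "TIS_Km": 0.17,
        "GAPDH_Vmax": 3.42, "GAPDH_Km": 0.22,
        "PGK_Vmax": 3.42, "PGK_Km": 0.01,
        "PGluMu_Vmax": 3.30, "PGluMu_Km": 2.1,
        "ENO_Vmax": 3.30, "ENO_Km": 0.4,
        "PK_Vmax": 0.50, "PK_Km": 2.7,
        "PDH_Vmax": 2.40, "PDH_Km": 2.7,
        "PEPCx_Vmax": 2.40, "PEPCx_K": 4.037441655296095,
        "TCA_Vmax": 0.80, "TCA_Km": 0.2,
        "G6PDH_Vmax": 8.60625, "G6PDH_K": 7.0, "G6PDH_Ki6pg": 4.0,
        "PGDH_Vmax": 2.7297, "PGDH_Km": 2.5, "PGDH_Kiribu": 10.0,
        "Ru5P_Vmax": 1.08, "Ru5P_Km": 0.33,
        "R5PI_Vmax": 0.72, "R5PI_Km": 0.33,
        "TKa_Vmax": 2.5984, "TKa_Kr5": 0.6, "TKa_Kx5": 0.42, "TKa_Kised": 10.0,
        "TKb_Vmax": 1.76, "TKb_Kx5": 0.42, "TKb_Ke4": 0.3,
        "TA_Vmax": 2.5856, "TA_Ks7": 0.45, "TA_Kgap": 0.66, "TA_Kie4": 10.0,
        "RPPK_Vmax": 0.12, "RPPK_Km": 1.0,
        "DAHPS_Vmax": 0.10, "DAHPS_Ke4": 0.08, "DAHPS_Kpep": 0.3,
        "SerSynth_Vmax": 0.12, "SerSynth_Km": 2.1,
        "PGM_Vmax": 0.04, "PGM_Km": 3.5,
        "G1PAT_Vmax": 0.03, "G1PAT_Km": 0.65,
        "G1PU_k": 0.005 / 0.65,
    }

    def mm(vmax: str, km: str, s: str) -> str:
        return f"{vmax} * {s} / ({km} + {s})"

    def bimm(vmax: str, k1: str, s1: str, k2: str, s2: str) -> str:
        return f"{vmax} * ({s1} / ({k1} + {s1})) * ({s2} / ({k2} + {s2}))"

    R = Reaction
    rxns = [
        R(id="PTS", enzyme_name="phosphotransferase uptake system",
          substrates=[("glcex", 1.0), ("pep", 1.0)],
          products=[("g6p", 1.0), ("pyr", 1.0)],
          modifiers=[("pg6", "inhibitor"), ("xyl5p", "inhibitor"),
                     ("rib5p", "inhibitor"), ("sed7p", "inhibitor"),
                     ("e4p", "inhibitor")],
          rate_law=bimm("PTS_Vmax", "PTS_Kglc", "glcex", "PTS_Kpep", "pep")
          + " / (1 + (pg6 + xyl5p + rib5p + sed7p + e4p) / PTS_Kisp)",
          vmax_params=["PTS_Vmax"], is_lumped=True),
        R(id="NonPTS", enzyme_name="pep-independent glucose uptake (lumped)",
          substrates=[("glcex", 1.0)], products=[("g6p", 1.0)],
          rate_law="NPTS_v", vmax_params=["NPTS_v"], is_lumped=True),
        R(id="PGI", enzyme_name="glucose-6-phosphate isomerase",
          substrates=[("g6p", 1.0)], products=[("f6p", 1.0)],
          modifiers=[("pg6", "inhibitor")],
          rate_law=mm("PGI_Vmax", "PGI_Km", "g6p") + " / (1 + pg6 / PGI_Ki6pg)",
          vmax_params=["PGI_Vmax"]),
        R(id="PFK", enzyme_name="phosphofructokinase",
          substrates=[("f6p", 1.0)], products=[("fdp", 1.0)],
          rate_law=mm("PFK_Vmax", "PFK_Km", "f6p"), vmax_params=["PFK_Vmax"]),
        R(id="ALDO", enzyme_name="aldolase",
          substrates=[("fdp", 1.0)], products=[("dhap", 1.0), ("gap", 1.0)],
          rate_law=mm("ALDO_Vmax", "ALDO_Km", "fdp"), vmax_params=["ALDO_Vmax"]),
        R(id="TIS", enzyme_name="triosephosphate isomerase",
          substrates=[("dhap", 1.0)], products=[("gap", 1.0)],
          rate_law=mm("TIS_Vmax", "TIS_Km", "dhap"), vmax_params=["TIS_Vmax"]),
        R(id="GAPDH", enzyme_name="glyceraldehyde-3-phosphate dehydrogenase",
          substrates=[("gap", 1.0)], products=[("pgp", 1.0)],
          rate_law=mm("GAPDH_Vmax", "GAPDH_Km", "gap"), vmax_params=["GAPDH_Vmax"]),
        R(id="PGK", enzyme_name="phosphoglycerate kinase",
          substrates=[("pgp", 1.0)], products=[("pg3", 1.0)],
          rate_law=mm("PGK_Vmax", "PGK_Km", "pgp"), vmax_params=["PGK_Vmax"]),
        R(id="PGluMu", enzyme_name="phosphoglycerate mutase",
          substrates=[("pg3", 1.0)], products=[("pg2", 1.0)],
          rate_law=mm("PGluMu_Vmax", "PGluMu_Km", "pg3"), vmax_params=["PGluMu_Vmax"]),
        R(id="ENO", enzyme_name="enolase",
          substrates=[("pg2", 1.0)], products=[("pep", 1.0)],
          rate_law=mm("ENO_Vmax", "ENO_Km", "pg2"), vmax_params=["ENO_Vmax"]),
        R(id="PK", enzyme_name="pyruvate kinase",
          substrates=[("pep", 1.0)], products=[("pyr", 1.0)],
          rate_law=mm("PK_Vmax", "PK_Km", "pep"), vmax_params=["PK_Vmax"]),
        R(id="PDH", enzyme_name="pyruvate dehydrogenase drain (lumped)",
          substrates=[("pyr", 1.0)],
          rate_law=mm("PDH_Vmax", "PDH_Km", "pyr"), vmax_params=["PDH_Vmax"],
          is_lumped=True),
        R(id="PEPCx", enzyme_name="pep carboxylase",
          substrates=[("pep", 1.0)], products=[("oaa", 1.0)],
          rate_law="PEPCx_Vmax * pep**4 / (PEPCx_K**4 + pep**4)",
          vmax_params=["PEPCx_Vmax"]),
        R(id="TCA", enzyme_name="TCA-cycle drain (lumped)",
          substrates=[("oaa", 1.0)],
          rate_law=mm("TCA_Vmax", "TCA_Km", "oaa"), vmax_params=["TCA_Vmax"],
          is_lumped=True),
        R(id="G6PDH", enzyme_name="glucose-6-phosphate dehydrogenase",
          substrates=[("g6p", 1.0)], products=[("pg6", 1.0)],
          modifiers=[("pg6", "inhibitor")],
          rate_law="G6PDH_Vmax * g6p**4 / (G6PDH_K**4 + g6p**4) / (1 + pg6 / G6PDH_Ki6pg)",
          vmax_params=["G6PDH_Vmax"]),
        R(id="PGDH", enzyme_name="6-phosphogluconate dehydrogenase",
          substrates=[("pg6", 1.0)], products=[("ribu5p", 1.0)],
          modifiers=[("ribu5p", "inhibitor")],
          rate_law=mm("PGDH_Vmax", "PGDH_Km", "pg6") + " / (1 + ribu5p / PGDH_Kiribu)",
          vmax_params=["PGDH_Vmax"]),
        R(id="Ru5P", enzyme_name="ribulose-5-phosphate epimerase",
          substrates=[("ribu5p", 1.0)], products=[("xyl5p", 1.0)],
          rate_law=mm("Ru5P_Vmax", "Ru5P_Km", "ribu5p"), vmax_params=["Ru5P_Vmax"]),
        R(id="R5PI", enzyme_name="ribose-5-phosphate isomerase",
          substrates=[("ribu5p", 1.0)], products=[("rib5p", 1.0)],
          rate_law=mm("R5PI_Vmax", "R5PI_Km", "ribu5p"), vmax_params=["R5PI_Vmax"]),
        R(id="TKa", enzyme_name="transketolase a",
          substrates=[("rib5p", 1.0), ("xyl5p", 1.0)],
          products=[("sed7p", 1.0), ("gap", 1.0)],
          modifiers=[("sed7p", "inhibitor")],
          rate_law=bimm("TKa_Vmax", "TKa_Kr5", "rib5p", "TKa_Kx5", "xyl5p")
          + " / (1 + sed7p / TKa_Kised)",
          vmax_params=["TKa_Vmax"]),
        R(id="TKb", enzyme_name="transketolase b",
          substrates=[("xyl5p", 1.0), ("e4p", 1.0)],
          products=[("f6p", 1.0), ("gap", 1.0)],
          rate_law=bimm("TKb_Vmax", "TKb_Kx5", "xyl5p", "TKb_Ke4", "e4p"),
          vmax_params=["TKb_Vmax"]),
        R(id="TA", enzyme_name="transaldolase",
          substrates=[("sed7p", 1.0), ("gap", 1.0)],
          products=[("e4p", 1.0), ("f6p", 1.0)],
          modifiers=[("e4p", "inhibitor")],
          rate_law=bimm("TA_Vmax", "TA_Ks7", "sed7p", "TA_Kgap", "gap")
          + " / (1 + e4p / TA_Kie4)",
          vmax_params=["TA_Vmax"]),
        R(id="RPPK", enzyme_name="ribose-phosphate drain to nucleotides (lumped)",
          substrates=[("rib5p", 1.0)],
          rate_law=mm("RPPK_Vmax", "RPPK_Km", "rib5p"), vmax_params=["RPPK_Vmax"],
          is_lumped=True),
        R(id="DAHPS", enzyme_name="aromatic biosynthesis drain (lumped)",
          substrates=[("e4p", 1.0), ("pep", 1.0)],
          rate_law=bimm("DAHPS_Vmax", "DAHPS_Ke4", "e4p", "DAHPS_Kpep", "pep"),
          vmax_params=["DAHPS_Vmax"], is_lumped=True),
        R(id="SerSynth", enzyme_name="serine biosynthesis drain (lumped)",
          substrates=[("pg3", 1.0)],
          rate_law=mm("SerSynth_Vmax", "SerSynth_Km", "pg3"),
          vmax_params=["SerSynth_Vmax"], is_lumped=True),
        R(id="PGM", enzyme_name="phosphoglucomutase",
          substrates=[("g6p", 1.0)], products=[("g1p", 1.0)],
          rate_law=mm("PGM_Vmax", "PGM_Km", "g6p"), vmax_params=["PGM_Vmax"]),
        R(id="G1PAT", enzyme_name="glucose-1-phosphate adenyltransferase",
          substrates=[("g1p", 1.0)],
          rate_law=mm("G1PAT_Vmax", "G1PAT_Km", "g1p"), vmax_params=["G1PAT_Vmax"]),
        R(id="G1PUtil", enzyme_name="glucose-1-phosphate utilization (lumped)",
          substrates=[("g1p", 1.0)],
          rate_law="G1PU_k * g1p", vmax_params=["G1PU_k"], is_lumped=True),
    ]
    return KineticModel(
        mets, rxns, params,
        initial_state=dict(CENTRAL_CARBON_STEADY_STATE),
        name="central_carbon_synthetic",
    )
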