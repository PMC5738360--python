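"""Rate modeling and parameter estimation for GPCR-coupled CRISPR reporters.

``chachakit`` models a receptor-cleavage ("ChaCha") architecture in which an
activated GPCR carries a protease that releases dCas9-effector molecules from
a membrane-sequestered adaptor fusion, driving a reporter gene. The package
provides the mass-action rate model and its closed-form steady state, ODE
simulation under piecewise-constant inducer/ligand schedules, seeded synthetic
datasets mimicking well-level flow-cytometry readouts, nonlinear least-squares
fits (per-receptor effector stoichiometry n, Hill dose-response EC50, dox
induction cooperativity), and ddCt qPCR quantification.
"""

from importlib import resources

from .params import (
    ChaChaRateParams,
    DoseResponseParams,
    DoxInductionParams,
    DoxRateConstants,
    SteadyStateParams,
)
from .model_core import (
    SteadyStateConvergenceError,
    chacha_steady_state_gfp,
    derive_steady_state_params,
    dox_steady_state_gfp,
    solve_coupled_steady_state,
)
from .dynamics import (
    Schedule,
    SimulationError,
    Trajectory,
    simulate_chacha,
    simulate_dox,
    time_to_fraction,
)
from .synthetic_data import (
    NoiseModel,
    default_adaptor_levels,
    default_ligand_doses,
    generate_dose_response,
    generate_dox_induction,
    generate_grid_dataset,
    generate_qpcr_plate,
    hill_response,
)
from .fitting import (
    FitConvergenceError,
    FitResult,
    IdentifiabilityError,
    fit_dox_hill,
    fit_hill_dose_response,
    fit_steady_state_model,
    pearson_r,
)
from .qpcr import (
    CT_THRESHOLD,
    analyze_plate,
    clamp_ct,
    clamp_plate,
    fold_change,
    relative_expression,
)

__version__ = "0.1.0"


def demo_config_path():
    """Path to the packaged demo configuration (truth parameter sets)."""
    return resources.files("chachakit").joinpath("data/demo_config.json")


__all__ = [
    "ChaChaRateParams",
    "DoseResponseParams",
    "DoxInductionParams",
    "DoxRateConstants",
    "SteadyStateParams",
    "SteadyStateConvergenceError",
    "chacha_steady_state_gfp",
    "derive_steady_state_params",
    "dox_steady_state_gfp",
    "solve_coupled_steady_state",
    "Schedule",
    "SimulationError",
    "Trajectory",
    "simulate_chacha",
    "simulate_dox",
    "time_to_fraction",
    "NoiseModel",
    "default_adaptor_levels",
    "default_ligand_doses",
    "generate_dose_response",
    "generate_dox_induction",
    "generate_grid_dataset",
    "generate_qpcr_plate",
    "hill_response",
    "FitConvergenceError",
    "FitResult",
    "IdentifiabilityError",
    "fit_dox_hill",
    "fit_hill_dose_response",
    "fit_steady_state_model",
    "pearson_r",
    "CT_THRESHOLD",
    "analyze_plate",
    "clamp_ct",
    "clamp_plate",
    "fold_change",
    "relative_expression",
    "demo_config_path",
    "__version__",
]
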