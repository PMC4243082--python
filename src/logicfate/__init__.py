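"""logicfate: multi-valued logical modelling of DNA-damage cell-fate decision.

A generic engine for Thomas-style multi-valued logical models (components,
rules, asynchronous/synchronous dynamics, stable states and attractors,
perturbations, regulatory-circuit analysis, Monte-Carlo reachability) plus
the bundled G1/S DNA-damage-checkpoint model whose stable states map damage
intensity to proliferation, transient cycle arrest, senescence or
apoptosis.
"""

from importlib import resources

from .core import (
    And,
    Atom,
    Component,
    Condition,
    ExclusivityError,
    LogicalModel,
    ModelError,
    Not,
    Or,
    Rule,
    Violation,
)
from .dynamics import (
    Attractor,
    StateSpaceTooLarge,
    attractors,
    brute_force_stable_states,
    stable_states,
    successors,
)
from .g1s import (
    DAMAGE_CONDITIONS,
    FATE_NODES,
    build_g1s_model,
    fate_of,
    fate_table,
    fate_table_frame,
    wild_type_fate_table,
)
from .circuits import (
    Circuit,
    FunctionalityReport,
    circuit_functionality,
    edge_decisive_contexts,
    enumerate_circuits,
)
from .io import parse_condition, read_model, write_model
from .montecarlo import (
    McConfig,
    McEstimate,
    estimate_probabilities,
    exact_absorption_probabilities,
    simulate_trajectory,
)
from .perturbations import (
    Perturbation,
    ScreenResult,
    apply_perturbation,
    gain_of_function,
    loss_of_function,
    mutant_screen,
    outcome_changes,
)
from .synthetic import RandomModelSpec, random_model, random_state

__version__ = "0.1.0"


def bundled_model_path() -> str:
    """Filesystem path of the bundled G1/S model file."""
    return str(resources.files("logicfate").joinpath("data", "g1s.json"))


__all__ = [
    "And", "Atom", "Component", "Condition", "ExclusivityError",
    "LogicalModel", "ModelError", "Not", "Or", "Rule", "Violation",
    "Attractor", "StateSpaceTooLarge", "attractors",
    "brute_force_stable_states", "stable_states", "successors",
    "DAMAGE_CONDITIONS", "FATE_NODES", "build_g1s_model", "fate_of",
    "fate_table", "fate_table_frame", "wild_type_fate_table",
    "Circuit", "FunctionalityReport", "circuit_functionality",
    "edge_decisive_contexts", "enumerate_circuits",
    "parse_condition", "read_model", "write_model",
    "McConfig", "McEstimate", "estimate_probabilities",
    "exact_absorption_probabilities", "simulate_trajectory",
    "Perturbation", "ScreenResult", "apply_perturbation",
    "gain_of_function", "loss_of_function", "mutant_screen",
    "outcome_changes",
    "RandomModelSpec", "random_model", "random_state",
    "bundled_model_path",
]
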