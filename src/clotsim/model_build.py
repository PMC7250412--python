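"""Assembly of the packaged full model.

The full model is the coagulation-cascade fragment (data) plus the
generated TXA-binding and fibrinolysis reactions.  ``scripts/build_model.py``
writes the result to ``models/full_model.json``, which is what
:func:`default_model` loads; rebuilding with default parameters reproduces
the packaged file exactly.
"""

from __future__ import annotations

from pathlib import Path

from .coagulation import CASCADE_PATH, build_coagulation_reactions, load_cascade_fragment
from .fibrinolysis import ActivationParams, InhibitorParams, build_fibrinolysis_reactions, fibrinolysis_species
from .network import ReactionNetwork, load_network, merge_fragments, require_valid
from .txa import TXABindingParams, binding_species, expand_binding_reactions

FULL_MODEL_PATH = Path(__file__).parent / "models" / "full_model.json"

#: Plasminogen circulates at roughly twice the antiplasmin level; the
#: 2:1 ratio is what lets antiplasmin deplete when activation is fast.
PLASMINOGEN_TOTAL = 2.0e-6


def build_full_model(
    act: ActivationParams | None = None,
    inh: InhibitorParams | None = None,
    txa: TXABindingParams | None = None,
    cascade: ReactionNetwork | None = None,
) -> ReactionNetwork:
    """Assemble the complete coagulation + fibrinolysis + TXA network."""
    act = act or ActivationParams()
    inh = inh or InhibitorParams()
    txa = txa or TXABindingParams()
    cascade = cascade or load_cascade_fragment()

    coag_rxns = build_coagulation_reactions(cascade)
    binding = ReactionNetwork(binding_species(), expand_binding_reactions(txa))
    fibrinolysis = ReactionNetwork(fibrinolysis_species(),
                                   build_fibrinolysis_reactions(act, inh, txa))
    network = merge_fragments(
        cascade, binding, fibrinolysis,
        metadata={
            "name": "coagulation-fibrinolysis-txa",
            "version": "1.0",
            "provenance": "assembled by clotsim.model_build.build_full_model",
        },
    )
    # the cascade fragment owns the coagulation reactions; merge_fragments
    # already concatenated them, so just set the fibrinolytic totals
    assert len(coag_rxns) == len(cascade.reactions)
    network = network.with_overrides({"Pg": PLASMINOGEN_TOTAL})
    return require_valid(network)


def default_model(path: str | Path = FULL_MODEL_PATH) -> ReactionNetwork:
    """Load the packaged physiological model file."""
    return load_network(path)


__all__ = [
    "build_full_model",
    "default_model",
    "FULL_MODEL_PATH",
    "CASCADE_PATH",
    "PLASMINOGEN_TOTAL",
]
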