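"""Regenerate the packaged model files.

Writes ``src/clotsim/models/coagulation_cascade.json`` (the extrinsic
tenase/prothrombinase cascade with stoichiometric inhibitors, rate
constants transcribed from published empirically calibrated ODE models of
TF-initiated thrombin generation) and ``src/clotsim/models/full_model.json``
(cascade + TXA binding + fibrinolysis with default parameters).

Run from the repository root:  python scripts/build_model.py
"""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from clotsim.network import (  # noqa: E402
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    MICHAELIS_MENTEN,
    KineticLaw,
    Reaction,
    ReactionNetwork,
    Species,
    require_valid,
    write_network,
)

NOTE = "extrinsic-cascade rate constant from empirically calibrated thrombin-generation ODE models"


def sp(name: str, value: float, unit: str, *tags: str) -> Species:
    from clotsim.units import to_molar

    return Species(name, to_molar(value, unit), unit, frozenset(tags))


def irr(rid: str, reactants, products, k: float, note: str = NOTE) -> Reaction:
    return Reaction(rid, tuple(reactants), tuple(products),
                    KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": k}), note=note)


def rev(rid: str, reactants, products, kon: float, koff: float, note: str = NOTE) -> Reaction:
    return Reaction(rid, tuple(reactants), tuple(products),
                    KineticLaw(MASS_ACTION_REVERSIBLE, {"kon": kon, "koff": koff}), note=note)


def build_cascade() -> ReactionNetwork:
    species = [
        sp("TF", 5.0, "pM", "cofactor"),
        sp("VII", 10.0, "nM", "zymogen"),
        sp("VIIa", 0.1, "nM", "protease"),
        sp("TF:VII", 0.0, "nM", "complex"),
        sp("TF:VIIa", 0.0, "nM", "complex", "protease"),
        sp("X", 160.0, "nM", "zymogen"),
        sp("Xa", 0.0, "nM", "protease"),
        sp("TF:VIIa:X", 0.0, "nM", "complex"),
        sp("TF:VIIa:Xa", 0.0, "nM", "complex"),
        sp("IX", 90.0, "nM", "zymogen"),
        sp("IXa", 0.0, "nM", "protease"),
        sp("TF:VIIa:IX", 0.0, "nM", "complex"),
        sp("II", 1.4, "uM", "zymogen"),
        sp("IIa", 0.0, "nM", "protease"),
        sp("mIIa", 0.0, "nM", "protease"),
        sp("VIII", 0.7, "nM", "cofactor"),
        sp("VIIIa", 0.0, "nM", "cofactor"),
        sp("IXa:VIIIa", 0.0, "nM", "complex"),
        sp("IXa:VIIIa:X", 0.0, "nM", "complex"),
        sp("VIIIa1L", 0.0, "nM", "cofactor"),
        sp("VIIIa2", 0.0, "nM", "cofactor"),
        sp("V", 20.0, "nM", "cofactor"),
        sp("Va", 0.0, "nM", "cofactor"),
        sp("Xa:Va", 0.0, "nM", "complex"),
        sp("Xa:Va:II", 0.0, "nM", "complex"),
        sp("TFPI", 2.5, "nM", "inhibitor"),
        sp("Xa:TFPI", 0.0, "nM", "complex"),
        sp("TF:VIIa:Xa:TFPI", 0.0, "nM", "complex"),
        sp("ATIII", 3.4, "uM", "inhibitor"),
        sp("Xa:ATIII", 0.0, "nM", "complex"),
        sp("mIIa:ATIII", 0.0, "nM", "complex"),
        sp("IXa:ATIII", 0.0, "nM", "complex"),
        sp("IIa:ATIII", 0.0, "nM", "complex"),
        sp("TF:VIIa:ATIII", 0.0, "nM", "complex"),
        sp("fibrinogen", 9.0, "uM", "zymogen"),
    ]

    r = [
        rev("tf_vii", [("TF", 1), ("VII", 1)], [("TF:VII", 1)], 3.2e6, 3.1e-3),
        rev("tf_viia", [("TF", 1), ("VIIa", 1)], [("TF:VIIa", 1)], 2.3e7, 3.1e-3),
        irr("tfviia_vii", [("TF:VIIa", 1), ("VII", 1)], [("TF:VIIa", 1), ("VIIa", 1)], 4.4e5),
        irr("xa_vii", [("Xa", 1), ("VII", 1)], [("Xa", 1), ("VIIa", 1)], 1.3e7),
        irr("iia_vii", [("IIa", 1), ("VII", 1)], [("IIa", 1), ("VIIa", 1)], 2.3e4),
        rev("tfviia_x", [("TF:VIIa", 1), ("X", 1)], [("TF:VIIa:X", 1)], 2.5e7, 1.05),
        irr("tenase_x", [("TF:VIIa:X", 1)], [("TF:VIIa:Xa", 1)], 6.0),
        rev("tfviia_xa", [("TF:VIIa", 1), ("Xa", 1)], [("TF:VIIa:Xa", 1)], 2.2e7, 19.0),
        rev("tfviia_ix", [("TF:VIIa", 1), ("IX", 1)], [("TF:VIIa:IX", 1)], 1.0e7, 2.4),
        irr("tenase_ix", [("TF:VIIa:IX", 1)], [("TF:VIIa", 1), ("IXa", 1)], 1.8),
        irr("xa_ii", [("Xa", 1), ("II", 1)], [("Xa", 1), ("IIa", 1)], 7.5e3),
        irr("iia_viii", [("IIa", 1), ("VIII", 1)], [("IIa", 1), ("VIIIa", 1)], 2.0e7),
        rev("ixa_viiia", [("IXa", 1), ("VIIIa", 1)], [("IXa:VIIIa", 1)], 1.0e7, 5.0e-3),
        rev("intrinsic_tenase_x", [("IXa:VIIIa", 1), ("X", 1)], [("IXa:VIIIa:X", 1)], 1.0e8, 1.0e-3),
        irr("intrinsic_tenase_cat", [("IXa:VIIIa:X", 1)], [("IXa:VIIIa", 1), ("Xa", 1)], 8.2),
        rev("viiia_decay", [("VIIIa", 1)], [("VIIIa1L", 1), ("VIIIa2", 1)], 6.0e-3, 2.2e4),
        irr("tenase_decay_x", [("IXa:VIIIa:X", 1)],
            [("VIIIa1L", 1), ("VIIIa2", 1), ("X", 1), ("IXa", 1)], 1.0e-3),
        irr("tenase_decay", [("IXa:VIIIa", 1)],
            [("VIIIa1L", 1), ("VIIIa2", 1), ("IXa", 1)], 1.0e-3),
        irr("iia_v", [("IIa", 1), ("V", 1)], [("IIa", 1), ("Va", 1)], 2.0e7),
        rev("prothrombinase", [("Xa", 1), ("Va", 1)], [("Xa:Va", 1)], 4.0e8, 0.2),
        rev("prothrombinase_ii", [("Xa:Va", 1), ("II", 1)], [("Xa:Va:II", 1)], 1.0e8, 103.0),
        irr("miia_generation", [("Xa:Va:II", 1)], [("Xa:Va", 1), ("mIIa", 1)], 63.5),
        irr("miia_activation", [("mIIa", 1), ("Xa:Va", 1)], [("IIa", 1), ("Xa:Va", 1)], 1.5e7),
        rev("xa_tfpi", [("Xa", 1), ("TFPI", 1)], [("Xa:TFPI", 1)], 9.0e5, 3.6e-4),
        rev("tfviiaxa_tfpi", [("TF:VIIa:Xa", 1), ("TFPI", 1)], [("TF:VIIa:Xa:TFPI", 1)],
            3.2e8, 1.1e-4),
        irr("tfviia_xatfpi", [("TF:VIIa", 1), ("Xa:TFPI", 1)], [("TF:VIIa:Xa:TFPI", 1)], 5.0e7),
        irr("xa_atiii", [("Xa", 1), ("ATIII", 1)], [("Xa:ATIII", 1)], 1.5e3),
        irr("miia_atiii", [("mIIa", 1), ("ATIII", 1)], [("mIIa:ATIII", 1)], 7.1e3),
        irr("ixa_atiii", [("IXa", 1), ("ATIII", 1)], [("IXa:ATIII", 1)], 4.9e2),
        irr("iia_atiii", [("IIa", 1), ("ATIII", 1)], [("IIa:ATIII", 1)], 7.1e3),
        irr("tfviia_atiii", [("TF:VIIa", 1), ("ATIII", 1)], [("TF:VIIa:ATIII", 1)], 2.3e2),
        Reaction("fibrin_formation", (("fibrinogen", 1),), (("fibrin", 1),),
                 KineticLaw(MICHAELIS_MENTEN, {"kcat": 59.0, "Km": 3.2e-6}),
                 enzyme="IIa",
                 note="thrombin-catalysed fibrinopeptide release; lumped clot species"),
    ]
    # the fragment references `fibrin`, declared here so it validates standalone
    species.append(sp("fibrin", 0.0, "uM", "clot"))
    return require_valid(ReactionNetwork(species, r, {
        "name": "tf-initiated-cascade",
        "version": "1.0",
        "provenance": "transcribed extrinsic-pathway mechanism; see reaction notes",
    }))


def main() -> None:
    models = ROOT / "src" / "clotsim" / "models"
    models.mkdir(parents=True, exist_ok=True)
    cascade = build_cascade()
    write_network(cascade, models / "coagulation_cascade.json")

    from clotsim.model_build import build_full_model

    full = build_full_model(cascade=cascade)
    write_network(full, models / "full_model.json")
    print(f"wrote {models / 'coagulation_cascade.json'} "
          f"({len(cascade.species)} species, {len(cascade.reactions)} reactions)")
    print(f"wrote {models / 'full_model.json'} "
          f"({len(full.species)} species, {len(full.reactions)} reactions)")


if __name__ == "__main__":
    main()
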