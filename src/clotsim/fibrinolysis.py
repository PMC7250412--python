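"""Plasminogen activation, fibrin degradation and the plasmin-inhibitor system.

Two activation routes: tPA is fibrin-templated (its catalytic efficiency
rises 500-fold with saturating fibrin cofactor) and only reaches variants
with a free y site; uPA works in solution on all four zymogen variants,
3-fold faster when the x site carries TXA.  Plasmin binds fibrin through
its y site and degrades it to inert FDP.

Inhibitor scopes encode the central asymmetry of the model:

* antiplasmin (AP) engages the y site, so it reaches y-free plasmin whether
  in solution or fibrin-bound, but cannot attack TXA-occupied plasmin
  directly - displacement happens through the reversible TXA equilibrium;
* A2M and A1AT are active-site trap/serpin inhibitors: they take any
  solution-phase plasmin (TXA-bound or not) but never fibrin-bound plasmin.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import (
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    MICHAELIS_MENTEN,
    MICHAELIS_MENTEN_MODULATED,
    KineticLaw,
    Reaction,
    Species,
)
from .txa import PLASMINOGEN_SPECIES, TXABindingParams

# re-exported here because flux diagnostics are used throughout the
# interpretation of the fibrinolysis scenarios
from .simulate import instantaneous_fluxes  # noqa: F401


@dataclass(frozen=True)
class ActivationParams:
    """Plasminogen-activation and fibrin-turnover rate constants.

    ``tpa_kcat``/``tpa_Km`` describe tPA acting on y-site-free plasminogen
    in fibrin-free solution; the modulated law multiplies the rate by
    ``1 + (fibrin_efficiency_factor - 1) * F / (F + fibrin_K_half)`` so the
    efficiency gain reaches exactly ``fibrin_efficiency_factor`` at
    saturating fibrin.  ``upa_kcat``/``upa_Km`` apply per zymogen variant,
    with the x-site enhancement taken from :class:`TXABindingParams`.
    Fibrin binding of plasmin and Michaelis-Menten degradation of fibrin by
    the bound enzyme are governed by the ``fibrin_*`` and ``lysis_*``
    constants.
    """

    tpa_kcat: float = 0.01
    tpa_Km: float = 65e-6
    fibrin_efficiency_factor: float = 500.0
    fibrin_K_half: float = 0.2e-6
    upa_kcat: float = 0.7
    upa_Km: float = 20e-6
    fibrin_kon: float = 1e7
    fibrin_koff: float = 60.0
    lysis_kcat: float = 15.0
    lysis_Km: float = 2e-6

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class InhibitorParams:
    """Second-order inactivation rates (M^-1 s^-1), all irreversible.

    ``k_ap_bound_factor`` scales antiplasmin's attack on fibrin-bound
    relative to free plasmin (1.0 = no protection on fibrin).
    """

    k_ap: float = 1e7
    k_a1at: float = 1.5e4
    k_a2m: float = 3e6
    k_pci_upa: float = 300.0
    k_pai_tpa: float = 4.5e7
    k_pai_upa: float = 1e5
    k_ap_bound_factor: float = 0.1

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.k_a1at >= self.k_ap:
            raise ValueError("A1AT must be the slow, weak inhibitor (k_a1at < k_ap)")


@dataclass(frozen=True)
class FibrinState:
    """Snapshot of the clot compartment, all molar."""

    fibrinogen: float
    fibrin: float
    fibrin_bound_plasmin: float
    fdp: float

    @property
    def fibrin_moiety_total(self) -> float:
        # fibrin-monomer equivalents: the bound-plasmin complex holds one
        return self.fibrinogen + self.fibrin + self.fibrin_bound_plasmin + self.fdp


def fibrinolysis_species() -> list[Species]:
    """Species introduced by the fibrinolysis subsystem (physiological
    initial concentrations; activators start at zero and are set per
    scenario)."""
    return [
        Species("tPA", 0.0, "nM", frozenset({"protease"})),
        Species("uPA", 0.0, "nM", frozenset({"protease"})),
        Species("AP", 1.0e-6, "uM", frozenset({"inhibitor"})),
        Species("A1AT", 40.0e-6, "uM", frozenset({"inhibitor"})),
        Species("A2M", 3.0e-6, "uM", frozenset({"inhibitor"})),
        Species("PCI", 90.0e-9, "nM", frozenset({"inhibitor"})),
        Species("PAI", 0.4e-9, "nM", frozenset({"inhibitor"})),
        Species("fibrin", 0.0, "uM", frozenset({"clot"})),
        Species("Pn:fibrin", 0.0, "uM", frozenset({"protease", "complex"})),
        Species("FDP", 0.0, "uM", frozenset({"sink"})),
        Species("AP:Pn", 0.0, "uM", frozenset({"complex"})),
        Species("A1AT:Pn", 0.0, "uM", frozenset({"complex"})),
        Species("A2M:Pn", 0.0, "uM", frozenset({"complex"})),
        Species("PCI:uPA", 0.0, "nM", frozenset({"complex"})),
        Species("PAI:tPA", 0.0, "nM", frozenset({"complex"})),
        Species("PAI:uPA", 0.0, "nM", frozenset({"complex"})),
    ]


def build_fibrinolysis_reactions(
    act: ActivationParams,
    inh: InhibitorParams,
    txa: TXABindingParams,
) -> list[Reaction]:
    """Emit the activation, fibrin-turnover and inhibitor reactions.

    The zymogen variants and their capability flags come from the binding
    scheme; activation of an x-occupied variant releases its TXA (plasmin
    carries only the y site), so total TXA is conserved.
    """
    rxns: list[Reaction] = []

    # (a) tPA activation, fibrin-cofactor modulated, y-free zymogens only
    for name, caps in PLASMINOGEN_SPECIES.items():
        if not caps.tpa_activatable:
            continue
        products = [("Pn", 1)] + ([("TXA", 1)] if caps.x_bound else [])
        rxns.append(Reaction(
            id=f"tpa_act_{name}",
            reactants=((name, 1),),
            products=tuple(products),
            enzyme="tPA",
            modifier="fibrin",
            law=KineticLaw(MICHAELIS_MENTEN_MODULATED, {
                "kcat": act.tpa_kcat,
                "Km": act.tpa_Km,
                "fold": act.fibrin_efficiency_factor,
                "K_half": act.fibrin_K_half,
            }),
            note="fibrin-templated tPA activation; efficiency x fold at saturating fibrin",
        ))

    # (b) uPA activation in solution, all zymogen variants
    for name, caps in PLASMINOGEN_SPECIES.items():
        if not caps.upa_activatable:
            continue
        kcat = act.upa_kcat * (txa.upa_enhancement if caps.x_bound else 1.0)
        plasmin = "Pny" if caps.y_bound else "Pn"
        products = [(plasmin, 1)] + ([("TXA", 1)] if caps.x_bound else [])
        rxns.append(Reaction(
            id=f"upa_act_{name}",
            reactants=((name, 1),),
            products=tuple(products),
            enzyme="uPA",
            law=KineticLaw(MICHAELIS_MENTEN, {"kcat": kcat, "Km": act.upa_Km}),
            note="solution-phase uPA activation"
                 + ("; x-site occupancy enhancement" if caps.x_bound else ""),
        ))

    # (c) plasmin-fibrin binding and degradation to FDP
    rxns.append(Reaction(
        id="pn_fibrin_binding",
        reactants=(("Pn", 1), ("fibrin", 1)),
        products=(("Pn:fibrin", 1),),
        law=KineticLaw(MASS_ACTION_REVERSIBLE, {"kon": act.fibrin_kon, "koff": act.fibrin_koff}),
        note="y-site-mediated plasmin binding to the clot",
    ))
    rxns.append(Reaction(
        id="fibrin_degradation",
        reactants=(("fibrin", 1),),
        products=(("FDP", 1),),
        enzyme="Pn:fibrin",
        law=KineticLaw(MICHAELIS_MENTEN, {"kcat": act.lysis_kcat, "Km": act.lysis_Km}),
        note="clot digestion by fibrin-bound plasmin",
    ))

    # (d) irreversible plasmin inhibitors, per scope
    rxns.append(Reaction(
        id="ap_pn", reactants=(("AP", 1), ("Pn", 1)), products=(("AP:Pn", 1),),
        law=KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": inh.k_ap}),
        note="antiplasmin on free y-free plasmin",
    ))
    rxns.append(Reaction(
        id="ap_pn_fibrin",
        reactants=(("AP", 1), ("Pn:fibrin", 1)),
        products=(("AP:Pn", 1), ("fibrin", 1)),
        law=KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": inh.k_ap * inh.k_ap_bound_factor}),
        note="antiplasmin reaches fibrin-bound plasmin; releases the fibrin unit",
    ))
    for inhibitor, rate in (("A1AT", inh.k_a1at), ("A2M", inh.k_a2m)):
        rxns.append(Reaction(
            id=f"{inhibitor.lower()}_pn",
            reactants=((inhibitor, 1), ("Pn", 1)),
            products=((f"{inhibitor}:Pn", 1),),
            law=KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": rate}),
            note=f"{inhibitor} on solution-phase plasmin",
        ))
        rxns.append(Reaction(
            id=f"{inhibitor.lower()}_pny",
            reactants=((inhibitor, 1), ("Pny", 1)),
            products=((f"{inhibitor}:Pn", 1), ("TXA", 1)),
            law=KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": rate}),
            note=f"{inhibitor} is not y-site-dependent: takes TXA-bound plasmin, freeing TXA",
        ))

    # (e) activator inhibition
    rxns.append(Reaction(
        id="pci_upa", reactants=(("PCI", 1), ("uPA", 1)), products=(("PCI:uPA", 1),),
        law=KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": inh.k_pci_upa}),
        note="protein C inhibitor inactivates urokinase",
    ))
    rxns.append(Reaction(
        id="pai_tpa", reactants=(("PAI", 1), ("tPA", 1)), products=(("PAI:tPA", 1),),
        law=KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": inh.k_pai_tpa}),
        note="PAI-type inhibition; tPA is the preferred target",
    ))
    rxns.append(Reaction(
        id="pai_upa", reactants=(("PAI", 1), ("uPA", 1)), products=(("PAI:uPA", 1),),
        law=KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": inh.k_pai_upa}),
        note="weak PAI-type inhibition of uPA (PCI is uPA's main inhibitor)",
    ))
    return rxns
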