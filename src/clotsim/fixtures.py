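"""Programmatic test fixtures with closed-form solutions.

Each fixture kind builds a tiny validated network and, where a closed form
exists, an analytic evaluator mapping a time array to exact concentrations.
The evaluators are independent of the ODE engine, so simulator agreement
is a real oracle check, not a self-comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.special import lambertw

from .network import (
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    MICHAELIS_MENTEN,
    KineticLaw,
    Reaction,
    ReactionNetwork,
    Species,
    require_valid,
)
from .txa import TXABindingParams, binding_species, expand_binding_reactions

AnalyticSolution = Callable[[np.ndarray], dict[str, np.ndarray]]

KINDS = ("irreversible_decay", "reversible_binding", "mm_enzyme",
         "open_chain", "full_model_subset")


@dataclass(frozen=True)
class FixtureSpec:
    """A fixture kind plus its rate constants and initial concentrations."""

    kind: str
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        object.__setattr__(self, "parameters", dict(self.parameters))


def make_fixture(spec: FixtureSpec) -> tuple[ReactionNetwork, AnalyticSolution | None]:
    """Build the network for *spec*; analytic evaluator where available."""
    builder = {
        "irreversible_decay": _irreversible_decay,
        "reversible_binding": _reversible_binding,
        "mm_enzyme": _mm_enzyme,
        "open_chain": _open_chain,
        "full_model_subset": _full_model_subset,
    }[spec.kind]
    network, analytic = builder(dict(spec.parameters))
    return require_valid(network), analytic


def _irreversible_decay(p: dict) -> tuple[ReactionNetwork, AnalyticSolution]:
    k = p.get("k", 0.01)
    A0 = p.get("A0", 1e-6)
    network = ReactionNetwork(
        [Species("A", A0, "uM"), Species("B", 0.0, "uM")],
        [Reaction("decay", (("A", 1),), (("B", 1),),
                  KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": k}))],
        {"name": "irreversible_decay"},
    )

    def analytic(t: np.ndarray) -> dict[str, np.ndarray]:
        t = np.asarray(t, dtype=float)
        a = A0 * np.exp(-k * t)
        return {"A": a, "B": A0 - a}

    return network, analytic


def _reversible_binding(p: dict) -> tuple[ReactionNetwork, AnalyticSolution]:
    kon = p.get("kon", 1e6)
    koff = p.get("koff", 1.0)
    A0 = p.get("A0", 2e-6)
    B0 = p.get("B0", 2e-6)
    C0 = p.get("C0", 0.0)
    network = ReactionNetwork(
        [Species("A", A0, "uM"), Species("B", B0, "uM"), Species("C", C0, "uM")],
        [Reaction("binding", (("A", 1), ("B", 1)), (("C", 1),),
                  KineticLaw(MASS_ACTION_REVERSIBLE, {"kon": kon, "koff": koff}))],
        {"name": "reversible_binding"},
    )

    # dc/dt = kon (TA - c)(TB - c) - koff c with totals TA, TB; the complex
    # relaxes between the roots of the equilibrium quadratic.
    TA, TB = A0 + C0, B0 + C0
    Kd = koff / kon
    b = TA + TB + Kd
    disc = np.sqrt(b * b - 4 * TA * TB)
    r1 = (b - disc) / 2.0  # stable equilibrium (r1 <= min(TA, TB))
    r2 = (b + disc) / 2.0

    def analytic(t: np.ndarray) -> dict[str, np.ndarray]:
        t = np.asarray(t, dtype=float)
        gamma = (C0 - r1) / (C0 - r2)
        E = gamma * np.exp(-kon * (r2 - r1) * t)
        c = (r1 - r2 * E) / (1.0 - E)
        return {"A": TA - c, "B": TB - c, "C": c}

    return network, analytic


def _mm_enzyme(p: dict) -> tuple[ReactionNetwork, AnalyticSolution]:
    kcat = p.get("kcat", 1.0)
    Km = p.get("Km", 1e-6)
    E0 = p.get("E0", 1e-9)
    S0 = p.get("S0", 10e-6)
    network = ReactionNetwork(
        [Species("E", E0, "nM"), Species("S", S0, "uM"), Species("P", 0.0, "uM")],
        [Reaction("mm", (("S", 1),), (("P", 1),),
                  KineticLaw(MICHAELIS_MENTEN, {"kcat": kcat, "Km": Km}), enzyme="E")],
        {"name": "mm_enzyme"},
    )

    # Integrated Michaelis-Menten (enzyme is not consumed, so this is exact
    # for the implemented rate law): S(t) = Km * W((S0/Km) exp((S0 - Vt)/Km))
    def analytic(t: np.ndarray) -> dict[str, np.ndarray]:
        t = np.asarray(t, dtype=float)
        u = np.log(S0 / Km) + (S0 - kcat * E0 * t) / Km
        s = Km * _lambertw_of_exp(u)
        return {"E": np.full_like(s, E0), "S": s, "P": S0 - s}

    return network, analytic


def _lambertw_of_exp(u: np.ndarray) -> np.ndarray:
    """Principal-branch W(exp(u)), stable for large positive u."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u < 500
    out[small] = np.real(lambertw(np.exp(u[small])))
    if np.any(~small):
        w = u[~small] - np.log(u[~small])
        for _ in range(6):  # Newton on w + log(w) = u
            w = w - (w + np.log(w) - u[~small]) / (1 + 1 / w)
        out[~small] = w
    return out


def _open_chain(p: dict) -> tuple[ReactionNetwork, AnalyticSolution]:
    k1 = p.get("k1", 0.02)
    k2 = p.get("k2", 0.005)
    A0 = p.get("A0", 1e-6)
    network = ReactionNetwork(
        [Species("A", A0, "uM"), Species("B", 0.0, "uM"), Species("C", 0.0, "uM")],
        [Reaction("step1", (("A", 1),), (("B", 1),),
                  KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": k1})),
         Reaction("step2", (("B", 1),), (("C", 1),),
                  KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": k2}))],
        {"name": "open_chain"},
    )

    def analytic(t: np.ndarray) -> dict[str, np.ndarray]:
        t = np.asarray(t, dtype=float)
        a = A0 * np.exp(-k1 * t)
        if abs(k1 - k2) < 1e-12 * max(k1, k2):
            b = A0 * k1 * t * np.exp(-k1 * t)
        else:
            b = A0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
        return {"A": a, "B": b, "C": A0 - a - b}

    return network, analytic


def _full_model_subset(p: dict) -> tuple[ReactionNetwork, None]:
    """TXA-binding-only subsystem: the two-site scheme with clamped totals."""
    params = TXABindingParams(
        kon_x=p.get("kon_x", 1e6), kon_y=p.get("kon_y", 1e6),
        Kd_x=p.get("Kd_x", 600e-6), Kd_y=p.get("Kd_y", 1.1e-6),
    )
    species = binding_species()
    network = ReactionNetwork(list(species), expand_binding_reactions(params),
                              {"name": "txa_binding_subsystem"})
    network = network.with_overrides({
        "Pg": p.get("Pg0", 2e-6),
        "TXA": p.get("TXA0", 10e-6),
        "Pn": p.get("Pn0", 0.0),
    })
    return network, None
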