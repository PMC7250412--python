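"""Two-site TXA-plasmin(ogen) binding scheme.

Plasminogen carries two independent TXA binding sites: the low-affinity
``x`` site (Kd 600 uM) whose occupancy speeds uPA-mediated activation
3-fold, and the high-affinity ``y`` site (Kd 1.1 uM) through which
plasmin(ogen) binds fibrin and is attacked by antiplasmin.  Site occupancy
expands the zymogen into four variants (Pg, Pgx, Pgy, Pgxy) and plasmin
into two (Pn, Pny); the x site is dropped on activation since its only
effect is on zymogen activation.

On-rates are not outcome-relevant (binding is fast relative to lysis); the
defaults make all binding equilibrium-controlled and the test suite checks
that rescaling them with fixed Kd leaves results unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import MASS_ACTION_REVERSIBLE, KineticLaw, Reaction, Species

#: Zymogen variants by (x occupied, y occupied).
PG_VARIANTS = ("Pg", "Pgx", "Pgy", "Pgxy")
PN_VARIANTS = ("Pn", "Pny")


@dataclass(frozen=True)
class VariantCapabilities:
    """What a plasmin(ogen) variant can do, fixed by its site occupancy."""

    x_bound: bool
    y_bound: bool
    zymogen: bool

    @property
    def tpa_activatable(self) -> bool:
        # tPA works on the fibrin surface: requires a free y site, zymogen only.
        return self.zymogen and not self.y_bound

    @property
    def upa_activatable(self) -> bool:
        return self.zymogen

    @property
    def fibrin_binding(self) -> bool:
        return not self.y_bound


#: Capability table for every plasmin(ogen) species in the model.
PLASMINOGEN_SPECIES: dict[str, VariantCapabilities] = {
    "Pg": VariantCapabilities(x_bound=False, y_bound=False, zymogen=True),
    "Pgx": VariantCapabilities(x_bound=True, y_bound=False, zymogen=True),
    "Pgy": VariantCapabilities(x_bound=False, y_bound=True, zymogen=True),
    "Pgxy": VariantCapabilities(x_bound=True, y_bound=True, zymogen=True),
    "Pn": VariantCapabilities(x_bound=False, y_bound=False, zymogen=False),
    "Pny": VariantCapabilities(x_bound=False, y_bound=True, zymogen=False),
}


@dataclass(frozen=True)
class TXABindingParams:
    """Equilibrium and rate constants of the two TXA sites.

    ``Kd_x``/``Kd_y`` are dissociation constants in molar; ``kon_x``/
    ``kon_y`` association rates in M^-1 s^-1 (off-rates follow from
    koff = Kd * kon); ``upa_enhancement`` is the fold-increase of
    uPA-mediated activation when the x site is occupied.
    """

    Kd_x: float = 600e-6
    Kd_y: float = 1.1e-6
    kon_x: float = 1e6
    kon_y: float = 1e6
    upa_enhancement: float = 3.0

    def __post_init__(self) -> None:
        for name in ("Kd_x", "Kd_y", "kon_x", "kon_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.upa_enhancement <= 1:
            raise ValueError("upa_enhancement must exceed 1")

    @property
    def koff_x(self) -> float:
        return self.Kd_x * self.kon_x

    @property
    def koff_y(self) -> float:
        return self.Kd_y * self.kon_y

    def with_kon_scaled(self, factor: float) -> "TXABindingParams":
        """Rescale both on-rates, holding the dissociation constants fixed."""
        return TXABindingParams(
            Kd_x=self.Kd_x,
            Kd_y=self.Kd_y,
            kon_x=self.kon_x * factor,
            kon_y=self.kon_y * factor,
            upa_enhancement=self.upa_enhancement,
        )


def binding_species(params_unused: TXABindingParams | None = None) -> list[Species]:
    """Species records introduced by the binding scheme (all start at zero
    except totals set elsewhere)."""
    tags = {
        "TXA": frozenset({"ligand"}),
        "Pg": frozenset({"zymogen"}),
        "Pgx": frozenset({"zymogen", "complex"}),
        "Pgy": frozenset({"zymogen", "complex"}),
        "Pgxy": frozenset({"zymogen", "complex"}),
        "Pn": frozenset({"protease"}),
        "Pny": frozenset({"protease", "complex"}),
    }
    return [Species(name, 0.0, "uM", tags[name]) for name in
            ("TXA", "Pg", "Pgx", "Pgy", "Pgxy", "Pn", "Pny")]


def expand_binding_reactions(params: TXABindingParams) -> list[Reaction]:
    """Reversible mass-action TXA binding at each free site of each variant.

    Five reversible pairs: x and y binding on Pg, the complementary site on
    Pgx and Pgy, and y binding on plasmin.  Site affinities are independent
    of the other site's occupancy (no cooperativity), so koff = Kd * kon
    holds per site in every context.
    """
    def rev(rid: str, free: str, bound: str, kon: float, koff: float, site: str) -> Reaction:
        return Reaction(
            id=rid,
            reactants=((free, 1), ("TXA", 1)),
            products=((bound, 1),),
            law=KineticLaw(MASS_ACTION_REVERSIBLE, {"kon": kon, "koff": koff}),
            note=f"TXA {site}-site binding, Kd = koff/kon",
        )

    p = params
    return [
        rev("txa_x_Pg", "Pg", "Pgx", p.kon_x, p.koff_x, "x"),
        rev("txa_y_Pg", "Pg", "Pgy", p.kon_y, p.koff_y, "y"),
        rev("txa_y_Pgx", "Pgx", "Pgxy", p.kon_y, p.koff_y, "y"),
        rev("txa_x_Pgy", "Pgy", "Pgxy", p.kon_x, p.koff_x, "x"),
        rev("txa_y_Pn", "Pn", "Pny", p.kon_y, p.koff_y, "y"),
    ]


def equilibrium_occupancy(Kd: float, ligand: float) -> float:
    """Single-site equilibrium occupancy ligand / (ligand + Kd).

    ``ligand`` is the free (clamped) ligand concentration in molar.
    """
    if Kd <= 0:
        raise ValueError("Kd must be strictly positive")
    if ligand < 0:
        raise ValueError("ligand concentration must be non-negative")
    return ligand / (ligand + Kd)


def equilibrium_partition(
    total_pg: float, txa_free: float, params: TXABindingParams
) -> dict[str, float]:
    """Independent-sites equilibrium split of plasminogen over its variants.

    Returns concentrations (molar) for Pg, Pgx, Pgy, Pgxy given a clamped
    free TXA concentration; fractions are products of the single-site
    occupancies and sum to one.
    """
    if total_pg < 0 or txa_free < 0:
        raise ValueError("concentrations must be non-negative")
    occ_x = equilibrium_occupancy(params.Kd_x, txa_free)
    occ_y = equilibrium_occupancy(params.Kd_y, txa_free)
    return {
        "Pg": total_pg * (1 - occ_x) * (1 - occ_y),
        "Pgx": total_pg * occ_x * (1 - occ_y),
        "Pgy": total_pg * (1 - occ_x) * occ_y,
        "Pgxy": total_pg * occ_x * occ_y,
    }
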