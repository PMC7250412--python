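"""Reaction-network data model, JSON I/O, validation and moiety analysis.

A :class:`ReactionNetwork` is a plain container of :class:`Species` and
:class:`Reaction` records.  The engine has no hard-coded biology: everything
it integrates comes from these records, which are serialisable to a single
human-diffable JSON document (see ``models/schema.json``).

Internally every concentration is molar and every time constant is in
seconds; display units are converted at the I/O boundary only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .units import UNIT_TO_MOLAR, from_molar, to_molar

SCHEMA_VERSION = 1

MASS_ACTION_IRREVERSIBLE = "mass_action_irreversible"
MASS_ACTION_REVERSIBLE = "mass_action_reversible"
MICHAELIS_MENTEN = "michaelis_menten"
MICHAELIS_MENTEN_MODULATED = "michaelis_menten_modulated"

#: Exact parameter set required by each kinetic-law kind.
LAW_PARAMS: dict[str, frozenset[str]] = {
    MASS_ACTION_IRREVERSIBLE: frozenset({"k"}),
    MASS_ACTION_REVERSIBLE: frozenset({"kon", "koff"}),
    MICHAELIS_MENTEN: frozenset({"kcat", "Km"}),
    MICHAELIS_MENTEN_MODULATED: frozenset({"kcat", "Km", "fold", "K_half"}),
}


class NetworkParseError(ValueError):
    """Raised when a model file does not conform to the schema."""


class NetworkValidationError(ValueError):
    """Raised when a structurally parseable network violates an invariant."""


@dataclass(frozen=True)
class Species:
    """A named chemical entity with an initial concentration in molar."""

    name: str
    initial_concentration: float  # molar
    display_unit: str = "nM"
    tags: frozenset[str] = field(default_factory=frozenset)

    def display_value(self) -> float:
        return from_molar(self.initial_concentration, self.display_unit)


@dataclass(frozen=True)
class KineticLaw:
    """A rate law: one of the registered kinds plus its parameter map.

    Parameter units are s^-1 or M^-1 s^-1 for mass action (depending on
    order), ``kcat`` s^-1 and ``Km`` M for Michaelis-Menten, and for the
    modulated variant additionally a dimensionless ``fold`` ceiling with a
    half-saturation constant ``K_half`` (M) for the modifier species.
    """

    kind: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))


@dataclass(frozen=True)
class Reaction:
    """Stoichiometry plus kinetic law.

    ``reactants`` and ``products`` are multisets encoded as tuples of
    ``(species_name, stoichiometric_coefficient)``.  ``enzyme`` is required
    for Michaelis-Menten kinds (the enzyme is not consumed), ``modifier``
    for the modulated kind (the saturating cofactor species).  ``note`` is
    free-text provenance.
    """

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    law: KineticLaw
    enzyme: str | None = None
    modifier: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple((s, int(n)) for s, n in self.reactants))
        object.__setattr__(self, "products", tuple((s, int(n)) for s, n in self.products))

    def net_stoichiometry(self) -> dict[str, int]:
        """Net change per firing, products minus reactants."""
        net: dict[str, int] = {}
        for name, n in self.reactants:
            net[name] = net.get(name, 0) - n
        for name, n in self.products:
            net[name] = net.get(name, 0) + n
        return {k: v for k, v in net.items() if v != 0}


@dataclass(frozen=True)
class Violation:
    """A single invariant violation; ``where`` names the offending record."""

    where: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.where}: {self.message}"


@dataclass
class ReactionNetwork:
    """An ordered collection of species and reactions plus metadata."""

    species: list[Species]
    reactions: list[Reaction]
    metadata: dict = field(default_factory=dict)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def initial_state(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """Initial concentration vector (molar), optionally overridden."""
        y0 = np.array([s.initial_concentration for s in self.species], dtype=float)
        if overrides:
            idx = self.species_index()
            for name, value in overrides.items():
                if name not in idx:
                    raise KeyError(f"override references unknown species {name!r}")
                if value < 0:
                    raise ValueError(f"override for {name!r} is negative")
                y0[idx[name]] = float(value)
        return y0

    def with_overrides(self, overrides: Mapping[str, float]) -> "ReactionNetwork":
        """Copy of the network with initial concentrations replaced (molar)."""
        y0 = self.initial_state(overrides)
        species = [replace(s, initial_concentration=float(c)) for s, c in zip(self.species, y0)]
        return ReactionNetwork(species, list(self.reactions), dict(self.metadata))

    def stoichiometric_matrix(self) -> np.ndarray:
        """Integer matrix S with S[i, j] = net change of species i in reaction j."""
        idx = self.species_index()
        S = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for name, n in rxn.net_stoichiometry().items():
                S[idx[name], j] = n
        return S


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(network: ReactionNetwork) -> list[Violation]:
    """Return every invariant violation; an empty list means the network is valid."""
    out: list[Violation] = []
    seen: set[str] = set()
    for sp in network.species:
        if sp.name in seen:
            out.append(Violation(sp.name, "duplicate species name"))
        seen.add(sp.name)
        if not np.isfinite(sp.initial_concentration) or sp.initial_concentration < 0:
            out.append(Violation(sp.name, f"initial concentration {sp.initial_concentration} is not >= 0"))
        if sp.display_unit not in UNIT_TO_MOLAR:
            out.append(Violation(sp.name, f"unknown display unit {sp.display_unit!r}"))

    names = {s.name for s in network.species}
    rids: set[str] = set()
    for rxn in network.reactions:
        if rxn.id in rids:
            out.append(Violation(rxn.id, "duplicate reaction id"))
        rids.add(rxn.id)
        for side, pairs in (("reactant", rxn.reactants), ("product", rxn.products)):
            for name, n in pairs:
                if name not in names:
                    out.append(Violation(rxn.id, f"{side} references undeclared species {name!r}"))
                if not isinstance(n, int) or n < 1:
                    out.append(Violation(rxn.id, f"stoichiometric coefficient {n!r} for {name!r} is not a positive integer"))
        law = rxn.law
        if law.kind not in LAW_PARAMS:
            out.append(Violation(rxn.id, f"unknown law kind {law.kind!r}"))
            continue
        expected = LAW_PARAMS[law.kind]
        got = set(law.params)
        if got != expected:
            out.append(Violation(rxn.id, f"law {law.kind} requires parameters {sorted(expected)}, got {sorted(got)}"))
        for pname, value in law.params.items():
            if not np.isfinite(value) or value <= 0:
                out.append(Violation(rxn.id, f"parameter {pname} = {value} is not strictly positive"))
        if law.kind in (MICHAELIS_MENTEN, MICHAELIS_MENTEN_MODULATED):
            total_substrate = sum(n for _, n in rxn.reactants)
            if total_substrate != 1:
                out.append(Violation(rxn.id, "Michaelis-Menten reaction must have exactly one substrate"))
            if rxn.enzyme is None:
                out.append(Violation(rxn.id, "Michaelis-Menten reaction requires an enzyme"))
            elif rxn.enzyme not in names:
                out.append(Violation(rxn.id, f"enzyme references undeclared species {rxn.enzyme!r}"))
        else:
            if rxn.enzyme is not None:
                out.append(Violation(rxn.id, "enzyme is only meaningful for Michaelis-Menten laws"))
        if law.kind == MICHAELIS_MENTEN_MODULATED:
            if rxn.modifier is None:
                out.append(Violation(rxn.id, "modulated law requires a modifier species"))
            elif rxn.modifier not in names:
                out.append(Violation(rxn.id, f"modifier references undeclared species {rxn.modifier!r}"))
        elif rxn.modifier is not None:
            out.append(Violation(rxn.id, "modifier is only meaningful for the modulated law"))
    return out


def require_valid(network: ReactionNetwork) -> ReactionNetwork:
    violations = validate(network)
    if violations:
        msg = "; ".join(str(v) for v in violations[:10])
        raise NetworkValidationError(f"{len(violations)} violation(s): {msg}")
    return network


# ---------------------------------------------------------------------------
# Conserved moieties
# ---------------------------------------------------------------------------

def conserved_moieties(network: ReactionNetwork) -> list[dict[str, int]]:
    """Integer conservation laws of the network.

    Each returned law ``L`` maps species names to integer coefficients such
    that for every reaction the weighted net stoichiometric change is zero,
    i.e. ``L . S == 0`` exactly.  Computed via the exact rational null space
    of the transposed stoichiometric matrix, scaled to primitive integer
    vectors with a positive leading coefficient.
    """
    import sympy

    S = network.stoichiometric_matrix()
    names = network.species_names
    if S.size == 0:
        return [{name: 1} for name in names]
    M = sympy.Matrix(S.T.tolist())
    laws: list[dict[str, int]] = []
    for vec in M.nullspace():
        rationals = [sympy.Rational(v) for v in vec]
        fracs = [Fraction(int(r.p), int(r.q)) for r in rationals]
        denom = 1
        for f in fracs:
            denom = denom * f.denominator // _gcd(denom, f.denominator)
        ints = [int(f * denom) for f in fracs]
        g = 0
        for v in ints:
            g = _gcd(g, abs(v))
        if g > 1:
            ints = [v // g for v in ints]
        lead = next((v for v in ints if v != 0), 1)
        if lead < 0:
            ints = [-v for v in ints]
        laws.append({name: c for name, c in zip(names, ints) if c != 0})
    return laws


def _gcd(a: int, b: int) -> int:
    while b:
        a, b = b, a % b
    return a


def is_conserved(network: ReactionNetwork, coefficients: Mapping[str, int]) -> bool:
    """Exact integer check that *coefficients* is a conservation law."""
    idx = network.species_index()
    L = np.zeros(len(network.species), dtype=np.int64)
    for name, c in coefficients.items():
        L[idx[name]] = c
    return bool(np.all(L @ network.stoichiometric_matrix() == 0))


def in_conserved_span(network: ReactionNetwork, coefficients: Mapping[str, int]) -> bool:
    """True iff *coefficients* lies in the span of the computed moiety basis."""
    import sympy

    basis = conserved_moieties(network)
    idx = network.species_index()

    def vec(law: Mapping[str, int]) -> list[int]:
        v = [0] * len(network.species)
        for name, c in law.items():
            v[idx[name]] = c
        return v

    B = sympy.Matrix([vec(law) for law in basis])
    target = sympy.Matrix([vec(coefficients)])
    return B.rank() == B.col_join(target).rank()


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

def _species_to_record(sp: Species) -> dict:
    return {
        "name": sp.name,
        "initial_concentration": sp.display_value(),
        "unit": sp.display_unit,
        "tags": sorted(sp.tags),
    }


def _reaction_to_record(rxn: Reaction) -> dict:
    rec: dict = {
        "id": rxn.id,
        "reactants": [{"species": s, "stoich": n} for s, n in rxn.reactants],
        "products": [{"species": s, "stoich": n} for s, n in rxn.products],
        "law": {"kind": rxn.law.kind, "params": dict(rxn.law.params)},
    }
    if rxn.enzyme is not None:
        rec["enzyme"] = rxn.enzyme
    if rxn.modifier is not None:
        rec["modifier"] = rxn.modifier
    if rxn.note:
        rec["note"] = rxn.note
    return rec


def network_to_dict(network: ReactionNetwork) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "metadata": dict(network.metadata),
        "species": [_species_to_record(s) for s in network.species],
        "reactions": [_reaction_to_record(r) for r in network.reactions],
    }


def write_network(network: ReactionNetwork, path: str | Path) -> None:
    """Write the network to a schema-conforming JSON document."""
    Path(path).write_text(json.dumps(network_to_dict(network), indent=1) + "\n")


def _parse_species(rec: dict, where: str) -> Species:
    for key in ("name", "initial_concentration", "unit"):
        if key not in rec:
            raise NetworkParseError(f"{where}: missing field {key!r}")
    try:
        conc = to_molar(float(rec["initial_concentration"]), rec["unit"])
    except (TypeError, ValueError) as exc:
        raise NetworkParseError(f"{where} ({rec.get('name')}): {exc}") from None
    return Species(
        name=str(rec["name"]),
        initial_concentration=conc,
        display_unit=rec["unit"],
        tags=frozenset(rec.get("tags", ())),
    )


def _parse_side(items, where: str) -> tuple[tuple[str, int], ...]:
    out = []
    for item in items:
        if "species" not in item or "stoich" not in item:
            raise NetworkParseError(f"{where}: reactant/product records need 'species' and 'stoich'")
        out.append((str(item["species"]), int(item["stoich"])))
    return tuple(out)


def _parse_reaction(rec: dict, where: str) -> Reaction:
    for key in ("id", "reactants", "products", "law"):
        if key not in rec:
            raise NetworkParseError(f"{where}: missing field {key!r}")
    law = rec["law"]
    if "kind" not in law or "params" not in law:
        raise NetworkParseError(f"{where} ({rec['id']}): law needs 'kind' and 'params'")
    return Reaction(
        id=str(rec["id"]),
        reactants=_parse_side(rec["reactants"], where),
        products=_parse_side(rec["products"], where),
        law=KineticLaw(str(law["kind"]), {k: float(v) for k, v in law["params"].items()}),
        enzyme=rec.get("enzyme"),
        modifier=rec.get("modifier"),
        note=rec.get("note", ""),
    )


def network_from_dict(doc: dict) -> ReactionNetwork:
    if not isinstance(doc, dict) or "species" not in doc or "reactions" not in doc:
        raise NetworkParseError("model document must contain 'species' and 'reactions' arrays")
    species = [_parse_species(rec, f"species[{i}]") for i, rec in enumerate(doc["species"])]
    reactions = [_parse_reaction(rec, f"reactions[{i}]") for i, rec in enumerate(doc["reactions"])]
    return ReactionNetwork(species, reactions, dict(doc.get("metadata", {})))


def load_network(path: str | Path) -> ReactionNetwork:
    """Load and validate a model file; concentrations are converted to molar."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise NetworkParseError(f"{path}: not valid JSON ({exc})") from None
    network = network_from_dict(doc)
    return require_valid(network)


def merge_fragments(*fragments: Iterable[ReactionNetwork], metadata: dict | None = None) -> ReactionNetwork:
    """Concatenate networks, keeping the first definition of each species."""
    species: list[Species] = []
    seen: set[str] = set()
    reactions: list[Reaction] = []
    for frag in fragments:
        for sp in frag.species:
            if sp.name not in seen:
                species.append(sp)
                seen.add(sp.name)
        reactions.extend(frag.reactions)
    return ReactionNetwork(species, reactions, metadata or {})
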