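"""Stiff ODE integration of a reaction network.

The network is compiled once into flat index arrays so the right-hand side
is a handful of vectorised numpy operations; the concentration span
(pM..mM) and timescale span (ms..hours) of the full model make an implicit
BDF solver mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import (
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    MICHAELIS_MENTEN,
    MICHAELIS_MENTEN_MODULATED,
    ReactionNetwork,
    require_valid,
)

_MAX_ORDER = 3  # supported total reactant stoichiometry per mass-action side


class SolverFailure(RuntimeError):
    """Integration failed; carries the last accepted state and time."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


@dataclass(frozen=True)
class SolverSettings:
    """Integration horizon, output grid and tolerances."""

    t_end: float = 7200.0
    output_points: int = 600
    output_times: Sequence[float] | None = None
    rtol: float = 1e-8
    atol: float = 1e-14
    max_step: float = np.inf
    #: negatives larger (in magnitude) than this many atol are a failure
    negative_tolerance_factor: float = 1e6

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")

    def grid(self) -> np.ndarray:
        if self.output_times is not None:
            t = np.asarray(self.output_times, dtype=float)
            if t.ndim != 1 or np.any(np.diff(t) <= 0):
                raise ValueError("output_times must be strictly increasing")
            return t
        return np.linspace(0.0, self.t_end, int(self.output_points))

    def refined(self, factor: float = 0.5) -> "SolverSettings":
        return SolverSettings(
            t_end=self.t_end, output_points=self.output_points,
            output_times=self.output_times, rtol=self.rtol * factor,
            atol=self.atol * factor, max_step=self.max_step,
            negative_tolerance_factor=self.negative_tolerance_factor,
        )


@dataclass
class TimeCourse:
    """Simulation output: time grid x species concentrations (molar)."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (len(times), n_species)
    species_order: list[str]
    scenario_provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {name: i for i, name in enumerate(self.species_order)}

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[:, self._index[species]]

    def __contains__(self, species: str) -> bool:
        return species in self._index

    def final(self, species: str) -> float:
        return float(self[species][-1])

    def to_frame(self):
        """Wide pandas DataFrame, one column per species, index = time (s)."""
        import pandas as pd

        return pd.DataFrame(self.concentrations, index=pd.Index(self.times, name="time_s"),
                            columns=self.species_order)

    def to_tidy(self):
        """Tidy DataFrame with columns (time_s, species, concentration_M)."""
        frame = self.to_frame().reset_index().melt(
            id_vars="time_s", var_name="species", value_name="concentration_M")
        return frame

    def write_csv(self, path: str | Path, tidy: bool = False) -> None:
        import json

        frame = self.to_tidy() if tidy else self.to_frame().reset_index()
        frame.to_csv(path, index=False)
        if self.scenario_provenance:
            sidecar = Path(path).with_suffix(Path(path).suffix + ".provenance.json")
            sidecar.write_text(json.dumps(self.scenario_provenance, indent=1, default=str))


@dataclass
class _Compiled:
    """Flat arrays driving the vectorised flux evaluation."""

    n_species: int
    kind: np.ndarray            # per-reaction law-kind code
    # mass action: up to _MAX_ORDER factor slots per direction, the dummy
    # index n_species points at a constant 1.0 slot
    fwd_idx: np.ndarray         # (R, _MAX_ORDER)
    rev_idx: np.ndarray
    k_fwd: np.ndarray
    k_rev: np.ndarray
    # Michaelis-Menten slots
    enzyme_idx: np.ndarray
    substrate_idx: np.ndarray
    kcat: np.ndarray
    Km: np.ndarray
    modifier_idx: np.ndarray
    fold: np.ndarray
    K_half: np.ndarray
    is_mass_action: np.ndarray
    is_reversible: np.ndarray
    is_mm: np.ndarray
    is_modulated: np.ndarray
    N: np.ndarray               # (n_species, R) net stoichiometry


def _compile(network: ReactionNetwork) -> _Compiled:
    idx = network.species_index()
    n = len(network.species)
    R = len(network.reactions)
    dummy = n

    fwd_idx = np.full((R, _MAX_ORDER), dummy, dtype=np.intp)
    rev_idx = np.full((R, _MAX_ORDER), dummy, dtype=np.intp)
    k_fwd = np.zeros(R)
    k_rev = np.zeros(R)
    enzyme_idx = np.full(R, dummy, dtype=np.intp)
    substrate_idx = np.full(R, dummy, dtype=np.intp)
    modifier_idx = np.full(R, dummy, dtype=np.intp)
    kcat = np.zeros(R)
    Km = np.ones(R)
    fold = np.ones(R)
    K_half = np.ones(R)
    kind = np.zeros(R, dtype=np.intp)

    def fill(slots: np.ndarray, j: int, pairs) -> None:
        pos = 0
        for name, count in pairs:
            for _ in range(count):
                if pos >= _MAX_ORDER:
                    raise ValueError(
                        f"reaction {network.reactions[j].id}: total stoichiometry above "
                        f"{_MAX_ORDER} is not supported")
                slots[j, pos] = idx[name]
                pos += 1

    for j, rxn in enumerate(network.reactions):
        law = rxn.law
        if law.kind == MASS_ACTION_IRREVERSIBLE:
            kind[j] = 0
            k_fwd[j] = law.params["k"]
            fill(fwd_idx, j, rxn.reactants)
        elif law.kind == MASS_ACTION_REVERSIBLE:
            kind[j] = 1
            k_fwd[j] = law.params["kon"]
            k_rev[j] = law.params["koff"]
            fill(fwd_idx, j, rxn.reactants)
            fill(rev_idx, j, rxn.products)
        elif law.kind in (MICHAELIS_MENTEN, MICHAELIS_MENTEN_MODULATED):
            kind[j] = 2 if law.kind == MICHAELIS_MENTEN else 3
            kcat[j] = law.params["kcat"]
            Km[j] = law.params["Km"]
            enzyme_idx[j] = idx[rxn.enzyme]
            substrate_idx[j] = idx[rxn.reactants[0][0]]
            if kind[j] == 3:
                fold[j] = law.params["fold"]
                K_half[j] = law.params["K_half"]
                modifier_idx[j] = idx[rxn.modifier]
        else:  # pragma: no cover - rejected by validation
            raise ValueError(f"unknown law kind {law.kind!r}")

    return _Compiled(
        n_species=n, kind=kind,
        fwd_idx=fwd_idx, rev_idx=rev_idx, k_fwd=k_fwd, k_rev=k_rev,
        enzyme_idx=enzyme_idx, substrate_idx=substrate_idx, kcat=kcat, Km=Km,
        modifier_idx=modifier_idx, fold=fold, K_half=K_half,
        is_mass_action=(kind == 0), is_reversible=(kind == 1),
        is_mm=(kind == 2), is_modulated=(kind == 3),
        N=network.stoichiometric_matrix().astype(float),
    )


def _fluxes(c: _Compiled, y: np.ndarray) -> np.ndarray:
    y_aug = np.append(y, 1.0)
    fwd = y_aug[c.fwd_idx].prod(axis=1)
    flux = c.k_fwd * fwd
    if c.is_reversible.any():
        rev = y_aug[c.rev_idx].prod(axis=1)
        flux = flux - c.is_reversible * c.k_rev * rev
    mm = c.is_mm | c.is_modulated
    if mm.any():
        s = y_aug[c.substrate_idx]
        e = y_aug[c.enzyme_idx]
        v = c.kcat * e * s / (c.Km + s)
        if c.is_modulated.any():
            m = np.maximum(y_aug[c.modifier_idx], 0.0)
            v = v * np.where(c.is_modulated, 1.0 + (c.fold - 1.0) * m / (m + c.K_half), 1.0)
        flux = np.where(mm, v, flux)
    return flux


def build_rhs(network: ReactionNetwork) -> Callable[[float, np.ndarray], np.ndarray]:
    """Derivative evaluator d(state)/dt for a validated network.

    The evaluator is deterministic and side-effect-free:
    ``dy/dt = N . flux(y)`` with fluxes per kinetic-law definition.
    """
    require_valid(network)
    c = _compile(network)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return c.N @ _fluxes(c, y)

    return rhs


def instantaneous_fluxes(network: ReactionNetwork, state: Sequence[float]) -> np.ndarray:
    """Per-reaction flux vector (M/s) at the given state.

    Reversible reactions report their net (forward minus reverse) flux.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (len(network.species),):
        raise ValueError(
            f"state has shape {y.shape}, expected ({len(network.species)},)")
    if np.any(y < 0):
        raise ValueError("state must be non-negative")
    require_valid(network)
    return _fluxes(_compile(network), y)


def simulate(
    network: ReactionNetwork,
    overrides: Mapping[str, float] | None = None,
    settings: SolverSettings | None = None,
    provenance: dict | None = None,
) -> TimeCourse:
    """Integrate the network with a stiff BDF solver.

    ``overrides`` replaces initial concentrations (molar) by species name.
    Small negative excursions (below ``negative_tolerance_factor * atol``)
    are clipped to zero in the output; anything larger raises
    :class:`SolverFailure`, as do step-size underflows.
    """
    settings = settings or SolverSettings()
    require_valid(network)
    y0 = network.initial_state(overrides)
    c = _compile(network)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return c.N @ _fluxes(c, y)

    grid = settings.grid()
    t_span = (float(grid[0]), float(grid[-1]))
    sol = solve_ivp(
        rhs, t_span, y0, method="BDF", t_eval=grid,
        rtol=settings.rtol, atol=settings.atol, max_step=settings.max_step,
    )
    if not sol.success:
        last_t = float(sol.t[-1]) if sol.t.size else t_span[0]
        last_y = sol.y[:, -1] if sol.t.size else y0
        raise SolverFailure(f"integration failed: {sol.message}", last_t, last_y)

    conc = sol.y.T.copy()
    floor = -settings.negative_tolerance_factor * settings.atol
    worst = conc.min(initial=0.0)
    if worst < floor:
        i_t, i_s = np.unravel_index(np.argmin(conc), conc.shape)
        raise SolverFailure(
            f"species {network.species_names[i_s]} reached {worst:.3e} M at "
            f"t = {sol.t[i_t]:.1f} s (beyond the negative tolerance)",
            float(sol.t[i_t]), conc[i_t],
        )
    np.clip(conc, 0.0, None, out=conc)
    conc[0] = y0  # first row is exactly the initial condition

    return TimeCourse(
        times=sol.t.copy(),
        concentrations=conc,
        species_order=list(network.species_names),
        scenario_provenance=dict(provenance or {},
                                 overrides={k: float(v) for k, v in (overrides or {}).items()},
                                 settings=vars(settings) | {},
                                 ),
    )


def conservation_drift(
    network: ReactionNetwork, tc: TimeCourse, law: Mapping[str, int]
) -> float:
    """Max relative drift of a conserved-moiety total over a time course."""
    idx = {name: i for i, name in enumerate(tc.species_order)}
    total = np.zeros(len(tc.times))
    for name, coeff in law.items():
        total += coeff * tc.concentrations[:, idx[name]]
    ref = total[0]
    if ref == 0:
        return float(np.max(np.abs(total)))
    return float(np.max(np.abs(total - ref)) / abs(ref))
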