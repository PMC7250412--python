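"""Scenario definitions, lysis metrics, dose sweeps and effect classification.

A :class:`Scenario` pins down every initial condition the experiments vary
(TF, the two activators, TXA, the four inhibitor levels) plus solver
settings, so each simulated number is traceable to one record.  The sweep
drivers reproduce the three experiment families: TXA dose-response under
tPA, inhibitor-knockout panels under uPA, and tPA:uPA balance sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fibrinolysis import ActivationParams, InhibitorParams
from .model_build import build_full_model
from .network import ReactionNetwork
from .simulate import SolverSettings, TimeCourse, simulate
from .txa import TXABindingParams

#: TXA dose ladder used across the experiment families (molar).
PAPER_TXA_DOSES: tuple[float, ...] = (0.0, 1e-6, 3e-6, 14e-6, 54e-6, 3470e-6)

#: tPA levels of the activator-balance sweep (molar); uPA is held at 5 nM.
BALANCE_TPA_LEVELS: tuple[float, ...] = (0.1e-9, 1.0e-9, 2.5e-9)

ANTI = "anti_fibrinolytic"
NEUTRAL = "neutral"
PRO = "pro_fibrinolytic"


@dataclass(frozen=True)
class Scenario:
    """Initial-condition overrides (molar) plus solver settings.

    ``None`` for an inhibitor means "use the packaged physiological level";
    zero is an explicit knockout.
    """

    tf: float = 5e-12
    tpa: float = 0.0
    upa: float = 0.0
    txa: float = 0.0
    ap: float | None = None
    a1at: float | None = None
    a2m: float | None = None
    pci: float | None = None
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        for name in ("tf", "tpa", "upa", "txa", "ap", "a1at", "a2m", "pci"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative")

    _SPECIES_FIELDS = {"TF": "tf", "tPA": "tpa", "uPA": "upa", "TXA": "txa",
                       "AP": "ap", "A1AT": "a1at", "A2M": "a2m", "PCI": "pci"}

    def overrides(self, network: "ReactionNetwork | None" = None) -> dict[str, float]:
        """Initial-condition override map (molar).

        When *network* is given, default-valued entries for species the
        model does not declare are dropped (so small fixture models work),
        but an explicitly set level for a missing species is an error.
        """
        mapping = {name: getattr(self, field)
                   for name, field in self._SPECIES_FIELDS.items()}
        out = {k: float(v) for k, v in mapping.items() if v is not None}
        if network is not None:
            names = set(network.species_names)
            defaults = type(self)()
            for key in list(out):
                if key not in names:
                    if out[key] != (getattr(defaults, self._SPECIES_FIELDS[key]) or 0.0):
                        raise KeyError(
                            f"scenario sets {key} but the model has no such species")
                    del out[key]
        return out

    def provenance(self) -> dict:
        return {"scenario": {k: getattr(self, k)
                             for k in ("tf", "tpa", "upa", "txa", "ap", "a1at", "a2m", "pci")}}


@dataclass(frozen=True)
class LysisMetrics:
    """Summary of one fibrin time course.

    ``lysis_time_50`` is the first time after the fibrin peak at which
    fibrin falls to ``threshold_fraction`` of the peak (None if never);
    ``percent_fibrin_remaining_at_end`` is relative to the peak.
    """

    fibrin_peak: float
    t_peak: float
    lysis_time_50: float | None
    percent_fibrin_remaining_at_end: float
    time_of_ap_depletion: float | None


def _first_crossing_below(times: np.ndarray, values: np.ndarray, threshold: float,
                          start: int = 0) -> float | None:
    """Linearly interpolated first downward crossing of *threshold*."""
    for i in range(start + 1, len(values)):
        if values[i] <= threshold:
            if values[i - 1] <= threshold:
                return float(times[i - 1]) if i - 1 > start else float(times[i])
            t0, t1 = times[i - 1], times[i]
            v0, v1 = values[i - 1], values[i]
            return float(t0 + (v0 - threshold) * (t1 - t0) / (v0 - v1))
    return None


def compute_lysis_metrics(
    tc: TimeCourse,
    threshold_fraction: float = 0.5,
    fibrin_species: str = "fibrin",
    ap_species: str = "AP",
    ap_depletion_fraction: float = 0.01,
) -> LysisMetrics:
    """Metrics per the type definition; crossings are interpolated linearly."""
    if fibrin_species not in tc:
        raise ValueError(f"time course does not contain {fibrin_species!r}")
    fibrin = tc[fibrin_species]
    i_peak = int(np.argmax(fibrin))
    peak = float(fibrin[i_peak])
    t_peak = float(tc.times[i_peak])
    if peak <= 0.0:
        remaining = 100.0
        lysis_time = None
    else:
        remaining = float(100.0 * fibrin[-1] / peak)
        lysis_time = _first_crossing_below(tc.times, fibrin, threshold_fraction * peak, i_peak)

    ap_depletion = None
    if ap_species in tc:
        ap = tc[ap_species]
        if ap[0] > 0:
            ap_depletion = _first_crossing_below(tc.times, ap, ap_depletion_fraction * ap[0])
    return LysisMetrics(peak, t_peak, lysis_time, remaining, ap_depletion)


def classify_txa_effect(
    doses: Sequence[float],
    lysis_times: Sequence[float | None],
    rel_tolerance: float = 0.05,
) -> str:
    """Anti/neutral/pro classification of a dose-response of lysis times.

    An undefined lysis time counts as +inf (fully inhibited).  Changes
    between consecutive doses within *rel_tolerance* count as "similar";
    the label is anti (pro) iff some change is a rise (fall) beyond
    tolerance and no change is a fall (rise) beyond tolerance.
    """
    order = np.argsort(np.asarray(doses, dtype=float))
    lt = [math.inf if lysis_times[i] is None else float(lysis_times[i]) for i in order]
    rises = falls = 0
    for a, b in zip(lt, lt[1:]):
        if a == b:
            continue
        if math.isinf(a) and math.isinf(b):
            continue
        if math.isinf(b) or (not math.isinf(a) and b > a * (1 + rel_tolerance)):
            rises += 1
        elif math.isinf(a) or b < a * (1 - rel_tolerance):
            falls += 1
    if rises and not falls:
        return ANTI
    if falls and not rises:
        return PRO
    return NEUTRAL


@dataclass
class SweepResult:
    """One TXA dose sweep: per-dose metrics and (optionally) time courses."""

    doses: list[float]
    metrics: list[LysisMetrics]
    timecourses: dict[float, TimeCourse] | None = None
    rel_tolerance: float = 0.05

    @property
    def lysis_times(self) -> list[float | None]:
        return [m.lysis_time_50 for m in self.metrics]

    @property
    def classification(self) -> str:
        return classify_txa_effect(self.doses, self.lysis_times, self.rel_tolerance)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for dose, m in zip(self.doses, self.metrics):
            rows.append({
                "txa_dose_M": dose,
                "fibrin_peak_M": m.fibrin_peak,
                "t_peak_s": m.t_peak,
                "lysis_time_50_s": m.lysis_time_50,
                "percent_fibrin_remaining_at_end": m.percent_fibrin_remaining_at_end,
                "time_of_ap_depletion_s": m.time_of_ap_depletion,
            })
        return pd.DataFrame(rows)


def run_scenario(
    scenario: Scenario, network: ReactionNetwork | None = None
) -> TimeCourse:
    network = network if network is not None else build_full_model()
    return simulate(network, scenario.overrides(network), scenario.solver,
                    provenance=scenario.provenance())


def run_dose_sweep(
    base: Scenario,
    txa_doses: Sequence[float] = PAPER_TXA_DOSES,
    network: ReactionNetwork | None = None,
    keep_timecourses: bool = False,
    threshold_fraction: float = 0.5,
) -> SweepResult:
    """One simulation per TXA dose, everything else held fixed."""
    doses = list(dict.fromkeys(float(d) for d in txa_doses))
    if any(d < 0 for d in doses):
        raise ValueError("TXA doses must be non-negative")
    network = network if network is not None else build_full_model()
    metrics: list[LysisMetrics] = []
    tcs: dict[float, TimeCourse] = {}
    for dose in doses:
        tc = run_scenario(replace(base, txa=dose), network)
        metrics.append(compute_lysis_metrics(tc, threshold_fraction))
        if keep_timecourses:
            tcs[dose] = tc
    return SweepResult(doses, metrics, tcs if keep_timecourses else None)


#: Fig-5-style knockout panel compositions (A2M present?, A1AT present?).
KNOCKOUT_PANELS: dict[str, tuple[bool, bool]] = {
    "A": (True, True),
    "B": (True, False),
    "C": (False, True),
    "D": (False, False),
}


def run_knockout_panel(
    base: Scenario,
    txa_doses: Sequence[float] = PAPER_TXA_DOSES,
    network: ReactionNetwork | None = None,
    keep_timecourses: bool = False,
) -> dict[str, SweepResult]:
    """Dose sweeps for the four A2M/A1AT presence-absence combinations."""
    if base.upa <= 0:
        raise ValueError("knockout panel requires uPA-driven fibrinolysis (upa > 0)")
    network = network if network is not None else build_full_model()
    panels: dict[str, SweepResult] = {}
    for label, (with_a2m, with_a1at) in KNOCKOUT_PANELS.items():
        scenario = replace(base,
                           a2m=None if with_a2m else 0.0,
                           a1at=None if with_a1at else 0.0)
        panels[label] = run_dose_sweep(scenario, txa_doses, network, keep_timecourses)
    return panels


def run_tpa_upa_balance(
    base: Scenario,
    tpa_levels: Sequence[float] = BALANCE_TPA_LEVELS,
    txa_doses: Sequence[float] = PAPER_TXA_DOSES,
    network: ReactionNetwork | None = None,
    keep_timecourses: bool = False,
) -> dict[float, SweepResult]:
    """Dose sweeps at fixed uPA while tPA is stepped up (A2M = A1AT = 0)."""
    if base.a2m != 0.0 or base.a1at != 0.0:
        raise ValueError("balance sweep is defined in the A2M = A1AT = 0 regime")
    if base.upa <= 0:
        raise ValueError("balance sweep holds uPA fixed at a positive level")
    network = network if network is not None else build_full_model()
    out: dict[float, SweepResult] = {}
    for tpa in tpa_levels:
        out[float(tpa)] = run_dose_sweep(replace(base, tpa=float(tpa)),
                                         txa_doses, network, keep_timecourses)
    return out


# ---------------------------------------------------------------------------
# Local sensitivity
# ---------------------------------------------------------------------------

_PARAM_OWNERS = {
    **{name: "txa" for name in ("Kd_x", "Kd_y", "kon_x", "kon_y", "upa_enhancement")},
    **{name: "act" for name in ActivationParams.__dataclass_fields__},
    **{name: "inh" for name in InhibitorParams.__dataclass_fields__},
}


def _model_with_parameter(name: str, value: float) -> ReactionNetwork:
    act, inh, txa = ActivationParams(), InhibitorParams(), TXABindingParams()
    owner = _PARAM_OWNERS.get(name)
    if owner == "txa":
        txa = replace(txa, **{name: value})
    elif owner == "act":
        act = replace(act, **{name: value})
    elif owner == "inh":
        inh = replace(inh, **{name: value})
    else:
        raise KeyError(f"unknown model parameter {name!r}")
    return build_full_model(act=act, inh=inh, txa=txa)


def default_parameter_value(name: str) -> float:
    owner = _PARAM_OWNERS.get(name)
    if owner is None:
        raise KeyError(f"unknown model parameter {name!r}")
    source = {"txa": TXABindingParams(), "act": ActivationParams(), "inh": InhibitorParams()}[owner]
    return float(getattr(source, name))


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    delta: float
    derivative: float  # d(lysis_time_50) / d(log parameter)
    lysis_time_low: float
    lysis_time_high: float


def local_sensitivity(
    base: Scenario, parameter: str, delta: float = 0.1
) -> SensitivityResult:
    """Two-sided finite-difference d(lysis_time_50)/d(log p).

    ``delta`` is the relative perturbation: the metric is evaluated at
    p * (1 + delta) and p / (1 + delta).  Note that for TXA-site on-rates
    the dissociation constant is held fixed by construction (koff = Kd*kon).
    Raises if the metric is undefined on either side.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if parameter == "TXA":
        p0 = base.txa
        if p0 <= 0:
            raise ValueError("TXA sensitivity needs a positive base dose")
        values = (p0 / (1 + delta), p0 * (1 + delta))
        tcs = [run_scenario(replace(base, txa=v)) for v in values]
    else:
        p0 = default_parameter_value(parameter)
        values = (p0 / (1 + delta), p0 * (1 + delta))
        tcs = [run_scenario(base, _model_with_parameter(parameter, v)) for v in values]
    lysis = [compute_lysis_metrics(tc).lysis_time_50 for tc in tcs]
    if lysis[0] is None or lysis[1] is None:
        raise ValueError(
            f"lysis_time_50 undefined at a perturbed point; {parameter} at "
            f"{values} is a non-differentiable point for this scenario")
    dlogp = 2 * math.log(1 + delta)
    return SensitivityResult(parameter, delta, (lysis[1] - lysis[0]) / dlogp,
                             lysis[0], lysis[1])
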