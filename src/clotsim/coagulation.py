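"""TF-initiated thrombin generation and fibrin formation.

The cascade is data, not code: it ships as a model-file fragment
(``models/coagulation_cascade.json``, rate constants transcribed from
published in-vitro-calibrated ODE models of the extrinsic pathway) and is
registered here after a check for the mandatory entry and exit species.
This module only adds the thrombogram summary used for regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import NetworkValidationError, Reaction, ReactionNetwork, load_network, require_valid
from .simulate import TimeCourse

#: Species the cascade fragment must declare to be usable as the clot source.
MANDATORY_SPECIES = ("TF", "II", "IIa", "fibrinogen")

_DATA_DIR = Path(__file__).parent / "models"
CASCADE_PATH = _DATA_DIR / "coagulation_cascade.json"


def load_cascade_fragment(path: str | Path = CASCADE_PATH) -> ReactionNetwork:
    return load_network(path)


def build_coagulation_reactions(source: ReactionNetwork) -> list[Reaction]:
    """Validate a cascade fragment and return its reactions.

    Raises :class:`NetworkValidationError` when a mandatory species (the
    initiator TF, prothrombin/thrombin, or the fibrin substrate) is absent.
    """
    require_valid(source)
    names = {s.name for s in source.species}
    missing = [name for name in MANDATORY_SPECIES if name not in names]
    if missing:
        raise NetworkValidationError(
            f"cascade fragment is missing mandatory species: {', '.join(missing)}")
    return list(source.reactions)


@dataclass(frozen=True)
class ThrombinMetrics:
    """Standard thrombogram summary.

    ``lag_time`` is the first time thrombin exceeds ``lag_fraction`` of its
    peak (linearly interpolated); ``etp`` the trapezoidal integral (M s).
    Lag and time-to-peak are ``None`` when thrombin never rises.
    """

    lag_time: float | None
    peak_height: float
    time_to_peak: float | None
    etp: float


def thrombin_metrics(
    tc: TimeCourse, species: str = "IIa", lag_fraction: float = 0.1
) -> ThrombinMetrics:
    if len(tc.times) == 0:
        raise ValueError("empty time course")
    if species not in tc:
        raise ValueError(f"time course does not contain {species!r}")
    thrombin = tc[species]
    etp = float(np.trapezoid(thrombin, tc.times))
    peak = float(thrombin.max())
    if peak <= 0.0:
        return ThrombinMetrics(None, 0.0, None, etp)
    i_peak = int(np.argmax(thrombin))
    threshold = lag_fraction * peak
    lag: float | None = None
    for i in range(1, i_peak + 1):
        if thrombin[i] >= threshold:
            t0, t1 = tc.times[i - 1], tc.times[i]
            c0, c1 = thrombin[i - 1], thrombin[i]
            lag = float(t0) if c1 == c0 else float(t0 + (threshold - c0) * (t1 - t0) / (c1 - c0))
            break
    if lag is None and thrombin[0] >= threshold:
        lag = float(tc.times[0])
    return ThrombinMetrics(lag, peak, float(tc.times[i_peak]), etp)
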