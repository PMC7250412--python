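"""Concentration unit handling.

All internal state is molar; display units exist only at I/O boundaries.
"""

from __future__ import annotations

#: Multiplicative factor unit -> molar.
UNIT_TO_MOLAR: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def to_molar(value: float, unit: str) -> float:
    """Convert *value* expressed in *unit* to molar."""
    try:
        return value * UNIT_TO_MOLAR[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit: {unit!r}") from None


def from_molar(value: float, unit: str) -> float:
    """Convert a molar *value* to *unit*."""
    try:
        return value / UNIT_TO_MOLAR[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit: {unit!r}") from None
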