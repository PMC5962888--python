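"""tDCS montage arithmetic and safety screening.

The emulated protocol delivers 0.75 mA through an intracephalic pair: a
small 9 cm^2 cathode over the right posterior parietal cortex (under the
EEG cap, where P2/CP2 were removed) and a larger 25 cm^2 anode over the
left supraorbital area.  Different electrode sizes concentrate the current
density under the cathode (0.08 mA/cm^2) while keeping the anode weak
(0.03 mA/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MontageCheck", "validate_tdcs_montage", "DEFAULT_SAFETY_BOUND"]

#: Conventional conservative current-density bound for scalp tDCS.
DEFAULT_SAFETY_BOUND = 0.10  # mA/cm^2


class TdcsError(ValueError):
    """Raised for non-physical stimulation parameters."""


@dataclass(frozen=True)
class MontageCheck:
    """Current-density record for one stimulation electrode."""

    role: str  # "cathode" or "anode"
    area_cm2: float
    current_ma: float
    current_density: float  # mA/cm^2, rounded to 2 decimals
    exceeds_safety_bound: bool


def validate_tdcs_montage(
    current_ma: float = 0.75,
    cathode_area_cm2: float = 9.0,
    anode_area_cm2: float = 25.0,
    safety_bound: float = DEFAULT_SAFETY_BOUND,
) -> tuple[MontageCheck, MontageCheck]:
    """Compute per-electrode current densities and flag unsafe values.

    Density = current / area, reported rounded to 2 decimals (mA/cm^2).
    """
    if min(current_ma, cathode_area_cm2, anode_area_cm2) <= 0:
        raise TdcsError("current and electrode areas must be positive")
    out = []
    for role, area in (("cathode", cathode_area_cm2), ("anode", anode_area_cm2)):
        density = round(current_ma / area, 2)
        out.append(
            MontageCheck(
                role=role,
                area_cm2=float(area),
                current_ma=float(current_ma),
                current_density=density,
                exceeds_safety_bound=density > safety_bound,
            )
        )
    return out[0], out[1]
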