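"""Cooking-quality parameters and commercial-type classification from biometry.

Water uptake (WUp), volumetric expansion ratio (VER) and solids leached
(SL) are computed from raw before/after-cooking measurements:

    WUp = 100 * (cooked_mass - uncooked_mass) / uncooked_mass        [%]
    VER = cooked_volume / uncooked_volume                            [ratio]
    SL  = 100 * (W1 - W2) / uncooked_mass                            [%]

where W1 is the weight of the drying container with the dried cooking-water
aliquot and W2 the empty container.  SL as printed refers to the aliquot
only; an opt-in mode scales it by total_water_volume / aliquot_volume to
express leaching into the whole cooking water.

Grain commercial types are assigned from length and length/width ratio by
the standard trade rules; the rules do not tile biometry space, so grains in
the gaps are returned as "unclassified".  Aromatic designations (Basmati,
European Aromatic) are commercial metadata and are never inferred from
biometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "CookingMeasurement",
    "CookingParameters",
    "GrainBiometry",
    "cooking_parameters",
    "classify_commercial_type",
]


@dataclass(frozen=True)
class CookingMeasurement:
    """Raw measurements from cooking one rice sample (grams / millilitres)."""

    variety: str
    uncooked_mass: float
    cooked_mass: float
    uncooked_volume: float
    cooked_volume: float
    aliquot_dry_with_container_W1: float
    empty_container_W2: float
    aliquot_volume: float = 50.0
    total_water: float = 120.0

    def __post_init__(self) -> None:
        if self.uncooked_mass <= 0:
            raise ValueError("uncooked_mass must be > 0")
        if self.uncooked_volume <= 0:
            raise ValueError("uncooked_volume must be > 0")
        if self.aliquot_dry_with_container_W1 < self.empty_container_W2:
            raise ValueError("W1 must be >= W2")
        if self.cooked_mass < self.uncooked_mass:
            warnings.warn(
                f"{self.variety!r}: cooked mass below uncooked mass",
                RuntimeWarning, stacklevel=3,
            )


@dataclass(frozen=True)
class CookingParameters:
    variety: str
    WUp: float
    VER: float
    SL: float


@dataclass(frozen=True)
class GrainBiometry:
    """Grain length and width in mm; ratio is derived."""

    variety: str
    length: float
    width: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("length and width must be > 0")

    @property
    def ratio(self) -> float:
        return self.length / self.width


def cooking_parameters(
    m: CookingMeasurement, scale_sl_to_total_water: bool = False
) -> CookingParameters:
    """WUp, VER and SL from one raw cooking measurement."""
    wup = 100.0 * (m.cooked_mass - m.uncooked_mass) / m.uncooked_mass
    ver = m.cooked_volume / m.uncooked_volume
    sl = 100.0 * (m.aliquot_dry_with_container_W1 - m.empty_container_W2) / m.uncooked_mass
    if scale_sl_to_total_water:
        sl *= m.total_water / m.aliquot_volume
    return CookingParameters(variety=m.variety, WUp=wup, VER=ver, SL=sl)


def classify_commercial_type(b: GrainBiometry) -> str:
    """Commercial grain type from biometry, by the standard trade rules.

    Long A: length > 6.0 mm and 2 < length/width < 3.
    Long B: length > 6.0 mm and length/width >= 3.
    Medium grain: 5.2 < length < 6.0 mm and length/width < 3.
    Short grain: length <= 5.2 mm and length/width < 2.

    Inequalities are applied strictly as stated (boundary grains, e.g.
    length exactly 6.0 mm, fall through to "unclassified").
    """
    length, ratio = b.length, b.ratio
    if length > 6.0 and 2.0 < ratio < 3.0:
        return "Long A"
    if length > 6.0 and ratio >= 3.0:
        return "Long B"
    if 5.2 < length < 6.0 and ratio < 3.0:
        return "Medium grain"
    if length <= 5.2 and ratio < 2.0:
        return "Short grain"
    return "unclassified"
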