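"""Cooking-quality parameters and commercial-type classification.

Computes water uptake, volumetric expansion and solids leached from raw
cooking measurements of a 12 g rice sample, then classifies grains into
trade types from their length and length/width ratio.
"""

from ricegi import (
    CookingMeasurement,
    GrainBiometry,
    classify_commercial_type,
    cooking_parameters,
)

m = CookingMeasurement(
    variety="example",
    uncooked_mass=12.0, cooked_mass=36.0,       # tripled its weight
    uncooked_volume=15.0, cooked_volume=60.0,   # quadrupled its volume
    aliquot_dry_with_container_W1=20.6, empty_container_W2=20.0,
)
cp = cooking_parameters(m)
print(f"WUp = {cp.WUp:.0f} % (weight gained), VER = {cp.VER:.1f} "
      f"(volume ratio), SL = {cp.SL:.1f} % (solids leached to cooking water)")

for length, width in [(6.5, 2.6), (6.9, 2.1), (5.6, 2.4), (5.0, 2.8)]:
    b = GrainBiometry("grain", length, width)
    print(f"length {length} mm, ratio {b.ratio:.2f} -> "
          f"{classify_commercial_type(b)}")
# aromatic designations (Basmati, European Aromatic) are commercial
# metadata, never inferred from biometry
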