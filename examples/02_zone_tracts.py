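"""Classify census tracts into exposure zones by distance from burn zones.

Builds a synthetic burn-zone polygon and a grid of tract points, classifies
them under the primary 20 km buffer and the 10 km sensitivity buffer, and
prints the zone tallies.
"""

import numpy as np
from shapely.geometry import Polygon

from fireits import BurnZone, TractGeometry, classify_tracts, zoning_frame

burn = BurnZone(
    "synthetic-fire",
    Polygon(
        [(-118.6, 34.0), (-118.4, 34.0), (-118.35, 34.15),
         (-118.5, 34.25), (-118.65, 34.1), (-118.6, 34.0)]
    ),
)

rng = np.random.default_rng(0)
tracts = [
    TractGeometry(
        f"tract-{i:03d}",
        float(-118.5 + rng.uniform(-0.8, 0.8)),
        float(34.1 + rng.uniform(-0.8, 0.8)),
        in_la_county=bool(rng.random() < 0.6),
    )
    for i in range(200)
]

for buffer_km in (20.0, 10.0):
    frame = zoning_frame(classify_tracts(tracts, [burn], buffer_km))
    tally = frame["zone"].value_counts().to_dict()
    print(f"buffer {buffer_km:4.0f} km: {tally}")
print(
    "High = tract point within the buffer of any burn-zone boundary; "
    "moderate = beyond the buffer but in LA County; minimal = beyond the "
    "buffer elsewhere. Shrinking the buffer moves tracts high -> moderate/minimal."
)
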