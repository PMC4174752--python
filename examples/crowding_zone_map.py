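"""Map the crowding zone: accuracy as a function of flanker position.

Trains the zone variant (151x151 display, 48 RFs, ellipticity 0.5) and
probes a single flanker over a grid of positions. Prints the row of the
map through the target and summary statistics of the interference zone.
"""

import numpy as np

import sparsecrowd as sc

cfg = sc.default_config("zone")
zm = sc.run_zone_map(cfg, seed=0, n_iterations=4, stride=5)

dy, dx = zm.cell_center_offsets()
ri = int(np.argmin(np.abs(dy)))
print("accuracy along the horizontal through the target:")
for x, v in zip(dx, zm.grid[ri]):
    print(f"  flanker at {x:+4.0f} px: {v:.2f}")
print(f"far-flanker level: {zm.far_level():.3f}; worst cell: {zm.grid.min():.3f}")
# The impaired region around the target is elongated horizontally (radially)
# and reaches farther on the eccentric (+) side than the foveal side.
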