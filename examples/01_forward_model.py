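"""Forward model: idealized 10/10 montage, source grid, analytic lead field.

Builds the 64-channel spherical montage and a cubic source grid, computes
the closed-form single-sphere lead field under a common average reference,
and inspects the scalp pattern of one tangential dipole.
"""

import numpy as np

from oddball_stda.forward_model import (
    build_source_grid,
    compute_leadfield,
    standard_montage_1010,
)

montage = standard_montage_1010(head_radius_cm=9.2)
print(f"montage: {len(montage.labels)} electrodes "
      f"({len(montage.scalp_labels)} scalp + 2 mastoids)")
print("Cz position (cm):", np.round(montage.position("Cz"), 3))
print("M1 position (cm):", np.round(montage.position("M1"), 3))

grid = build_source_grid(inner_radius_cm=7.8, spacing_mm=10.0)
print(f"\nsource grid: {grid.n_voxels} voxels, spacing {grid.spacing_cm} cm")

lf = compute_leadfield(montage, grid, reference="CAR")
print("lead field gain shape (channels, voxels, orientations):", lf.gain.shape)

# a left superior-temporal dipole pointing toward the vertex (tangential):
# negative fronto-centrally, positive below the Sylvian fissure at the
# mastoids -- the classic MMN polarity inversion.
from oddball_stda.synthetic_data import tangentialize

pos = (5.2, 1.0, 3.2)
voxel = grid.nearest_voxel(pos)
moment = np.array(tangentialize(pos, (0.0, 0.0, 1.0))) * -25.0  # nA*m
topo = lf.gain[:, voxel, :] @ moment
for label in ("Fz", "FCz", "Cz", "M1", "M2"):
    i = list(lf.labels).index(label)
    print(f"  {label:3s}: {topo[i]:+.3f} uV")
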