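"""Numba inner loops for ellipsoid-membership voxel counting."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def count_hits_per_pixel(vox, centers, Ms, lobe_ok):
    """Voxels (n_v, 3) inside the union of each pixel's excitation ellipsoids.

    centers: (n_p, n_lobes, 3) ellipsoid centers per pixel.
    Ms: (n_p, n_lobes, 6) symmetric quadratic forms (xx, yy, zz, xy, xz, yz);
        a voxel v is inside lobe l of pixel p iff (v-c)^T M (v-c) <= 1.
    lobe_ok: (n_p, n_lobes) lobe validity flags.
    Returns per-pixel counts (n_p,).
    """
    n_p = centers.shape[0]
    n_l = centers.shape[1]
    n_v = vox.shape[0]
    counts = np.zeros(n_p, dtype=np.int64)
    for p in range(n_p):
        c = 0
        for v in range(n_v):
            inside = False
            for l in range(n_l):
                if not lobe_ok[p, l]:
                    continue
                dx = vox[v, 0] - centers[p, l, 0]
                dy = vox[v, 1] - centers[p, l, 1]
                dz = vox[v, 2] - centers[p, l, 2]
                q = (Ms[p, l, 0] * dx * dx + Ms[p, l, 1] * dy * dy
                     + Ms[p, l, 2] * dz * dz
                     + 2.0 * (Ms[p, l, 3] * dx * dy + Ms[p, l, 4] * dx * dz
                              + Ms[p, l, 5] * dy * dz))
                if q <= 1.0:
                    inside = True
                    break
            if inside:
                c += 1
        counts[p] = c
    return counts
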