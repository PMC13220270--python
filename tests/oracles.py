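"""Independent oracle implementations used only by the test suite.

Each oracle reimplements a quantity through a different route than the
package (flood-fill connectivity instead of Dijkstra, brute-force sphere
scans, scipy's rotation fitting) so agreement is evidence, not
tautology.
"""

import numpy as np
from scipy import ndimage

_CONN26 = np.ones((3, 3, 3), dtype=int)


def maximin_bottleneck_floodfill(clearance, passable, seed, target_mask):
    """Brute-force widest-path bottleneck via threshold connectivity.

    The bottleneck between seed and target region equals the largest
    clearance threshold t at which they are 26-connected within
    {passable and clearance >= t}; found by bisection over the sorted
    unique clearance values (the bottleneck always equals one of them).
    Returns None when no passable path exists at all.
    """
    vals = np.unique(clearance[passable])
    if len(vals) == 0 or not passable[seed]:
        return None

    def connected(t):
        region = passable & (clearance >= t)
        if not region[seed]:
            return False
        lab, _ = ndimage.label(region, structure=_CONN26)
        return bool(np.any(lab[target_mask & region] == lab[seed]))

    if not connected(vals[0]):
        return None
    lo, hi = 0, len(vals) - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if connected(vals[mid]):
            lo = mid
        else:
            hi = mid - 1
    return float(vals[lo])


def brute_clearance(point, positions, radii):
    """Distance from a point to the nearest sphere surface, plain loop."""
    best = np.inf
    for p, r in zip(positions, radii):
        best = min(best, float(np.linalg.norm(np.asarray(point) - p)) - r)
    return best


def kabsch_rmsd_scipy(mobile, reference):
    """Minimum RMSD of two point sets via scipy's rotation fitting."""
    from scipy.spatial.transform import Rotation

    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref, mob)
    diff = rot.apply(mob) - ref
    return float(np.sqrt((diff**2).sum() / len(ref)))
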