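"""Spatially constrained permutations (spin test) of parcel maps.

Parcel-level statistics inherit spatial autocorrelation, so free
permutation nulls are anticonservative. The spin test rotates the parcel
centroids on the sphere (left hemisphere by a uniform random rotation,
right hemisphere by its x-mirrored twin) and reassigns each parcel the
value of the nearest rotated parcel under greedy one-to-one matching,
yielding hemisphere-preserving permutations that keep the map's
smoothness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class SpinNullSet:
    permutations: np.ndarray        # (n_null, n_parcels) int
    preserved_hemispheres: bool
    seed: int

    @property
    def n_null(self) -> int:
        return self.permutations.shape[0]


def _random_rotation(rng) -> np.ndarray:
    """Uniform 3D rotation from a normalised quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _greedy_match(original: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """One-to-one assignment original position -> rotated parcel.

    Globally greedy on the distance matrix (closest available pair
    first), so an identity rotation returns the identity permutation and
    every null is a true bijection.
    """
    D = cdist(original, rotated)
    n = D.shape[0]
    order = np.argsort(D, axis=None)
    row_done = np.zeros(n, dtype=bool)
    col_done = np.zeros(n, dtype=bool)
    perm = np.full(n, -1, dtype=int)
    assigned = 0
    for flat in order:
        i, j = divmod(int(flat), n)
        if row_done[i] or col_done[j]:
            continue
        perm[i] = j
        row_done[i] = True
        col_done[j] = True
        assigned += 1
        if assigned == n:
            break
    return perm


def generate_spins(
    parcel_meta: pd.DataFrame,
    n_null: int,
    seed: int = 0,
    preserve_hemispheres: bool = True,
) -> SpinNullSet:
    """Spin permutations for centroids on (or near) the unit sphere.

    ``parcel_meta`` needs columns hemisphere ('L'/'R') and x/y/z. Left
    parcels map to left and right to right; duplicated centroids within
    a hemisphere are rejected.
    """
    coords = parcel_meta[["x", "y", "z"]].to_numpy(dtype=float)
    hemi = parcel_meta["hemisphere"].to_numpy()
    n = len(coords)
    rng = np.random.default_rng(seed)
    mirror = np.diag([-1.0, 1.0, 1.0])

    idx = {h: np.where(hemi == h)[0] for h in ("L", "R")}
    for h, ids in idx.items():
        if ids.size and len(np.unique(coords[ids].round(12), axis=0)) < ids.size:
            raise ValueError(f"duplicate centroids in hemisphere {h}")

    perms = np.empty((n_null, n), dtype=int)
    for k in range(n_null):
        R = _random_rotation(rng)
        perm = np.empty(n, dtype=int)
        for h, ids in idx.items():
            if ids.size == 0:
                continue
            rot = R if h == "L" else mirror @ R @ mirror
            rotated = coords[ids] @ rot.T
            local = _greedy_match(coords[ids], rotated)
            perm[ids] = ids[local]
        perms[k] = perm
    return SpinNullSet(permutations=perms, preserved_hemispheres=preserve_hemispheres, seed=seed)


def spin_p(
    observed_stat: float,
    statistic_fn: Callable[[np.ndarray], float],
    parcel_map: np.ndarray,
    spins: SpinNullSet,
) -> float:
    """Two-sided spin p-value.

    p = (1 + #{|stat(spun map)| >= |observed|}) / (1 + n_null). The
    statistic function must be pure.
    """
    parcel_map = np.asarray(parcel_map)
    obs = abs(float(observed_stat))
    count = 0
    for perm in spins.permutations:
        if abs(float(statistic_fn(parcel_map[perm]))) >= obs:
            count += 1
    return (1 + count) / (1 + spins.n_null)
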