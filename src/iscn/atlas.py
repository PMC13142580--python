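"""Desikan-Killiany 68-region atlas fixture.

The pipeline operates on the standard 68-region Desikan-Killiany (DK)
cortical parcellation (34 regions per hemisphere). All tables and matrices
use the fixed region order defined here: left hemisphere first, then right,
each alphabetically by region name.

Parcel positions for the spin permutation test are synthetic unit-sphere
centroids: 34 points per hemisphere placed by a Fibonacci lattice on a
half-sphere, mirrored across the midsagittal (x = 0) plane. They preserve
the geometry the spatial-null test needs (a spherical layout with
hemispheric mirror symmetry) without requiring surface reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: 34 DK region base names (FreeSurfer naming), alphabetical.
DK_BASE_NAMES = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

N_REGIONS = 68

#: Base names of anterior cingulate cortex parcels (subtype S1 anchor).
ACC_BASE_NAMES = ("caudalanteriorcingulate", "rostralanteriorcingulate")

#: Base names of the temporal / central / parietal parcels used for the
#: temporoparietal subtype (S2) pattern.
TEMPOROPARIETAL_BASE_NAMES = (
    "bankssts",
    "inferiorparietal",
    "inferiortemporal",
    "middletemporal",
    "postcentral",
    "precentral",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "transversetemporal",
)


@dataclass(frozen=True)
class RegionAtlas:
    """Fixed 68-region parcellation with spherical parcel centroids.

    Attributes
    ----------
    names : tuple of str
        Region labels ``{lh,rh}_<base>`` in canonical order.
    hemispheres : numpy.ndarray of str
        ``"L"`` or ``"R"`` per region.
    centroids : numpy.ndarray, shape (68, 3)
        Unit-norm parcel centroids; left-hemisphere points have x < 0 and
        right-hemisphere points are their exact mirror images.
    """

    names: tuple
    hemispheres: np.ndarray
    centroids: np.ndarray

    def __post_init__(self):
        if len(self.names) != N_REGIONS:
            raise ValueError(f"expected {N_REGIONS} regions, got {len(self.names)}")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def hemisphere_mask(self, hemi: str) -> np.ndarray:
        return self.hemispheres == hemi

    def match(self, base_names) -> np.ndarray:
        """Indices of all regions (both hemispheres) with the given base names."""
        idx = [
            i
            for i, n in enumerate(self.names)
            if n.split("_", 1)[1] in set(base_names)
        ]
        return np.asarray(idx, dtype=int)


def _fibonacci_hemisphere(n: int, side: str) -> np.ndarray:
    """Place `n` near-evenly spaced unit vectors on the x<0 (L) or x>0 (R) half-sphere."""
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    k = np.arange(n)
    # z in (-1, 1), spiral in azimuth; restrict azimuth to one half-sphere.
    z = (2.0 * k + 1.0) / n - 1.0
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = np.mod(k / golden, 1.0) * np.pi  # half turn: y free, x one-signed
    x = r * np.sin(phi)  # in [0, r]
    y = r * np.cos(phi)
    pts = np.column_stack([x, y, z])
    if side == "L":
        pts[:, 0] *= -1.0
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def dk_atlas_fixture() -> RegionAtlas:
    """Return the packaged 68-region DK atlas with unit-sphere centroids.

    Left and right centroids are mirror images across x = 0, so mirrored
    spin rotations act consistently on both hemispheres.
    """
    names = tuple(f"lh_{b}" for b in DK_BASE_NAMES) + tuple(
        f"rh_{b}" for b in DK_BASE_NAMES
    )
    hemis = np.array(["L"] * 34 + ["R"] * 34)
    left = _fibonacci_hemisphere(34, "L")
    right = left.copy()
    right[:, 0] *= -1.0
    return RegionAtlas(names=names, hemispheres=hemis, centroids=np.vstack([left, right]))


#: Column labels for the 68 thickness columns in a cohort table.
def thickness_columns(atlas: RegionAtlas | None = None) -> list:
    atlas = atlas or dk_atlas_fixture()
    return [f"thk_{n}" for n in atlas.names]
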