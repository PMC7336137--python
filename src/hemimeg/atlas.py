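"""246-node brain parcellation bookkeeping.

The analyses in this package operate on a Brainnetome-style parcellation:
246 regions of interest (123 per hemisphere, 210 cortical + 36 subcortical)
grouped into 48 larger brain areas (24 per hemisphere).  This module holds
the atlas table representation, its validation rules, the hemispheric index
blocks used to slice intra-hemispheric sub-networks out of whole-brain
adjacency matrices, and exact medoid centroid computation for labelled
voxel volumes.

Canonical node order is all left-hemisphere nodes first (node_id 1-123)
followed by all right-hemisphere nodes (124-246).  Adjacency matrices
produced by this package follow that order, so the right intra-hemispheric
network is the lower-right 123x123 principal submatrix and the left network
the upper-left one, independent of any visual "quadrant" convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

N_NODES = 246
N_PER_HEMISPHERE = 123
N_AREAS_PER_HEMISPHERE = 24

REQUIRED_COLUMNS = (
    "node_id",
    "name",
    "hemisphere",
    "area_group",
    "cortical",
    "mni_x",
    "mni_y",
    "mni_z",
)

# Per-hemisphere area groups with node counts and a rough centroid seed
# coordinate (|x|, y, z in mm).  Counts follow the Brainnetome grouping
# scheme: 24 areas per hemisphere, 105 cortical + 18 subcortical nodes.
_AREA_SCHEME: list[tuple[str, int, bool, tuple[float, float, float]]] = [
    ("SFG", 7, True, (18, 30, 45)),
    ("MFG", 7, True, (35, 30, 30)),
    ("IFG", 6, True, (48, 25, 10)),
    ("OrG", 6, True, (25, 40, -15)),
    ("PrG", 6, True, (35, -15, 50)),
    ("PCL", 2, True, (8, -30, 60)),
    ("STG", 6, True, (55, -15, 5)),
    ("MTG", 4, True, (58, -30, -5)),
    ("ITG", 7, True, (52, -30, -22)),
    ("FuG", 3, True, (35, -45, -18)),
    ("PhG", 6, True, (25, -25, -22)),
    ("pSTS", 2, True, (55, -45, 12)),
    ("SPL", 5, True, (25, -55, 55)),
    ("IPL", 6, True, (45, -50, 40)),
    ("PCun", 4, True, (8, -60, 40)),
    ("PoG", 4, True, (40, -25, 50)),
    ("INS", 6, True, (38, 5, 2)),
    ("CG", 7, True, (6, -10, 35)),
    ("MVOcC", 5, True, (10, -80, 10)),
    ("LOcC", 6, True, (35, -85, 5)),
    ("Amyg", 2, False, (22, -3, -18)),
    ("Hipp", 2, False, (28, -22, -12)),
    ("BG", 6, False, (18, 5, 2)),
    ("Tha", 8, False, (10, -18, 8)),
]


class AtlasValidationError(ValueError):
    """Raised when an atlas table violates a structural invariant."""


@dataclass(frozen=True)
class AtlasTable:
    """Validated 246-node atlas table in canonical row order."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _validate(self.table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def node_ids(self) -> np.ndarray:
        return self.table["node_id"].to_numpy()

    def area_of(self, node_id: int) -> tuple[str, str]:
        """Return (hemisphere, area_group) for a node id."""
        row = self.table.loc[self.table["node_id"] == node_id]
        if row.empty:
            raise KeyError(f"unknown node_id {node_id}")
        return str(row.iloc[0]["hemisphere"]), str(row.iloc[0]["area_group"])


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasValidationError(f"missing required columns: {missing}")
    if len(df) != N_NODES:
        raise AtlasValidationError(f"expected {N_NODES} rows, found {len(df)}")
    ids = df["node_id"].to_numpy()
    if len(np.unique(ids)) != N_NODES:
        raise AtlasValidationError("node_id values are not unique")
    if not set(ids) == set(range(1, N_NODES + 1)):
        raise AtlasValidationError("node_id must cover 1..246")
    hemis = set(df["hemisphere"].unique())
    if not hemis <= {"L", "R"}:
        raise AtlasValidationError(f"hemisphere codes must be L/R, got {hemis}")
    counts = df["hemisphere"].value_counts()
    for h in ("L", "R"):
        if counts.get(h, 0) != N_PER_HEMISPHERE:
            raise AtlasValidationError(
                f"hemisphere {h} has {counts.get(h, 0)} nodes, "
                f"expected {N_PER_HEMISPHERE}"
            )
    for h in ("L", "R"):
        n_areas = df.loc[df["hemisphere"] == h, "area_group"].nunique()
        if n_areas != N_AREAS_PER_HEMISPHERE:
            raise AtlasValidationError(
                f"hemisphere {h} has {n_areas} area groups, "
                f"expected {N_AREAS_PER_HEMISPHERE}"
            )


def build_default_atlas() -> AtlasTable:
    """Construct the bundled synthetic default atlas.

    The table mirrors the structure of the Brainnetome parcellation (node
    counts per area, cortical/subcortical split, 24 areas per hemisphere)
    but its node names and MNI coordinates are synthetic placeholders:
    area seed coordinates jittered deterministically, with the x coordinate
    mirrored between hemispheres.
    """
    rng = np.random.default_rng(202,)
    jitter = {  # one jitter draw per (area, node index), shared across hemispheres
        (area, k): rng.uniform(-8, 8, size=3)
        for area, n, _, _ in _AREA_SCHEME
        for k in range(n)
    }
    rows = []
    node_id = 1
    for hemi, sign in (("L", -1.0), ("R", 1.0)):
        for area, n, cortical, (ax, ay, az) in _AREA_SCHEME:
            for k in range(n):
                dx, dy, dz = jitter[(area, k)]
                rows.append(
                    {
                        "node_id": node_id,
                        "name": f"{area}_{hemi}_{k + 1}",
                        "hemisphere": hemi,
                        "area_group": f"{area}_{hemi}",
                        "cortical": bool(cortical),
                        "mni_x": round(sign * (ax + dx), 1),
                        "mni_y": round(ay + dy, 1),
                        "mni_z": round(az + dz, 1),
                    }
                )
                node_id += 1
    return AtlasTable(pd.DataFrame(rows))


def default_atlas() -> AtlasTable:
    """Load the TSV table bundled with the package."""
    with resources.as_file(
        resources.files("hemimeg").joinpath("data/atlas246.tsv")
    ) as p:
        return load_atlas(p)


def load_atlas(path: str | Path) -> AtlasTable:
    """Read and validate an atlas table from tab-separated text."""
    df = pd.read_csv(path, sep="\t")
    if "cortical" in df.columns:
        df["cortical"] = df["cortical"].astype(bool)
    return AtlasTable(df)


def save_atlas(atlas: AtlasTable, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


def hemisphere_blocks(atlas: AtlasTable) -> tuple[list[int], list[int]]:
    """Node ids of the left and right hemispheric blocks.

    Returns two disjoint sorted lists of node ids (1-based) of length 123
    each, partitioning 1..246.  In canonical order, position of node id
    ``i`` is ``i - 1``, so these double as slicing indices after
    subtracting one.
    """
    df = atlas.table
    left = sorted(int(i) for i in df.loc[df["hemisphere"] == "L", "node_id"])
    right = sorted(int(i) for i in df.loc[df["hemisphere"] == "R", "node_id"])
    return left, right


@dataclass(frozen=True)
class LabeledVolume:
    """A voxel grid with integer ROI labels (0 = background)."""

    labels: np.ndarray  # integer array, shape = grid_shape
    voxel_size: float = 2.0

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @classmethod
    def from_voxel_list(
        cls,
        coords: np.ndarray,
        labels: np.ndarray,
        grid_shape: tuple[int, int, int] | None = None,
        voxel_size: float = 2.0,
    ) -> "LabeledVolume":
        """Build a volume from (n, 3) voxel coordinates and their labels."""
        coords = np.asarray(coords, dtype=int)
        labels = np.asarray(labels, dtype=int)
        if grid_shape is None:
            grid_shape = tuple(coords.max(axis=0) + 1)
        vol = np.zeros(grid_shape, dtype=int)
        vol[coords[:, 0], coords[:, 1], coords[:, 2]] = labels
        return cls(vol, voxel_size)

    @classmethod
    def load(cls, path: str | Path, voxel_size: float = 2.0) -> "LabeledVolume":
        """Load from NIfTI (via nibabel) or a text x/y/z/label list."""
        path = Path(path)
        if path.suffix in {".nii", ".gz"}:
            import nibabel as nib  # optional dependency, NIfTI input only

            img = nib.load(str(path))
            return cls(np.asarray(img.dataobj, dtype=int), voxel_size)
        arr = np.loadtxt(path, dtype=int, ndmin=2)
        if arr.shape[1] != 4:
            raise ValueError("text volume must have 4 columns: x y z label")
        return cls.from_voxel_list(arr[:, :3], arr[:, 3], voxel_size=voxel_size)


def medoid_centroid(vol: LabeledVolume, roi_label: int) -> tuple[int, int, int]:
    """Exact medoid voxel of an ROI.

    Returns the ROI voxel minimizing the sum of squared Euclidean distances
    to all other voxels of the same ROI (the k-medoids objective with k=1,
    solved exactly rather than by iterative swaps).  Ties are broken by the
    smallest linear (C-order ravel) voxel index, so the result is
    deterministic.
    """
    coords = np.argwhere(vol.labels == roi_label)
    if coords.size == 0:
        raise ValueError(f"label {roi_label} not present in volume")
    pts = coords.astype(float)
    n = len(pts)
    # sum_j ||v - p_j||^2 = n||v||^2 - 2 v.S + sum_j ||p_j||^2 ; the last
    # term is constant over candidates and dropped.
    s = pts.sum(axis=0)
    obj = n * np.einsum("ij,ij->i", pts, pts) - 2.0 * pts @ s
    lin = np.ravel_multi_index(coords.T, vol.grid_shape)
    order = np.lexsort((lin, obj))  # min objective, then min linear index
    best = coords[order[0]]
    return int(best[0]), int(best[1]), int(best[2])
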