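"""Synthetic bilateral region atlas.

The atlas is an integer-labeled 3D volume plus a region table pairing
the 13 left/right homologous regions.  Regions are axis-aligned blocks
placed mirror-symmetrically about the midsagittal (first-axis) plane:
the asymmetry index depends only on region *means*, so anatomical shape
is irrelevant to the statistics.  Hemisphere membership is recorded in
the region table, never inferred from voxel coordinates, which keeps
the bookkeeping independent of RAS/LAS orientation conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import AtlasError, SizingError
from .regions import REGION_NAMES


@dataclass(frozen=True)
class RegionSpec:
    """One hemisphere of a homologous region pair."""

    pair_name: str
    hemisphere: str  # "left" | "right"
    label_id: int
    baseline_mean: float

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise AtlasError(f"bad hemisphere {self.hemisphere!r}")
        if self.label_id <= 0:
            raise AtlasError("label_id must be a positive integer")
        if self.baseline_mean <= 0:
            raise AtlasError("baseline_mean must be > 0")


@dataclass
class RegionAtlas:
    """Integer-labeled volume (0 = background) with its region table."""

    label_volume: np.ndarray
    voxel_size: tuple[float, float, float]
    regions: list[RegionSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        self.validate()

    # -- bookkeeping -------------------------------------------------

    def validate(self) -> None:
        ids = [r.label_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise AtlasError("duplicate label ids in region table")
        present = set(np.unique(self.label_volume)) - {0}
        declared = set(ids)
        if present - declared:
            raise AtlasError(f"labels in volume missing from table: {sorted(present - declared)}")
        for r in self.regions:
            if r.label_id not in present:
                raise AtlasError(f"label {r.label_id} ({r.pair_name}/{r.hemisphere}) occupies no voxel")
        for name, count in pd.Series([r.pair_name for r in self.regions]).value_counts().items():
            if count != 2:
                raise AtlasError(f"pair {name!r} appears {count} times, expected one per hemisphere")

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])

    @property
    def pair_names(self) -> list[str]:
        seen: list[str] = []
        for r in self.regions:
            if r.pair_name not in seen:
                seen.append(r.pair_name)
        return seen

    def pairs(self) -> dict[str, dict[str, RegionSpec]]:
        """pair_name -> {"left": spec, "right": spec}."""
        out: dict[str, dict[str, RegionSpec]] = {}
        for r in self.regions:
            out.setdefault(r.pair_name, {})[r.hemisphere] = r
        return out

    def region_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.pair_name, r.hemisphere, r.label_id, r.baseline_mean) for r in self.regions],
            columns=["pair_name", "hemisphere", "label_id", "baseline_mean"],
        )

    # -- I/O ---------------------------------------------------------

    def save(self, volume_path: str | Path, table_path: str | Path) -> None:
        img = nib.Nifti1Image(self.label_volume.astype(np.int16), self.affine)
        nib.save(img, str(volume_path))
        self.region_table().to_csv(table_path, index=False)

    @classmethod
    def load(cls, volume_path: str | Path, table_path: str | Path) -> "RegionAtlas":
        img = nib.load(str(volume_path))
        table = pd.read_csv(table_path)
        regions = [
            RegionSpec(row.pair_name, row.hemisphere, int(row.label_id), float(row.baseline_mean))
            for row in table.itertuples()
        ]
        vol = np.asarray(img.dataobj).astype(np.int32)
        voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
        return cls(vol, voxel_size, regions)


def generate_atlas(
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    seed: int = 0,
    block: int = 6,
) -> RegionAtlas:
    """Place 13 mirror-symmetric block pairs on the grid.

    Blocks are cubes of edge ``block`` (shrunk down to 2 if the grid is
    tight) laid on a lattice in the left half of the first axis and
    mirrored to the right half (``x' = nx - 1 - x``).  Baseline mean
    uptake per pair is drawn once from U(80, 120) counts with ``seed``;
    the label geometry itself is deterministic.

    Raises :class:`SizingError` when the grid cannot hold all 26 blocks.
    """
    nx, ny, nz = grid_shape
    rng = np.random.default_rng(seed)
    baselines = rng.uniform(80.0, 120.0, size=len(REGION_NAMES))

    half = nx // 2
    slots: list[tuple[int, int, int]] = []
    b = None
    for b_try in range(min(block, 6), 1, -1):
        step = b_try + 1
        xs = range(1, half - b_try + 1, step)
        ys = range(1, ny - b_try + 1, step)
        zs = range(1, nz - b_try + 1, step)
        slots = [(x, y, z) for z in zs for y in ys for x in xs]
        if len(slots) >= len(REGION_NAMES):
            b = b_try
            break
    if b is None:
        raise SizingError(
            f"grid {grid_shape} too small to place {len(REGION_NAMES)} mirror-symmetric block pairs"
        )

    labels = np.zeros(grid_shape, dtype=np.int16)
    regions: list[RegionSpec] = []
    for i, name in enumerate(REGION_NAMES):
        x, y, z = slots[i]
        left_id, right_id = 2 * i + 1, 2 * i + 2
        labels[x:x + b, y:y + b, z:z + b] = left_id
        xr = nx - x - b  # mirror of [x, x+b) under x' = nx-1-x
        labels[xr:xr + b, y:y + b, z:z + b] = right_id
        base = float(baselines[i])
        regions.append(RegionSpec(name, "left", left_id, base))
        regions.append(RegionSpec(name, "right", right_id, base))

    return RegionAtlas(labels, tuple(float(v) for v in voxel_size), regions)
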