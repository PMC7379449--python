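"""Regional mean uptake and asymmetry-index feature extraction.

``region_means`` averages voxel values over each atlas label (plain
arithmetic mean, background excluded, no trimming or normalization —
the asymmetry index cancels any global scale by construction).
``compute_features`` converts paired left/right means into the 13
asymmetry indices that feed the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import RegionAtlas
from .errors import AlignmentError, AtlasError, PairingError, ParseError
from .regions import CLASSES, REGION_NAMES

#: Elementwise tolerance when comparing volume and atlas affines.
AFFINE_ATOL = 1e-4


@dataclass
class RegionMeans:
    subject_id: str
    means: dict[int, float]
    voxel_counts: dict[int, int]


def region_means(volume: np.ndarray, atlas: RegionAtlas,
                 subject_id: str = "") -> RegionMeans:
    """Mean voxel value per atlas label.

    Raises :class:`AlignmentError` on grid-shape mismatch and
    :class:`AtlasError` if any declared label occupies no voxel.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.shape != atlas.label_volume.shape:
        raise AlignmentError(
            f"volume grid {volume.shape} does not match atlas grid {atlas.label_volume.shape}")
    ids = [r.label_id for r in atlas.regions]
    counts = np.bincount(atlas.label_volume.ravel(), minlength=max(ids) + 1)
    empty = [i for i in ids if counts[i] == 0]
    if empty:
        raise AtlasError(f"labels with zero voxels: {empty}")
    means = ndimage.mean(volume, labels=atlas.label_volume, index=ids)
    if not np.all(np.isfinite(means)):
        raise AtlasError("non-finite region mean encountered")
    return RegionMeans(
        subject_id,
        {i: float(m) for i, m in zip(ids, means)},
        {i: int(counts[i]) for i in ids},
    )


def asymmetry_index(left_mean, right_mean):
    """AI = 200 * (L - R) / (L + R) for positive region means.

    Antisymmetric in its arguments and invariant to any common positive
    scaling; strictly inside (-200, 200) for positive inputs.  Accepts
    scalars or arrays.  Non-positive inputs are rejected: PET counts
    are positive and the formula's denominator must not vanish.
    """
    left = np.asarray(left_mean, dtype=np.float64)
    right = np.asarray(right_mean, dtype=np.float64)
    if np.any(left <= 0) or np.any(right <= 0):
        raise ValueError("region means must be strictly positive")
    out = 200.0 * (left - right) / (left + right)
    return float(out) if out.ndim == 0 else out


def compute_features(rm: RegionMeans, atlas: RegionAtlas) -> pd.Series:
    """One AI per region pair, keyed by pair name in canonical order."""
    pairs = atlas.pairs()
    values: dict[str, float] = {}
    for name in atlas.pair_names:
        specs = pairs[name]
        if "left" not in specs or "right" not in specs:
            raise PairingError(f"pair {name!r} is missing a hemisphere")
        for hemi in ("left", "right"):
            if specs[hemi].label_id not in rm.means:
                raise PairingError(f"no mean for {name!r}/{hemi}")
        values[name] = asymmetry_index(rm.means[specs["left"].label_id],
                                       rm.means[specs["right"].label_id])
    order = [n for n in REGION_NAMES if n in values] + [
        n for n in values if n not in REGION_NAMES]
    return pd.Series({n: values[n] for n in order}, name=rm.subject_id)


def features_from_volume(volume: np.ndarray, atlas: RegionAtlas,
                         subject_id: str = "") -> pd.Series:
    return compute_features(region_means(volume, atlas, subject_id), atlas)


def feature_table_from_subjects(subjects, atlas: RegionAtlas,
                                labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stack per-subject feature rows into an AsymmetryFeatureTable."""
    rows = [features_from_volume(s.volume, atlas, s.subject_id) for s in subjects]
    table = pd.DataFrame(rows)
    table.insert(0, "subject_id", [s.subject_id for s in subjects])
    side = {s.subject_id: s.true_side for s in subjects}
    if labels is not None:
        side = dict(zip(labels["subject_id"], labels["label"]))
    table.insert(1, "label", [side[s.subject_id] for s in subjects])
    return table.reset_index(drop=True)


# -- volume and table I/O ---------------------------------------------


def load_volume(path: str | Path, atlas: RegionAtlas) -> np.ndarray:
    """Load a NIfTI volume and check alignment with the atlas affine."""
    img = nib.load(str(path))
    if not np.allclose(img.affine, atlas.affine, atol=AFFINE_ATOL, rtol=0.0):
        raise AlignmentError(f"affine of {path} differs from atlas affine beyond {AFFINE_ATOL}")
    vol = np.asarray(img.dataobj, dtype=np.float64)
    if vol.shape != atlas.label_volume.shape:
        raise AlignmentError(f"grid of {path} does not match atlas grid")
    return vol


def validate_feature_table(table: pd.DataFrame, require_label: bool = False) -> pd.DataFrame:
    feature_cols = [c for c in table.columns if c not in ("subject_id", "label")]
    unknown = [c for c in feature_cols if c not in REGION_NAMES]
    if unknown:
        raise ParseError(f"unknown feature columns: {unknown}")
    if not feature_cols:
        raise ParseError("feature table holds no region columns")
    if table[feature_cols].isna().any().any():
        raise ParseError("feature table contains missing AI values")
    if "label" in table.columns:
        bad = set(table["label"].dropna()) - set(CLASSES)
        if bad:
            raise ParseError(f"labels outside {CLASSES}: {sorted(bad)}")
    elif require_label:
        raise ParseError("feature table has no label column")
    return table


def read_feature_table(path: str | Path, require_label: bool = False) -> pd.DataFrame:
    return validate_feature_table(pd.read_csv(path), require_label)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_feature_table(table).to_csv(path, index=False)


def split_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix (region columns only) and label vector."""
    validate_feature_table(table, require_label=True)
    cols = [c for c in table.columns if c in REGION_NAMES]
    return table[cols], table["label"]
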