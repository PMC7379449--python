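"""Synthetic TLE PET cohort generator.

Emulates the statistical structure of an interictal FDG-PET cohort of
mesial TLE patients: two classes (Left/Right TLE, default class ratio
27:22 in a cohort of 49), ipsilateral hypometabolism of a few percent
in mesial temporal structures and their associated regions, additive
Gaussian voxel noise, and one multiplicative global scale factor per
subject (the quantity the asymmetry index must cancel).

Two routes are provided:

* the volume route (:func:`generate_subject` / :func:`generate_cohort`)
  builds atlas-aligned 3D volumes, which exercise the imaging layer;
* the feature route (:func:`generate_feature_table`) draws asymmetry
  indices directly as Gaussians around the closed form
  ``±200*d/(2-d)`` and is cheap enough for repeated-replicate studies.

Randomness uses a single ``SeedSequence`` per cohort, split per subject
by counter, so regenerating subject *k* never disturbs subject *j*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .atlas import RegionAtlas, generate_atlas
from .errors import ConfigError
from .regions import CLASSES, REGION_NAMES, expected_ai

#: Default fractional ipsilateral uptake reductions.  Chosen so the
#: implied AI magnitudes (200*d/(2-d)) span roughly 2-6: strongest in
#: mesial structures, weaker in neocortical temporal and associated
#: regions.
DEFAULT_EFFECTS: dict[str, float] = {
    "Hippocampus": 0.06,
    "Parahippocampal gyrus": 0.05,
    "Amygdala": 0.05,
    "Temporal pole of middle temporal gyrus": 0.04,
    "Temporal pole of superior temporal gyrus": 0.04,
    "Middle temporal gyrus": 0.03,
    "Superior temporal gyrus": 0.03,
    "Inferior temporal gyrus": 0.03,
    "Insula": 0.02,
    "Thalamus": 0.02,
    "Rolandic operculum": 0.02,
    "Opercular part of inferior frontal gyrus": 0.02,
    "Supramarginal gyrus": 0.02,
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the reference cohort: 49 subjects with 27 Left and
    22 Right TLE, a planted hippocampal reduction of 6% (AI -6.19 on
    the left), no contralateral compensation, voxel noise SD of 10
    counts on ~100-count baselines, AI-scale noise SD of 2 for the
    feature route, and per-subject global scaling in [0.8, 1.2].
    """

    n_subjects: int = 49
    left_fraction: float = 27 / 49
    effect_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    contralateral_gain: float = 0.0
    voxel_noise_sd: float = 10.0
    ai_noise_sd: float = 2.0
    global_scale_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if not 0.0 < self.left_fraction < 1.0:
            raise ConfigError("left_fraction must lie in (0, 1)")
        for name, d in self.effect_map.items():
            if name not in REGION_NAMES:
                raise ConfigError(f"unknown region in effect_map: {name!r}")
            if not 0.0 <= d < 0.5:
                raise ConfigError(f"delta for {name!r} must lie in [0, 0.5)")
        if self.contralateral_gain < 0.0:
            raise ConfigError("contralateral_gain must be >= 0")
        if self.voxel_noise_sd < 0.0 or self.ai_noise_sd < 0.0:
            raise ConfigError("noise SDs must be >= 0")
        lo, hi = self.global_scale_range
        if not 0.0 < lo <= hi:
            raise ConfigError("global_scale_range must be a positive interval")

    # -- YAML round trip ----------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["global_scale_range"] = list(d["global_scale_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        if "global_scale_range" in d:
            d["global_scale_range"] = tuple(d["global_scale_range"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class SyntheticSubject:
    subject_id: str
    true_side: str  # "Left" | "Right"
    volume: np.ndarray
    applied_scale: float


def _side_factors(pair_name: str, hemisphere: str, true_side: str,
                  config: CohortConfig) -> float:
    """Multiplicative uptake factor for one region of one subject."""
    delta = config.effect_map.get(pair_name)
    if delta is None:
        return 1.0
    ipsilateral = (true_side == "Left" and hemisphere == "left") or (
        true_side == "Right" and hemisphere == "right")
    if ipsilateral:
        return 1.0 - delta
    return 1.0 + config.contralateral_gain


def generate_subject(atlas: RegionAtlas, true_side: str, config: CohortConfig,
                     rng: np.random.Generator,
                     subject_id: str = "S000") -> SyntheticSubject:
    """Draw one PET-like volume aligned to ``atlas``.

    Region voxels are set to ``baseline_mean * factor`` (ipsilateral
    hypometabolism / contralateral gain), Gaussian voxel noise is added,
    negative values are clipped to zero, and the whole volume is then
    multiplied by one global scale drawn from ``global_scale_range``.
    """
    if true_side not in CLASSES:
        raise ConfigError(f"true_side must be one of {CLASSES}, got {true_side!r}")
    vol = np.zeros(atlas.label_volume.shape, dtype=np.float64)
    for r in atlas.regions:
        factor = _side_factors(r.pair_name, r.hemisphere, true_side, config)
        mean = r.baseline_mean * factor
        if mean <= 0:
            raise ConfigError(f"non-positive expected uptake in {r.pair_name}/{r.hemisphere}")
        vol[atlas.label_volume == r.label_id] = mean
    if config.voxel_noise_sd > 0:
        vol += rng.normal(0.0, config.voxel_noise_sd, size=vol.shape)
        np.clip(vol, 0.0, None, out=vol)
    scale = float(rng.uniform(*config.global_scale_range))
    vol *= scale
    return SyntheticSubject(subject_id, true_side, vol, scale)


def _cohort_sides(config: CohortConfig, rng: np.random.Generator) -> list[str]:
    n_left = round(config.n_subjects * config.left_fraction)
    sides = ["Left"] * n_left + ["Right"] * (config.n_subjects - n_left)
    return [sides[i] for i in rng.permutation(config.n_subjects)]


def generate_cohort(atlas: RegionAtlas, config: CohortConfig
                    ) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Generate a full cohort of subject volumes plus its label table."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_subjects + 1)
    sides = _cohort_sides(config, np.random.default_rng(children[0]))
    subjects = []
    for i, side in enumerate(sides):
        sid = f"S{i + 1:03d}"
        subjects.append(generate_subject(
            atlas, side, config, np.random.default_rng(children[i + 1]), sid))
    labels = pd.DataFrame({"subject_id": [s.subject_id for s in subjects],
                           "label": sides})
    return subjects, labels


def generate_feature_table(config: CohortConfig) -> pd.DataFrame:
    """Draw an asymmetry-index feature table directly (no volumes).

    Each AI is Gaussian with SD ``ai_noise_sd`` around the closed form
    ``expected_ai(delta, contralateral_gain, side)`` (zero for regions
    without a planted effect).  Columns: subject_id, label, then the 13
    region pair names in canonical order.
    """
    root = np.random.SeedSequence(config.seed)
    order_rng, value_rng = (np.random.default_rng(s) for s in root.spawn(2))
    sides = _cohort_sides(config, order_rng)
    n = config.n_subjects
    means = np.zeros((n, len(REGION_NAMES)))
    for j, name in enumerate(REGION_NAMES):
        delta = config.effect_map.get(name, 0.0)
        for i, side in enumerate(sides):
            means[i, j] = expected_ai(delta, config.contralateral_gain, side)
    values = means + value_rng.normal(0.0, config.ai_noise_sd, size=means.shape)
    table = pd.DataFrame(values, columns=list(REGION_NAMES))
    table.insert(0, "label", sides)
    table.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(n)])
    return table


def write_cohort(out_dir: str | Path, config: CohortConfig,
                 atlas: RegionAtlas | None = None,
                 features_only: bool = False) -> dict:
    """Materialize a cohort on disk; returns a manifest dict.

    Writes ``config.yaml`` always; with ``features_only`` a feature CSV,
    otherwise the atlas (NIfTI + region CSV), one NIfTI per subject and
    a label CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"seed": config.seed, "n_subjects": config.n_subjects}
    if features_only:
        table = generate_feature_table(config)
        table.to_csv(out / "features.csv", index=False)
        manifest["features"] = "features.csv"
        return manifest
    if atlas is None:
        atlas = generate_atlas((64, 64, 48), seed=config.seed)
    atlas.save(out / "atlas.nii.gz", out / "regions.csv")
    subjects, labels = generate_cohort(atlas, config)
    for s in subjects:
        img = nib.Nifti1Image(s.volume.astype(np.float32), atlas.affine)
        nib.save(img, str(out / f"{s.subject_id}.nii.gz"))
    labels.to_csv(out / "labels.csv", index=False)
    manifest.update({"atlas": "atlas.nii.gz", "regions": "regions.csv",
                     "labels": "labels.csv",
                     "subjects": [f"{s.subject_id}.nii.gz" for s in subjects]})
    return manifest
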