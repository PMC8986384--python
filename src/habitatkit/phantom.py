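"""Synthetic multi-sequence MRI phantoms with known intratumoral habitats.

Real habitat-imaging studies start from co-registered multiparametric breast
MRI with a tumour ROI and a per-patient binary mutation label determined by
immunohistochemistry. This module emulates that data regime so that every
downstream stage (preprocessing, clustering, validity features, modelling)
can be exercised end to end with a known ground truth:

* six registered sequences on one grid,
* a compact spherical tumour ROI containing K latent habitats, carved into
  spatially contiguous blobs by k-means on voxel coordinates,
* sequence- and habitat-specific mean intensities plus i.i.d. Gaussian noise,
* a binary group label ("mutant" / "wild-type") that modulates the habitat
  geometry: ``centroid_scale`` multiplies the habitat intensity means (hence
  their spread) and ``dispersion_scale`` multiplies the within-habitat noise,
  so the cluster-validity statistics carry group information,
* an immunohistochemistry staining percentage consistent with the group
  label under the standard -/+/++/+++ scoring rule.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .habitats import kmeans_cluster
from .preprocess import SEQUENCE_NAMES, StudyBundle, VolumeGrid

logger = logging.getLogger("habitatkit")

#: Default habitat mean intensities (arbitrary units), one row per habitat,
#: one column per sequence in SEQUENCE_NAMES order. Chosen so each habitat
#: pair is well separated (per-sequence gaps ~30-50 a.u.) without any single
#: sequence dominating the 6-D geometry.
DEFAULT_HABITAT_MEANS = np.array(
    [
        [100.0, 120.0, 80.0, 90.0, 110.0, 70.0],
        [140.0, 90.0, 110.0, 120.0, 80.0, 100.0],
        [80.0, 150.0, 95.0, 70.0, 130.0, 120.0],
    ]
)


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic study.

    Defaults describe a 24 mm cube at 1 mm isotropic spacing holding an
    8 mm-radius spherical tumour (~2100 ROI voxels) with three habitats and
    additive Gaussian noise of 10 a.u. against habitat-mean gaps of 30-50 a.u.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius: float = 8.0
    n_habitats: int = 3
    habitat_means: np.ndarray | None = None
    noise_sd: float = 10.0
    centroid_scale: float = 1.0
    dispersion_scale: float = 1.0
    group: int = 0
    seed: int = 0

    def resolved_means(self) -> np.ndarray:
        if self.habitat_means is not None:
            means = np.asarray(self.habitat_means, dtype=float)
        else:
            if self.n_habitats != DEFAULT_HABITAT_MEANS.shape[0]:
                raise ValueError(
                    "habitat_means must be given explicitly when n_habitats != "
                    f"{DEFAULT_HABITAT_MEANS.shape[0]}"
                )
            means = DEFAULT_HABITAT_MEANS.copy()
        if means.shape != (self.n_habitats, len(SEQUENCE_NAMES)):
            raise ValueError(
                f"habitat_means must be {self.n_habitats} x {len(SEQUENCE_NAMES)}, "
                f"got {means.shape}"
            )
        return means

    def validate(self) -> None:
        if self.n_habitats < 2:
            raise ValueError("n_habitats must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.centroid_scale <= 0 or self.dispersion_scale <= 0:
            raise ValueError("centroid_scale and dispersion_scale must be > 0")
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive ints")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if self.tumor_radius <= 0:
            raise ValueError("tumor_radius must be > 0")
        # The sphere (centred on the grid centre) must be contained in the
        # voxel-centre extent of the grid on every axis.
        for n, s in zip(self.grid_shape, self.voxel_spacing):
            if self.tumor_radius > (n - 1) * s / 2.0:
                raise ValueError(
                    f"tumor of radius {self.tumor_radius} mm does not fit a grid "
                    f"of {n} voxels at {s} mm spacing"
                )
        self.resolved_means()


@dataclass
class GroundTruth:
    """Latent state of a phantom: habitat map, group label, IHC percentage."""

    habitat_label_volume: np.ndarray
    group_label: int
    ihc_percent: float


class IhcResult(NamedTuple):
    category: str
    positive: bool


def ihc_to_label(percent_positive: float) -> IhcResult:
    """Map an IHC staining percentage to its category and binary label.

    Scoring rule: <5% stained cells scores "-", 5-25% scores "+", 26-50%
    scores "++" and >50% scores "+++"; "-" is negative and every other
    category is positive. The stated integer ranges leave (25, 26) undefined;
    the gap is closed half-open, i.e. "+" covers [5, 25] and "++" covers
    (25, 50].
    """
    p = float(percent_positive)
    if not (0.0 <= p <= 100.0) or not math.isfinite(p):
        raise ValueError(f"staining percentage must be in [0, 100], got {p}")
    if p < 5.0:
        return IhcResult("-", False)
    if p <= 25.0:
        return IhcResult("+", True)
    if p <= 50.0:
        return IhcResult("++", True)
    return IhcResult("+++", True)


def _partition_roi(
    coords_mm: np.ndarray, n_habitats: int, seed: int
) -> np.ndarray:
    """Split ROI voxel coordinates into spatially contiguous blobs.

    k-means on physical coordinates yields a Voronoi partition, hence
    connected, "spatially limited" habitats. Returns 1-based labels.
    """
    labeling = kmeans_cluster(coords_mm, k=n_habitats, seed=seed, n_init=1)
    return labeling.labels


def generate_phantom(params: PhantomParams) -> tuple[StudyBundle, GroundTruth]:
    """Generate one synthetic study and its ground truth, deterministically.

    The voxel intensity of habitat ``h`` in sequence ``s`` is
    ``habitat_means[h, s] * centroid_scale + N(0, noise_sd * dispersion_scale)``;
    the same noise model applies to the zero-mean background.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    means = params.resolved_means() * params.centroid_scale
    sd = params.noise_sd * params.dispersion_scale

    shape = tuple(params.grid_shape)
    spacing = tuple(float(s) for s in params.voxel_spacing)
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    center = [(n - 1) * s / 2.0 for n, s in zip(shape, spacing)]
    grid = np.meshgrid(*axes, indexing="ij")
    dist2 = sum((g - c) ** 2 for g, c in zip(grid, center))
    mask = dist2 <= params.tumor_radius**2
    n_roi = int(mask.sum())
    if n_roi < params.n_habitats:
        raise ValueError("ROI too small to host the requested habitats")

    coords_mm = np.column_stack([g[mask] for g in grid])
    habitat_seed = int(rng.integers(2**31 - 1))
    roi_labels = _partition_roi(coords_mm, params.n_habitats, habitat_seed)

    label_volume = np.zeros(shape, dtype=int)
    label_volume[mask] = roi_labels

    sequences: dict[str, VolumeGrid] = {}
    for s, name in enumerate(SEQUENCE_NAMES):
        vals = np.zeros(shape, dtype=float)
        vals[mask] = means[roi_labels - 1, s]
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=shape)
        sequences[name] = VolumeGrid(vals, spacing=spacing)

    roi_mask = VolumeGrid(mask.astype(np.uint8), spacing=spacing)
    study_id = f"phantom-{params.seed:08d}"
    study = StudyBundle(sequences, roi_mask, study_id=study_id)

    if params.group:
        ihc_percent = float(rng.uniform(5.0, 100.0))
    else:
        ihc_percent = float(rng.uniform(0.0, 5.0))
    truth = GroundTruth(
        habitat_label_volume=label_volume,
        group_label=int(bool(params.group)),
        ihc_percent=ihc_percent,
    )
    return study, truth


@dataclass(frozen=True)
class GroupEffect:
    """How the binary group modulates habitat geometry across a cohort.

    Mutant phantoms get their habitat-mean spread multiplied by
    ``mutant_centroid_scale`` and their noise sd by ``mutant_dispersion_scale``;
    wild-type phantoms use the corresponding wild-type scales. On top of the
    group effect every phantom draws individual lognormal jitter (sd
    ``between_subject_sd`` on the log scale) on both multipliers, emulating
    between-patient biological variability; with identical group scales the
    label is therefore independent of the images (the null cohort).
    """

    mutant_centroid_scale: float = 1.5
    mutant_dispersion_scale: float = 1.3
    wildtype_centroid_scale: float = 1.0
    wildtype_dispersion_scale: float = 1.0
    between_subject_sd: float = 0.05

    @classmethod
    def identity(cls) -> "GroupEffect":
        """Null effect: both groups share unit scales."""
        return cls(
            mutant_centroid_scale=1.0,
            mutant_dispersion_scale=1.0,
        )

    def scales_for(self, group: int) -> tuple[float, float]:
        if group:
            return self.mutant_centroid_scale, self.mutant_dispersion_scale
        return self.wildtype_centroid_scale, self.wildtype_dispersion_scale


def generate_cohort(
    n: int,
    prevalence: float,
    effect: GroupEffect | None = None,
    seed: int = 0,
    base_params: PhantomParams | None = None,
) -> list[tuple[StudyBundle, GroundTruth]]:
    """Generate a cohort of phantoms with ``ceil(n * prevalence)`` mutants.

    Per-phantom seeds and jitters are derived deterministically from the
    master seed, so a cohort is reproducible bit for bit.
    """
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie strictly between 0 and 1")
    effect = effect if effect is not None else GroupEffect()
    base = base_params if base_params is not None else PhantomParams()

    n_mutant = math.ceil(n * prevalence)
    if n_mutant == 0 or n_mutant == n:
        raise ValueError(
            f"degenerate cohort: {n_mutant} mutants out of {n} leaves a class empty"
        )
    groups = np.array([1] * n_mutant + [0] * (n - n_mutant))

    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    jitters = rng.normal(0.0, effect.between_subject_sd, size=(n, 2))

    cohort = []
    for i in range(n):
        cs, ds = effect.scales_for(int(groups[i]))
        params = PhantomParams(
            grid_shape=base.grid_shape,
            voxel_spacing=base.voxel_spacing,
            tumor_radius=base.tumor_radius,
            n_habitats=base.n_habitats,
            habitat_means=base.habitat_means,
            noise_sd=base.noise_sd,
            centroid_scale=cs * float(np.exp(jitters[i, 0])),
            dispersion_scale=ds * float(np.exp(jitters[i, 1])),
            group=int(groups[i]),
            seed=int(child_seeds[i]),
        )
        cohort.append(generate_phantom(params))
    logger.debug("generated cohort: n=%d (%d mutant), seed=%d", n, n_mutant, seed)
    return cohort


# ---------------------------------------------------------------------------
# NIfTI export
# ---------------------------------------------------------------------------

def _nifti_affine(grid: VolumeGrid) -> np.ndarray:
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    return affine


def save_study_nifti(
    study: StudyBundle, truth: GroundTruth, out_dir: Path
) -> dict[str, str]:
    """Write one study as NIfTI files; returns a path map for the manifest."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for name in SEQUENCE_NAMES:
        grid = study.sequences[name]
        img = nib.Nifti1Image(grid.values.astype(np.float32), _nifti_affine(grid))
        path = out_dir / f"{study.study_id}_{name}.nii.gz"
        nib.save(img, path)
        paths[name] = str(path)
    mask_img = nib.Nifti1Image(
        study.roi_mask.values.astype(np.uint8), _nifti_affine(study.roi_mask)
    )
    mask_path = out_dir / f"{study.study_id}_mask.nii.gz"
    nib.save(mask_img, mask_path)
    paths["mask"] = str(mask_path)
    truth_img = nib.Nifti1Image(
        truth.habitat_label_volume.astype(np.int16), _nifti_affine(study.roi_mask)
    )
    truth_path = out_dir / f"{study.study_id}_truth.nii.gz"
    nib.save(truth_img, truth_path)
    paths["truth"] = str(truth_path)
    return paths


def load_study_nifti(paths: dict[str, str], study_id: str) -> StudyBundle:
    """Load a study previously written by :func:`save_study_nifti`."""
    import nibabel as nib

    def _to_grid(path: str) -> VolumeGrid:
        img = nib.load(path)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(o) for o in img.affine[:3, 3])
        return VolumeGrid(np.asarray(img.dataobj, dtype=float), spacing, origin)

    sequences = {name: _to_grid(paths[name]) for name in SEQUENCE_NAMES}
    mask = _to_grid(paths["mask"])
    return StudyBundle(sequences, mask, study_id=study_id)


def save_params_sidecar(params: PhantomParams, path: Path) -> None:
    """Echo all generation parameters to a JSON sidecar."""
    d = asdict(params)
    if d["habitat_means"] is not None:
        d["habitat_means"] = np.asarray(d["habitat_means"]).tolist()
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))
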