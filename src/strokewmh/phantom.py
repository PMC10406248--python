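"""Synthetic multi-site, multi-modal brain phantoms with ground truth.

Generates desk-scale 3D "subjects" that exercise everything the WMH
segmentation pipeline cares about without requiring MRI data: multi-modal
tissue contrasts (FLAIR / T1 / T2), periventricular and deep WMH clusters,
an optional stroke lesion whose FLAIR signal can mimic WMH, and per-site
multiplicative/additive intensity shifts with rescaled noise to emulate
scanner and acquisition differences between research sites.

The anatomy is deliberately minimal: an ellipsoidal brain, two ellipsoidal
lateral ventricles, spherical lesion blobs. That is enough structure to
give intensity features, spatial weighting, periventricular clustering and
stroke/WMH confusability genuine signal, which is all the downstream
experiments need.

Intensity model per modality::

    value = gain * class_mean + offset + N(0, noise_scale * noise_sd)

optionally after Gaussian smoothing of the class-mean image. With zero
noise and no smoothing, every voxel's value equals its tissue class mean
exactly, which the test suite exploits.

Determinism: one integer seed per subject drives a private
``numpy.random.Generator``; a cohort fans a base seed out by addition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import LabelMask, Volume3D, distance_to_mask, write_volume

__all__ = [
    "TissueModel",
    "SiteEffect",
    "LesionGeometry",
    "PhantomSubject",
    "GenerationError",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
]

TISSUES = ("background", "parenchyma", "csf", "wmh", "stroke")
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class GenerationError(RuntimeError):
    """Lesions could not be placed without violating disjointness."""


@dataclass(frozen=True)
class TissueModel:
    """Per-tissue class mean intensities and noise, per modality.

    The defaults encode the contrasts that define the segmentation
    problem: WMH is FLAIR-hyperintense relative to parenchyma, CSF is
    dark on T1 and FLAIR and bright on T2, and the stroke lesion defaults
    to the *same* means as WMH on every modality — maximal confusability,
    so stroke-handling experiments have signal.
    """

    means: dict = field(
        default_factory=lambda: {
            "background": {"FLAIR": 0.0, "T1": 0.0, "T2": 0.0},
            "parenchyma": {"FLAIR": 120.0, "T1": 120.0, "T2": 110.0},
            "csf": {"FLAIR": 60.0, "T1": 50.0, "T2": 200.0},
            "wmh": {"FLAIR": 170.0, "T1": 100.0, "T2": 160.0},
            "stroke": {"FLAIR": 170.0, "T1": 100.0, "T2": 160.0},
            "mimic": {"FLAIR": 170.0, "T1": 100.0, "T2": 160.0},
        }
    )
    noise_sd: dict = field(
        default_factory=lambda: {"FLAIR": 8.0, "T1": 8.0, "T2": 8.0}
    )
    smoothing_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.means["wmh"]["FLAIR"] <= self.means["parenchyma"]["FLAIR"]:
            raise ValueError("WMH must be FLAIR-hyperintense relative to parenchyma")
        if self.means["csf"]["T1"] >= self.means["parenchyma"]["T1"]:
            raise ValueError("CSF must be T1-hypointense relative to parenchyma")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be >= 0")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.means["parenchyma"].keys())


@dataclass(frozen=True)
class SiteEffect:
    """Linear intensity distortion + noise rescaling for one acquisition site."""

    gain: float = 1.0
    offset: float = 0.0
    noise_scale: float = 1.0
    site_id: str = "site-A"

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    @classmethod
    def identity(cls, site_id: str = "site-A") -> "SiteEffect":
        return cls(1.0, 0.0, 1.0, site_id)


@dataclass(frozen=True)
class LesionGeometry:
    """Grid, anatomy and lesion-placement parameters.

    Millimetre quantities are world-space; the default grid is 64^3 at
    1 mm isotropic with the world origin at the volume centre. Ellipsoid
    centres/semi-axes are in mm relative to that origin.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_semiaxes_mm: tuple[float, float, float] = (26.0, 30.0, 22.0)
    ventricle_centers_mm: tuple = ((-8.0, -2.0, 2.0), (8.0, -2.0, 2.0))
    ventricle_semiaxes_mm: tuple[float, float, float] = (4.0, 12.0, 6.0)
    n_wmh_clusters: int = 12
    n_wmh_jitter: int = 4
    wmh_radius_range_mm: tuple[float, float] = (2.0, 4.5)
    periventricular_fraction: float = 0.7
    d_pv_mm: float = 10.0
    stroke_present: bool = True
    stroke_radius_mm: float = 9.0
    #: deep non-WMH hyperintense blobs (0 = none): structures whose
    #: intensity mimics WMH but which lie far from the ventricles, like
    #: the bright midline/artifact tissue that draws false positives in
    #: real pipelines. They make lesion *location* genuinely informative.
    n_mimic_clusters: int = 0
    mimic_radius_range_mm: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.periventricular_fraction <= 1.0:
            raise ValueError("periventricular_fraction must lie in [0, 1]")
        if self.wmh_radius_range_mm[0] <= 0:
            raise ValueError("WMH radii must be positive")

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world affine centring world (0,0,0) on the grid centre."""
        aff = np.eye(4)
        for i in range(3):
            aff[i, i] = self.voxel_size[i]
            aff[i, 3] = -self.voxel_size[i] * (self.shape[i] - 1) / 2.0
        return aff


@dataclass
class PhantomSubject:
    """One generated subject: modality volumes + ground-truth masks on one grid."""

    subject_id: str
    site_id: str
    seed: int
    volumes: dict  # modality -> Volume3D
    masks: dict  # role in {WMH_GOLD, STROKE, BRAIN, VENTRICLE} -> LabelMask

    @property
    def brain(self) -> LabelMask:
        return self.masks["BRAIN"]

    @property
    def gold(self) -> LabelMask:
        return self.masks["WMH_GOLD"]

    @property
    def stroke(self) -> LabelMask:
        return self.masks["STROKE"]

    @property
    def ventricles(self) -> LabelMask:
        return self.masks["VENTRICLE"]


def _ellipsoid(shape, affine, center_mm, semiaxes_mm) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    world = [
        affine[i, i] * idx[i] + affine[i, 3] for i in range(3)
    ]  # diagonal affines only, which is all the generator produces
    acc = np.zeros(shape, dtype=float)
    for w, c, a in zip(world, center_mm, semiaxes_mm):
        acc += ((w - c) / a) ** 2
    return acc <= 1.0


def _sphere(shape, affine, center_vox, radius_mm, voxel_size) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    acc = np.zeros(shape, dtype=float)
    for i in range(3):
        acc += ((idx[i] - center_vox[i]) * voxel_size[i]) ** 2
    return acc <= radius_mm**2


def generate_subject(
    tissue: TissueModel,
    geom: LesionGeometry,
    site: SiteEffect,
    seed: int,
    subject_id: str | None = None,
    n_clusters: int | None = None,
) -> PhantomSubject:
    """Generate one phantom subject deterministically from ``seed``.

    Placement order: ventricles are fixed anatomy; the stroke sphere (if
    any) is rejection-sampled to lie inside the brain and clear of the
    ventricles; WMH cluster seeds are then drawn periventricular (within
    ``d_pv_mm`` of the ventricle surface) with probability
    ``periventricular_fraction``, otherwise deep, and each spherical blob
    is clipped against brain, ventricles and stroke so the mask
    disjointness invariants hold exactly.

    Raises
    ------
    GenerationError
        After 1000 failed placement attempts for any lesion.
    """
    rng = np.random.default_rng(seed)
    shape, affine = tuple(geom.shape), geom.affine
    vox = geom.voxel_size

    brain = _ellipsoid(shape, affine, (0.0, 0.0, 0.0), geom.brain_semiaxes_mm)
    vent = np.zeros(shape, dtype=bool)
    for c in geom.ventricle_centers_mm:
        vent |= _ellipsoid(shape, affine, c, geom.ventricle_semiaxes_mm)
    vent &= brain

    vent_mask = LabelMask(vent, affine, "VENTRICLE")
    dist_vent = distance_to_mask(vent_mask).data if vent.any() else None

    stroke = np.zeros(shape, dtype=bool)
    if geom.stroke_present:
        brain_idx = np.argwhere(brain & ~vent)
        for attempt in range(1000):
            center = brain_idx[rng.integers(len(brain_idx))]
            blob = _sphere(shape, affine, center, geom.stroke_radius_mm, vox)
            if (blob & ~brain).any() or (blob & vent).any():
                continue
            stroke = blob
            break
        else:
            raise GenerationError("could not place stroke lesion in 1000 attempts")

    n = geom.n_wmh_clusters if n_clusters is None else int(n_clusters)
    forbidden = vent | stroke | ~brain
    pv_pool = np.argwhere(
        brain & ~forbidden & (dist_vent > 0) & (dist_vent <= geom.d_pv_mm)
    )
    deep_pool = np.argwhere(brain & ~forbidden & (dist_vent > geom.d_pv_mm))
    wmh = np.zeros(shape, dtype=bool)
    for _ in range(n):
        placed = False
        for attempt in range(1000):
            use_pv = rng.random() < geom.periventricular_fraction
            pool = pv_pool if (use_pv and len(pv_pool)) else deep_pool
            if not len(pool):
                pool = pv_pool if len(pv_pool) else None
            if pool is None:
                break
            center = pool[rng.integers(len(pool))]
            radius = rng.uniform(*geom.wmh_radius_range_mm)
            blob = _sphere(shape, affine, center, radius, vox) & brain & ~vent & ~stroke
            if not blob.any():
                continue
            wmh |= blob
            placed = True
            break
        if not placed:
            raise GenerationError("could not place WMH cluster in 1000 attempts")

    mimic = np.zeros(shape, dtype=bool)
    if geom.n_mimic_clusters > 0:
        mimic_pool = np.argwhere(
            brain & ~vent & ~stroke & ~wmh & (dist_vent > geom.d_pv_mm)
        )
        for _ in range(geom.n_mimic_clusters):
            for attempt in range(1000):
                center = mimic_pool[rng.integers(len(mimic_pool))]
                radius = rng.uniform(*geom.mimic_radius_range_mm)
                blob = (
                    _sphere(shape, affine, center, radius, vox)
                    & brain & ~vent & ~stroke & ~wmh
                )
                if blob.any():
                    mimic |= blob
                    break
            else:
                raise GenerationError("could not place mimic cluster in 1000 attempts")

    labels = np.zeros(shape, dtype=np.uint8)
    # 0 bg, 1 parenchyma, 2 csf, 3 wmh, 4 stroke, 5 mimic
    labels[brain] = 1
    labels[vent] = 2
    labels[stroke] = 4
    labels[wmh] = 3
    labels[mimic] = 5

    volumes: dict[str, Volume3D] = {}
    class_order = ("background", "parenchyma", "csf", "wmh", "stroke", "mimic")
    for modality in tissue.modalities:
        img = np.zeros(shape, dtype=np.float64)
        for code, name in enumerate(class_order):
            # tissue models without an explicit mimic class reuse the WMH
            # means (a mimic is WMH-intensity tissue by definition)
            cls = tissue.means.get(name, tissue.means["wmh"])
            img[labels == code] = cls[modality]
        if tissue.smoothing_fwhm_mm > 0:
            sigma = [
                tissue.smoothing_fwhm_mm * _FWHM_TO_SIGMA / v for v in vox
            ]
            img = ndimage.gaussian_filter(img, sigma=sigma)
        img = site.gain * img + site.offset
        sd = site.noise_scale * tissue.noise_sd[modality]
        if sd > 0:
            img = img + rng.normal(0.0, sd, size=shape)
        volumes[modality] = Volume3D(img, affine, modality)

    masks = {
        "BRAIN": LabelMask(brain, affine, "BRAIN"),
        "VENTRICLE": vent_mask,
        "STROKE": LabelMask(stroke, affine, "STROKE"),
        "WMH_GOLD": LabelMask(wmh, affine, "WMH_GOLD"),
    }
    sid = subject_id if subject_id is not None else f"sub-{seed:05d}"
    return PhantomSubject(sid, site.site_id, seed, volumes, masks)


def generate_cohort(
    n: int,
    tissue: TissueModel | None = None,
    geom: LesionGeometry | None = None,
    site: SiteEffect | None = None,
    base_seed: int = 0,
) -> list[PhantomSubject]:
    """Generate ``n`` subjects with seeds ``base_seed .. base_seed+n-1``.

    Per-subject lesion count varies within ``n_wmh_clusters +/- n_wmh_jitter``
    (never below 1), drawn from the subject's own generator so each subject
    is reproducible in isolation from its seed alone.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    tissue = tissue or TissueModel()
    geom = geom or LesionGeometry()
    site = site or SiteEffect.identity()
    cohort = []
    for i in range(n):
        seed = base_seed + i
        jitter_rng = np.random.default_rng(seed)
        lo = max(1, geom.n_wmh_clusters - geom.n_wmh_jitter)
        hi = geom.n_wmh_clusters + geom.n_wmh_jitter
        n_clusters = int(jitter_rng.integers(lo, hi + 1))
        cohort.append(
            generate_subject(
                tissue, geom, site, seed,
                subject_id=f"{site.site_id}-sub-{i:03d}",
                n_clusters=n_clusters,
            )
        )
    return cohort


def write_cohort(cohort: list[PhantomSubject], out_dir: str | Path) -> Path:
    """Write each subject's NIfTI files plus a cohort manifest CSV.

    Returns the manifest path. Layout: ``<out>/<subject_id>/<name>.nii.gz``
    with one manifest row per subject listing ids, seed and file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    fieldnames = ["subject_id", "site_id", "seed"]
    file_keys: list[str] = []
    rows = []
    for sub in cohort:
        sub_dir = out_dir / sub.subject_id
        sub_dir.mkdir(exist_ok=True)
        row = {"subject_id": sub.subject_id, "site_id": sub.site_id, "seed": sub.seed}
        for modality, vol in sub.volumes.items():
            p = sub_dir / f"{modality}.nii.gz"
            write_volume(vol, p)
            row[modality] = str(p)
        for role, mask in sub.masks.items():
            p = sub_dir / f"{role}.nii.gz"
            write_volume(mask, p)
            row[role] = str(p)
        file_keys = [k for k in row if k not in fieldnames]
        rows.append(row)
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames + file_keys)
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def load_cohort(manifest: str | Path) -> list[PhantomSubject]:
    """Read a cohort written by :func:`write_cohort` back into memory."""
    from .volumes import read_mask, read_volume

    manifest = Path(manifest)
    cohort = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            volumes = {
                m: read_volume(row[m], m)
                for m in ("FLAIR", "T1", "T2")
                if row.get(m)
            }
            masks = {
                r: read_mask(row[r], r)
                for r in ("BRAIN", "VENTRICLE", "STROKE", "WMH_GOLD")
                if row.get(r)
            }
            cohort.append(
                PhantomSubject(
                    row["subject_id"], row["site_id"], int(row["seed"]), volumes, masks
                )
            )
    return cohort
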