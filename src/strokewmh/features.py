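"""Per-voxel feature construction and training-point sampling.

Feature vectors follow the k-NN voxel-classification recipe: normalized
modality intensities, optional cubic-patch local-average intensities (to
buffer against misregistration), and optional spatially weighted template
coordinates (because WMH lesions favour some locations, e.g. the
periventricular white matter, over others).

Column layout, fixed and fingerprinted::

    [intensity per modality]
    [patch mean per modality]          (if patch_size > 0)
    [sw * x, sw * y, sw * z]           (if spatial_weighting > 0)

Rows are the voxels of the effective brain mask in lexicographic
(C-order) voxel-index order, so the layout is deterministic.

Spatial columns are world coordinates divided by 100 mm before the
``sw`` multiplier is applied, so that with unit-normalized intensities
``sw = 1`` acts as a mild location prior and ``sw = 10`` a strong one —
``sw`` behaves as a linear scaling factor on how much location influences
neighbour distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import LabelMask, Volume3D, check_same_grid

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "SamplingConfig",
    "normalize_intensities",
    "extract_features",
    "sample_training_points",
    "ALL_LESION",
    "EQUAL_NONLESION",
]

#: sentinel: use every gold-mask voxel as a lesion training point
ALL_LESION = "all"
#: sentinel: match the non-lesion count to the drawn lesion count
EQUAL_NONLESION = "equal"

#: divisor applied to world mm coordinates before the sw multiplier
SPATIAL_SCALE_MM = 100.0


@dataclass(frozen=True)
class FeatureConfig:
    """Which features to build.

    Parameters
    ----------
    modalities : tuple of str
        Ordered subset of ("FLAIR", "T1", "T2"); FLAIR is mandatory.
    patch_size : int
        Side of the cubic local-averaging patch in voxels; 0 disables the
        patch columns. The tested grid is {0, 3, 6, 9}.
    spatial_weighting : float
        Scale on the (scaled) template coordinates; 0 drops the spatial
        columns entirely. The tested grid is {0, 1, 5, 10}.
    intensity_normalization : str
        "percentile_01_99" (clip to within-brain [q1, q99], map to [0,1]),
        "zscore" (within-brain standardization), or "none".
    """

    modalities: tuple[str, ...] = ("FLAIR", "T1")
    patch_size: int = 0
    spatial_weighting: float = 1.0
    intensity_normalization: str = "percentile_01_99"

    def __post_init__(self) -> None:
        if "FLAIR" not in self.modalities:
            raise ValueError("FLAIR must always be among the feature modalities")
        if self.patch_size < 0 or self.spatial_weighting < 0:
            raise ValueError("patch_size and spatial_weighting must be >= 0")
        if self.intensity_normalization not in ("percentile_01_99", "zscore", "none"):
            raise ValueError(
                f"unknown normalization {self.intensity_normalization!r}"
            )

    @property
    def n_columns(self) -> int:
        m = len(self.modalities)
        return m * (1 + (self.patch_size > 0)) + 3 * (self.spatial_weighting > 0)

    @property
    def column_names(self) -> tuple[str, ...]:
        cols = [f"int_{m}" for m in self.modalities]
        if self.patch_size > 0:
            cols += [f"patch{self.patch_size}_{m}" for m in self.modalities]
        if self.spatial_weighting > 0:
            cols += ["sw_x", "sw_y", "sw_z"]
        return tuple(cols)

    @property
    def fingerprint(self) -> str:
        return (
            f"mod={'+'.join(self.modalities)}|p={self.patch_size}"
            f"|sw={self.spatial_weighting:g}|norm={self.intensity_normalization}"
        )


@dataclass
class FeatureMatrix:
    """Per-voxel feature rows with back-pointers into the volume grid."""

    X: np.ndarray  # (n_voxels, n_columns) float64
    voxel_index: np.ndarray  # (n_voxels,) flat C-order indices, ascending
    shape: tuple[int, int, int]
    affine: np.ndarray
    fingerprint: str

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.voxel_index.shape[0]:
            raise ValueError("row count must match voxel_index length")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def rows_for_voxels(self, flat_indices: np.ndarray) -> np.ndarray:
        """Map flat voxel indices to row numbers (voxel_index is sorted)."""
        rows = np.searchsorted(self.voxel_index, flat_indices)
        if np.any(rows >= self.n_rows) or np.any(
            self.voxel_index[rows] != flat_indices
        ):
            raise KeyError("some voxels are outside the feature matrix domain")
        return rows


@dataclass(frozen=True)
class SamplingConfig:
    """Training-point sampling policy.

    ``location`` constrains where non-lesion points may come from:
    "any" (anywhere in the effective brain outside the WMH mask),
    "noborder" (additionally excluding the 1-voxel 26-neighbourhood
    border of the WMH mask), or "surround" (only that border shell).
    Counts may be integers, or the sentinels ``ALL_LESION`` /
    ``EQUAL_NONLESION``.
    """

    location: str = "any"
    n_lesion: int | str = 2000
    n_nonlesion: int | str = EQUAL_NONLESION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.location not in ("any", "noborder", "surround"):
            raise ValueError(f"unknown location policy {self.location!r}")
        for name, v in (("n_lesion", self.n_lesion), ("n_nonlesion", self.n_nonlesion)):
            if isinstance(v, str):
                ok = (name == "n_lesion" and v == ALL_LESION) or (
                    name == "n_nonlesion" and v == EQUAL_NONLESION
                )
                if not ok:
                    raise ValueError(f"bad sentinel for {name}: {v!r}")
            elif v < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def fingerprint(self) -> str:
        return (
            f"loc={self.location}|nles={self.n_lesion}|nnon={self.n_nonlesion}"
            f"|seed={self.seed}"
        )


# ---------------------------------------------------------------------------


def normalize_intensities(
    vol: Volume3D, brain: LabelMask, method: str = "percentile_01_99"
) -> Volume3D:
    """Normalize intensities within the brain mask; outside-brain voxels become 0.

    percentile_01_99
        Clip to the within-brain 1st/99th percentiles, then map that range
        linearly to [0, 1]. A constant image (q1 == q99) maps to 0.
    zscore
        ``(v - mean_brain) / sd_brain``; a zero within-brain standard
        deviation is a degenerate image and raises.
    """
    check_same_grid(vol, brain)
    if brain.empty():
        raise ValueError("brain mask is empty")
    vals = vol.data[brain.data]
    out = np.zeros_like(vol.data, dtype=np.float64)
    if method == "none":
        out[brain.data] = vals
    elif method == "percentile_01_99":
        q1, q99 = np.percentile(vals, [1.0, 99.0])
        if q99 > q1:
            out[brain.data] = (np.clip(vals, q1, q99) - q1) / (q99 - q1)
        # else: degenerate constant image -> all zeros, documented
    elif method == "zscore":
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0:
            raise ValueError("zscore normalization of a constant image is degenerate")
        out[brain.data] = (vals - mu) / sd
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return Volume3D(out, vol.affine, vol.modality)


def _masked_patch_mean(data: np.ndarray, mask: np.ndarray, p: int) -> np.ndarray:
    # Mean over the p^3 cube intersected with the mask. scipy's uniform
    # filter with an even size shifts the window one voxel toward the
    # origin side, which is the documented convention for even p.
    num = ndimage.uniform_filter(data * mask, size=p, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(mask.astype(np.float64), size=p, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = 0.0
    return out


def extract_features(
    volumes: dict[str, Volume3D],
    effective_brain: LabelMask,
    cfg: FeatureConfig,
) -> FeatureMatrix:
    """Build the feature matrix over every effective-brain voxel.

    ``effective_brain`` is the sampling/query domain — the brain mask with
    the stroke lesion already removed when input-masking is active.
    Intensities are normalized per the config *within this mask*; patch
    means average only over in-mask neighbours, so excluded (e.g. stroke)
    voxels never leak into features.
    """
    missing = [m for m in cfg.modalities if m not in volumes]
    if missing:
        raise ValueError(f"missing modality volume(s): {missing}")
    for m in cfg.modalities:
        check_same_grid(volumes[m], effective_brain)

    mask = effective_brain.data
    flat = np.flatnonzero(mask)  # C-order == lexicographic voxel index
    cols: list[np.ndarray] = []

    normed: dict[str, np.ndarray] = {}
    for m in cfg.modalities:
        nv = normalize_intensities(volumes[m], effective_brain, cfg.intensity_normalization)
        normed[m] = nv.data
        cols.append(nv.data.ravel()[flat])

    if cfg.patch_size > 0:
        for m in cfg.modalities:
            pm = _masked_patch_mean(normed[m], mask, cfg.patch_size)
            cols.append(pm.ravel()[flat])

    if cfg.spatial_weighting > 0:
        ijk = np.stack(np.unravel_index(flat, mask.shape), axis=1).astype(np.float64)
        world = effective_brain.world_coordinates(ijk)
        cols.append(cfg.spatial_weighting * world[:, 0] / SPATIAL_SCALE_MM)
        cols.append(cfg.spatial_weighting * world[:, 1] / SPATIAL_SCALE_MM)
        cols.append(cfg.spatial_weighting * world[:, 2] / SPATIAL_SCALE_MM)

    X = np.column_stack(cols) if cols else np.empty((flat.size, 0))
    return FeatureMatrix(
        X, flat, effective_brain.shape, effective_brain.affine, cfg.fingerprint
    )


def _border_shell(gold: np.ndarray) -> np.ndarray:
    """1-voxel 26-neighbourhood dilation of the gold mask, minus the mask."""
    struct = ndimage.generate_binary_structure(3, 3)
    return ndimage.binary_dilation(gold, structure=struct) & ~gold


def sample_training_points(
    gold: LabelMask,
    effective_brain: LabelMask,
    cfg: SamplingConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw lesion / non-lesion training voxels (flat indices, sorted).

    Lesion points are sampled uniformly without replacement from the gold
    mask restricted to the effective brain (``ALL_LESION`` takes every
    such voxel). The non-lesion candidate pool depends on the location
    policy; ``EQUAL_NONLESION`` matches the drawn lesion count. Asking for
    more points than a pool holds draws the whole pool and emits a
    warning rather than failing.
    """
    check_same_grid(gold, effective_brain)
    rng = np.random.default_rng(cfg.seed)

    gold_arr = gold.data & effective_brain.data
    lesion_pool = np.flatnonzero(gold_arr)
    border = _border_shell(gold_arr)
    if cfg.location == "any":
        nonlesion_arr = effective_brain.data & ~gold_arr
    elif cfg.location == "noborder":
        nonlesion_arr = effective_brain.data & ~gold_arr & ~border
    else:  # surround
        nonlesion_arr = effective_brain.data & border
    nonlesion_pool = np.flatnonzero(nonlesion_arr)

    def draw(pool: np.ndarray, n: int, what: str) -> np.ndarray:
        if n >= pool.size:
            if n > pool.size:
                warnings.warn(
                    f"requested {n} {what} training points but pool has only "
                    f"{pool.size}; using the whole pool",
                    stacklevel=3,
                )
            return np.sort(pool)
        return np.sort(rng.choice(pool, size=n, replace=False))

    if cfg.n_lesion == ALL_LESION:
        lesion = np.sort(lesion_pool)
    else:
        lesion = draw(lesion_pool, int(cfg.n_lesion), "lesion")

    n_non = lesion.size if cfg.n_nonlesion == EQUAL_NONLESION else int(cfg.n_nonlesion)
    nonlesion = draw(nonlesion_pool, n_non, "non-lesion")
    return lesion, nonlesion
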