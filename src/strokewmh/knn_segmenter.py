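"""Supervised k-NN voxel classification of white-matter hyperintensities.

Each query voxel's WMH probability is the fraction of its ``k`` nearest
labelled training feature vectors (Euclidean distance) carrying the WMH
label, so probabilities are exact multiples of ``1/k``. A fixed threshold
then binarizes the probability map.

Stroke lesions are handled in one of two modes:

``mask_input``
    The stroke is removed from the brain mask *before* feature extraction
    and training-point sampling, so infarcted tissue never contaminates
    the non-WMH training class and receives probability 0 at prediction.
``mask_output``
    The whole brain is classified, then the (optionally mm-dilated)
    stroke mask is zeroed out of both the probability map and the final
    mask.

In both modes the final segmentation never intersects the stroke mask.

Exactness: neighbour search runs through scikit-learn's tree/brute
backends, which return true Euclidean nearest neighbours; equal-distance
ties are resolved toward the lower training-row index via a stable
re-sort (with a brute-force fallback for tie blocks extending past the
search window), so outputs are reproducible across platforms and
invariant to training-row permutations in the absence of ties.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .features import (
    FeatureConfig,
    FeatureMatrix,
    SamplingConfig,
    extract_features,
    sample_training_points,
)
from .volumes import LabelMask, Volume3D, check_same_grid, dilate_mask

__all__ = [
    "KnnModel",
    "SegmentationSettings",
    "UnfitModelError",
    "fit",
    "predict_probability",
    "binarize",
    "segment_subject",
    "knn_probabilities",
]

#: probability thresholds tested by the optimization experiments
DEFAULT_TAU_GRID = (0.8, 0.85, 0.9, 0.95, 0.99)


class UnfitModelError(RuntimeError):
    """No usable training data (e.g. zero lesion voxels in the cohort)."""


@dataclass(frozen=True)
class SegmentationSettings:
    """Everything that defines one segmentation configuration.

    ``k`` is the neighbour count (not part of the optimization grid),
    ``tau`` the probability threshold (comparison is >=), and
    ``stroke_mode`` selects input- vs output-masking of the stroke
    lesion; ``output_dilation_mm`` dilates the stroke mask before output
    removal (mask_output mode only).
    """

    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    sampling_config: SamplingConfig = field(default_factory=SamplingConfig)
    k: int = 40
    tau: float = 0.85
    stroke_mode: str = "mask_input"
    output_dilation_mm: float = 0.0
    threshold_mode: str = "fixed"  # "fixed" | "adaptive"

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.stroke_mode not in ("mask_input", "mask_output"):
            raise ValueError(f"unknown stroke_mode {self.stroke_mode!r}")
        if self.output_dilation_mm < 0:
            raise ValueError("output_dilation_mm must be >= 0")
        if self.threshold_mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")

    @property
    def fingerprint(self) -> str:
        return (
            f"{self.feature_config.fingerprint}|{self.sampling_config.fingerprint}"
            f"|k={self.k}|tau={self.tau:g}|stroke={self.stroke_mode}"
            f"|dil={self.output_dilation_mm:g}"
        )

    def with_(self, **kwargs) -> "SegmentationSettings":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class KnnModel:
    """Labelled training vectors + k, with provenance for auditability."""

    X: np.ndarray  # (n_train, n_features)
    y: np.ndarray  # (n_train,) 1 = WMH, 0 = non-WMH
    k: int
    fingerprint: str  # feature-config fingerprint the query must match
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.k <= len(self.X):
            raise ValueError("k must satisfy 1 <= k <= number of training rows")

    @property
    def n_rows(self) -> int:
        return len(self.X)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "KnnModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a KnnModel")
        return model


def effective_brain_mask(subject, settings: SegmentationSettings) -> LabelMask:
    """The feature/sampling domain: brain minus stroke in mask_input mode."""
    brain = subject.masks["BRAIN"]
    stroke = subject.masks.get("STROKE")
    if settings.stroke_mode == "mask_input" and stroke is not None and not stroke.empty():
        return LabelMask(brain.data & ~stroke.data, brain.affine, "BRAIN")
    return LabelMask(brain.data.copy(), brain.affine, "BRAIN")


def fit(
    training_subjects,
    settings: SegmentationSettings,
    feature_cache: dict | None = None,
) -> KnnModel:
    """Build a k-NN model from labelled training subjects.

    Per subject: extract features over the effective brain, sample
    lesion / non-lesion training voxels per the sampling policy (the
    per-subject sampling seed is the config seed plus the subject's
    position, so cohorts are reproducible), and stack the rows. In
    ``mask_input`` mode stroke voxels are outside the effective brain and
    can never be sampled.

    ``feature_cache`` maps ``(subject_id, feature fingerprint, stroke_mode)``
    to a precomputed FeatureMatrix; the leave-one-out driver uses it to
    avoid re-extracting features for every fold.
    """
    if not training_subjects:
        raise UnfitModelError("at least one training subject is required")
    rows, labels = [], []
    sub_ids = []
    for i, sub in enumerate(training_subjects):
        gold = sub.masks.get("WMH_GOLD")
        if gold is None:
            raise ValueError(f"subject {sub.subject_id} has no gold-standard WMH mask")
        eff = effective_brain_mask(sub, settings)
        fm = _features_for(sub, eff, settings, feature_cache)
        scfg = replace(
            settings.sampling_config, seed=settings.sampling_config.seed + i
        )
        lesion, nonlesion = sample_training_points(gold, eff, scfg)
        if lesion.size:
            rows.append(fm.X[fm.rows_for_voxels(lesion)])
            labels.append(np.ones(lesion.size, dtype=np.int8))
        if nonlesion.size:
            rows.append(fm.X[fm.rows_for_voxels(nonlesion)])
            labels.append(np.zeros(nonlesion.size, dtype=np.int8))
        sub_ids.append(sub.subject_id)
    X = np.concatenate(rows) if rows else np.empty((0, settings.feature_config.n_columns))
    y = np.concatenate(labels) if labels else np.empty((0,), dtype=np.int8)
    if not np.any(y == 1):
        raise UnfitModelError("no lesion voxels anywhere in the training cohort")
    return KnnModel(
        X, y, settings.k, settings.feature_config.fingerprint,
        provenance={
            "subjects": sub_ids,
            "sampling": settings.sampling_config.fingerprint,
            "stroke_mode": settings.stroke_mode,
        },
    )


def _features_for(sub, eff: LabelMask, settings, cache: dict | None) -> FeatureMatrix:
    if cache is None:
        return extract_features(sub.volumes, eff, settings.feature_config)
    key = (
        sub.subject_id,
        getattr(sub, "seed", None),
        settings.feature_config.fingerprint,
        settings.stroke_mode,
    )
    if key not in cache:
        cache[key] = extract_features(sub.volumes, eff, settings.feature_config)
    return cache[key]


# ---------------------------------------------------------------------------
# Core k-NN


def _brute_row(train_X, query_row, k):
    d2 = np.einsum("ij,ij->i", train_X - query_row, train_X - query_row)
    order = np.lexsort((np.arange(len(train_X)), np.sqrt(d2)))
    return order[:k]


def knn_probabilities(
    train_X: np.ndarray, labels: np.ndarray, query_X: np.ndarray, k: int
) -> np.ndarray:
    """WMH probability per query row: (#WMH among k nearest) / k.

    Exact Euclidean nearest neighbours; equal-distance ties break toward
    the lower training-row index.
    """
    n_train = len(train_X)
    if not 1 <= k <= n_train:
        raise ValueError("k must satisfy 1 <= k <= number of training rows")
    if query_X.shape[1] != train_X.shape[1]:
        raise ValueError("query feature count does not match training features")
    if len(query_X) == 0:
        return np.empty((0,))

    labels = np.asarray(labels, dtype=np.float64)
    kn = min(k + 1, n_train)
    nn = NearestNeighbors(n_neighbors=kn).fit(train_X)
    dist, ind = nn.kneighbors(query_X)
    out = labels[ind[:, :k]].mean(axis=1)

    if kn > k:
        # Only the composition of the first k matters for the probability,
        # so ties are a concern solely when the k-th and (k+1)-th distances
        # coincide; those rare rows are re-resolved exhaustively with the
        # stable (distance, index) order.
        tied = np.flatnonzero(dist[:, k] <= dist[:, k - 1])
        for r in tied:
            out[r] = labels[_brute_row(train_X, query_X[r], k)].mean()
    return out


def predict_probability(model: KnnModel, query: FeatureMatrix) -> Volume3D:
    """Classify every query voxel; returns a probability map (0 outside the domain)."""
    if query.fingerprint != model.fingerprint:
        raise ValueError(
            f"feature mismatch: query {query.fingerprint!r} vs model {model.fingerprint!r}"
        )
    p = knn_probabilities(model.X, model.y, query.X, model.k)
    out = np.zeros(query.shape, dtype=np.float64)
    out.ravel()[query.voxel_index] = p
    return Volume3D(out, query.affine, "PROB")


def binarize(prob: Volume3D, tau: float) -> LabelMask:
    """Threshold a probability map: mask = (p >= tau)."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    return LabelMask(prob.data >= tau, prob.affine, "WMH_AUTO")


def segment_subject(
    model: KnnModel,
    subject,
    settings: SegmentationSettings,
    feature_cache: dict | None = None,
) -> tuple[Volume3D, LabelMask]:
    """Segment one subject: probability map + binary WMH mask.

    mask_input: stroke voxels are excluded from the query domain, so they
    carry probability 0. mask_output: the full brain is classified, then
    voxels inside ``dilate(stroke, output_dilation_mm)`` are zeroed in
    both outputs. Either way the returned mask is stroke-free. An empty
    stroke mask makes the two modes identical.
    """
    stroke = subject.masks.get("STROKE")
    if stroke is None:
        raise ValueError(
            f"subject {subject.subject_id}: stroke mask required (may be empty)"
        )
    brain = subject.masks["BRAIN"]
    check_same_grid(brain, stroke)

    eff = effective_brain_mask(subject, settings)
    fm = _features_for(subject, eff, settings, feature_cache)
    prob = predict_probability(model, fm)
    mask = binarize(prob, settings.tau)

    if settings.stroke_mode == "mask_output" and not stroke.empty():
        removal = dilate_mask(stroke, settings.output_dilation_mm)
        prob.data[removal.data] = 0.0
        mask = LabelMask(mask.data & ~removal.data, mask.affine, "WMH_AUTO")
    # contract: never intersect the stroke mask, either mode
    assert not (mask.data & stroke.data).any()
    return prob, mask
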