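"""Unsupervised Gaussian-mixture lesion segmentation.

A contrast-based baseline in the spirit of whole-brain generative tissue
segmenters: voxel intensity vectors within the brain mask are modelled as
a K-component Gaussian mixture fitted per subject by EM, the lesion class
is identified transparently as the component with the highest FLAIR mean
(WMH is FLAIR-hyperintense by definition), its responsibility becomes the
lesion probability map, and a posterior threshold produces the mask. The
stroke lesion is removed from the *output* only — there is no input
masking step, mirroring how unsupervised pipelines are typically run.

Because the mixture is refitted to each subject's own intensities, the
method is inherently robust to between-site gain/offset shifts — the
property the cross-site experiments probe.

This is a plain mixture model: no deformable atlas, no mesh priors, no
scan-adaptive hyperparameters. EM is implemented directly (diagonal
covariances, k-means initialization, variance flooring at 1e-6 of the
per-feature data variance) so the per-iteration log-likelihood trace is
available; monotone non-decrease of that trace is asserted in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .volumes import LabelMask, Volume3D, check_same_grid

__all__ = [
    "GmmParams",
    "FittedGmm",
    "fit_gmm",
    "lesion_probability",
    "segment_unsupervised",
    "DEFAULT_GMM_TAU_GRID",
]

#: posterior thresholds swept by the experiments; 0.1 is the optimized default
DEFAULT_GMM_TAU_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
DEFAULT_GMM_TAU = 0.1


@dataclass(frozen=True)
class GmmParams:
    """Mixture configuration: K classes over per-voxel intensity vectors."""

    n_classes: int = 4
    max_iters: int = 200
    tol: float = 1e-6  # relative change of mean log-likelihood
    variance_floor_frac: float = 1e-6  # of per-feature data variance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")


@dataclass
class FittedGmm:
    """Fitted mixture: means (K, d), diagonal variances (K, d), weights (K,)."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    modalities: tuple[str, ...]
    loglik_trace: np.ndarray  # mean log-likelihood per EM iteration
    converged: bool
    floored: bool  # any variance hit the floor

    @property
    def n_classes(self) -> int:
        return len(self.weights)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "means": self.means.tolist(),
                    "variances": self.variances.tolist(),
                    "weights": self.weights.tolist(),
                    "modalities": list(self.modalities),
                    "converged": self.converged,
                }
            )
        )


def _log_gauss_diag(X, means, variances, weights):
    """(n, K) joint log density log(pi_k) + log N(x; mu_k, diag sigma2_k)."""
    n, d = X.shape
    out = np.empty((n, len(weights)))
    for k in range(len(weights)):
        diff2 = (X - means[k]) ** 2 / variances[k]
        out[:, k] = (
            np.log(weights[k])
            - 0.5 * (d * np.log(2 * np.pi) + np.sum(np.log(variances[k])))
            - 0.5 * diff2.sum(axis=1)
        )
    return out


def fit_gmm(
    X: np.ndarray,
    params: GmmParams = GmmParams(),
    modalities: tuple[str, ...] = (),
) -> tuple[FittedGmm, np.ndarray]:
    """EM fit of a diagonal-covariance Gaussian mixture.

    Parameters
    ----------
    X : ndarray (n_voxels, n_modalities)
        Intensity vectors within the brain mask.
    params : GmmParams
    modalities : tuple of str
        Column names of ``X`` (needed by the lesion rule).

    Returns
    -------
    fitted : FittedGmm
    responsibilities : ndarray (n_voxels, K), rows summing to 1.

    K-means (seeded) initializes the component means; EM then alternates
    responsibilities / parameter updates until the relative change of the
    mean log-likelihood drops below ``tol`` or ``max_iters`` is reached.
    Collapsing components have their variances floored with a flag rather
    than failing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty (n, d) array")
    n, d = X.shape
    K = params.n_classes
    if len(np.unique(X, axis=0)) < K:
        raise ValueError(f"need at least {K} distinct intensity vectors")

    data_var = X.var(axis=0)
    floor = params.variance_floor_frac * np.where(data_var > 0, data_var, 1.0)

    if K == 1:
        means = X.mean(axis=0, keepdims=True)
        variances = np.maximum(X.var(axis=0, keepdims=True), floor)
        weights = np.ones(1)
        resp = np.ones((n, 1))
        ll = float(_log_gauss_diag(X, means, variances, weights).mean())
        fitted = FittedGmm(
            means, variances, weights, tuple(modalities),
            np.array([ll]), True, bool(np.any(X.var(axis=0) < floor)),
        )
        return fitted, resp

    km = KMeans(n_clusters=K, n_init=1, random_state=params.seed).fit(X)
    means = km.cluster_centers_.copy()
    variances = np.tile(np.maximum(data_var, floor), (K, 1))
    counts = np.bincount(km.labels_, minlength=K).astype(float)
    weights = np.maximum(counts, 1.0)
    weights /= weights.sum()

    trace = []
    floored = False
    converged = False
    prev_ll = -np.inf
    resp = np.full((n, K), 1.0 / K)
    for _ in range(params.max_iters):
        # E step
        logp = _log_gauss_diag(X, means, variances, weights)
        m = logp.max(axis=1, keepdims=True)
        logsum = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        resp = np.exp(logp - logsum[:, None])
        ll = float(logsum.mean())
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= params.tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for k in range(K):
            diff2 = (X - means[k]) ** 2
            var_k = (resp[:, k] @ diff2) / nk[k]
            if np.any(var_k < floor):
                floored = True
            variances[k] = np.maximum(var_k, floor)

    fitted = FittedGmm(
        means, variances, weights, tuple(modalities),
        np.asarray(trace), converged, floored,
    )
    return fitted, resp


def lesion_class_index(fitted: FittedGmm, rule: str = "highest_flair_mean",
                       manual_index: int | None = None) -> int:
    """Identify the lesion component.

    ``highest_flair_mean`` (default): the component whose FLAIR-channel
    mean is largest. ``manual_class_index``: caller-specified.
    """
    if rule == "manual_class_index":
        if manual_index is None or not 0 <= manual_index < fitted.n_classes:
            raise ValueError("manual_class_index requires a valid class index")
        return int(manual_index)
    if rule != "highest_flair_mean":
        raise ValueError(f"unknown lesion rule {rule!r}")
    if "FLAIR" not in fitted.modalities:
        raise ValueError("highest_flair_mean rule requires a FLAIR channel")
    flair_col = fitted.modalities.index("FLAIR")
    return int(np.argmax(fitted.means[:, flair_col]))


def lesion_probability(
    fitted: FittedGmm,
    resp: np.ndarray,
    brain: LabelMask,
    rule: str = "highest_flair_mean",
    manual_index: int | None = None,
) -> Volume3D:
    """Map the lesion component's responsibility back onto the grid."""
    k = lesion_class_index(fitted, rule, manual_index)
    out = np.zeros(brain.shape, dtype=np.float64)
    out[brain.data] = resp[:, k]
    return Volume3D(out, brain.affine, "PROB")


def segment_unsupervised(
    subject,
    params: GmmParams = GmmParams(),
    tau: float = DEFAULT_GMM_TAU,
    rule: str = "highest_flair_mean",
    modalities: tuple[str, ...] = ("FLAIR", "T1"),
) -> tuple[Volume3D, LabelMask, FittedGmm]:
    """Per-subject unsupervised segmentation with output stroke removal.

    Fits the mixture to the subject's own within-brain intensity vectors
    (raw units — EM adapts to whatever scale the site produced), takes
    the lesion-class posterior, thresholds at ``tau`` and finally deletes
    stroke voxels from both map and mask.
    """
    brain = subject.masks["BRAIN"]
    stroke = subject.masks.get("STROKE")
    use = tuple(m for m in modalities if m in subject.volumes)
    if "FLAIR" not in use:
        raise ValueError("FLAIR volume is required")
    for m in use:
        check_same_grid(subject.volumes[m], brain)
    X = np.column_stack([subject.volumes[m].data[brain.data] for m in use])
    fitted, resp = fit_gmm(X, params, use)
    prob = lesion_probability(fitted, resp, brain, rule)
    mask = LabelMask(prob.data >= tau, brain.affine, "WMH_AUTO")
    if stroke is not None and not stroke.empty():
        check_same_grid(brain, stroke)
        prob.data[stroke.data] = 0.0
        mask = LabelMask(mask.data & ~stroke.data, mask.affine, "WMH_AUTO")
    return prob, mask, fitted
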