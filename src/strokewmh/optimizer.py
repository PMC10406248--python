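"""Settings optimization and validation experiments.

The experimental engine around the supervised segmenter:

* :func:`loo_score` — leave-one-out cross-validation of one settings
  configuration over a training cohort, scored with the full metric
  suite; the key triple is (SI, ICC, FNRc): overlap, volumetric
  agreement, and cluster-level sensitivity.
* :func:`select_best` — the 2/3-metric dominance rule: a configuration
  wins if it is at least as good as every rival on >= 2 of the 3 key
  metrics (SI and ICC higher is better, FNRc lower). Dominance cycles
  are possible; the documented fallback is highest SI, flagged.
* :func:`phased_optimize` — one-factor-at-a-time coordinate search:
  each phase varies one settings dimension at a time around the current
  best (modalities, spatial weighting, patch, training-point location,
  training-point counts, then threshold), adopting per-dimension
  winners, until a full phase changes nothing.
* :func:`cross_site_experiment` — same-site (80/20 split), cross-site,
  and mixed-sample supervised arms plus the unsupervised GMM arm, all
  scored identically, probing how a supervised voxel classifier degrades
  under between-site intensity shifts while a per-subject unsupervised
  fit does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import knn_segmenter as knn
from .features import ALL_LESION, EQUAL_NONLESION
from .gmm_segmenter import DEFAULT_GMM_TAU, GmmParams, segment_unsupervised
from .knn_segmenter import SegmentationSettings
from .metrics import CohortReport, cohort_report

__all__ = [
    "SettingsGrid",
    "PhaseResult",
    "loo_score",
    "select_best",
    "phased_optimize",
    "cross_site_experiment",
]


@dataclass(frozen=True)
class SettingsGrid:
    """Option lists for each user-settings dimension.

    ``points_options`` holds (n_lesion, n_nonlesion) pairs; the sentinels
    from :mod:`strokewmh.features` express "all lesion voxels" and
    "equal non-lesion count". ``extended_nonlesion`` appends the larger
    non-lesion counts swept in the follow-up extension (10k..58k with
    2000 lesion points).
    """

    modalities_options: tuple = (("FLAIR", "T1"), ("FLAIR", "T1", "T2"))
    sw_options: tuple = (0.0, 1.0, 5.0, 10.0)
    patch_options: tuple = (0, 3, 6, 9)
    location_options: tuple = ("any", "noborder", "surround")
    points_options: tuple = (
        (ALL_LESION, EQUAL_NONLESION),
        (2000, 2000),
        (2000, 10000),
    )
    tau_options: tuple = knn.DEFAULT_TAU_GRID
    extended_nonlesion: bool = False
    dims: tuple = ("modalities", "sw", "patch", "location", "points", "tau")

    def options(self, dim: str) -> tuple:
        if dim == "points" and self.extended_nonlesion:
            return self.points_options + tuple(
                (2000, n) for n in (10000, 20000, 40000, 58000)
            )
        return {
            "modalities": self.modalities_options,
            "sw": self.sw_options,
            "patch": self.patch_options,
            "location": self.location_options,
            "points": self.points_options,
            "tau": self.tau_options,
        }[dim]

    def contains(self, settings: SegmentationSettings) -> bool:
        return all(
            _get_dim(settings, d) in self.options(d) for d in self.dims
        )


def _get_dim(s: SegmentationSettings, dim: str):
    if dim == "modalities":
        return s.feature_config.modalities
    if dim == "sw":
        return s.feature_config.spatial_weighting
    if dim == "patch":
        return s.feature_config.patch_size
    if dim == "location":
        return s.sampling_config.location
    if dim == "points":
        return (s.sampling_config.n_lesion, s.sampling_config.n_nonlesion)
    if dim == "tau":
        return s.tau
    raise KeyError(dim)


def _set_dim(s: SegmentationSettings, dim: str, value) -> SegmentationSettings:
    if dim == "modalities":
        return s.with_(feature_config=s.feature_config.__class__(
            modalities=tuple(value),
            patch_size=s.feature_config.patch_size,
            spatial_weighting=s.feature_config.spatial_weighting,
            intensity_normalization=s.feature_config.intensity_normalization,
        ))
    if dim == "sw":
        fc = s.feature_config
        return s.with_(feature_config=fc.__class__(
            modalities=fc.modalities, patch_size=fc.patch_size,
            spatial_weighting=float(value),
            intensity_normalization=fc.intensity_normalization,
        ))
    if dim == "patch":
        fc = s.feature_config
        return s.with_(feature_config=fc.__class__(
            modalities=fc.modalities, patch_size=int(value),
            spatial_weighting=fc.spatial_weighting,
            intensity_normalization=fc.intensity_normalization,
        ))
    if dim == "location":
        sc = s.sampling_config
        return s.with_(sampling_config=sc.__class__(
            location=value, n_lesion=sc.n_lesion,
            n_nonlesion=sc.n_nonlesion, seed=sc.seed,
        ))
    if dim == "points":
        sc = s.sampling_config
        n_les, n_non = value
        return s.with_(sampling_config=sc.__class__(
            location=sc.location, n_lesion=n_les, n_nonlesion=n_non, seed=sc.seed,
        ))
    if dim == "tau":
        return s.with_(tau=float(value))
    raise KeyError(dim)


def loo_score(
    cohort,
    settings: SegmentationSettings,
    feature_cache: dict | None = None,
    connectivity: int = 26,
) -> tuple[dict, CohortReport]:
    """Leave-one-out cross-validation of one configuration.

    For each subject: fit the k-NN model on the rest, segment the
    held-out subject, score against its gold mask. Returns the key-metric
    summary ``{"SI", "ICC", "FNRc"}`` (cohort means; ICC over the LOO
    volume pairs) and the full report. Deterministic given the settings'
    seeds.
    """
    cohort = list(cohort)
    if len(cohort) < 3:
        raise ValueError("LOO scoring needs at least 3 subjects (ICC requires 3 pairs)")
    for sub in cohort:
        if "WMH_GOLD" not in sub.masks:
            raise ValueError(f"subject {sub.subject_id} is missing its gold mask")
    if feature_cache is None:
        feature_cache = {}
    pairs, ids = [], []
    for i, held_out in enumerate(cohort):
        train = cohort[:i] + cohort[i + 1:]
        model = knn.fit(train, settings, feature_cache)
        _, auto = knn.segment_subject(model, held_out, settings, feature_cache)
        pairs.append((held_out.gold, auto))
        ids.append(held_out.subject_id)
    report = cohort_report(pairs, ids, connectivity)
    summary = {
        "SI": report.means["SI"],
        "ICC": report.icc,
        "FNRc": report.means["FNRc"],
    }
    return summary, report


def _beats(x: dict, y: dict) -> bool:
    """x dominates y under the 2/3 rule (SI up, ICC up, FNRc down).

    Strict wins decide: x dominates with >= 2 strict wins, or with 1
    strict win and ties elsewhere. This is antisymmetric, so two
    configurations can never dominate each other.
    """
    sx = (x["SI"] > y["SI"]) + (x["ICC"] > y["ICC"]) + (x["FNRc"] < y["FNRc"])
    sy = (y["SI"] > x["SI"]) + (y["ICC"] > x["ICC"]) + (y["FNRc"] < x["FNRc"])
    return sx >= 2 or (sx == 1 and sy == 0)


def select_best(scored: list[tuple]) -> tuple[int, dict]:
    """Pick the winner under the 2/3-metric dominance rule.

    Parameters
    ----------
    scored : list of (label, summary)
        ``summary`` must carry finite SI, ICC, FNRc.

    Returns
    -------
    index : int
        Winner's position in the input list.
    info : dict
        ``{"rule": "dominance" | "si_fallback", "all_identical": bool}``.

    The winner must beat every rival on at least 2 of the 3 metrics
    (ties count in its favour). If a dominance cycle leaves no such
    configuration, the highest SI wins — flagged in the phase log. Order
    among exact co-winners resolves to the first listed.
    """
    if len(scored) < 1:
        raise ValueError("select_best needs at least one configuration")
    summaries = [s for _, s in scored]
    for s in summaries:
        if any(not np.isfinite(s[m]) for m in ("SI", "ICC", "FNRc")):
            raise ValueError("select_best requires finite SI, ICC, FNRc")
    all_identical = all(
        s["SI"] == summaries[0]["SI"]
        and s["ICC"] == summaries[0]["ICC"]
        and s["FNRc"] == summaries[0]["FNRc"]
        for s in summaries
    )
    if all_identical and len(summaries) > 1:
        warnings.warn("all configurations scored identically; keeping the first",
                      stacklevel=2)
        return 0, {"rule": "dominance", "all_identical": True}
    for i, si in enumerate(summaries):
        if all(_beats(si, sj) for j, sj in enumerate(summaries) if j != i):
            return i, {"rule": "dominance", "all_identical": False}
    best = int(np.argmax([s["SI"] for s in summaries]))
    return best, {"rule": "si_fallback", "all_identical": False}


@dataclass
class PhaseResult:
    """Audit record of one optimization phase."""

    phase: int
    evaluations: list = field(default_factory=list)  # (dim, option, summary)
    winners: dict = field(default_factory=dict)  # dim -> (option, info)
    settings_after: SegmentationSettings | None = None
    changed: bool = False


def phased_optimize(
    cohort,
    grid: SettingsGrid,
    start: SegmentationSettings | None = None,
    max_phases: int = 4,
    feature_cache: dict | None = None,
) -> tuple[SegmentationSettings, list[PhaseResult], bool]:
    """One-factor-at-a-time coordinate search over the settings grid.

    Each phase walks the grid dimensions in order; for each it scores
    every option (others held at the incumbent) by LOO and adopts the
    2/3-rule winner before moving on. The search stops when a full phase
    adopts no change, or after ``max_phases`` phases (returning the best
    so far with ``converged=False``). LOO results are cached by settings
    fingerprint, so unchanged configurations are never recomputed.
    """
    current = start if start is not None else SegmentationSettings()
    if not grid.contains(current):
        raise ValueError("the starting settings must be a member of the grid")
    if feature_cache is None:
        feature_cache = {}
    loo_cache: dict[str, dict] = {}

    def scored(settings: SegmentationSettings) -> dict:
        key = settings.fingerprint
        if key not in loo_cache:
            loo_cache[key], _ = loo_score(cohort, settings, feature_cache)
        return loo_cache[key]

    trail: list[PhaseResult] = []
    converged = False
    for phase in range(1, max_phases + 1):
        result = PhaseResult(phase=phase)
        changed = False
        for dim in grid.dims:
            options = grid.options(dim)
            if len(options) == 1:
                continue
            candidates = [(_get_dim(current, dim) == opt, opt,
                           _set_dim(current, dim, opt)) for opt in options]
            entries = []
            for _, opt, settings in candidates:
                summary = scored(settings)
                entries.append((opt, summary))
                result.evaluations.append((dim, opt, summary))
            idx, info = select_best(entries)
            win_opt = entries[idx][0]
            result.winners[dim] = (win_opt, info)
            if win_opt != _get_dim(current, dim):
                current = _set_dim(current, dim, win_opt)
                changed = True
        result.settings_after = current
        result.changed = changed
        trail.append(result)
        if not changed:
            converged = True
            break
    return current, trail, converged


def _split(cohort, rng, train_frac: float = 0.8):
    n = len(cohort)
    n_train = int(round(train_frac * n))
    if not 1 <= n_train < n:
        raise ValueError(f"cohort of {n} subjects is too small for an 80/20 split")
    order = rng.permutation(n)
    train = [cohort[i] for i in order[:n_train]]
    test = [cohort[i] for i in order[n_train:]]
    return train, test


def _score_arm(model, subjects, settings, feature_cache) -> CohortReport:
    pairs, ids = [], []
    for sub in subjects:
        _, auto = knn.segment_subject(model, sub, settings, feature_cache)
        pairs.append((sub.gold, auto))
        ids.append(sub.subject_id)
    return cohort_report(pairs, ids)


def cross_site_experiment(
    cohort_a,
    cohort_b,
    settings: SegmentationSettings,
    seed: int = 0,
    gmm_params: GmmParams | None = None,
    gmm_tau: float = DEFAULT_GMM_TAU,
    feature_cache: dict | None = None,
) -> dict:
    """Same-site / cross-site / mixed-sample validation, plus the GMM arm.

    Arms (identical settings throughout):

    * ``same_site_A`` — train on 80% of site A, test on the held-out 20%.
    * ``same_site_B`` — likewise within site B.
    * ``cross_site_A_to_B`` — the site-A model applied to site B's test set.
    * ``mixed`` — train on an equal random half-split drawn from both
      sites' training subjects, test on the union of both test sets.
    * ``gmm_A`` / ``gmm_B`` — the unsupervised mixture segmenter on each
      test set (no training data by construction).

    Returns ``{"reports": {arm: CohortReport}, "mean_si": {arm: float}}``.
    """
    cohort_a, cohort_b = list(cohort_a), list(cohort_b)
    if len(cohort_a) < 4 or len(cohort_b) < 4:
        raise ValueError("each cohort needs at least 4 subjects for an 80/20 split")
    if feature_cache is None:
        feature_cache = {}
    rng = np.random.default_rng(seed)
    train_a, test_a = _split(cohort_a, rng)
    train_b, test_b = _split(cohort_b, rng)

    model_a = knn.fit(train_a, settings, feature_cache)
    model_b = knn.fit(train_b, settings, feature_cache)

    n_mix = max(1, min(len(train_a), len(train_b)) // 2)
    pick_a = [train_a[i] for i in rng.choice(len(train_a), n_mix, replace=False)]
    pick_b = [train_b[i] for i in rng.choice(len(train_b), n_mix, replace=False)]
    model_mixed = knn.fit(pick_a + pick_b, settings, feature_cache)

    reports = {
        "same_site_A": _score_arm(model_a, test_a, settings, feature_cache),
        "same_site_B": _score_arm(model_b, test_b, settings, feature_cache),
        "cross_site_A_to_B": _score_arm(model_a, test_b, settings, feature_cache),
        "mixed": _score_arm(model_mixed, test_a + test_b, settings, feature_cache),
    }

    gmm_params = gmm_params or GmmParams()
    for arm, subjects in (("gmm_A", test_a), ("gmm_B", test_b)):
        pairs, ids = [], []
        for sub in subjects:
            _, mask, _ = segment_unsupervised(
                sub, gmm_params, gmm_tau,
                modalities=settings.feature_config.modalities,
            )
            pairs.append((sub.gold, mask))
            ids.append(sub.subject_id)
        reports[arm] = cohort_report(pairs, ids)

    mean_si = {arm: rep.means["SI"] for arm, rep in reports.items()}
    return {"reports": reports, "mean_si": mean_si}
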