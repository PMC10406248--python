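"""Lesion segmentation scoring: voxel, cluster and volumetric agreement.

Compares an automated WMH mask ``A`` against a gold-standard mask ``G``:

Voxel level
    With TP = |G ∩ A|, FP = |A \\ G|, FN = |G \\ A|:
    SI (Dice) = 2TP / (2TP + FP + FN), FDR = FP / |A|, FNR = FN / |G|.

Cluster level (connected components, 26-connectivity by default;
"overlap" between clusters means at least one shared voxel)
    FDRc = fraction of A-clusters with no G overlap;
    FNRc = fraction of G-clusters with no A overlap;
    with MTA = (|G| + |A|) / 2, DER = (voxels in all zero-overlap
    clusters of G and of A) / MTA (detection error) and OER = (voxels of
    overlapping clusters lying outside G ∩ A) / MTA (outline error).

Volumetric agreement
    ICC(A,1): two-way random effects, absolute agreement, single
    measure, over paired per-subject lesion volumes in mm³.

Metrics that are undefined for a subject (empty A or empty G) are
recorded as NaN with a flag and excluded from cohort means — silently
scoring them as zero would bias the means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import LabelMask, check_same_grid, connected_components

__all__ = [
    "SubjectScore",
    "CohortReport",
    "voxel_metrics",
    "cluster_metrics",
    "icc_agreement",
    "score_subject",
    "cohort_report",
    "METRIC_COLUMNS",
]

#: report column order
METRIC_COLUMNS = ("SI", "FDR", "FNR", "FDRc", "FNRc", "DER", "OER")


@dataclass
class SubjectScore:
    """All per-subject metrics plus the two lesion volumes (mm³)."""

    subject_id: str
    SI: float
    FDR: float
    FNR: float
    FDRc: float
    FNRc: float
    DER: float
    OER: float
    gold_mm3: float
    auto_mm3: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            **{m: getattr(self, m) for m in METRIC_COLUMNS},
            "gold_mm3": self.gold_mm3,
            "auto_mm3": self.auto_mm3,
        }


@dataclass
class CohortReport:
    """Per-subject scores, cohort means and the volume-agreement ICC."""

    scores: list[SubjectScore]
    icc: float
    means: dict = field(default_factory=dict)
    n_undefined: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per subject plus a means row, Table-style column order."""
        rows = [s.as_dict() for s in self.scores]
        df = pd.DataFrame(rows)
        mean_row = {"subject_id": "mean", **self.means,
                    "gold_mm3": df["gold_mm3"].mean(),
                    "auto_mm3": df["auto_mm3"].mean()}
        return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)

    def summary(self) -> dict:
        """Cohort means in report order, ICC last."""
        out = {m: self.means.get(m, math.nan) for m in METRIC_COLUMNS}
        out["ICC"] = self.icc
        return out


def voxel_metrics(gold: LabelMask, auto: LabelMask) -> tuple[float, float, float]:
    """(SI, FDR, FNR); NaN where the defining denominator mask is empty."""
    check_same_grid(gold, auto)
    g, a = gold.data, auto.data
    tp = int((g & a).sum())
    fp = int((a & ~g).sum())
    fn = int((g & ~a).sum())
    n_a, n_g = tp + fp, tp + fn
    si = 2 * tp / (2 * tp + fp + fn) if n_g > 0 else math.nan
    fdr = fp / n_a if n_a > 0 else math.nan
    fnr = fn / n_g if n_g > 0 else math.nan
    return si, fdr, fnr


def cluster_metrics(
    gold: LabelMask, auto: LabelMask, connectivity: int = 26
) -> tuple[float, float, float, float]:
    """(FDRc, FNRc, DER, OER) under the given cluster connectivity."""
    check_same_grid(gold, auto)
    g_lab, n_g = connected_components(gold, connectivity)
    a_lab, n_a = connected_components(auto, connectivity)

    g, a = gold.data, auto.data
    inter = g & a
    # a cluster "overlaps" iff any of its voxels lies in the other mask
    g_hit = np.unique(g_lab[inter]) if inter.any() else np.empty(0, dtype=g_lab.dtype)
    a_hit = np.unique(a_lab[inter]) if inter.any() else np.empty(0, dtype=a_lab.dtype)

    fdrc = (n_a - len(a_hit)) / n_a if n_a > 0 else math.nan
    fnrc = (n_g - len(g_hit)) / n_g if n_g > 0 else math.nan

    mta = (int(g.sum()) + int(a.sum())) / 2.0
    if mta == 0:
        return fdrc, fnrc, math.nan, math.nan

    g_matched = np.isin(g_lab, g_hit) & g
    a_matched = np.isin(a_lab, a_hit) & a
    unmatched_vox = int((g & ~g_matched).sum()) + int((a & ~a_matched).sum())
    outline_vox = int(g_matched.sum()) + int(a_matched.sum()) - 2 * int(inter.sum())
    return fdrc, fnrc, unmatched_vox / mta, outline_vox / mta


def icc_agreement(gold_volumes, auto_volumes) -> float:
    """ICC(A,1) between paired gold and automated lesion volumes.

    Two-way random effects, absolute agreement, single measure — the
    "ICC2" row of :func:`pingouin.intraclass_corr`. Requires at least 3
    pairs and non-degenerate variance.
    """
    import pingouin as pg

    gold_volumes = np.asarray(gold_volumes, dtype=float)
    auto_volumes = np.asarray(auto_volumes, dtype=float)
    if gold_volumes.shape != auto_volumes.shape or gold_volumes.ndim != 1:
        raise ValueError("volume lists must be paired 1D sequences")
    n = len(gold_volumes)
    if n < 3:
        raise ValueError("ICC requires at least 3 paired volumes")
    if np.allclose(np.concatenate([gold_volumes, auto_volumes]),
                   gold_volumes[0]):
        raise ValueError("zero total variance: ICC is degenerate")
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["gold", "auto"], n),
            "volume": np.concatenate([gold_volumes, auto_volumes]),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # perfect agreement makes pingouin's F statistics divide by zero;
        # the ICC point estimate itself is still well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="volume"
        )
    # the ICC(A,1) row is labelled "ICC2" or "ICC(A,1)" depending on version
    row = res[res["Type"].isin(("ICC2", "ICC(A,1)"))]
    return float(row["ICC"].iloc[0])


def score_subject(
    gold: LabelMask, auto: LabelMask, subject_id: str = "", connectivity: int = 26
) -> SubjectScore:
    """All voxel- and cluster-level metrics for one subject."""
    si, fdr, fnr = voxel_metrics(gold, auto)
    fdrc, fnrc, der, oer = cluster_metrics(gold, auto, connectivity)
    vals = dict(SI=si, FDR=fdr, FNR=fnr, FDRc=fdrc, FNRc=fnrc, DER=der, OER=oer)
    undefined = tuple(m for m, v in vals.items() if math.isnan(v))
    return SubjectScore(
        subject_id=subject_id,
        **vals,
        gold_mm3=gold.volume_mm3,
        auto_mm3=auto.volume_mm3,
        undefined=undefined,
    )


def cohort_report(
    pairs, subject_ids=None, connectivity: int = 26
) -> CohortReport:
    """Score a cohort of (gold, auto) mask pairs.

    Cohort means are taken per metric over the subjects where that metric
    is defined; counts of undefined subjects per metric are reported
    alongside. The ICC is computed over the volume pairs when at least 3
    subjects are available, else NaN.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cohort_report requires at least one subject")
    if subject_ids is None:
        subject_ids = [f"subject-{i:03d}" for i in range(len(pairs))]
    scores = [
        score_subject(g, a, sid, connectivity)
        for (g, a), sid in zip(pairs, subject_ids)
    ]
    means, n_undef = {}, {}
    for m in METRIC_COLUMNS:
        vals = np.array([getattr(s, m) for s in scores], dtype=float)
        defined = vals[~np.isnan(vals)]
        means[m] = float(defined.mean()) if defined.size else math.nan
        n_undef[m] = int(np.isnan(vals).sum())
    gv = [s.gold_mm3 for s in scores]
    av = [s.auto_mm3 for s in scores]
    try:
        icc = icc_agreement(gv, av) if len(scores) >= 3 else math.nan
    except ValueError:
        icc = math.nan
    return CohortReport(scores=scores, icc=icc, means=means, n_undefined=n_undef)
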