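"""Representational similarity analysis.

ROI RDMs are correlation-distance matrices over image-level patterns.
Two ideal model RDMs summarise the labels: semantic categories as
orthogonal one-hot vectors (correlation distance, so 0 within category
and 1.5 between), and quality levels as the 2-d codes low=(0,1),
neutral=(1,1), high=(1,0) under Euclidean distance, which places neutral
equidistant (distance 1) from low and high while low-high is sqrt(2).
The information content of a label in an ROI is the Pearson (optionally
Spearman) correlation between the upper triangles of the ROI RDM and the
ideal RDM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CATEGORIES, QUALITIES
from .representation import RepresentationSet
from .stats import WelchAnovaResult, games_howell, welch_anova

QUALITY_CODES = {"low": (0.0, 1.0), "neutral": (1.0, 1.0), "high": (1.0, 0.0)}


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix with an item index."""

    matrix: np.ndarray
    item_index: pd.DataFrame
    metric: str = "pearson_distance"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("RDM matrix must be symmetric")
        if not np.allclose(np.diag(m), 0, atol=1e-12):
            raise ValueError("RDM diagonal must be zero")
        if self.metric == "pearson_distance" and (
            (m < -1e-12).any() or (m > 2 + 1e-9).any()
        ):
            raise ValueError("correlation distances must lie in [0, 2]")
        if self.metric == "euclidean" and (m < -1e-12).any():
            raise ValueError("euclidean distances must be non-negative")
        self.matrix = m

    @property
    def n_items(self) -> int:
        return self.matrix.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_items, k=1)
        return self.matrix[iu]

    def subset(self, mask: np.ndarray) -> "RDM":
        idx = np.flatnonzero(mask)
        return RDM(
            matrix=self.matrix[np.ix_(idx, idx)],
            item_index=self.item_index.iloc[idx].reset_index(drop=True),
            metric=self.metric,
        )


def compute_rdm(patterns: np.ndarray, item_index: pd.DataFrame) -> RDM:
    """Correlation-distance RDM: entry (i, j) = 1 - Pearson r(row_i, row_j)."""
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 items and >= 2 dimensions")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"item {bad} has a constant pattern; correlation undefined")
    c = np.corrcoef(x)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, 2.0)
    return RDM(matrix=d, item_index=item_index.reset_index(drop=True))


def ideal_semantic_rdm(item_index: pd.DataFrame) -> RDM:
    """Correlation-distance RDM of one-hot category codes (0 or 1.5)."""
    labels = item_index["category"]
    unknown = set(labels) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    same = labels.to_numpy()[:, None] == labels.to_numpy()[None, :]
    # r(one-hot_a, one-hot_b) = 1 if a == b else -1/2  ->  distance 0 or 1.5
    m = np.where(same, 0.0, 1.5)
    np.fill_diagonal(m, 0.0)
    return RDM(matrix=m, item_index=item_index.reset_index(drop=True))


def ideal_quality_rdm(item_index: pd.DataFrame) -> RDM:
    """Euclidean RDM of the 2-d quality codes (values 0, 1 or sqrt(2))."""
    labels = item_index["quality"]
    unknown = set(labels) - set(QUALITIES)
    if unknown:
        raise ValueError(f"unknown qualities: {sorted(unknown)}")
    codes = np.array([QUALITY_CODES[q] for q in labels])
    diff = codes[:, None, :] - codes[None, :, :]
    m = np.sqrt((diff**2).sum(axis=-1))
    return RDM(matrix=m, item_index=item_index.reset_index(drop=True),
               metric="euclidean")


def information_content(roi_rdm: RDM, ideal_rdm: RDM,
                        method: str = "pearson") -> float:
    """Correlation between the strictly-upper triangles of two RDMs.

    Returns NaN (flagged, never silently 0) when either triangle is
    constant, e.g. an all-same-category subset against the semantic
    ideal.
    """
    if roi_rdm.n_items != ideal_rdm.n_items:
        raise ValueError("RDMs cover different item sets")
    if not roi_rdm.item_index["image_id"].equals(ideal_rdm.item_index["image_id"]):
        raise ValueError("RDM item orderings differ")
    a = roi_rdm.upper_triangle()
    b = ideal_rdm.upper_triangle()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def group_average_rdm(rdms: list[RDM]) -> RDM:
    """Entrywise mean RDM over participants (identical item indices)."""
    if not rdms:
        raise ValueError("no RDMs to average")
    ref = rdms[0].item_index["image_id"]
    for r in rdms[1:]:
        if not r.item_index["image_id"].equals(ref):
            raise ValueError("RDM item indices mismatch across participants")
    m = np.mean([r.matrix for r in rdms], axis=0)
    return RDM(matrix=m, item_index=rdms[0].item_index, metric=rdms[0].metric)


def information_content_table(reps: RepresentationSet,
                              method: str = "pearson") -> pd.DataFrame:
    """Per participant x ROI: quality information content over all images
    and semantic information content within each quality condition.

    Semantic content per quality is computed on the sub-RDM restricted to
    that quality's images; a row with quality ``"all"`` gives the
    whole-RDM semantic and quality correlations.
    """
    rows = []
    for (participant, roi), pats in reps.averaged.items():
        rdm = compute_rdm(pats, reps.image_index)
        sem = ideal_semantic_rdm(reps.image_index)
        qual = ideal_quality_rdm(reps.image_index)
        rows.append(
            {
                "participant": participant, "roi": roi, "quality": "all",
                "label_type": "semantic",
                "r": information_content(rdm, sem, method=method),
            }
        )
        rows.append(
            {
                "participant": participant, "roi": roi, "quality": "all",
                "label_type": "quality",
                "r": information_content(rdm, qual, method=method),
            }
        )
        for q in QUALITIES:
            mask = (reps.image_index["quality"] == q).to_numpy()
            sub = rdm.subset(mask)
            sub_ideal = sem.subset(mask)
            rows.append(
                {
                    "participant": participant, "roi": roi, "quality": q,
                    "label_type": "semantic",
                    "r": information_content(sub, sub_ideal, method=method),
                }
            )
    return pd.DataFrame(rows)


def compare_across_quality(table: pd.DataFrame, roi: str) -> tuple[
    WelchAnovaResult, pd.DataFrame
]:
    """Welch ANOVA (+ Games-Howell) of semantic content across qualities.

    Groups are the per-participant semantic information-content values
    of ``roi`` under each of the three quality conditions.
    """
    sub = table[
        (table["roi"] == roi)
        & (table["label_type"] == "semantic")
        & (table["quality"] != "all")
    ]
    groups = [
        sub[sub["quality"] == q]["r"].dropna().to_numpy() for q in QUALITIES
    ]
    anova = welch_anova(groups)
    posthoc = games_howell(groups, labels=list(QUALITIES))
    return anova, posthoc
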