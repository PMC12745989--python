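"""Decoding perceived image quality from ROI representation vectors.

Quality labels are quantized as 1 (low), 2 (neutral), 3 (high) and
regressed from the concatenated repetition-averaged representation
vectors of one or more ROIs with an RBF-kernel SVR (C = 1, epsilon =
0.1) under repeated four-fold cross-validation.  Agreement between the
continuous out-of-fold predictions and the integer targets is scored
with the Spearman rank (SRCC) and Pearson linear (PLCC) correlation
coefficients, the standard metrics in image-quality assessment.  A group
prediction averages the per-participant predicted scores per image
before scoring, and every ROI set is tested against the all-ROI joint
model with Welch t-tests under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .mapping import stratified_folds
from .representation import RepresentationSet
from .stats import bh_fdr, welch_ttest

QUALITY_SCORE = {"low": 1, "neutral": 2, "high": 3}


def quality_targets(image_index: pd.DataFrame) -> np.ndarray:
    """Integer quality score per image: 1 = low, 2 = neutral, 3 = high."""
    return image_index["quality"].map(QUALITY_SCORE).to_numpy(dtype=float)


def srcc(predicted, actual) -> float:
    """Spearman rank correlation.

    Equals 1 - 6 sum(d_i^2) / (n (n^2 - 1)) on untied data; with ties
    (the integer targets are heavily tied) mid-ranks are used, i.e. the
    Pearson correlation of the rank vectors.  Constant input -> NaN.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def plcc(predicted, actual) -> float:
    """Pearson linear correlation; constant input -> NaN."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def roi_set_features(reps: RepresentationSet, participant: str,
                     roi_set: tuple[str, ...]) -> np.ndarray:
    """Image x (dim * n_rois) feature matrix: concatenated averaged vectors."""
    if not roi_set:
        raise ValueError("roi_set must name at least one ROI")
    mats = [reps.averaged[(participant, roi)] for roi in roi_set]
    n_images = {m.shape[0] for m in mats}
    if len(n_images) != 1:
        raise ValueError("ROIs cover different image sets")
    return np.concatenate(mats, axis=1)


def decode_quality(
    reps: RepresentationSet,
    participant: str,
    roi_set: tuple[str, ...],
    n_folds: int = 4,
    n_repeats: int = 10,
    seed: int = 0,
    stratify: bool = True,
) -> dict:
    """Repeated cross-validated SVR decoding of quality for one ROI set.

    Returns out-of-fold predictions (repeat x image) plus the SRCC and
    PLCC per repeat averaged into the reported values.
    """
    X = roi_set_features(reps, participant, roi_set)
    y = quality_targets(reps.image_index)
    cats = (
        reps.image_index["category"].astype(str)
        + "/" + reps.image_index["quality"].astype(str)
    ).to_numpy()
    rng = np.random.default_rng(seed)
    preds = np.empty((n_repeats, len(y)))
    srcc_r, plcc_r = [], []
    for rep in range(n_repeats):
        folds = stratified_folds(cats, n_folds, rng, stratify=stratify)
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            scaler = StandardScaler().fit(X[tr])
            model = SVR(kernel="rbf", C=1.0, epsilon=0.1).fit(
                scaler.transform(X[tr]), y[tr]
            )
            preds[rep, te] = model.predict(scaler.transform(X[te]))
        srcc_r.append(srcc(preds[rep], y))
        plcc_r.append(plcc(preds[rep], y))
    return {
        "participant": participant,
        "roi_set": "+".join(roi_set),
        "srcc": float(np.mean(srcc_r)),
        "plcc": float(np.mean(plcc_r)),
        "predictions": preds,
        "n_repeats": n_repeats,
        "seed": seed,
    }


def decoding_table(
    reps: RepresentationSet,
    roi_sets: list[tuple[str, ...]] | None = None,
    n_folds: int = 4,
    n_repeats: int = 10,
    seed: int = 0,
    participants: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Decode every ROI set for every participant; add group-level rows.

    Default ROI sets are all singles, all pairs, and the all-ROI joint
    set.  Group rows are computed from the participant-averaged
    predicted score per image, not from averaged correlations.
    """
    participants = participants or reps.participants
    rois = reps.rois
    if roi_sets is None:
        roi_sets = (
            [(r,) for r in rois]
            + [tuple(p) for p in itertools.combinations(rois, 2)]
            + [tuple(rois)]
        )
    master = np.random.default_rng(seed)
    seeds = {
        (p, s): int(master.integers(2**31))
        for s in range(len(roi_sets)) for p in participants
    }
    y = quality_targets(reps.image_index)
    rows, predictions = [], {}
    for s, roi_set in enumerate(roi_sets):
        per_part_preds = []
        for p in participants:
            res = decode_quality(
                reps, p, roi_set, n_folds=n_folds, n_repeats=n_repeats,
                seed=seeds[(p, s)],
            )
            predictions[(p, res["roi_set"])] = res["predictions"]
            per_part_preds.append(res["predictions"].mean(axis=0))
            rows.append({k: res[k] for k in
                         ("participant", "roi_set", "srcc", "plcc")})
        group_pred = np.mean(per_part_preds, axis=0)
        rows.append(
            {
                "participant": "group",
                "roi_set": "+".join(roi_set),
                "srcc": srcc(group_pred, y),
                "plcc": plcc(group_pred, y),
            }
        )
    return pd.DataFrame(rows), predictions


def random_baseline(targets: np.ndarray, seed: int = 0, n_repeats: int = 100,
                    integer_scores: bool = False) -> pd.DataFrame:
    """SRCC/PLCC of random scores against the targets, per repeat.

    Scores are continuous uniform on [1, 3] by default; with
    ``integer_scores`` they are uniform draws from {1, 2, 3}.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        if integer_scores:
            scores = rng.integers(1, 4, size=len(targets)).astype(float)
        else:
            scores = rng.uniform(1.0, 3.0, size=len(targets))
        rows.append({"repeat": rep, "srcc": srcc(scores, targets),
                     "plcc": plcc(scores, targets)})
    return pd.DataFrame(rows)


def group_prediction(per_participant_predictions: list[np.ndarray],
                     targets: np.ndarray) -> tuple[float, float]:
    """Average the predicted score per image across participants, then score."""
    preds = [np.asarray(p, dtype=float) for p in per_participant_predictions]
    if not preds:
        raise ValueError("no predictions supplied")
    n = {p.shape for p in preds}
    if len(n) != 1 or preds[0].shape != np.asarray(targets).shape:
        raise ValueError("prediction vectors must align with the target images")
    mean_pred = np.mean(preds, axis=0)
    return srcc(mean_pred, targets), plcc(mean_pred, targets)


def compare_to_joint(table: pd.DataFrame, metric: str = "srcc",
                     q: float = 0.1, joint_label: str | None = None,
                     equal_var: bool = False) -> pd.DataFrame:
    """Test every ROI set against the all-ROI joint model, BH-FDR corrected.

    Per ROI set a two-tailed Welch t-test compares participant-level
    performance with the joint model's; sets whose difference survives
    FDR at ``q`` are marked significant, the rest are flagged as
    statistically indistinguishable from the joint model.
    """
    part = table[table["participant"] != "group"]
    if joint_label is None:
        joint_label = max(part["roi_set"], key=lambda s: s.count("+"))
    joint = part[part["roi_set"] == joint_label][metric].to_numpy()
    if len(joint) < 2:
        raise ValueError("need >= 2 participants for the joint reference")
    rows = []
    for roi_set, grp in part[part["roi_set"] != joint_label].groupby(
        "roi_set", sort=False
    ):
        vals = grp[metric].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"need >= 2 participants for ROI set {roi_set}")
        if np.var(vals) == 0 and np.var(joint) == 0:
            t, p = (0.0, 1.0) if np.mean(vals) == np.mean(joint) else (np.inf, 0.0)
        elif equal_var:
            res = stats.ttest_ind(vals, joint, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
        else:
            t, p = welch_ttest(vals, joint)
        rows.append({"roi_set": roi_set, "mean_diff": float(np.mean(vals) -
                                                            np.mean(joint)),
                     "t": t, "p": p})
    out = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(out["p"].to_numpy(), q=q)
    out["p_fdr"] = p_adj
    out["significant"] = reject
    out["matches_joint"] = ~out["significant"]
    return out
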