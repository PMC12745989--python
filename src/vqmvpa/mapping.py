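"""Inter-ROI pattern mapping with quality-conditional generalization.

An epsilon-insensitive support-vector regressor with an RBF kernel
(C = 1, epsilon = 0.1) is trained independently for every dimension of
the target ROI's representation vector, with inputs standardized on the
training fold.  Cross-prediction over the two stimulus repetitions
(rep-1 source -> rep-2 target and vice versa) avoids inflation from
trial-specific noise shared between simultaneously measured areas, and
the per-image prediction score is the Pearson correlation between the
actual and predicted target vectors.  The noise ceiling -- the mean over
images of the correlation between the two repetition patterns -- bounds
achievable performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .design import CATEGORIES, QUALITIES
from .representation import RepresentationSet
from .stats import WelchAnovaResult, games_howell, welch_anova


def prediction_score(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson rho = Cov(y, yhat) / sqrt(Var(y) Var(yhat)); NaN if constant."""
    y = np.asarray(actual, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    if y.shape != yh.shape or y.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if y.std() == 0 or yh.std() == 0:
        return float("nan")
    return float(np.corrcoef(y, yh)[0, 1])


@dataclass
class MappingModel:
    """Per-dimension RBF-SVR mapping from one ROI's vectors to another's."""

    source_roi: str
    target_roi: str
    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "scale"
    models: list = field(default_factory=list, repr=False)
    scaler: StandardScaler | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.models:
            raise RuntimeError("model is not fitted")
        Xs = self.scaler.transform(X)
        return np.column_stack([m.predict(Xs) for m in self.models])


def fit_mapping(train_X: np.ndarray, train_Y: np.ndarray,
                model: MappingModel | None = None) -> MappingModel:
    """Fit one SVR per target dimension on standardized inputs."""
    X = np.asarray(train_X, dtype=float)
    Y = np.asarray(train_Y, dtype=float)
    if X.shape[0] != Y.shape[0] or X.shape[0] < 2:
        raise ValueError("need >= 2 matched training images")
    if X.std() == 0:
        raise ValueError("training inputs are constant")
    model = model or MappingModel(source_roi="A", target_roi="B")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    model.scaler = scaler
    model.models = [
        SVR(kernel="rbf", C=model.C, epsilon=model.epsilon,
            gamma=model.gamma).fit(Xs, Y[:, d])
        for d in range(Y.shape[1])
    ]
    return model


def cross_predict_score(
    model_12: MappingModel,
    model_21: MappingModel,
    src_rep: np.ndarray,
    tgt_rep: np.ndarray,
    test_idx: np.ndarray,
) -> float:
    """Mean per-image rho over both cross-repetition directions.

    ``model_12`` maps source repetition 1 to target repetition 2 and
    ``model_21`` the reverse; each held-out image is scored in both
    directions and all scores are averaged.
    """
    pred_2 = model_12.predict(src_rep[0][test_idx])
    pred_1 = model_21.predict(src_rep[1][test_idx])
    scores = []
    for i in range(len(test_idx)):
        scores.append(prediction_score(tgt_rep[1][test_idx][i], pred_2[i]))
        scores.append(prediction_score(tgt_rep[0][test_idx][i], pred_1[i]))
    return float(np.nanmean(scores))


def stratified_folds(labels: np.ndarray, n_folds: int,
                     rng: np.random.Generator,
                     stratify: bool = True) -> np.ndarray:
    """Fold assignment (0..n_folds-1) per item, category-stratified by default."""
    n = len(labels)
    if n % n_folds:
        raise ValueError(f"{n} items are not divisible into {n_folds} equal folds")
    assign = np.empty(n, dtype=int)
    if stratify:
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            rng.shuffle(idx)
            assign[idx] = np.arange(len(idx)) % n_folds
    else:
        idx = rng.permutation(n)
        assign[idx] = np.arange(n) % n_folds
    return assign


def quality_generalization(
    reps: RepresentationSet,
    source: str,
    target: str,
    train_quality: str,
    n_folds: int = 4,
    n_repeats: int = 10,
    seed: int = 0,
    participants: list[str] | None = None,
    stratify: bool = True,
) -> pd.DataFrame:
    """Train on one quality condition, test fold-matched on all three.

    Per repeat the images of each quality are divided into ``n_folds``
    folds (stratified by content category); for each fold f the mapping
    is trained on the other folds of ``train_quality`` and tested on
    fold f of every quality, so no test image ever enters its training
    set.  Returns per (participant, test_quality) rows with the mean
    cross-prediction rho over folds and repeats, plus per-fold detail.
    """
    if train_quality not in QUALITIES:
        raise ValueError(f"unknown quality {train_quality!r}")
    participants = participants or reps.participants
    qual = reps.image_index["quality"].to_numpy()
    cats = reps.image_index["category"].to_numpy()
    q_idx = {q: np.flatnonzero(qual == q) for q in QUALITIES}
    rows = []
    master = np.random.default_rng(seed)
    # one independent stream per (participant, repeat)
    streams = {
        (p, rep): np.random.default_rng(master.integers(2**31))
        for p in participants for rep in range(n_repeats)
    }
    for p in participants:
        src_rep = reps.per_repetition[(p, source)]
        tgt_rep = reps.per_repetition[(p, target)]
        for rep in range(n_repeats):
            rng = streams[(p, rep)]
            folds = {
                q: stratified_folds(cats[q_idx[q]], n_folds, rng, stratify)
                for q in QUALITIES
            }
            for f in range(n_folds):
                train_imgs = q_idx[train_quality][folds[train_quality] != f]
                m12 = fit_mapping(
                    src_rep[0][train_imgs], tgt_rep[1][train_imgs],
                    MappingModel(source, target),
                )
                m21 = fit_mapping(
                    src_rep[1][train_imgs], tgt_rep[0][train_imgs],
                    MappingModel(source, target),
                )
                for q in QUALITIES:
                    test_imgs = q_idx[q][folds[q] == f]
                    rho = cross_predict_score(m12, m21, src_rep, tgt_rep, test_imgs)
                    rows.append(
                        {
                            "participant": p, "source": source, "target": target,
                            "train_quality": train_quality, "test_quality": q,
                            "repeat": rep, "fold": f, "rho": rho,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_mapping(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean rho over folds x repeats, per test quality."""
    return (
        table.groupby(
            ["participant", "source", "target", "train_quality", "test_quality"],
            sort=False,
        )["rho"]
        .mean()
        .reset_index()
    )


def noise_ceiling(reps: RepresentationSet,
                  participants: list[str] | None = None,
                  rois: list[str] | None = None) -> pd.DataFrame:
    """Per (participant, ROI) mean over images of rho(rep1_i, rep2_i).

    Images whose repetition pattern is constant are flagged and excluded;
    their count is reported in ``n_excluded``.
    """
    participants = participants or reps.participants
    rois = rois or reps.rois
    rows = []
    for p in participants:
        for roi in rois:
            pr = reps.per_repetition[(p, roi)]
            scores = np.array(
                [prediction_score(pr[0, i], pr[1, i]) for i in range(pr.shape[1])]
            )
            ok = ~np.isnan(scores)
            rows.append(
                {
                    "participant": p, "roi": roi,
                    "ceiling": float(scores[ok].mean()),
                    "n_images": int(ok.sum()),
                    "n_excluded": int((~ok).sum()),
                }
            )
    return pd.DataFrame(rows)


def group_noise_ceiling(table: pd.DataFrame) -> pd.DataFrame:
    """Group noise ceiling per ROI: mean of participant ceilings."""
    return table.groupby("roi", sort=False)["ceiling"].mean().reset_index()


def mapping_significance(summary: pd.DataFrame, source: str, target: str,
                         train_quality: str) -> tuple[WelchAnovaResult,
                                                      pd.DataFrame]:
    """Welch ANOVA + Games-Howell of per-participant rho across test qualities."""
    sub = summary[
        (summary["source"] == source)
        & (summary["target"] == target)
        & (summary["train_quality"] == train_quality)
    ]
    groups = [
        sub[sub["test_quality"] == q]["rho"].to_numpy() for q in QUALITIES
    ]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least two participants per test quality")
    return welch_anova(groups), games_howell(groups, labels=list(QUALITIES))
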