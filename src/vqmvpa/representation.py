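"""Reliability-based pattern extraction.

Turns trial-level betas into per-image ROI representation vectors:
split-half (odd/even runs) voxel reliability over the 18 task x category
x quality condition means, top-k voxel selection per unilateral ROI,
left+right hemisphere concatenation, repetition averaging and per-pattern
z-scoring.  With the default k=100 every vector has length 200.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CATEGORIES, QUALITIES, TASKS, StimulusDesign
from .simulate import BetaDataset, HEMISPHERES

CONDITIONS = [
    (t, c, q) for t in TASKS for c in CATEGORIES for q in QUALITIES
]  # 18 conditions


def condition_profiles(betas: BetaDataset, participant: str,
                       roi: str) -> np.ndarray:
    """Half x condition(18) x voxel mean-beta profiles.

    Trials are averaged within each of the 18 conditions per run, runs
    are split into odd and even halves by run number, and the per-run
    condition means are averaged within each half.
    """
    trials = betas.design.participant_trials(participant)
    arr = betas.betas[(participant, roi)]
    runs = sorted(trials["run"].unique())
    if len(runs) < 2:
        raise ValueError("need at least two runs for an odd/even split")
    halves = {0: [r for r in runs if r % 2 == 1], 1: [r for r in runs if r % 2 == 0]}
    n_vox = arr.shape[1]
    out = np.empty((2, len(CONDITIONS), n_vox))
    for h, half_runs in halves.items():
        for ci, (t, c, q) in enumerate(CONDITIONS):
            mask = (
                trials["run"].isin(half_runs)
                & (trials["task"] == t)
                & (trials["category"] == c)
                & (trials["quality"] == q)
            ).to_numpy()
            if not mask.any():
                raise ValueError(
                    f"condition (task={t}, category={c}, quality={q}) has no "
                    f"trials in the {'odd' if h == 0 else 'even'} half"
                )
            # mean per run, then mean over runs in the half
            sub = trials[mask]
            per_run = [
                arr[(sub["run"] == r).reindex(trials.index, fill_value=False)
                    .to_numpy() & mask].mean(axis=0)
                for r in half_runs
                if ((sub["run"] == r).any())
            ]
            out[h, ci] = np.mean(per_run, axis=0)
    return out


@dataclass
class ReliabilityMap:
    """Split-half Pearson reliability per voxel; NaN flags undefined voxels."""

    values: dict[tuple[str, str], np.ndarray]


def compute_voxel_reliability(profiles: np.ndarray) -> np.ndarray:
    """Pearson r between the odd- and even-half 18-condition profiles.

    Voxels with a zero-variance profile in either half get NaN (they are
    ranked below every defined value during selection).
    """
    odd, even = profiles[0], profiles[1]
    oc = odd - odd.mean(axis=0)
    ec = even - even.mean(axis=0)
    num = (oc * ec).sum(axis=0)
    den = np.sqrt((oc**2).sum(axis=0) * (ec**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return r


def select_reliable_voxels(reliability: np.ndarray, k: int = 100) -> np.ndarray:
    """Indices of the k most reliable voxels, in canonical (ascending) order.

    Ties at the cutoff are broken toward the lower voxel index; NaN
    reliabilities rank last.
    """
    defined = np.flatnonzero(~np.isnan(reliability))
    if len(defined) < k:
        raise ValueError(
            f"only {len(defined)} voxels have defined reliability; need {k}"
        )
    # sort by (-r, index): descending reliability, ascending index on ties
    order = sorted(defined, key=lambda i: (-reliability[i], i))
    return np.sort(np.asarray(order[:k]))


def reliability_map(betas: BetaDataset, k: int = 100) -> tuple[ReliabilityMap, dict]:
    """Reliability and top-k selection for every (participant, unilateral ROI)."""
    rel = {}
    selections = {}
    for (participant, roi) in betas.betas:
        profiles = condition_profiles(betas, participant, roi)
        r = compute_voxel_reliability(profiles)
        rel[(participant, roi)] = r
        selections[(participant, roi)] = select_reliable_voxels(r, k=k)
    return ReliabilityMap(values=rel), selections


def zscore_pattern(x: np.ndarray) -> np.ndarray:
    """Z-score a pattern vector across its entries (population SD)."""
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant pattern")
    return (x - x.mean()) / sd


@dataclass
class RepresentationSet:
    """Per (participant, bilateral ROI) image-level representation vectors.

    ``per_repetition[(p, roi)]`` is repetition x image x dim;
    ``averaged[(p, roi)]`` is image x dim (mean of the two raw repetition
    vectors, z-scored afterwards).  ``image_index`` orders the images and
    carries their category/quality labels; hemisphere order within each
    vector is left then right.
    """

    per_repetition: dict[tuple[str, str], np.ndarray]
    averaged: dict[tuple[str, str], np.ndarray]
    image_index: pd.DataFrame

    @property
    def participants(self) -> list[str]:
        return sorted({p for p, _ in self.averaged})

    @property
    def rois(self) -> list[str]:
        seen = []
        for _, r in self.averaged:
            if r not in seen:
                seen.append(r)
        return seen

    @property
    def dim(self) -> int:
        return next(iter(self.averaged.values())).shape[1]


def build_representations(betas: BetaDataset, selections: dict,
                          zscore: str = "pattern") -> RepresentationSet:
    """Assemble image x dim representation matrices per bilateral ROI.

    For each image the selected left-hemisphere betas are concatenated
    with the selected right-hemisphere betas (canonical voxel order
    within each).  Per-repetition vectors keep the two presentations
    separate; the averaged variant takes their mean before z-scoring.
    ``zscore`` is ``"pattern"`` (each vector across its entries, the
    default) or ``"none"``.
    """
    if zscore not in ("pattern", "none"):
        raise ValueError(f"unknown zscore mode {zscore!r}")
    design = betas.design
    params = betas.params_used
    image_index = (
        design.images[["image_id", "task", "category", "quality"]]
        .reset_index(drop=True)
        .copy()
    )
    n_images = len(image_index)
    per_rep: dict[tuple[str, str], np.ndarray] = {}
    avg: dict[tuple[str, str], np.ndarray] = {}

    for participant in design.participants:
        trials = design.participant_trials(participant)
        counts = trials.groupby("image_id").size()
        bad = counts[counts != 2]
        if len(bad):
            raise ValueError(
                f"every image needs exactly 2 presentations; offenders: "
                f"{list(bad.index[:5])}"
            )
        # trial row indices per image per repetition
        idx = {
            (im, rep): int(i)
            for i, (im, rep) in enumerate(
                zip(trials["image_id"], trials["repetition"])
            )
        }
        for roi in params.roi_names:
            parts = []
            for hemi in HEMISPHERES:
                key = (participant, f"{roi}_{hemi}")
                sel = selections[key]
                parts.append(betas.betas[key][:, sel])
            full = np.concatenate(parts, axis=1)  # trials x 2k
            dim = full.shape[1]
            pr = np.empty((2, n_images, dim))
            av = np.empty((n_images, dim))
            for i, im in enumerate(image_index["image_id"]):
                v1 = full[idx[(im, 1)]]
                v2 = full[idx[(im, 2)]]
                mean = 0.5 * (v1 + v2)
                if zscore == "pattern":
                    v1, v2, mean = (
                        zscore_pattern(v1), zscore_pattern(v2), zscore_pattern(mean)
                    )
                pr[0, i], pr[1, i], av[i] = v1, v2, mean
            per_rep[(participant, roi)] = pr
            avg[(participant, roi)] = av

    return RepresentationSet(
        per_repetition=per_rep, averaged=avg, image_index=image_index
    )


def extract_representations(betas: BetaDataset, k: int = 100,
                            zscore: str = "pattern") -> RepresentationSet:
    """Convenience: reliability selection followed by pattern assembly."""
    _, selections = reliability_map(betas, k=k)
    return build_representations(betas, selections, zscore=zscore)
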