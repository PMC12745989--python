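"""Synthetic trial-level voxel betas with planted semantic/quality structure.

The generator emulates the statistical structure the downstream analysis
is designed to detect: semantic category coding whose strength in
low-level visual areas is attenuated by degrading image quality but is
constant in high-level areas, and an inter-areal transform that may
itself depend on quality.  Each image's category drive lives in a
3-dimensional latent code; a fixed loading matrix projects the latent
onto a subset of "reliable" voxels, the rest receive pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CATEGORIES, QUALITIES, StimulusDesign

ROI_NAMES = (
    "calcarine",
    "cuneus",
    "lingual",
    "superior_occipital",
    "middle_occipital",
    "inferior_occipital",
    "fusiform",
)
#: Early retinotopic / dorsal-early areas where quality degrades semantic coding.
LOW_LEVEL_ROIS = ("calcarine", "cuneus", "lingual", "superior_occipital")
#: Ventral-stream areas whose semantic coding is quality-invariant.
HIGH_LEVEL_ROIS = ("middle_occipital", "inferior_occipital", "fusiform")
HEMISPHERES = ("L", "R")


def default_gains() -> dict[tuple[str, str], float]:
    """Semantic gain per (ROI, quality): graded in low-level, flat in high-level."""
    gains = {}
    graded = {"low": 0.2, "neutral": 0.5, "high": 0.9}
    for roi in LOW_LEVEL_ROIS:
        for q in QUALITIES:
            gains[(roi, q)] = graded[q]
    for roi in HIGH_LEVEL_ROIS:
        for q in QUALITIES:
            gains[(roi, q)] = 0.8
    return gains


@dataclass
class SimulationParams:
    """Generative settings for the beta simulator.

    ``noise_sd`` (acquisition noise) and ``repetition_noise_sd``
    (trial-to-trial response variability) are both drawn independently
    per presentation and add in quadrature; the latent category drive is
    the only component shared between the two presentations of an image,
    so the signal-to-noise ratio sets both the split-half voxel
    reliability and the noise ceiling of the synthetic data.
    """

    roi_names: tuple[str, ...] = ROI_NAMES
    voxels_per_unilateral_roi: int = 150
    n_reliable_voxels: int = 100
    semantic_effect: float = 1.0
    semantic_gain_by_quality_and_roi: dict = field(default_factory=default_gains)
    quality_dependent_mixing: bool = True
    mixing_strength: float = 1.0
    latent_noise_sd: float = 0.5
    roi_latent_noise_sd: float = 0.35
    quality_bias_sd: float = 0.2
    noise_sd: float = 0.6
    repetition_noise_sd: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for (roi, q), g in self.semantic_gain_by_quality_and_roi.items():
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"gain for ({roi}, {q}) outside [0, 1]: {g}")
        if self.n_reliable_voxels > self.voxels_per_unilateral_roi:
            raise ValueError("more reliable voxels than voxels in the ROI")
        for name in ("semantic_effect", "noise_sd", "repetition_noise_sd",
                     "latent_noise_sd", "roi_latent_noise_sd",
                     "quality_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def gain(self, roi: str, quality: str) -> float:
        return self.semantic_gain_by_quality_and_roi[(roi, quality)]


@dataclass
class BetaDataset:
    """Trial x voxel beta arrays keyed by (participant, unilateral ROI)."""

    betas: dict[tuple[str, str], np.ndarray]
    design: StimulusDesign
    params_used: SimulationParams
    reliable_voxels: dict[tuple[str, str], np.ndarray]

    def unilateral_rois(self) -> list[str]:
        return [f"{r}_{h}" for r in self.params_used.roi_names for h in HEMISPHERES]


def _random_rotation(rng: np.random.Generator, dim: int = 3) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    m = rng.standard_normal((dim, dim))
    q, r = np.linalg.qr(m)
    return q * np.sign(np.diag(r))


def simulate_betas(design: StimulusDesign,
                   params: SimulationParams | None = None) -> BetaDataset:
    """Simulate the full beta dataset for every participant and unilateral ROI.

    Per image a 3-d latent ``z = semantic_effect * onehot(category) +
    latent noise`` is drawn once and shared by both presentations.  A
    low-level area's code is ``gain(roi, quality) * z``; a high-level
    area's code adds a quality-indexed rotation of the low-level code to
    its own (quality-invariant) semantic component, so the low-to-high
    relationship carries quality information when
    ``quality_dependent_mixing`` is on.  Voxel betas are the reliable
    voxels' loading matrix applied to the code plus independent Gaussian
    noise on every trial; unreliable voxels are pure noise.
    """
    params = params or SimulationParams()
    params.validate()
    root = np.random.default_rng(params.seed)
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}

    # mixing transforms, one per high-level ROI (areas receive the shared
    # low-level latent through their own pathway) and -- when mixing is
    # quality-dependent -- one per quality; shared across participants
    mix_rng = np.random.default_rng(root.integers(2**31))
    mixing: dict[tuple[str, str], np.ndarray] = {}
    for roi in params.roi_names:
        if roi not in HIGH_LEVEL_ROIS:
            continue
        if params.quality_dependent_mixing:
            for q in QUALITIES:
                mixing[(roi, q)] = _random_rotation(mix_rng)
        else:
            shared = _random_rotation(mix_rng)
            for q in QUALITIES:
                mixing[(roi, q)] = shared

    betas: dict[tuple[str, str], np.ndarray] = {}
    reliable: dict[tuple[str, str], np.ndarray] = {}
    n_vox = params.voxels_per_unilateral_roi
    n_rel = params.n_reliable_voxels

    for participant in design.participants:
        p_rng = np.random.default_rng(root.integers(2**31))
        trials = design.participant_trials(participant)
        image_ids = pd.unique(trials["image_id"])
        meta = trials.drop_duplicates("image_id").set_index("image_id")

        # per-image latent, shared across ROIs and repetitions
        z = {}
        for im in image_ids:
            onehot = np.zeros(len(CATEGORIES))
            onehot[cat_index[meta.loc[im, "category"]]] = 1.0
            z[im] = (
                params.semantic_effect * onehot
                + params.latent_noise_sd * p_rng.standard_normal(len(CATEGORIES))
            )

        # per-image ROI code; each ROI adds its own latent component
        # (shared across hemispheres and repetitions) so different ROIs
        # carry partially independent evidence about the same image
        codes: dict[str, dict[str, np.ndarray]] = {}
        for roi in params.roi_names:
            codes[roi] = {}
            for im in image_ids:
                q = meta.loc[im, "quality"]
                own = params.roi_latent_noise_sd * p_rng.standard_normal(
                    len(CATEGORIES)
                )
                if roi in HIGH_LEVEL_ROIS:
                    # compensation: the semantic component arrives at its
                    # own constant gain, so high-level semantic strength is
                    # quality-invariant; only the image-specific latent
                    # residual passes through the quality-indexed transform,
                    # which is what makes the low-to-high relationship vary
                    # with quality when mixing is quality-dependent
                    onehot = _onehot_of(meta.loc[im, "category"], cat_index)
                    resid = z[im] - params.semantic_effect * onehot
                    code = (
                        params.mixing_strength * (mixing[(roi, q)] @ resid)
                        + params.gain(roi, q) * params.semantic_effect * onehot
                        + own
                    )
                else:
                    code = params.gain(roi, q) * (z[im] + own)
                codes[roi][im] = code

        for roi in params.roi_names:
            for hemi in HEMISPHERES:
                key_rng = np.random.default_rng(p_rng.integers(2**31))
                rel_idx = np.sort(
                    key_rng.choice(n_vox, size=n_rel, replace=False)
                )
                # random response directions with unit power per voxel, so
                # every designated-reliable voxel is genuinely responsive
                loading = key_rng.standard_normal((n_rel, len(CATEGORIES)))
                loading /= np.linalg.norm(loading, axis=1, keepdims=True)

                # quality-specific mean-pattern component over the reliable
                # voxels: the multivariate analogue of the univariate
                # activation differences between quality levels; a fixed
                # vector per (ROI, hemisphere, quality), so it shifts every
                # same-quality pattern identically and leaves within-quality
                # representational geometry intact
                bias = {
                    q: params.quality_bias_sd * key_rng.standard_normal(n_rel)
                    for q in QUALITIES
                }
                arr = params.noise_sd * key_rng.standard_normal(
                    (len(trials), n_vox)
                )
                arr += params.repetition_noise_sd * key_rng.standard_normal(
                    (len(trials), n_vox)
                )
                for t, tr in enumerate(trials.itertuples(index=False)):
                    arr[t, rel_idx] += (
                        loading @ codes[roi][tr.image_id] + bias[tr.quality]
                    )
                betas[(participant, f"{roi}_{hemi}")] = arr
                reliable[(participant, f"{roi}_{hemi}")] = rel_idx

    return BetaDataset(
        betas=betas, design=design, params_used=params, reliable_voxels=reliable
    )


def _onehot_of(category: str, cat_index: dict[str, int]) -> np.ndarray:
    v = np.zeros(len(cat_index))
    v[cat_index[category]] = 1.0
    return v
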