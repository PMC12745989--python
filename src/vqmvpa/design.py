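"""Event-related stimulus design generation.

Builds the counterbalanced block/trial structure of the two-task
(quality assessment vs. content classification) experiment: each task
shows 144 unique images (16 per category x quality cell), each image
twice, in blocks of 18 trials whose total duration is held at exactly
96 s by solving the jittered inter-stimulus-interval schedule exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

CATEGORIES = ("face", "object", "scene")
QUALITIES = ("low", "neutral", "high")
TASKS = ("QA", "CC")

#: Task-block order within a run: odd runs QA-CC-CC-QA, even runs reversed.
ODD_RUN_BLOCK_ORDER = ("QA", "CC", "CC", "QA")
EVEN_RUN_BLOCK_ORDER = ("CC", "QA", "QA", "CC")


class InfeasibleScheduleError(ValueError):
    """Raised when no ISI multiset or trial ordering satisfies the constraints."""


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the event-related design.

    Defaults reproduce the study layout: 14 participants, 8 runs of 4
    blocks, 18 trials per block, 4 s instruction, 3.5 s images, ISIs
    jittered over {0.5, 2.5, 4.5} s with every block lasting exactly 96 s.
    """

    n_participants: int = 14
    n_runs: int = 8
    blocks_per_run: int = 4
    trials_per_block: int = 18
    instruction_s: float = 4.0
    image_duration_s: float = 3.5
    isi_menu_s: tuple[float, ...] = (0.5, 2.5, 4.5)
    block_total_s: float = 96.0
    images_per_cell: int = 16
    presentations_per_image: int = 2
    min_lag: int = 1
    shared_order: bool = True
    seed: int = 0

    @property
    def isi_sum_s(self) -> Fraction:
        """Exact per-block ISI budget implied by the timing identity."""
        return (
            Fraction(self.block_total_s)
            - Fraction(self.instruction_s)
            - self.trials_per_block * Fraction(self.image_duration_s)
        )

    @property
    def unique_images_per_task(self) -> int:
        return 9 * self.images_per_cell

    @property
    def trials_per_task(self) -> int:
        return self.unique_images_per_task * self.presentations_per_image

    def validate(self) -> None:
        n_cells = len(CATEGORIES) * len(QUALITIES)
        if n_cells != 9:  # pragma: no cover - structural constant
            raise AssertionError
        blocks_per_task = self.n_runs * self.blocks_per_run // 2
        if self.n_runs * self.blocks_per_run % 2:
            raise ValueError("total block count must be even (two tasks)")
        if blocks_per_task * self.trials_per_block != self.trials_per_task:
            raise ValueError(
                f"trials per task ({self.trials_per_task}) must fill "
                f"{blocks_per_task} blocks of {self.trials_per_block} trials"
            )
        if self.isi_sum_s < 0:
            raise ValueError("block_total_s too short for instruction + images")
        if self.blocks_per_run != 4:
            raise ValueError("block order counterbalancing assumes 4 blocks per run")


def solve_isi_schedule(
    n_isi: int,
    menu: tuple[float, ...],
    target_sum: float,
    rng: np.random.Generator,
) -> list[float]:
    """Draw ``n_isi`` intervals from ``menu`` summing exactly to ``target_sum``.

    The sum constraint is solved over exact rationals, so e.g. eighteen
    draws from {0.5, 2.5, 4.5} can be forced to total 29.0 s without
    floating-point drift.  Among all feasible multisets one is chosen
    uniformly at random, then shuffled.

    Raises
    ------
    InfeasibleScheduleError
        If no multiset of ``n_isi`` menu values reaches ``target_sum``.
    """
    menu = tuple(sorted(set(menu)))
    target = Fraction(target_sum)
    menu_f = [Fraction(m) for m in menu]

    solutions: list[tuple[int, ...]] = []

    def extend(idx: int, remaining_n: int, remaining_sum: Fraction, counts: list[int]):
        if idx == len(menu_f) - 1:
            if remaining_sum == menu_f[idx] * remaining_n:
                solutions.append(tuple(counts + [remaining_n]))
            return
        for c in range(remaining_n + 1):
            rest = remaining_sum - menu_f[idx] * c
            nrest = remaining_n - c
            # prune: remaining values are all >= menu_f[idx+1] and <= menu_f[-1]
            if rest < menu_f[idx + 1] * nrest or rest > menu_f[-1] * nrest:
                continue
            extend(idx + 1, nrest, rest, counts + [c])

    if len(menu_f) == 1:
        if menu_f[0] * n_isi == target:
            solutions.append((n_isi,))
    else:
        extend(0, n_isi, target, [])

    if not solutions:
        raise InfeasibleScheduleError(
            f"no multiset of {n_isi} ISIs from {menu} sums to {target_sum} "
            f"(budget is {float(target)} s)"
        )
    counts = solutions[rng.integers(len(solutions))]
    schedule = [m for m, c in zip(menu, counts) for _ in range(c)]
    rng.shuffle(schedule)
    return schedule


def shuffle_with_min_lag(items, min_lag: int, rng: np.random.Generator) -> list:
    """Randomly order ``items`` so repeats are >= ``min_lag`` apart.

    Two occurrences of the same item must be separated by at least
    ``min_lag`` intervening elements.  Implemented as a randomized
    backtracking search over item placements; the search is exhaustive,
    so a provably infeasible input raises rather than looping forever.
    """
    items = list(items)
    n = len(items)
    uniq: dict = {}
    for it in items:
        uniq[it] = uniq.get(it, 0) + 1
    keys = list(uniq)
    counts = [uniq[k] for k in keys]
    # necessary condition: the most frequent item needs room for its spacing
    if counts and (max(counts) - 1) * (min_lag + 1) + 1 > n:
        raise InfeasibleScheduleError(
            f"an item occurs {max(counts)} times; min_lag={min_lag} needs a "
            f"sequence of length >= {(max(counts) - 1) * (min_lag + 1) + 1}, got {n}"
        )

    out: list[int] = []
    last_pos = [-(min_lag + 1)] * len(keys)
    remaining = counts[:]

    def backtrack(pos: int) -> bool:
        if pos == n:
            return True
        candidates = [
            k for k in range(len(keys))
            if remaining[k] > 0 and pos - last_pos[k] > min_lag
        ]
        rng.shuffle(candidates)
        for k in candidates:
            prev = last_pos[k]
            last_pos[k] = pos
            remaining[k] -= 1
            out.append(k)
            if backtrack(pos + 1):
                return True
            out.pop()
            remaining[k] += 1
            last_pos[k] = prev
        return False

    if not backtrack(0):
        raise InfeasibleScheduleError(
            f"no ordering of {n} items satisfies min_lag={min_lag}"
        )
    return [keys[k] for k in out]


def bin_quality_by_mos(mos: float) -> str:
    """Map a mean opinion score (0-100) to a quality level.

    Scores below 35 are low quality, above 70 high quality; the closed
    interval [35, 70] (boundaries included) is neutral.
    """
    if not 0 <= mos <= 100:
        raise ValueError(f"MOS must lie in [0, 100], got {mos}")
    if mos < 35:
        return "low"
    if mos > 70:
        return "high"
    return "neutral"


def _image_table(config: DesignConfig) -> pd.DataFrame:
    """One row per unique image: id, task, category, quality."""
    rows = []
    for task in TASKS:
        for cat, qual in itertools.product(CATEGORIES, QUALITIES):
            for j in range(config.images_per_cell):
                rows.append(
                    {
                        "image_id": f"{task}_{cat}_{qual}_{j:03d}",
                        "task": task,
                        "category": cat,
                        "quality": qual,
                    }
                )
    return pd.DataFrame(rows)


def _task_sequence(images: pd.DataFrame, config: DesignConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Ordered trial sequence for one task (repetition-controlled)."""
    ids = list(images["image_id"]) * config.presentations_per_image
    order = shuffle_with_min_lag(ids, config.min_lag, rng)
    seen: dict[str, int] = {}
    reps = []
    for im in order:
        seen[im] = seen.get(im, 0) + 1
        reps.append(seen[im])
    seq = pd.DataFrame({"image_id": order, "repetition": reps})
    return seq.merge(images, on="image_id", how="left")


def _one_participant(config: DesignConfig, images: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    seqs = {
        task: _task_sequence(images[images["task"] == task], config, rng)
        for task in TASKS
    }
    cursor = {task: 0 for task in TASKS}
    rows = []
    for run in range(1, config.n_runs + 1):
        order = ODD_RUN_BLOCK_ORDER if run % 2 == 1 else EVEN_RUN_BLOCK_ORDER
        for block_idx, task in enumerate(order, start=1):
            isis = solve_isi_schedule(
                config.trials_per_block, config.isi_menu_s,
                float(config.isi_sum_s), rng,
            )
            block_onset = Fraction((block_idx - 1)) * Fraction(config.block_total_s)
            t = block_onset + Fraction(config.instruction_s)
            c = cursor[task]
            chunk = seqs[task].iloc[c : c + config.trials_per_block]
            cursor[task] = c + config.trials_per_block
            for trial_idx, (_, tr) in enumerate(chunk.iterrows(), start=1):
                rows.append(
                    {
                        "run": run,
                        "block": block_idx,
                        "task": task,
                        "trial": trial_idx,
                        "image_id": tr["image_id"],
                        "category": tr["category"],
                        "quality": tr["quality"],
                        "repetition": int(tr["repetition"]),
                        "onset_s": float(t),
                        "duration_s": config.image_duration_s,
                        "isi_s": isis[trial_idx - 1],
                    }
                )
                t += Fraction(config.image_duration_s) + Fraction(isis[trial_idx - 1])
    return pd.DataFrame(rows)


@dataclass
class StimulusDesign:
    """The full trial table plus the image catalogue and config used."""

    trials: pd.DataFrame
    images: pd.DataFrame
    config: DesignConfig

    def participant_trials(self, participant: str) -> pd.DataFrame:
        return self.trials[self.trials["participant"] == participant].reset_index(
            drop=True
        )

    @property
    def participants(self) -> list[str]:
        return list(pd.unique(self.trials["participant"]))


def generate_design(config: DesignConfig | None = None) -> StimulusDesign:
    """Generate the complete counterbalanced trial table.

    With ``shared_order=True`` (default) every participant sees the same
    stimulus sequence; otherwise sequences are re-randomized per
    participant.  Fully determined by ``config.seed``.
    """
    config = config or DesignConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    images = _image_table(config)

    frames = []
    base = _one_participant(config, images, rng)
    for p in range(1, config.n_participants + 1):
        tbl = base if config.shared_order else (
            base if p == 1 else _one_participant(config, images, rng)
        )
        tbl = tbl.copy()
        tbl.insert(0, "participant", f"sub-{p:02d}")
        frames.append(tbl)
    trials = pd.concat(frames, ignore_index=True)
    return StimulusDesign(trials=trials, images=images, config=config)


def block_durations(design: StimulusDesign) -> pd.DataFrame:
    """Per block: last-event offset + trailing ISI minus block onset.

    Uses exact rational arithmetic so the 96 s identity can be asserted
    to decimal exactness.
    """
    cfg = design.config
    rows = []
    for (p, run, block), grp in design.trials.groupby(
        ["participant", "run", "block"], sort=True
    ):
        onset = Fraction(block - 1) * Fraction(cfg.block_total_s)
        last = grp.iloc[-1]
        end = (
            Fraction(str(last["onset_s"]))
            + Fraction(str(last["duration_s"]))
            + Fraction(str(last["isi_s"]))
        )
        rows.append(
            {
                "participant": p,
                "run": run,
                "block": block,
                "duration_s": float(end - onset),
            }
        )
    return pd.DataFrame(rows)
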