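"""Adaptive contrast staircase and behavioral simulation.

The masking experiment titrates stimulus contrast with a staircase over a
fixed grid of contrast levels (2--77% in 3-point steps, 26 levels).  During
the first block a fixed rule is used (+1 level on an identification error,
-2 levels after two consecutive correct responses).  From the second block on
the rule adapts to whichever perceptual-awareness-scale (PAS) rating the
simulated observer has used least so far, trading accuracy against rating
coverage so that all four ratings (NE, WG, ACE, CE) occur often enough for
condition-resolved analyses.

The observer itself is a simple psychophysical model: identification
correctness is Bernoulli with a lapse-adjusted logistic psychometric function
of contrast, and the PAS rating is an ordinal bin of a noisy internal signal
driven by contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "PsychometricModel",
    "init_staircase",
    "staircase_update",
    "simulate_behavior",
]

#: PAS rating names in ascending order of reported vividness.
PAS_LABELS = ("NE", "WG", "ACE", "CE")


@dataclass(frozen=True)
class StaircaseConfig:
    """Contrast grid and adjustment rules of the adaptive staircase.

    ``first_block_rules`` is ``(increment_on_error, decrement_after_2_correct)``
    in grid levels.  ``adaptive_rules`` maps a PAS rating (1..4) to
    ``(decrement_after_2_correct, increment_on_error)``; the rule belonging to
    the currently least-used rating is applied.
    """

    min_contrast: float = 2.0
    max_contrast: float = 77.0
    step: float = 3.0
    first_block_rules: tuple[int, int] = (1, 2)
    adaptive_rules: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (3, 1), 2: (2, 1), 3: (1, 2), 4: (1, 3)}
    )

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("staircase step must be positive")
        if self.min_contrast > self.max_contrast:
            raise ValueError("min_contrast must not exceed max_contrast")
        if any(d <= 0 or i <= 0 for d, i in self.adaptive_rules.values()):
            raise ValueError("adaptive rule magnitudes must be positive")
        if any(v <= 0 for v in self.first_block_rules):
            raise ValueError("first-block rule magnitudes must be positive")


@dataclass
class StaircaseState:
    """Mutable staircase position and bookkeeping counters.

    ``level_index`` is 1-based into the level grid.  ``pas_usage`` counts how
    often each rating (1..4) has been given so far; the adaptive rule targets
    its argmin (ties resolved toward the lower rating).
    """

    level_index: int
    consecutive_correct: int = 0
    pas_usage: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0, 4: 0})
    block_index: int = 1


@dataclass(frozen=True)
class PsychometricModel:
    """Simulated observer linking contrast to identification and PAS rating.

    Identification (2-alternative) is Bernoulli with
    ``p = lapse/2 + (1 - lapse) * logistic(id_slope * (c - id_threshold))``,
    so accuracy is 0.5 at ``id_threshold``.  The PAS rating is the ordinal bin
    of an internal signal ``c + N(0, pas_noise_sd)`` against the three ordered
    cutpoints in ``pas_thresholds``.
    """

    id_threshold: float = 25.0
    id_slope: float = 0.12
    lapse: float = 0.02
    pas_thresholds: tuple[float, float, float] = (18.0, 30.0, 42.0)
    pas_noise_sd: float = 9.0

    def __post_init__(self) -> None:
        t = self.pas_thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValueError("pas_thresholds must be strictly increasing")
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")
        if self.id_slope <= 0:
            raise ValueError("id_slope must be positive")

    def p_correct(self, contrast: np.ndarray | float) -> np.ndarray | float:
        return self.lapse / 2.0 + (1.0 - self.lapse) * expit(
            self.id_slope * (np.asarray(contrast, dtype=float) - self.id_threshold)
        )

    def sample_pas(self, contrast: float, rng: np.random.Generator) -> int:
        signal = contrast + rng.normal(0.0, self.pas_noise_sd)
        return 1 + int(np.sum(signal > np.asarray(self.pas_thresholds)))


def init_staircase(config: StaircaseConfig) -> tuple[np.ndarray, StaircaseState]:
    """Build the contrast level grid and the starting state.

    The grid is the arithmetic sequence ``min, min+step, ...`` capped at
    ``max_contrast``.  The staircase starts at the middle level (1-based index
    ``(n+1)//2``) with zeroed counters.
    """
    n_levels = int(np.floor((config.max_contrast - config.min_contrast) / config.step + 1e-9)) + 1
    grid = config.min_contrast + config.step * np.arange(n_levels)
    state = StaircaseState(level_index=(n_levels + 1) // 2)
    return grid, state


def _least_used_pas(usage: dict[int, int]) -> int:
    # ties go to the lower rating
    return min(usage, key=lambda r: (usage[r], r))


def staircase_update(
    state: StaircaseState,
    correct: bool,
    config: StaircaseConfig,
    adaptive: bool,
) -> StaircaseState:
    """Advance the staircase one trial; returns a new state.

    First-block mode uses the fixed (+1 error / -2 after two correct) rule.
    Adaptive mode applies the rule of the currently least-used PAS rating.
    The two-consecutive-correct counter resets whenever a decrement fires or
    an error occurs.  The level index is clamped to the grid.
    """
    n_levels = int(np.floor((config.max_contrast - config.min_contrast) / config.step + 1e-9)) + 1
    if adaptive:
        dec, inc = config.adaptive_rules[_least_used_pas(state.pas_usage)]
    else:
        inc, dec = config.first_block_rules
    idx = state.level_index
    streak = state.consecutive_correct
    if correct:
        streak += 1
        if streak >= 2:
            idx -= dec
            streak = 0
    else:
        idx += inc
        streak = 0
    idx = min(max(idx, 1), n_levels)
    return replace(state, level_index=idx, consecutive_correct=streak,
                   pas_usage=dict(state.pas_usage))


def simulate_behavior(
    psychometric: PsychometricModel,
    config: StaircaseConfig | None = None,
    n_blocks: int = 11,
    trials_per_block: int = 72,
    seed: int = 0,
    stimuli: tuple[str, str] = ("square", "diamond"),
) -> pd.DataFrame:
    """Simulate a full staircased session; returns the trial table.

    Columns: ``trial_id, stimulus, contrast, correct, pas, block``.  Stimulus
    identity is balanced and randomly ordered within each block.  Block 1 runs
    the fixed first-block staircase rule; later blocks use the adaptive rule.
    Deterministic given ``seed``.
    """
    if config is None:
        config = StaircaseConfig()
    rng = np.random.default_rng(seed)
    grid, state = init_staircase(config)
    rows: list[tuple] = []
    trial_id = 0
    for block in range(1, n_blocks + 1):
        half = trials_per_block // 2
        stim_seq = np.array([0] * half + [1] * (trials_per_block - half))
        rng.shuffle(stim_seq)
        for s in stim_seq:
            contrast = float(grid[state.level_index - 1])
            correct = bool(rng.random() < psychometric.p_correct(contrast))
            pas = psychometric.sample_pas(contrast, rng)
            rows.append((trial_id, stimuli[s], contrast, correct, pas, block))
            state.pas_usage[pas] += 1
            state = staircase_update(state, correct, config, adaptive=block > 1)
            trial_id += 1
        state.block_index = block + 1
    return pd.DataFrame(
        rows, columns=["trial_id", "stimulus", "contrast", "correct", "pas", "block"]
    )
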