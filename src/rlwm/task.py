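"""Construction of RLWM task instances.

The task is a blocked stimulus-response learning paradigm: within a block,
``set_size`` novel stimuli are each shown ``iterations_per_stimulus`` times in
pseudo-random order and the participant must learn, by trial and error, which
of ``n_actions`` buttons is correct for each stimulus.  Multiple stimuli may
map to the same button.  Correct responses earn +1 or +2 points
probabilistically; incorrect responses earn 0.  After training, a surprise
test phase presents pairs of stimuli drawn from across all blocks and asks
which member was rewarded more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "BlockDesign",
    "TaskDesign",
    "generate_task",
    "build_test_pairs",
]


@dataclass
class TaskConfig:
    """Structural parameters of the training and test phases.

    Defaults follow the standard design: set sizes 2-5, nine iterations per
    stimulus, three response buttons, and an 80/20 split between +2 and +1
    points on correct trials.
    """

    set_sizes: tuple[int, ...] = (2, 3, 4, 5)
    blocks_per_set_size: dict[int, int] = field(
        default_factory=lambda: {2: 3, 3: 3, 4: 2, 5: 2}
    )
    iterations_per_stimulus: int = 9
    n_actions: int = 3
    # P(points) on correct trials; incorrect trials always earn 0.
    reward_points: dict[int, float] = field(default_factory=lambda: {2: 0.8, 1: 0.2})
    incorrect_points: int = 0
    test_pairs_per_stimulus: int = 4
    rng_seed: int | None = None

    def validate(self) -> None:
        if not self.set_sizes:
            raise ValueError("set_sizes must be non-empty")
        for ns in self.set_sizes:
            if not 2 <= ns <= 5:
                raise ValueError(f"set size {ns} outside the supported range [2, 5]")
            if ns not in self.blocks_per_set_size:
                raise ValueError(f"blocks_per_set_size missing an entry for set size {ns}")
        if self.iterations_per_stimulus < 1:
            raise ValueError("iterations_per_stimulus must be >= 1")
        if self.n_actions < 2:
            raise ValueError("n_actions must be >= 2")
        total = sum(self.reward_points.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"reward_points probabilities sum to {total}, not 1")


@dataclass
class BlockDesign:
    block_id: int
    set_size: int
    stimulus_ids: list[int]
    correct_action: dict[int, int]
    trial_sequence: list[int]


@dataclass
class TaskDesign:
    """A concrete task instance: ordered blocks plus test-phase pairs."""

    config: TaskConfig
    blocks: list[BlockDesign]
    test_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def all_stimuli(self) -> list[int]:
        out: list[int] = []
        for b in self.blocks:
            out.extend(b.stimulus_ids)
        return out

    @property
    def n_training_trials(self) -> int:
        return sum(len(b.trial_sequence) for b in self.blocks)

    def set_size_of(self, stimulus: int) -> int:
        for b in self.blocks:
            if stimulus in b.correct_action:
                return b.set_size
        raise KeyError(f"stimulus {stimulus} not in any block")

    def to_trial_frame(self) -> pd.DataFrame:
        """One row per training trial: block, set_size, stimulus, correct_action."""
        rows = []
        for b in self.blocks:
            for i, s in enumerate(b.trial_sequence):
                rows.append(
                    {
                        "block_id": b.block_id,
                        "set_size": b.set_size,
                        "trial_index": i,
                        "stimulus_id": s,
                        "correct_action": b.correct_action[s],
                    }
                )
        return pd.DataFrame(rows)

    def to_pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"left_stimulus": a, "right_stimulus": b} for a, b in self.test_pairs]
        )


def _pseudo_random_sequence(
    stimuli: list[int], iterations: int, rng: np.random.Generator
) -> list[int]:
    """Shuffle per iteration sweep, rejecting immediate repeats at sweep joins.

    Each stimulus appears exactly once per sweep, hence exactly ``iterations``
    times overall, and no stimulus ever appears twice in a row.
    """
    if len(stimuli) < 2:
        raise ValueError(
            "pseudo-random sequencing without immediate repeats requires >= 2 stimuli"
        )
    seq: list[int] = []
    for _ in range(iterations):
        sweep = list(rng.permutation(stimuli))
        if seq and sweep[0] == seq[-1]:
            # swap the offending head with a later element
            j = int(rng.integers(1, len(sweep)))
            sweep[0], sweep[j] = sweep[j], sweep[0]
        seq.extend(sweep)
    return seq


def generate_task(config: TaskConfig, rng: np.random.Generator) -> TaskDesign:
    """Build a full training-phase design from ``config``.

    Blocks of each set size are created with fresh (globally unique) stimulus
    ids, correct actions are assigned uniformly at random, trial sequences are
    pseudo-random with no immediate stimulus repeats, and block order is
    shuffled.
    """
    config.validate()
    blocks: list[BlockDesign] = []
    next_stim = 0
    spec = [
        ns for ns in config.set_sizes for _ in range(config.blocks_per_set_size[ns])
    ]
    order = rng.permutation(len(spec))
    for block_id, idx in enumerate(order):
        ns = spec[idx]
        stimuli = list(range(next_stim, next_stim + ns))
        next_stim += ns
        correct = {s: int(rng.integers(0, config.n_actions)) for s in stimuli}
        seq = _pseudo_random_sequence(stimuli, config.iterations_per_stimulus, rng)
        blocks.append(
            BlockDesign(
                block_id=block_id,
                set_size=ns,
                stimulus_ids=stimuli,
                correct_action=correct,
                trial_sequence=seq,
            )
        )
    return TaskDesign(config=config, blocks=blocks)


def build_test_pairs(
    design: TaskDesign,
    pairs_per_stimulus: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Sample test-phase stimulus pairs from across all training blocks.

    Pairing proceeds in rounds: each round shuffles all stimuli and pairs them
    consecutively, so every stimulus appears exactly once per round (twice when
    the total count is odd and it absorbs the leftover).  Pairs never contain
    the same stimulus twice and left/right assignment is random.
    """
    if rng is None:
        rng = np.random.default_rng(design.config.rng_seed)
    if pairs_per_stimulus is None:
        pairs_per_stimulus = design.config.test_pairs_per_stimulus
    stimuli = design.all_stimuli
    if len(stimuli) < 2:
        raise ValueError("need at least 2 stimuli to build test pairs")
    pairs: list[tuple[int, int]] = []
    for _ in range(pairs_per_stimulus):
        perm = list(rng.permutation(stimuli))
        if len(perm) % 2 == 1:
            # leftover stimulus gets paired with a random partner
            leftover = perm.pop()
            partner = perm[int(rng.integers(0, len(perm)))]
            pairs.append((leftover, partner))
        for i in range(0, len(perm) - 1, 2):
            pairs.append((perm[i], perm[i + 1]))
    # randomize presentation side
    out = []
    for a, b in pairs:
        if rng.random() < 0.5:
            a, b = b, a
        out.append((int(a), int(b)))
    return out
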