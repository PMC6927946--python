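"""Constrained pseudo-random S+/S- trial sequencing and odor counterbalancing.

Go/no-go sessions present a rewarded (S+) and an unrewarded (S-) stimulus.
To keep the reward base rate unbiased while preventing the animal from
exploiting local structure, trials are served from pre-generated blocks in
which every fixed-size bin contains exactly the prescribed number of S+
trials and no run of identical labels exceeds a cap.  A block is consumed
in order and only replaced by a freshly generated block once it has been
fully served.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Sequence

import numpy as np

__all__ = [
    "TrialLabel",
    "SequenceParams",
    "SequenceBlock",
    "SequenceConfigError",
    "Scheduler",
    "CounterbalanceAssignment",
    "generate_block",
    "validate_labels",
    "assign_counterbalance",
]


class TrialLabel(enum.Enum):
    """The two stimulus classes of a go/no-go task; S_PLUS is rewarded."""

    S_PLUS = "S_PLUS"
    S_MINUS = "S_MINUS"

    def __str__(self) -> str:  # compact form used in sequence files
        return "S+" if self is TrialLabel.S_PLUS else "S-"


class SequenceConfigError(ValueError):
    """Raised when sequence constraints are unsatisfiable or inconsistent."""


@dataclasses.dataclass(frozen=True)
class SequenceParams:
    """Constraints for one pseudo-random block.

    Defaults encode the standard protocol: blocks of 1000 trials, exactly
    50 S+ within every consecutive 100-trial bin, and no more than three
    consecutive identical labels.
    """

    block_length: int = 1000
    bin_size: int = 100
    per_bin_splus: int = 50
    max_run: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_length <= 0 or self.bin_size <= 0:
            raise SequenceConfigError("block_length and bin_size must be positive")
        if self.block_length % self.bin_size != 0:
            raise SequenceConfigError(
                f"block_length {self.block_length} not divisible by bin_size {self.bin_size}"
            )
        if not 0 <= self.per_bin_splus <= self.bin_size:
            raise SequenceConfigError(
                f"per_bin_splus {self.per_bin_splus} outside [0, bin_size={self.bin_size}]"
            )
        if self.max_run < 1:
            raise SequenceConfigError("max_run must be >= 1")
        majority = max(self.per_bin_splus, self.bin_size - self.per_bin_splus)
        minority = self.bin_size - majority
        if majority > (minority + 1) * self.max_run:
            raise SequenceConfigError(
                f"max_run {self.max_run} too small: {majority} majority labels cannot be "
                f"split by {minority} minority labels into runs of <= {self.max_run}"
            )


@dataclasses.dataclass(frozen=True)
class SequenceBlock:
    """An immutable label sequence satisfying the balance and run constraints."""

    labels: tuple[TrialLabel, ...]
    params: SequenceParams
    block_id: int = 0

    def __len__(self) -> int:
        return len(self.labels)


def validate_labels(labels: Sequence[TrialLabel], params: SequenceParams) -> list[str]:
    """Check a label sequence against the block constraints.

    Returns a list of human-readable violations; empty means valid.  Runs are
    evaluated across bin boundaries over the whole sequence.
    """
    violations: list[str] = []
    if len(labels) != params.block_length:
        violations.append(
            f"length {len(labels)} != block_length {params.block_length}"
        )
        return violations
    for start in range(0, params.block_length, params.bin_size):
        n_plus = sum(
            1 for lab in labels[start : start + params.bin_size] if lab is TrialLabel.S_PLUS
        )
        if n_plus != params.per_bin_splus:
            violations.append(
                f"bin starting at {start}: {n_plus} S+ != required {params.per_bin_splus}"
            )
    run = 0
    prev: TrialLabel | None = None
    for i, lab in enumerate(labels):
        run = run + 1 if lab is prev else 1
        prev = lab
        if run == params.max_run + 1:
            violations.append(
                f"run of {lab} longer than max_run {params.max_run} ending at index >= {i}"
            )
    return violations


def _fill_block(rng: np.random.Generator, params: SequenceParams) -> list[TrialLabel] | None:
    """One sampling attempt: uniform choice among feasible labels per position.

    Feasibility look-ahead (within the current bin, given a trailing run of
    length r of the candidate label): the remaining candidate labels x must
    fit into runs of at most max_run separated by the y remaining other
    labels, i.e. x <= (max_run - r) + y*max_run, and symmetrically
    y <= (x + 1)*max_run.  Returns None if a dead end is hit (the caller
    restarts), which can only happen through a bin boundary.
    """
    mr = params.max_run
    labels: list[TrialLabel] = []
    run_len = 0
    run_lab: TrialLabel | None = None
    n_bins = params.block_length // params.bin_size
    for _ in range(n_bins):
        remaining = {
            TrialLabel.S_PLUS: params.per_bin_splus,
            TrialLabel.S_MINUS: params.bin_size - params.per_bin_splus,
        }
        for _ in range(params.bin_size):
            cands = []
            for lab in (TrialLabel.S_PLUS, TrialLabel.S_MINUS):
                if remaining[lab] == 0:
                    continue
                r = run_len + 1 if lab is run_lab else 1
                if r > mr:
                    continue
                x = remaining[lab] - 1
                other = TrialLabel.S_MINUS if lab is TrialLabel.S_PLUS else TrialLabel.S_PLUS
                y = remaining[other]
                if x > (mr - r) + y * mr or y > (x + 1) * mr:
                    continue
                cands.append(lab)
            if not cands:
                return None
            lab = cands[int(rng.integers(len(cands)))] if len(cands) > 1 else cands[0]
            run_len = run_len + 1 if lab is run_lab else 1
            run_lab = lab
            remaining[lab] -= 1
            labels.append(lab)
    return labels


def generate_block(
    params: SequenceParams, block_id: int = 0, max_attempts: int = 10_000
) -> SequenceBlock:
    """Generate a pseudo-random block satisfying all constraints.

    Pure function of ``params`` (including its seed): identical inputs yield
    an identical block.  Raises :class:`SequenceConfigError` if the
    constraints are unsatisfiable or no valid block is found within
    ``max_attempts`` restarts.
    """
    rng = np.random.Generator(np.random.PCG64(params.seed))
    for _ in range(max_attempts):
        labels = _fill_block(rng, params)
        if labels is not None:
            return SequenceBlock(tuple(labels), params, block_id)
    raise SequenceConfigError(
        f"no admissible sequence found in {max_attempts} attempts for {params}"
    )


class Scheduler:
    """Serve block labels strictly in order, independently per animal.

    Each animal consumes its own stream of blocks; a new block (with a new
    ``block_id`` and a deterministically derived seed) is generated only when
    the current one is exhausted, so no label can repeat before the full
    block has been served.
    """

    def __init__(self, params: SequenceParams, seed: int | None = None) -> None:
        self.params = params
        self.seed = params.seed if seed is None else seed
        self._blocks: dict[str, SequenceBlock] = {}
        self._cursor: dict[str, int] = {}
        self._animal_index: dict[str, int] = {}
        self._block_count: dict[str, int] = {}

    def register(self, animal_id: str) -> None:
        if animal_id in self._cursor:
            raise ValueError(f"animal {animal_id!r} already registered")
        idx = len(self._animal_index)
        self._animal_index[animal_id] = idx
        self._block_count[animal_id] = 0
        self._blocks[animal_id] = self._new_block(animal_id)
        self._cursor[animal_id] = 0

    def _new_block(self, animal_id: str) -> SequenceBlock:
        count = self._block_count[animal_id]
        ss = np.random.SeedSequence(
            entropy=(self.seed, self._animal_index[animal_id], count)
        )
        derived = int(ss.generate_state(1)[0] % (2**31))
        block_params = dataclasses.replace(self.params, seed=derived)
        self._block_count[animal_id] = count + 1
        return generate_block(block_params, block_id=count)

    def cursor(self, animal_id: str) -> tuple[int, int]:
        """(block_id, index) of the next label to be served."""
        if animal_id not in self._cursor:
            raise KeyError(f"animal {animal_id!r} not registered with scheduler")
        return self._blocks[animal_id].block_id, self._cursor[animal_id]

    def draw_next(self, animal_id: str) -> TrialLabel:
        if animal_id not in self._cursor:
            raise KeyError(f"animal {animal_id!r} not registered with scheduler")
        block = self._blocks[animal_id]
        i = self._cursor[animal_id]
        label = block.labels[i]
        i += 1
        if i >= len(block):
            self._blocks[animal_id] = self._new_block(animal_id)
            i = 0
        self._cursor[animal_id] = i
        return label


@dataclasses.dataclass(frozen=True)
class CounterbalanceAssignment:
    """Per-animal S+/S- odor designation, balanced within treatment groups."""

    splus_odor: dict[str, str]
    sminus_odor: dict[str, str]
    groups: dict[str, str]


def assign_counterbalance(
    cohort: Sequence[tuple[str, str]],
    odor_pair: tuple[str, str],
    seed: int = 0,
) -> CounterbalanceAssignment:
    """Designate each odor as S+ for half of every treatment group.

    Within each group the split differs by at most one animal; for odd group
    sizes the odor receiving the extra animal is seed-determined.  This
    cancels intrinsic odor preferences at the group level.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    odor_a, odor_b = odor_pair
    if odor_a == odor_b:
        raise ValueError("odor pair must contain two distinct odors")
    ids = [a for a, _ in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal_id in cohort")
    rng = np.random.Generator(np.random.PCG64(seed))
    splus: dict[str, str] = {}
    sminus: dict[str, str] = {}
    groups = dict(cohort)
    by_group: dict[str, list[str]] = {}
    for animal, group in cohort:
        by_group.setdefault(group, []).append(animal)
    for group in sorted(by_group):
        members = list(by_group[group])
        rng.shuffle(members)
        half = len(members) // 2
        n_a = half + (int(rng.integers(2)) if len(members) % 2 else 0)
        for i, animal in enumerate(members):
            if i < n_a:
                splus[animal], sminus[animal] = odor_a, odor_b
            else:
                splus[animal], sminus[animal] = odor_b, odor_a
    return CounterbalanceAssignment(splus, sminus, groups)
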