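"""Counterbalanced trial-sequence generation for the two adjustment studies.

Study 1: two sessions of 8 blocks x 144 trials (2304 trials total).  Tasks
alternate in predictable miniblocks of four (AAAA BBBB ...), the rotation
direction is constant within a session, 20% of trials withhold the response
bar, and the 18 distance bins are counterbalanced over the four serial
positions within a miniblock (16 per bin x position per session, 32 over
the experiment).

Study 2: 5 blocks x 396 trials (1980 total; 2 blocks in session 1, 3 in
session 2).  Task order is random, 27.27% of trials (540) replace the
adjustment response with a speeded 2AFC probe (twice as often on rotation
as on no-rotation trials), and among non-2AFC trials every distance bin
occurs 40 times per task (rotation occurrences split equally over the two
directions).

Every trial carries a design-assigned distance bin; orientations are
realized by drawing an actual distance uniformly within the assigned bin
and chaining ``current = wrap(previous - d)`` within a block, so that
``d = previous - current``.  The first trial of each block starts the chain
at a fresh uniform-random orientation; its assigned bin therefore has no
realized counterpart and the analysis never uses it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import wrap_orientation

N_BINS = 18
BIN_WIDTH = 10.0
BIN_EDGES = np.arange(-90.0, 90.0 + BIN_WIDTH, BIN_WIDTH)

TASK_NO_ROTATION = "no_rotation"
TASK_ROTATE_CW = "rotate_cw"
TASK_ROTATE_CCW = "rotate_ccw"
MODE_ADJUST = "adjust"
MODE_NONE = "none"
MODE_2AFC = "two_afc"

#: fixed on-disk schema of a trial table
TRIAL_COLUMNS = [
    "study",
    "subject",
    "session",
    "block",
    "trial",
    "task",
    "response_mode",
    "bin",
    "stimulus_deg",
]

STUDY1_BLOCKS_PER_SESSION = 8
STUDY1_TRIALS_PER_BLOCK = 144
STUDY1_NO_RESPONSE_FRACTION = 0.20
STUDY2_TRIALS_PER_BLOCK = 396
STUDY2_BLOCKS_BY_SESSION = {1: 2, 2: 3}
STUDY2_TWO_AFC_FRACTION = 0.2727  # 540 of 1980 trials
STUDY2_REPS_PER_TASK_PER_BIN = 40

__all__ = [
    "make_bins",
    "bin_index",
    "bin_interval",
    "generate_study1_design",
    "generate_study2_design",
    "validate_counterbalance",
    "CounterbalanceReport",
    "TRIAL_COLUMNS",
]


def make_bins():
    """The 18 half-open 10-degree distance bins partitioning [-90, 90)."""
    return [(BIN_EDGES[i], BIN_EDGES[i + 1]) for i in range(N_BINS)]


def bin_interval(index: int):
    if not 0 <= index < N_BINS:
        raise ValueError(f"bin index {index} out of range 0..{N_BINS - 1}")
    return BIN_EDGES[index], BIN_EDGES[index + 1]


def bin_index(distance_deg):
    """Bin index of signed distance(s); +90 wraps onto the -90 edge (bin 0)."""
    d = np.asarray(distance_deg, dtype=float)
    d = np.mod(d + 90.0, 180.0) - 90.0  # -> [-90, 90)
    idx = np.floor((d + 90.0) / BIN_WIDTH).astype(int)
    idx = np.clip(idx, 0, N_BINS - 1)
    return idx if idx.ndim else int(idx)


def _subject_parity(subject_id) -> int:
    """Stable 0/1 parity of a subject label, used to counterbalance the
    study-1 rotation direction across subjects."""
    digest = hashlib.md5(str(subject_id).encode()).hexdigest()
    return int(digest, 16) % 2


def _realize_orientations(bins: np.ndarray, block_starts: np.ndarray, rng) -> np.ndarray:
    """Chain stimulus orientations from assigned bins.

    ``block_starts`` flags rows that begin a block: they restart the chain at
    a uniform-random orientation.  Elsewhere current = wrap(previous - d)
    with d drawn uniformly within the assigned bin.
    """
    n = len(bins)
    lo = BIN_EDGES[bins]
    d = rng.uniform(lo, lo + BIN_WIDTH)
    theta = np.empty(n)
    for i in range(n):
        if block_starts[i]:
            theta[i] = rng.uniform(0.0, 180.0)
        else:
            theta[i] = theta[i - 1] - d[i]
    return wrap_orientation(theta)


def generate_study1_design(
    subject_id,
    seed: int,
    first_task: str = TASK_NO_ROTATION,
    rotation_direction_session1: str | None = None,
) -> pd.DataFrame:
    """Generate the full two-session study-1 trial table for one subject.

    The rotation direction is constant within a session and flips between
    sessions; its session-1 value defaults to a stable function of the
    subject label so that it is counterbalanced across a cohort.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if first_task not in (TASK_NO_ROTATION, "rotation"):
        raise ValueError("first_task must be 'no_rotation' or 'rotation'")
    rng = np.random.default_rng(seed)
    if rotation_direction_session1 is None:
        rotation_direction_session1 = (
            TASK_ROTATE_CW if _subject_parity(subject_id) == 0 else TASK_ROTATE_CCW
        )
    other = (
        TASK_ROTATE_CCW
        if rotation_direction_session1 == TASK_ROTATE_CW
        else TASK_ROTATE_CW
    )
    rot_dir = {1: rotation_direction_session1, 2: other}

    n_per_session = STUDY1_BLOCKS_PER_SESSION * STUDY1_TRIALS_PER_BLOCK
    n_miniblocks = n_per_session // 4
    reps = n_miniblocks // N_BINS  # 16 per bin x position per session
    frames = []
    for session in (1, 2):
        # bins per serial position: each bin exactly `reps` times per position
        bins_by_pos = np.empty((n_miniblocks, 4), dtype=int)
        for pos in range(4):
            seq = np.repeat(np.arange(N_BINS), reps)
            rng.shuffle(seq)
            bins_by_pos[:, pos] = seq
        bins = bins_by_pos.reshape(-1)

        # predictable AAAA BBBB task pattern
        mini_is_rotation = (np.arange(n_miniblocks) % 2).astype(bool)
        if first_task == "rotation":
            mini_is_rotation = ~mini_is_rotation
        task = np.where(
            np.repeat(mini_is_rotation, 4), rot_dir[session], TASK_NO_ROTATION
        )

        # 20% no-response trials, pseudo-random, never the session's first trial
        n_none = round(STUDY1_NO_RESPONSE_FRACTION * n_per_session)
        none_idx = rng.choice(np.arange(1, n_per_session), size=n_none, replace=False)
        response_mode = np.full(n_per_session, MODE_ADJUST, dtype=object)
        response_mode[none_idx] = MODE_NONE

        trial = np.arange(n_per_session)
        block = trial // STUDY1_TRIALS_PER_BLOCK
        block_starts = trial % STUDY1_TRIALS_PER_BLOCK == 0
        stimulus = _realize_orientations(bins, block_starts, rng)

        frames.append(
            pd.DataFrame(
                {
                    "study": 1,
                    "subject": subject_id,
                    "session": session,
                    "block": block,
                    "trial": trial,
                    "task": task,
                    "response_mode": response_mode,
                    "bin": bins,
                    "stimulus_deg": stimulus,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def generate_study2_design(subject_id, seed: int) -> pd.DataFrame:
    """Generate the full two-session study-2 trial table for one subject."""
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    n_total = STUDY2_TRIALS_PER_BLOCK * sum(STUDY2_BLOCKS_BY_SESSION.values())
    n_2afc = round(STUDY2_TWO_AFC_FRACTION * n_total)  # 540
    n_2afc_rot = round(n_2afc * 2 / 3)  # 360, split over cw/ccw
    n_2afc_norot = n_2afc - n_2afc_rot  # 180

    # counterbalanced non-2AFC core: 40 per bin per task, rotation split cw/ccw
    tasks, bins, modes = [], [], []
    for b in range(N_BINS):
        tasks += [TASK_NO_ROTATION] * STUDY2_REPS_PER_TASK_PER_BIN
        tasks += [TASK_ROTATE_CW] * (STUDY2_REPS_PER_TASK_PER_BIN // 2)
        tasks += [TASK_ROTATE_CCW] * (STUDY2_REPS_PER_TASK_PER_BIN // 2)
        bins += [b] * (2 * STUDY2_REPS_PER_TASK_PER_BIN)
    modes += [MODE_ADJUST] * len(tasks)
    # 2AFC catch trials: bins uniform at random, excluded from counterbalancing
    tasks += [TASK_ROTATE_CW] * (n_2afc_rot // 2) + [TASK_ROTATE_CCW] * (
        n_2afc_rot - n_2afc_rot // 2
    )
    tasks += [TASK_NO_ROTATION] * n_2afc_norot
    bins += list(rng.integers(0, N_BINS, size=n_2afc))
    modes += [MODE_2AFC] * n_2afc

    tasks = np.asarray(tasks, dtype=object)
    bins = np.asarray(bins, dtype=int)
    modes = np.asarray(modes, dtype=object)
    assert len(tasks) == n_total
    order = rng.permutation(n_total)  # random task order
    tasks, bins, modes = tasks[order], bins[order], modes[order]

    session = np.repeat(
        [1, 2],
        [
            STUDY2_BLOCKS_BY_SESSION[1] * STUDY2_TRIALS_PER_BLOCK,
            STUDY2_BLOCKS_BY_SESSION[2] * STUDY2_TRIALS_PER_BLOCK,
        ],
    )
    block_global = np.arange(n_total) // STUDY2_TRIALS_PER_BLOCK
    block = np.where(session == 1, block_global, block_global - STUDY2_BLOCKS_BY_SESSION[1])
    trial = np.where(
        session == 1,
        np.arange(n_total),
        np.arange(n_total) - STUDY2_BLOCKS_BY_SESSION[1] * STUDY2_TRIALS_PER_BLOCK,
    )
    block_starts = np.arange(n_total) % STUDY2_TRIALS_PER_BLOCK == 0
    stimulus = _realize_orientations(bins, block_starts, rng)

    return pd.DataFrame(
        {
            "study": 2,
            "subject": subject_id,
            "session": session,
            "block": block,
            "trial": trial,
            "task": tasks,
            "response_mode": modes,
            "bin": bins,
            "stimulus_deg": stimulus,
        }
    )[TRIAL_COLUMNS]


@dataclass
class CounterbalanceReport:
    counts: pd.DataFrame
    passed: bool
    expected: int


def validate_counterbalance(table: pd.DataFrame) -> CounterbalanceReport:
    """Check the design's distance-bin counterbalancing.

    Study 1: counts of assigned bins by serial position within the miniblock
    (all must be equal).  Study 2: counts of assigned bins by task
    (no-rotation vs rotation) among non-2AFC trials.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"malformed trial table, missing columns: {missing}")
    study = int(table["study"].iloc[0])
    if study == 1:
        t = table.copy()
        t["serial_pos"] = t["trial"] % 4 + 1
        counts = pd.crosstab(t["bin"], t["serial_pos"])
    elif study == 2:
        t = table[table["response_mode"] != MODE_2AFC].copy()
        t["task_class"] = np.where(
            t["task"] == TASK_NO_ROTATION, "no_rotation", "rotation"
        )
        counts = pd.crosstab(t["bin"], t["task_class"])
    else:
        raise ValueError(f"unknown study {study}")
    counts = counts.reindex(index=range(N_BINS), fill_value=0)
    values = counts.to_numpy()
    passed = bool(values.size > 0 and np.all(values == values.flat[0]))
    expected = int(values.flat[0]) if passed else -1
    return CounterbalanceReport(counts=counts, passed=passed, expected=expected)
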