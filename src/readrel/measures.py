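"""Word-level reading measures from fixation sequences and keypress logs.

Eye-tracking measures are computed from fixations that have already been
mapped to white-space-delimited words (drift correction and saccade detection
are upstream concerns).  The first pass of word ``w`` is the maximal run of
consecutive fixations on ``w`` that begins with the first fixation on ``w``,
provided no word to the right of ``w`` was fixated earlier; words first
reached only by a regression have no first pass and their first-pass measures
are missing.  Missing durations are encoded as NaN (never 0) so that
lognormal modelling downstream never sees zero reading times.

Self-paced reading yields one reaction time per word: the difference between
consecutive keypress timestamps (the first word is timed from screen onset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FixationSequence",
    "WordMeasures",
    "KeypressLog",
    "compute_word_measures",
    "spr_times",
    "measures_frame",
    "read_fixation_log",
    "read_keypress_log",
    "compute_measures_file",
]

DURATION_MEASURES = ("FFD", "FPRT", "RPD", "TFT")
ALL_MEASURES = ("FFD", "FPRT", "RPD", "TFT", "FPReg", "SKIP", "N_FIX")


@dataclass(frozen=True)
class FixationSequence:
    """Ordered, word-mapped fixations of one screen.

    ``word_index`` holds the 0-based position of the fixated word on the
    screen; ``duration`` is in milliseconds and must be positive.
    """

    word_index: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        wi = np.asarray(self.word_index, dtype=int)
        du = np.asarray(self.duration, dtype=float)
        if wi.shape != du.shape or wi.ndim != 1:
            raise ValueError("word_index and duration must be matching 1-d arrays")
        if wi.size and wi.min() < 0:
            raise ValueError("word indices must be >= 0")
        if wi.size and du.min() <= 0:
            raise ValueError("fixation durations must be positive")
        object.__setattr__(self, "word_index", wi)
        object.__setattr__(self, "duration", du)

    def __len__(self) -> int:
        return self.word_index.size


@dataclass
class WordMeasures:
    """Reading measures of a single word (durations in ms, NaN = missing)."""

    word_index: int
    FFD: float
    FPRT: float
    RPD: float
    TFT: float
    FPReg: float
    SKIP: int
    N_FIX: int


@dataclass(frozen=True)
class KeypressLog:
    """Ordered keypress timestamps (ms) of one self-paced-reading screen.

    Keypress k ends the display of word k; word indices are implicitly
    consecutive from 0.  ``onset`` is the screen-onset timestamp used to time
    the first word; if None, the first word's time is undefined (NaN).
    """

    timestamps: np.ndarray
    onset: float | None = None

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1 or ts.size == 0:
            raise ValueError("timestamps must be a non-empty 1-d array")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.onset is not None and ts[0] <= self.onset:
            raise ValueError("first keypress must follow screen onset")
        if self.onset is None and ts.size < 2:
            raise ValueError("need >= 2 keypresses or a screen onset")
        object.__setattr__(self, "timestamps", ts)


def compute_word_measures(
    fixations: FixationSequence, n_words: int
) -> list[WordMeasures]:
    """Compute FFD, FPRT, RPD, TFT, FPReg, SKIP and N_FIX for every word.

    Parameters
    ----------
    fixations
        Word-mapped fixation sequence of one screen.
    n_words
        Number of words on the screen; every fixated index must be < n_words.

    Returns
    -------
    list of :class:`WordMeasures`, one per word in screen order.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    wi = fixations.word_index
    du = fixations.duration
    if wi.size and wi.max() >= n_words:
        raise ValueError("fixated word index out of range")

    n_fix = np.zeros(n_words, dtype=int)
    tft = np.zeros(n_words)
    ffd = np.full(n_words, np.nan)
    fprt = np.full(n_words, np.nan)
    rpd = np.full(n_words, np.nan)
    fpreg = np.full(n_words, np.nan)

    # One left-to-right scan.  A word has a first pass iff its first fixation
    # precedes the first fixation on any word to its right; equivalently, the
    # running maximum of fixated indices increases when the word is entered.
    first_idx = np.full(n_words, -1, dtype=int)
    for t in range(wi.size):
        w = wi[t]
        n_fix[w] += 1
        tft[w] += du[t]
        if first_idx[w] < 0:
            first_idx[w] = t

    running_max = -1
    has_first_pass = np.zeros(n_words, dtype=bool)
    for t in range(wi.size):
        w = wi[t]
        if first_idx[w] == t and w > running_max:
            has_first_pass[w] = True
        running_max = max(running_max, w)

    for w in np.flatnonzero(has_first_pass):
        t0 = first_idx[w]
        # first-pass run: consecutive fixations on w starting at t0
        t_end = t0
        while t_end + 1 < wi.size and wi[t_end + 1] == w:
            t_end += 1
        ffd[w] = du[t0]
        fprt[w] = du[t0 : t_end + 1].sum()
        if t_end + 1 < wi.size:
            fpreg[w] = 1.0 if wi[t_end + 1] < w else 0.0
        else:
            fpreg[w] = 0.0
        # go-past: everything from the start of the first pass up to (but
        # excluding) the first later fixation on a word to the right of w;
        # for the last word reached, the window extends to sequence end
        later = np.flatnonzero(wi[t0:] > w)
        t_exit = t0 + later[0] if later.size else wi.size
        rpd[w] = du[t0:t_exit].sum()

    return [
        WordMeasures(
            word_index=w,
            FFD=float(ffd[w]),
            FPRT=float(fprt[w]),
            RPD=float(rpd[w]),
            TFT=float(tft[w]),
            FPReg=float(fpreg[w]),
            SKIP=int(n_fix[w] == 0),
            N_FIX=int(n_fix[w]),
        )
        for w in range(n_words)
    ]


def spr_times(log: KeypressLog) -> np.ndarray:
    """Per-word self-paced reading times (ms) from a keypress log.

    Word k is timed as ``timestamp[k] - timestamp[k-1]``; word 0 is timed
    from screen onset (NaN if no onset was recorded).
    """
    ts = log.timestamps
    out = np.empty(ts.size)
    out[0] = ts[0] - log.onset if log.onset is not None else np.nan
    out[1:] = np.diff(ts)
    return out


def measures_frame(measures: list[WordMeasures], **ids: object) -> pd.DataFrame:
    """Tidy one-row-per-word frame; extra keyword ids become leading columns."""
    df = pd.DataFrame([vars(m) for m in measures])
    for key, value in reversed(list(ids.items())):
        df.insert(0, key, value)
    return df


def read_fixation_log(path) -> dict[tuple, FixationSequence]:
    """Read a fixation-log CSV into one FixationSequence per (trial, screen).

    Expected columns: ``trial_id, screen_id, fixation_order, word_index,
    duration_ms``.
    """
    df = pd.read_csv(path)
    required = {"trial_id", "screen_id", "fixation_order", "word_index", "duration_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixation log missing columns: {sorted(missing)}")
    out: dict[tuple, FixationSequence] = {}
    for key, grp in df.groupby(["trial_id", "screen_id"], sort=True):
        grp = grp.sort_values("fixation_order")
        if grp["fixation_order"].duplicated().any():
            raise ValueError(f"duplicate fixation_order in trial/screen {key}")
        out[key] = FixationSequence(
            word_index=grp["word_index"].to_numpy(),
            duration=grp["duration_ms"].to_numpy(),
        )
    return out


def read_keypress_log(path) -> dict[tuple, KeypressLog]:
    """Read a keypress CSV (``trial_id, screen_id, word_index, timestamp_ms``).

    A row with ``word_index == -1`` records the screen onset.
    """
    df = pd.read_csv(path)
    required = {"trial_id", "screen_id", "word_index", "timestamp_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"keypress log missing columns: {sorted(missing)}")
    out: dict[tuple, KeypressLog] = {}
    for key, grp in df.groupby(["trial_id", "screen_id"], sort=True):
        grp = grp.sort_values("word_index")
        onset_rows = grp[grp["word_index"] < 0]
        onset = float(onset_rows["timestamp_ms"].iloc[0]) if len(onset_rows) else None
        presses = grp[grp["word_index"] >= 0]
        words = presses["word_index"].to_numpy()
        if not np.array_equal(words, np.arange(words.size)):
            raise ValueError(f"word indices not consecutive from 0 in {key}")
        out[key] = KeypressLog(
            timestamps=presses["timestamp_ms"].to_numpy(), onset=onset
        )
    return out


def compute_measures_file(path, fmt: str, n_words: int | None = None) -> pd.DataFrame:
    """Compute the tidy measures table for a whole log file.

    ``fmt`` is ``"fixations"`` or ``"keypresses"``.  For fixation logs,
    ``n_words`` defaults per screen to ``max(word_index) + 1``.
    """
    if fmt == "fixations":
        frames = []
        for (trial, screen), seq in read_fixation_log(path).items():
            nw = n_words if n_words is not None else int(seq.word_index.max()) + 1
            frames.append(
                measures_frame(
                    compute_word_measures(seq, nw), trial_id=trial, screen_id=screen
                )
            )
        return pd.concat(frames, ignore_index=True)
    if fmt == "keypresses":
        rows = []
        for (trial, screen), log in read_keypress_log(path).items():
            times = spr_times(log)
            for w, t in enumerate(times):
                rows.append(
                    {
                        "trial_id": trial,
                        "screen_id": screen,
                        "word_index": w,
                        "SPR": t,
                    }
                )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown format {fmt!r}")
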