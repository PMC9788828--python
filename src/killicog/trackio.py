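"""Reading and writing pose tracks, manual score sheets and trial metadata.

Pose tracks use the DeepLabCut CSV export dialect: three header rows
(``scorer`` / ``bodyparts`` / ``coords``), one ``x``, ``y``, ``likelihood``
column triplet per tracked keypoint, and the frame index as the first column.
Coordinates follow the image convention (origin top-left, y increases
downward); missing coordinates are empty cells on disk and NaN in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PoseTrack",
    "TrialMeta",
    "SessionTable",
    "PoseFormatError",
    "PoseValidationError",
    "DEFAULT_ALIASES",
    "read_pose_csv",
    "write_pose_csv",
    "read_manual_scores",
    "write_manual_scores",
    "read_trial_meta",
    "load_session",
]

#: Keypoint-name aliases resolved on read ("snout" and "head" label the same
#: anatomical point in different annotation runs).
DEFAULT_ALIASES: dict[str, str] = {"snout": "head", "fish_head": "head", "fish_tail": "tail"}

COORDS = ("x", "y", "likelihood")


class PoseFormatError(ValueError):
    """Structurally malformed pose CSV (missing header row or coord column)."""


class PoseValidationError(ValueError):
    """Well-formed file with invalid values (e.g. likelihood outside [0,1])."""


@dataclass
class TrialMeta:
    """Per-trial metadata with the trial timing constants (seconds).

    The red cue light turns on at ``light_on_s`` (default 2 s) and food
    reaches the water surface at ``food_drop_s`` (nominally 9 s); analysis
    windows end at ``trial_end_s`` (18 s).
    """

    fish_id: str
    trial_number: int
    sex: str = ""
    age_days: float = float("nan")
    ate: bool = False
    light_on_s: float = 2.0
    food_drop_s: float = 9.0
    trial_end_s: float = 18.0

    def __post_init__(self) -> None:
        if not (self.light_on_s < self.food_drop_s < self.trial_end_s):
            raise ValueError(
                "timing must satisfy light_on_s < food_drop_s < trial_end_s, got "
                f"{self.light_on_s}, {self.food_drop_s}, {self.trial_end_s}"
            )


@dataclass
class PoseTrack:
    """One trial's keypoint time series.

    ``data`` holds a MultiIndex-column frame ``(keypoint, coord)`` with
    coords ``x``, ``y``, ``likelihood`` per keypoint and one row per video
    frame (strictly increasing frame index).
    """

    data: pd.DataFrame
    fish_id: str = ""
    trial_number: int = 0
    fps: float = 20.0

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise PoseFormatError("track data needs (keypoint, coord) MultiIndex columns")
        idx = np.asarray(self.data.index)
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise PoseValidationError("frame index must be strictly increasing")
        for kp in self.keypoints:
            missing = set(COORDS) - set(self.data[kp].columns)
            if missing:
                raise PoseFormatError(f"keypoint {kp!r} lacks columns {sorted(missing)}")
        lik = self.data.loc[:, (slice(None), "likelihood")].to_numpy(float)
        bad = (lik < 0) | (lik > 1)
        if np.any(bad & ~np.isnan(lik)):
            frame = int(np.where(bad.any(axis=1))[0][0])
            raise PoseValidationError(f"likelihood outside [0,1] at frame row {frame}")

    @property
    def keypoints(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def times(self) -> np.ndarray:
        """Frame times in seconds (frame index / fps)."""
        return np.asarray(self.data.index, dtype=float) / self.fps

    def xy(self, keypoint: str) -> pd.DataFrame:
        if keypoint not in self.keypoints:
            raise KeyError(f"unknown keypoint {keypoint!r}; have {self.keypoints}")
        return self.data[keypoint][["x", "y"]]

    def likelihood(self, keypoint: str) -> pd.Series:
        if keypoint not in self.keypoints:
            raise KeyError(f"unknown keypoint {keypoint!r}; have {self.keypoints}")
        return self.data[(keypoint, "likelihood")]

    def copy(self) -> "PoseTrack":
        return replace(self, data=self.data.copy())


@dataclass
class SessionTable:
    """All tracks of a recording session keyed by ``(fish_id, trial_number)``.

    ``missing`` lists (fish_id, trial_number) pairs present in the metadata
    but without a track file — reported, not fatal, so sessions with a lost
    trial remain analyzable.
    """

    tracks: dict[tuple[str, int], PoseTrack] = field(default_factory=dict)
    meta: dict[tuple[str, int], TrialMeta] = field(default_factory=dict)
    missing: list[tuple[str, int]] = field(default_factory=list)

    def fish_ids(self) -> list[str]:
        return sorted({k[0] for k in self.tracks})

    def trials_of(self, fish_id: str) -> dict[int, PoseTrack]:
        return {t: tr for (f, t), tr in sorted(self.tracks.items()) if f == fish_id}

    def meta_of(self, fish_id: str) -> dict[int, TrialMeta]:
        return {t: m for (f, t), m in sorted(self.meta.items()) if f == fish_id}


def _resolve_alias(name: str, aliases: Mapping[str, str] | None) -> str:
    table = DEFAULT_ALIASES if aliases is None else aliases
    return table.get(name, name)


def read_pose_csv(
    path: str | Path,
    fps: float = 20.0,
    fish_id: str = "",
    trial_number: int = 0,
    aliases: Mapping[str, str] | None = None,
) -> PoseTrack:
    """Read a DeepLabCut-export CSV into a :class:`PoseTrack`.

    The file must carry the three header rows (scorer, bodyparts, coords)
    and an x/y/likelihood triplet for every keypoint. Empty cells become
    NaN (explicit missing marker). ``n_frames`` equals the file's data-row
    count — no frame is ever silently dropped.
    """
    path = Path(path)
    head = pd.read_csv(path, header=None, nrows=3)
    labels = [str(v).strip().lower() for v in head.iloc[:, 0]]
    expected = ["scorer", "bodyparts", "coords"]
    for row_name in expected:
        if row_name not in labels:
            raise PoseFormatError(f"{path.name}: missing header row {row_name!r}")
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    # normalize to (bodypart, coord) columns, dropping the scorer level
    df.columns = pd.MultiIndex.from_tuples(
        [(_resolve_alias(str(b), aliases), str(c)) for (_, b, c) in df.columns]
    )
    for kp in df.columns.get_level_values(0).unique():
        got = set(df[kp].columns)
        lacking = set(COORDS) - got
        if lacking:
            raise PoseFormatError(f"{path.name}: keypoint {kp!r} lacks {sorted(lacking)} column")
    df = df.astype(float)
    lik = df.loc[:, (slice(None), "likelihood")].to_numpy()
    bad = np.where((lik < 0) | (lik > 1))
    if bad[0].size:
        raise PoseValidationError(
            f"{path.name}: likelihood outside [0,1] at frame row {int(bad[0][0])}"
        )
    return PoseTrack(data=df, fish_id=fish_id, trial_number=trial_number, fps=fps)


def write_pose_csv(track: PoseTrack, path: str | Path, scorer: str = "killicog") -> Path:
    """Write a track in the same three-header-row dialect read_pose_csv accepts."""
    if track.n_frames == 0:
        raise ValueError("refusing to write a track with zero frames")
    path = Path(path)
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, b, c) for (b, c) in df.columns], names=["scorer", "bodyparts", "coords"]
    )
    df.index.name = None
    df.to_csv(path, float_format="%.6f")
    return path


def read_manual_scores(path: str | Path) -> pd.DataFrame:
    """Read a per-second manual score sheet.

    Expects columns ``second``, ``upward``, ``at_surface`` and optionally
    ``eating``; flags must be 0/1. Rows are returned ordered by second;
    gaps in the second column raise a warning but are kept as-is.
    """
    df = pd.read_csv(path)
    required = {"second", "upward", "at_surface"}
    lacking = required - set(df.columns)
    if lacking:
        raise PoseFormatError(f"{Path(path).name}: score sheet lacks columns {sorted(lacking)}")
    for col in ("upward", "at_surface"):
        vals = df[col].dropna()
        if not vals.isin([0, 1]).all():
            bad = vals[~vals.isin([0, 1])].iloc[0]
            raise PoseValidationError(f"{col} flag must be 0/1, got {bad!r}")
    df = df.sort_values("second").reset_index(drop=True)
    secs = df["second"].to_numpy()
    if len(secs) > 1 and not np.all(np.diff(secs) == 1):
        warnings.warn(f"{Path(path).name}: gaps in the per-second score sheet", stacklevel=2)
    return df


def write_manual_scores(scores: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    scores.to_csv(path, index=False)
    return path


def read_trial_meta(path: str | Path) -> list[TrialMeta]:
    """Read a per-trial metadata CSV (fish_id, trial_number, sex, age_days, ate)."""
    df = pd.read_csv(path)
    lacking = {"fish_id", "trial_number"} - set(df.columns)
    if lacking:
        raise PoseFormatError(f"metadata lacks columns {sorted(lacking)}")
    out = []
    for _, row in df.iterrows():
        kwargs = dict(
            fish_id=str(row["fish_id"]),
            trial_number=int(row["trial_number"]),
            sex=str(row.get("sex", "")),
            age_days=float(row.get("age_days", np.nan)),
            ate=bool(row.get("ate", False)),
        )
        for key in ("light_on_s", "food_drop_s", "trial_end_s"):
            if key in df.columns:
                kwargs[key] = float(row[key])
        out.append(TrialMeta(**kwargs))
    return out


def _track_files(track_dir: Path) -> Iterable[Path]:
    return sorted(track_dir.glob("*.csv"))


def load_session(
    track_dir: str | Path,
    meta_path: str | Path,
    fps: float = 20.0,
    aliases: Mapping[str, str] | None = None,
) -> SessionTable:
    """Assemble a :class:`SessionTable` from a directory of track CSVs.

    Track files are named ``<fish_id>_trial<k>.csv``. Metadata rows without a
    matching track file go on the session's ``missing`` list (a completeness
    report, not an error); a duplicated (fish, trial) file is an error.
    """
    track_dir = Path(track_dir)
    metas = read_trial_meta(meta_path)
    session = SessionTable()
    for m in metas:
        key = (m.fish_id, m.trial_number)
        if key in session.meta:
            raise ValueError(f"duplicate metadata row for {key}")
        session.meta[key] = m

    for f in _track_files(track_dir):
        stem = f.stem
        if "_trial" not in stem:
            warnings.warn(f"ignoring unrecognized track file name {f.name}", stacklevel=2)
            continue
        fish_id, _, trial = stem.rpartition("_trial")
        key = (fish_id, int(trial))
        if key in session.tracks:
            raise ValueError(f"duplicate track file for {key}")
        session.tracks[key] = read_pose_csv(
            f, fps=fps, fish_id=fish_id, trial_number=int(trial), aliases=aliases
        )
        if key not in session.meta:
            warnings.warn(f"track {key} has no metadata row", stacklevel=2)

    session.missing = sorted(k for k in session.meta if k not in session.tracks)
    return session
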