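"""CSV readers/writers with schema validation.

One canonical dialect throughout: comma separated, dot decimals, UTF-8,
header row.  Errors name the file, the 1-based data row and the field.
The deposited-format import is a thin adapter (column map plus speaker-side
normalization), not a second parser.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .simulate import Track
from .spatial import ARENA_HALFLENGTH

__all__ = [
    "SchemaError",
    "NIGHTS_COLUMNS",
    "EGGS_COLUMNS",
    "TRACKS_COLUMNS",
    "read_nights",
    "write_nights",
    "read_eggs",
    "write_eggs",
    "read_tracks",
    "write_tracks",
    "import_gradient_table",
]

NIGHTS_COLUMNS = [
    "experiment_id",
    "arena_id",
    "repetition_id",
    "night_index",
    "session_id",
    "n_females",
    "clusters_treatment",
    "clusters_control",
]
EGGS_COLUMNS = ["night_index", "female_id", "cluster_id", "position_cm", "n_eggs"]
TRACKS_COLUMNS = ["moth_id", "trial_id", "playback_side", "t_s", "x_cm", "y_cm"]


class SchemaError(ValueError):
    """A table failed schema validation."""


def _check_columns(df: pd.DataFrame, columns: List[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path, integer: bool = False) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    bad = s.isna() & df[col].notna() | df[col].isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise SchemaError(f"{path}: row {row}, field '{col}': non-numeric or missing value")
    if integer and not np.allclose(s, np.round(s)):
        row = int(np.flatnonzero(~np.isclose(s, np.round(s)))[0]) + 1
        raise SchemaError(f"{path}: row {row}, field '{col}': expected an integer")
    return s.astype(int) if integer else s.astype(float)


def read_nights(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, NIGHTS_COLUMNS, path)
    for col in ("night_index", "n_females", "clusters_treatment", "clusters_control"):
        df[col] = _numeric(df, col, path, integer=True)
    for col, lo in (("night_index", 1), ("n_females", 1), ("clusters_treatment", 0), ("clusters_control", 0)):
        bad = df[col] < lo
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise SchemaError(f"{path}: row {row}, field '{col}': value below {lo}")
    df["laid"] = (df["clusters_treatment"] + df["clusters_control"]) > 0
    return df[NIGHTS_COLUMNS + ["laid"]]


def write_nights(nights: pd.DataFrame, path) -> None:
    nights[NIGHTS_COLUMNS].to_csv(path, index=False)


def read_eggs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, EGGS_COLUMNS, path)
    df["night_index"] = _numeric(df, "night_index", path, integer=True)
    df["n_eggs"] = _numeric(df, "n_eggs", path, integer=True)
    df["position_cm"] = _numeric(df, "position_cm", path)
    bad = df["position_cm"].abs() > ARENA_HALFLENGTH
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise SchemaError(
            f"{path}: row {row}, field 'position_cm': "
            f"|position| exceeds the {ARENA_HALFLENGTH} cm arena bound"
        )
    bad = df["n_eggs"] < 1
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise SchemaError(f"{path}: row {row}, field 'n_eggs': must be >= 1")
    return df[EGGS_COLUMNS]


def write_eggs(eggs: pd.DataFrame, path) -> None:
    eggs[EGGS_COLUMNS].to_csv(path, index=False)


def read_tracks(path) -> List[Track]:
    df = pd.read_csv(path)
    _check_columns(df, TRACKS_COLUMNS, path)
    for col in ("t_s", "x_cm", "y_cm"):
        df[col] = _numeric(df, col, path)
    tracks = []
    for (moth, trial), grp in df.groupby(["moth_id", "trial_id"], sort=False):
        grp = grp.sort_values("t_s")
        side = grp["playback_side"].iloc[0]
        if not (grp["playback_side"] == side).all():
            raise SchemaError(f"{path}: track {moth}/{trial}: inconsistent playback_side")
        try:
            tracks.append(
                Track(
                    moth_id=str(moth),
                    trial_id=str(trial),
                    playback_side=str(side),
                    t=grp["t_s"].to_numpy(),
                    x=grp["x_cm"].to_numpy(),
                    y=grp["y_cm"].to_numpy(),
                )
            )
        except ValueError as e:
            raise SchemaError(f"{path}: track {moth}/{trial}: {e}") from e
    return tracks


def tracks_to_frame(tracks: List[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        rows.append(
            pd.DataFrame(
                {
                    "moth_id": tr.moth_id,
                    "trial_id": tr.trial_id,
                    "playback_side": tr.playback_side,
                    "t_s": tr.t,
                    "x_cm": tr.x,
                    "y_cm": tr.y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_tracks(tracks: List[Track], path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def import_gradient_table(
    path,
    column_map: Dict[str, str],
    speaker_side_col: Optional[str] = None,
    positive_side_value: str = "right",
) -> pd.DataFrame:
    """Adapter for deposited-style gradient tables.

    ``column_map`` maps our schema names (``night_index, female_id,
    cluster_id, position_cm, n_eggs``) to the file's column names.  If
    ``speaker_side_col`` names a column giving the physical speaker side for
    each night, positions recorded with the speaker on the
    ``positive_side_value`` end are sign-flipped so the speaker is always at
    -75 cm after normalization.
    """
    raw = pd.read_csv(path)
    missing = [v for v in column_map.values() if v not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df = pd.DataFrame({ours: raw[theirs] for ours, theirs in column_map.items()})
    if speaker_side_col is not None:
        if speaker_side_col not in raw.columns:
            raise SchemaError(f"{path}: missing column(s) ['{speaker_side_col}']")
        flip = raw[speaker_side_col].astype(str).str.lower() == positive_side_value
        df.loc[flip, "position_cm"] = -df.loc[flip, "position_cm"]
    for col in EGGS_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: column map must cover '{col}'")
    df["position_cm"] = _numeric(df, "position_cm", path)
    bad = df["position_cm"].abs() > ARENA_HALFLENGTH
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise SchemaError(
            f"{path}: row {row}, field 'position_cm': "
            f"|position| exceeds the {ARENA_HALFLENGTH} cm arena bound"
        )
    return df[EGGS_COLUMNS]
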