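"""File formats.

All files are plain text: trajectories and BM series as comma-separated CSV
(header row, '.' decimal, UTF-8), reports as TSV, ground truth and manifests
as JSON, image stacks as multi-page TIFF.

Trajectory CSV schema: bead_id, frame, t_s, x_nm, y_nm, recorded.
Unrecorded frames carry empty x/y fields.  Timestamps must be uniform at the
frame interval; violations raise with the offending line number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .simulate import Trajectory, TrajectoryTruth
from .processing import BMSeries

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_truth",
    "read_truth",
    "write_bm_series",
    "read_bm_series",
    "write_events",
    "write_report",
    "write_stack",
    "read_stack",
    "sha256_file",
]


def write_trajectories(trajs: Sequence[Trajectory], path) -> None:
    frames = []
    for traj in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "bead_id": traj.bead_id,
                    "frame": np.arange(traj.n_frames),
                    "t_s": traj.times,
                    "x_nm": traj.x,
                    "y_nm": traj.y,
                    "recorded": traj.recorded.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_trajectories(path, frame_rate: float = 30.0,
                      truth: Optional[Dict[str, TrajectoryTruth]] = None) -> List[Trajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"bead_id", "frame", "t_s", "x_nm", "y_nm", "recorded"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    trajs = []
    for bead_id, grp in df.groupby("bead_id", sort=False):
        t = grp["t_s"].to_numpy()
        dt = np.diff(t)
        if len(dt):
            bad = np.nonzero(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-12))[0]
            if len(bad):
                line = grp.index[bad[0] + 1] + 2  # +2: header and 0-base
                raise ValueError(f"{path}: non-uniform timestamp at line {line}")
            rate = 1.0 / dt[0]
        else:
            rate = frame_rate
        trajs.append(
            Trajectory(
                bead_id=str(bead_id),
                times=t,
                x=grp["x_nm"].to_numpy(),
                y=grp["y_nm"].to_numpy(),
                recorded=grp["recorded"].to_numpy().astype(bool),
                frame_rate=rate,
                truth=(truth or {}).get(str(bead_id)),
            )
        )
    if not trajs:
        raise ValueError(f"{path}: no trajectories")
    return trajs


def write_truth(trajs: Sequence[Trajectory], path) -> None:
    payload = {
        t.bead_id: (asdict(t.truth) if t.truth is not None else None)
        for t in trajs
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> Dict[str, TrajectoryTruth]:
    payload = json.loads(Path(path).read_text())
    return {
        k: TrajectoryTruth(**v) for k, v in payload.items() if v is not None
    }


def write_bm_series(series: Sequence[BMSeries], path) -> None:
    frames = [
        pd.DataFrame({"bead_id": s.bead_id, "t_s": s.times, "bm_nm": s.bm})
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_bm_series(path, window_frames: int = 20, frame_rate: float = 30.0,
                   stride: int = 1) -> List[BMSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for bead_id, grp in df.groupby("bead_id", sort=False):
        out.append(
            BMSeries(
                bead_id=str(bead_id),
                times=grp["t_s"].to_numpy(),
                bm=grp["bm_nm"].to_numpy(),
                window_frames=window_frames,
                frame_rate=frame_rate,
                stride=stride,
            )
        )
    return out


def write_events(events_df: pd.DataFrame, path) -> None:
    events_df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_report(report_df: pd.DataFrame, path) -> None:
    report_df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
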