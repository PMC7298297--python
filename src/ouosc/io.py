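"""Delimited-text serialization of traces, datasets and result tables.

The on-disk trace table is a CSV with columns ``cell_id, channel, time_h,
intensity`` (optional ``z_um``); one row per sample.  Ground truth for
synthetic datasets goes in a companion CSV (``cell_id, label, model,
alpha, beta, sigma2``).  All tables are plain text so mock experiments
round-trip losslessly through files.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .kernels import OUoscParams
from .synthetic import SyntheticDataset
from .trace import Trace

__all__ = [
    "read_traces",
    "write_traces",
    "write_dataset",
    "read_ground_truth",
]

REQUIRED_COLUMNS = ["cell_id", "channel", "time_h", "intensity"]


def write_traces(traces: Sequence[Trace], path) -> None:
    """Write traces to the standard CSV trace table."""
    frames = []
    for tr in traces:
        df = pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "channel": tr.channel,
                "time_h": tr.times,
                "intensity": tr.values,
            }
        )
        if tr.z_position is not None:
            df["z_um"] = tr.z_position
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> List[Trace]:
    """Read the standard trace table, validating columns and grid uniformity.

    Traces are grouped by ``(cell_id, channel)``; a missing column, NaN
    intensity, or an irregular time stamp raises a descriptive error naming
    the offending cell and row.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df["intensity"].isna().any():
        row = int(df.index[df["intensity"].isna()][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: NaN intensity at file row {row}")
    traces = []
    for (cell_id, channel), group in df.groupby(["cell_id", "channel"], sort=False):
        times = group["time_h"].to_numpy(dtype=float)
        diffs = np.diff(times)
        if len(times) < 2:
            raise ValueError(f"{path}: trace {cell_id}/{channel} has fewer than 2 samples")
        dt = np.median(diffs)
        bad = np.nonzero(np.abs(diffs - dt) > 1e-6 * dt)[0]
        if bad.size:
            row = int(group.index[bad[0] + 1]) + 2
            raise ValueError(
                f"{path}: irregular time stamp for cell {cell_id}/{channel} at file row {row}"
            )
        z = group["z_um"].to_numpy(dtype=float) if "z_um" in group.columns else None
        if z is not None and np.all(np.isnan(z)):
            z = None
        traces.append(
            Trace(
                cell_id=str(cell_id),
                channel=str(channel),
                times=times,
                values=group["intensity"].to_numpy(dtype=float),
                z_position=z,
            )
        )
    return traces


def write_dataset(dataset: SyntheticDataset, trace_path, truth_path) -> None:
    """Serialize a synthetic dataset: trace table + ground-truth table."""
    write_traces(dataset.all_traces(), trace_path)
    rows = []
    for v, label, params in zip(dataset.venus, dataset.labels, dataset.true_params):
        if isinstance(params, OUoscParams):
            rows.append(
                dict(cell_id=v.cell_id, label=label, model="OUosc",
                     alpha=params.alpha_ouosc, beta=params.beta, sigma2=params.sigma2)
            )
        else:
            rows.append(
                dict(cell_id=v.cell_id, label=label, model="OU",
                     alpha=params.alpha_ou, beta=np.nan, sigma2=params.sigma2)
            )
    pd.DataFrame(rows).to_csv(truth_path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"cell_id", "label", "model", "alpha"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing ground-truth column(s): {sorted(missing)}")
    return df


def group_by_channel(traces: Sequence[Trace]) -> Dict[str, List[Trace]]:
    """Split a mixed trace list into per-channel lists, preserving order."""
    out: Dict[str, List[Trace]] = {}
    for tr in traces:
        out.setdefault(tr.channel, []).append(tr)
    return out
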