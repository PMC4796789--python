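"""Persistence helpers: trajectories to HDF5, metrics to CSV, morphologies
to JSON (the JSON side lives on :class:`~cldend.morphology.Morphology`)."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .detsim import IonParams, Trajectory
from .diffmetrics import DiffusionMetrics

__all__ = ["save_trajectory", "load_trajectory", "metrics_table", "save_metrics_csv"]


def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("cl", data=traj.cl, compression="gzip")
        if traj.v is not None:
            f.create_dataset("v", data=traj.v, compression="gzip")
        if traj.events:
            f.create_dataset("events", data=np.array(traj.events))
        if traj.ions is not None:
            for k, v in vars(traj.ions).items():
                f.attrs[f"ions_{k}"] = v


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        ion_kwargs = {
            k[len("ions_"):]: float(v)
            for k, v in f.attrs.items()
            if k.startswith("ions_")
        }
        return Trajectory(
            times=f["times"][:],
            cl=f["cl"][:],
            v=f["v"][:] if "v" in f else None,
            events=[tuple(e) for e in f["events"][:]] if "events" in f else [],
            ions=IonParams(**ion_kwargs) if ion_kwargs else None,
        )


def metrics_table(metrics: DiffusionMetrics) -> pd.DataFrame:
    """(time, variance, d_app) table for one metrics object."""
    return pd.DataFrame(
        {"time_ms": metrics.times, "variance_um2": metrics.variance,
         "d_app_um2_per_ms": metrics.d_app}
    )


def save_metrics_csv(metrics: DiffusionMetrics, path) -> None:
    metrics_table(metrics).to_csv(path, index=False)
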