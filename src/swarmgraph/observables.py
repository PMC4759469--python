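"""Time-series and event statistics extracted from simulated trajectories.

The central event statistic is the hitting time tau of the monotone raft
property: the first timestep at which the largest connected chain of cells
reaches the threshold size m.  Along the monotone Models 1-2 the giant
component never shrinks, so tau is a proper stopping time; replicates that
never reach the threshold within the horizon are reported as censored, never
imputed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .graph_core import CellGraph, ConfigurationError


@dataclass
class Trajectory:
    """Per-timestep record of one simulation replicate.

    All series share length ``t_max + 1`` (including t = 0).  ``snapshots``
    maps a timestep to the sorted multiset of component sizes at that time.
    """

    times: np.ndarray
    edge_counts: np.ndarray
    avg_degrees: np.ndarray
    giant_sizes: np.ndarray
    snapshots: dict[int, np.ndarray]
    n_cells: int
    replicate: int = 0
    final_graph: Optional[CellGraph] = None
    saturated_at: Optional[int] = None

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": self.replicate,
                "t": self.times,
                "edges": self.edge_counts,
                "avg_degree": self.avg_degrees,
                "giant_size": self.giant_sizes,
            }
        )


@dataclass(frozen=True)
class HittingTimeSample:
    """First time the giant component reached size m, or a censoring marker."""

    threshold_m: int
    tau: Optional[int]
    censored_at: Optional[int] = None

    @property
    def censored(self) -> bool:
        return self.tau is None


def hitting_time(traj: Trajectory, m: int) -> HittingTimeSample:
    """First recorded time with ``giant_size >= m``.

    m = 1 always yields tau = 0 (a lone cell is a size-1 component).  When
    the threshold is never reached within the horizon the sample is censored
    at the last recorded time.
    """
    if not 1 <= m <= traj.n_cells:
        raise ConfigurationError(
            f"threshold m={m} must lie in [1, N={traj.n_cells}]"
        )
    hits = np.nonzero(traj.giant_sizes >= m)[0]
    if hits.size == 0:
        return HittingTimeSample(
            threshold_m=m, tau=None, censored_at=int(traj.times[-1])
        )
    return HittingTimeSample(threshold_m=m, tau=int(traj.times[hits[0]]))


def component_size_histogram(snapshot: Sequence[int] | Counter) -> dict[int, int]:
    """Counts per component size; conserves cells: sum(size * count) = N."""
    if isinstance(snapshot, Counter):
        return dict(snapshot)
    return dict(Counter(int(s) for s in snapshot))


def mean_component_size(snapshot: Sequence[int]) -> float:
    """Average component size N / (#components) of one snapshot."""
    sizes = np.asarray(snapshot)
    return float(sizes.sum() / sizes.size)


def summarize_replicates(trajs: Sequence[Trajectory]) -> pd.DataFrame:
    """Pointwise mean and standard deviation across replicates.

    Mirrors the figure convention of averaging n independent simulations.
    Returns a frame with columns t, and mean/sd of each recorded series.
    """
    if len(trajs) == 0:
        raise ValueError("need at least one trajectory")
    horizon = len(trajs[0])
    if any(len(tr) != horizon for tr in trajs):
        raise ValueError("trajectories have mismatched horizons")
    stacked = {
        name: np.stack([getattr(tr, name) for tr in trajs])
        for name in ("edge_counts", "avg_degrees", "giant_sizes")
    }
    out = {"t": trajs[0].times}
    for name, arr in stacked.items():
        out[f"{name[:-1]}_mean"] = arr.mean(axis=0)
        out[f"{name[:-1]}_sd"] = arr.std(axis=0, ddof=0)
    return pd.DataFrame(out)


def hitting_times_frame(
    trajs: Sequence[Trajectory], m: int
) -> pd.DataFrame:
    """Hitting-time table (replicate, m, tau, censored) across replicates."""
    rows = []
    for tr in trajs:
        s = hitting_time(tr, m)
        rows.append(
            {
                "replicate": tr.replicate,
                "m": m,
                "tau": -1 if s.censored else s.tau,
                "censored": int(s.censored),
            }
        )
    return pd.DataFrame(rows)
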