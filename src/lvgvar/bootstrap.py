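"""Case-drop bootstrap for network-structure stability.

Each replicate removes a fixed proportion of the data — a contiguous block
of measurement occasions for time series (respecting temporal dependency),
or a random subject subset for panel data — reruns the full search
pipeline, and tallies how often each signed edge is included.  Failed
replicates are counted, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import DataError, MomentData
from .io import Dataset, timeseries_moments
from .search import run_pipeline

__all__ = ["BootstrapSummary", "casedrop_resample", "bootstrap_search"]


@dataclass
class BootstrapSummary:
    """Per-edge inclusion counts, split by sign, over bootstrap replicates."""

    edges: list  # searchable parameter names, fixed order
    positive: np.ndarray  # count of replicates including the edge with weight > 0
    negative: np.ndarray
    co_inclusion: np.ndarray  # edge x edge joint inclusion counts
    attempted: int
    succeeded: int
    settings: dict = field(default_factory=dict)

    @property
    def counts(self) -> np.ndarray:
        return self.positive + self.negative

    @property
    def proportions(self) -> np.ndarray:
        if self.succeeded == 0:
            return np.full(len(self.edges), np.nan)
        return self.counts / self.succeeded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge": self.edges,
                "included": self.counts,
                "positive": self.positive,
                "negative": self.negative,
                "proportion": self.proportions,
            }
        )

    def merge(self, other: "BootstrapSummary") -> "BootstrapSummary":
        """Combine two summaries with identical settings (count additivity)."""
        if self.edges != other.edges or self.settings != other.settings:
            raise ValueError("summaries have different edges or settings")
        return BootstrapSummary(
            edges=list(self.edges),
            positive=self.positive + other.positive,
            negative=self.negative + other.negative,
            co_inclusion=self.co_inclusion + other.co_inclusion,
            attempted=self.attempted + other.attempted,
            succeeded=self.succeeded + other.succeeded,
            settings=dict(self.settings),
        )


def casedrop_resample(
    dataset: Dataset,
    proportion: float,
    mode: str = None,
    seed=None,
    wrap: bool = True,
) -> Dataset:
    """Drop a fixed proportion of cases; deterministic given the seed.

    ``mode='block'`` (time series) removes ``ceil(proportion * n)``
    consecutive occasions starting at a uniformly chosen index; with the
    wrap rule the segment truncated at the series end continues from the
    start.  Remaining occasions on either side of the removed segment are
    never paired across the gap.  ``mode='subjects'`` (panel) removes a
    uniform random subject subset.
    """
    if not 0.0 <= proportion < 1.0:
        raise ValueError("proportion must be in [0, 1)")
    if mode is None:
        mode = "block" if dataset.kind == "timeseries" else "subjects"
    rng = np.random.default_rng(seed)
    n = dataset.n_rows
    k = int(np.ceil(proportion * n))
    if n - k < 2:
        raise DataError("dropping this proportion leaves fewer than 2 cases")
    if k == 0:
        return dataset
    if mode == "block":
        if dataset.kind != "timeseries":
            raise ValueError("block mode applies to time-series data")
        start = int(rng.integers(0, n))
        if wrap:
            dropped = (start + np.arange(k)) % n
        else:
            dropped = np.arange(start, min(start + k, n))
        keep = np.setdiff1d(np.arange(n), dropped)
        frame = dataset.frame.iloc[keep].reset_index(drop=True)
        block = dataset.block[keep]
        # split blocks across any removed gap so pairs never straddle it
        jump = np.concatenate([[False], np.diff(keep) != 1])
        changed = np.concatenate([[True], block[1:] != block[:-1]])
        new_block = np.cumsum(jump | changed) - 1
        return Dataset(
            kind="timeseries",
            frame=frame,
            variables=list(dataset.variables),
            block=new_block,
            occasion=dataset.occasion[keep],
        )
    if mode == "subjects":
        if dataset.kind != "panel":
            raise ValueError("subjects mode applies to panel data")
        dropped = rng.choice(n, size=k, replace=False)
        keep = np.setdiff1d(np.arange(n), dropped)
        return Dataset(
            kind="panel",
            frame=dataset.frame.iloc[keep].reset_index(drop=True),
            variables=list(dataset.variables),
            n_waves=dataset.n_waves,
        )
    raise ValueError(f"unknown resampling mode {mode!r}")


def bootstrap_search(
    dataset: Dataset,
    spec,
    n_boot: int = 1000,
    proportion: float = 0.25,
    mode: str = None,
    method: str = None,
    alpha: float = 0.01,
    adjustment: str = "none",
    strategy: str = "modelsearch",
    seed=None,
) -> BootstrapSummary:
    """Rerun the full search pipeline on case-drop resamples.

    Replicate seeds are derived deterministically from the master seed, so
    identical settings yield an identical summary.
    """
    if method is None:
        method = "fiml" if dataset.kind == "timeseries" else "ml"
    from .specs import compile_spec

    edges = [p.name for p in compile_spec(spec).params if p.searchable]
    idx = {nm: i for i, nm in enumerate(edges)}
    pos = np.zeros(len(edges), dtype=int)
    neg = np.zeros(len(edges), dtype=int)
    co = np.zeros((len(edges), len(edges)), dtype=int)
    succeeded = 0
    children = np.random.SeedSequence(seed).spawn(n_boot)
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            sub = casedrop_resample(dataset, proportion, mode=mode, seed=rep_seed)
            if sub.kind == "timeseries":
                data = timeseries_moments(sub, method=method)
            else:
                frame = sub.frame.dropna() if method == "ml" else sub.frame
                data = MomentData.from_dataframe(frame)
            final, _ = run_pipeline(
                spec,
                data,
                method=method,
                alpha=alpha,
                adjustment=adjustment,
                strategy=strategy,
            )
            if not final.converged:
                continue
        except Exception:
            continue
        succeeded += 1
        included = []
        for p in final.model.params:
            if not p.searchable or p.value == 0.0:
                continue
            i = idx[p.name]
            included.append(i)
            if p.value > 0:
                pos[i] += 1
            else:
                neg[i] += 1
        for a in included:
            for b in included:
                co[a, b] += 1
    return BootstrapSummary(
        edges=edges,
        positive=pos,
        negative=neg,
        co_inclusion=co,
        attempted=n_boot,
        succeeded=succeeded,
        settings={
            "proportion": proportion,
            "mode": mode or ("block" if dataset.kind == "timeseries" else "subjects"),
            "alpha": alpha,
            "adjustment": adjustment,
            "strategy": strategy,
            "seed": seed,
        },
    )
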