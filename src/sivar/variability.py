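"""%dSI series, 6-h block pooling by outcome group, and empirical CDFs.

The variability metric is the forward hour-to-hour percent change in
insulin sensitivity, %dSI_i = 100*(SI_{i+1} - SI_i)/SI_i. Values are pooled
across patients and hours into 6-hour blocks per outcome group; a %dSI value
at hour i belongs to the block containing i (its first hour). Empirical CDFs
are right-continuous step functions over each pooled block sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .icing import ModelInputError
from .identification import SIProfileResults, profiles_to_frame

logger = logging.getLogger(__name__)

METRIC_SI = "si"
METRIC_DELTA_SI = "delta_si"


def compute_delta_si(profile: SIProfileResults) -> pd.DataFrame:
    """Forward %dSI series for one profile (delegates to the results object)."""
    return profile.delta_si()


@dataclass(frozen=True)
class BlockSample:
    """Pooled metric values for one 6-h block and outcome group."""

    block: int
    group: str
    metric: str
    values: np.ndarray

    def __post_init__(self):
        if not (0 <= self.block):
            raise ModelInputError("block index must be >= 0")
        v = np.asarray(self.values, float)
        if v.size and not np.all(np.isfinite(v)):
            raise ModelInputError("block values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if self.n else float("nan")

    def quantiles(self, qs=(25, 50, 75)) -> np.ndarray:
        return np.percentile(self.values, qs)


def pool_blocks(profiles: Sequence[SIProfileResults],
                outcomes: Mapping[str, str],
                metric: str = METRIC_SI,
                n_blocks: int = 12,
                block_hours: int = 6) -> list[BlockSample]:
    """Pool hourly values into per-group 6-h blocks, hours [6b, 6b+6).

    ``outcomes`` maps patient_id -> survivor|non-survivor. Ordering within a
    block is deterministic (patient_id, hour). Empty group-blocks are returned
    with n=0 and logged; downstream testing excludes them.
    """
    if metric == METRIC_SI:
        frame = profiles_to_frame(profiles).rename(columns={"si": "value"})
    elif metric == METRIC_DELTA_SI:
        parts = [p.delta_si().rename(columns={"delta_si_pct": "value"})
                 for p in profiles]
        parts = [p for p in parts if len(p)]
        frame = (pd.concat(parts, ignore_index=True) if parts
                 else pd.DataFrame(columns=["patient_id", "hour", "value"]))
    else:
        raise ModelInputError(f"unknown metric {metric!r}")

    frame = frame[(frame["hour"] >= 0) & (frame["hour"] < n_blocks * block_hours)]
    frame = frame.sort_values(["patient_id", "hour"], kind="mergesort")
    frame["group"] = frame["patient_id"].map(dict(outcomes))
    if frame["group"].isna().any():
        missing = frame.loc[frame["group"].isna(), "patient_id"].unique()
        raise ModelInputError(f"no outcome for patient(s): {list(missing)[:5]}")

    out: list[BlockSample] = []
    groups = sorted(set(outcomes.values()))
    for b in range(n_blocks):
        lo, hi = b * block_hours, (b + 1) * block_hours
        sub = frame[(frame["hour"] >= lo) & (frame["hour"] < hi)]
        for g in groups:
            vals = sub.loc[sub["group"] == g, "value"].to_numpy(float)
            if vals.size == 0:
                logger.warning("empty block %d for group %s (metric %s)", b, g, metric)
            out.append(BlockSample(block=b, group=g, metric=metric, values=vals))
    return out


class EmpiricalCDF:
    """Right-continuous empirical CDF: F(x) = #{v <= x} / n."""

    def __init__(self, values):
        v = np.asarray(values, float)
        if v.size == 0:
            raise ModelInputError("empirical CDF needs at least one value")
        if not np.all(np.isfinite(v)):
            raise ModelInputError("CDF values must be finite")
        self.sorted = np.sort(v)
        self.n = v.size

    def __call__(self, x):
        idx = np.searchsorted(self.sorted, np.asarray(x, float), side="right")
        out = idx / self.n
        return float(out) if np.ndim(x) == 0 else out

    @property
    def steps(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted values, cumulative fractions) defining the step function."""
        return self.sorted, np.arange(1, self.n + 1) / self.n

    def to_frame(self) -> pd.DataFrame:
        x, y = self.steps
        return pd.DataFrame({"value": x, "cum_fraction": y})


def empirical_cdf(sample: BlockSample | np.ndarray) -> EmpiricalCDF:
    values = sample.values if isinstance(sample, BlockSample) else sample
    return EmpiricalCDF(values)


def block_summary_table(samples: Sequence[BlockSample]) -> pd.DataFrame:
    """Per block x group medians and IQRs (report-table layout)."""
    rows = []
    for s in samples:
        if s.n:
            q25, q50, q75 = s.quantiles()
        else:
            q25 = q50 = q75 = float("nan")
        rows.append((s.block, s.group, s.metric, q50, q25, q75, s.n))
    return pd.DataFrame(rows, columns=["block", "group", "metric",
                                       "median", "q25", "q75", "n"])
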