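"""Spatial and duration statistics of capillary stalls.

Capillary blocks ("stalls") are temporary obstructions of a capillary
segment by a blood cell.  If blocks occurred at random positions along
capillaries with pericyte somata uniformly spaced ``s`` apart, the distance
from a block to the nearest soma would be uniform on [0, s/2], giving a
cumulative distribution that is a straight line reaching unity at s/2
(72 µm for the measured one-pericyte-per-144-µm spacing).  A one-sample
Kolmogorov-Smirnov test against this null detects soma-clustered stalling.

Also provides the percent-of-segments-blocked summary, branch-order
breakdowns (counted from penetrating arterioles and from ascending venules
separately) and per-cell-class stall-duration summaries with fold ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

CELL_CLASSES = ("neutrophil", "monocyte", "RBC", "unknown")


@dataclass
class StallDataset:
    """Table of capillary stalls with distance to the nearest pericyte soma.

    ``data`` columns: distance_um (required); optional segment_id,
    branch_order_pa, branch_order_av, cell_class, duration_s.  Distances
    beyond spacing/2 are geometrically inconsistent with the stated
    inter-pericyte spacing; they are flagged and excluded from analyses
    (with a warning), never silently kept or clipped.
    """

    data: pd.DataFrame
    spacing_um: float = 144.0
    out_of_range: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if "distance_um" not in self.data.columns:
            raise ValueError("stall table needs a distance_um column")
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        d = self.data["distance_um"].to_numpy(dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        self.out_of_range = d > self.spacing_um / 2.0
        if self.out_of_range.any():
            warnings.warn(
                f"{int(self.out_of_range.sum())} stall(s) farther than half the "
                f"inter-pericyte spacing ({self.spacing_um / 2:.0f} µm); "
                "excluded from analyses",
                stacklevel=2,
            )

    @property
    def distances_um(self) -> np.ndarray:
        """Usable (in-range) distances."""
        d = self.data["distance_um"].to_numpy(dtype=float)
        return d[~self.out_of_range]


@dataclass(frozen=True)
class KSResult:
    statistic: float   # sup-norm D
    p_value: float
    n: int


@dataclass(frozen=True)
class SegmentSurvey:
    """Count of capillary segments scored for blocks in an image stack."""

    n_segments: int
    n_blocked: int
    stack_dims_um: tuple[float, float, float] = (94.0, 94.0, 10.0)

    def __post_init__(self) -> None:
        if self.n_segments < 0 or self.n_blocked < 0:
            raise ValueError("counts must be non-negative")
        if self.n_blocked > self.n_segments:
            raise ValueError("blocked segments cannot exceed total segments")


def uniform_null_cdf(distance_um, spacing_um: float = 144.0):
    """CDF of stall-to-soma distance under random block positions.

    Uniform on [0, spacing/2]: a straight line from 0 reaching unity at
    half the inter-pericyte spacing (72 µm for 144 µm spacing).
    Vectorised over ``distance_um``.
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.minimum(2.0 * d / spacing_um, 1.0)
    return float(out) if np.isscalar(distance_um) else out


def _ks_statistic(u_sorted: np.ndarray) -> float:
    """Sup-norm of the empirical CDF of uniform(0,1)-transformed samples,
    taking both one-sided gaps at every sample point."""
    n = u_sorted.size
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u_sorted)
    d_minus = np.max(u_sorted - (i - 1) / n)
    return float(max(d_plus, d_minus))


def ks_uniform_test(dataset: StallDataset) -> KSResult:
    """One-sample KS test of the stall distances against the uniform null.

    D is the sup-norm distance between the empirical CDF and the straight
    line ``uniform_null_cdf``; the p-value uses the asymptotic Kolmogorov
    distribution with the standard small-sample correction factor
    ``sqrt(n) + 0.12 + 0.11/sqrt(n)``.
    """
    d = dataset.distances_um
    n = d.size
    if n < 5:
        raise ValueError(f"need at least 5 usable distances, got {n}")
    u = np.sort(uniform_null_cdf(d, dataset.spacing_um))
    stat = _ks_statistic(u)
    p = float(kolmogorov((np.sqrt(n) + 0.12 + 0.11 / np.sqrt(n)) * stat))
    return KSResult(statistic=stat, p_value=min(max(p, 0.0), 1.0), n=n)


def percent_blocked(survey: SegmentSurvey) -> float:
    """Percent of scored capillary segments containing a block."""
    if survey.n_segments == 0:
        raise ValueError("survey contains no segments")
    return 100.0 * survey.n_blocked / survey.n_segments


def branch_order_breakdown(dataset: StallDataset) -> pd.DataFrame:
    """Fraction of stalls per branch order, from the PA and AV separately.

    Returns a tidy frame with columns scheme ("from_pa"/"from_av"), order,
    n and fraction; fractions sum to 1 within each scheme.  Stalls with a
    missing order are excluded; their count is reported in the frame's
    ``attrs["n_missing"]``.
    """
    cols = {"from_pa": "branch_order_pa", "from_av": "branch_order_av"}
    present = {k: c for k, c in cols.items() if c in dataset.data.columns}
    if not present:
        raise ValueError("stall table has no branch-order columns")
    rows = []
    missing: dict[str, int] = {}
    usable = dataset.data.loc[~dataset.out_of_range]
    for scheme, col in present.items():
        orders = usable[col]
        missing[scheme] = int(orders.isna().sum())
        counts = orders.dropna().astype(int).value_counts().sort_index()
        total = int(counts.sum())
        for order, n in counts.items():
            rows.append(
                {"scheme": scheme, "order": int(order), "n": int(n),
                 "fraction": n / total}
            )
    out = pd.DataFrame(rows, columns=["scheme", "order", "n", "fraction"])
    out.attrs["n_missing"] = missing
    return out


def stall_duration_summary(
    dataset: StallDataset, by: str = "cell_class"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class stall-duration summary and pairwise fold-ratio table.

    Returns (summary, fold_ratios): summary has mean/median/n per class;
    fold_ratios[i, j] = mean duration of class i / mean duration of class j
    for classes present in the data (absent classes simply do not appear).
    """
    if by not in dataset.data.columns or "duration_s" not in dataset.data.columns:
        raise ValueError(f"stall table needs {by!r} and duration_s columns")
    usable = dataset.data.loc[~dataset.out_of_range]
    grouped = usable.dropna(subset=[by, "duration_s"]).groupby(by)["duration_s"]
    summary = grouped.agg(mean="mean", median="median", n="count")
    means = summary["mean"]
    folds = pd.DataFrame(
        np.divide.outer(means.to_numpy(), means.to_numpy()),
        index=means.index, columns=means.index,
    )
    return summary, folds


def stall_duration_from_frames(
    first_frame: int, last_frame: int, rate_hz: float = 2.0
) -> float:
    """Stall duration from its first and last frame at the acquisition rate:
    (last - first + 1) / rate."""
    if last_frame < first_frame:
        raise ValueError("last frame precedes first frame")
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    return (last_frame - first_frame + 1) / rate_hz
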