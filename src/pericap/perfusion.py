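"""Capillary patency and blood-brain-barrier leakage quantification.

Patency: vessels that carried flow in vivo fill with intravascular
gelatin-FITC-albumin at perfusion; the patent (dye-filled) vessel length is
expressed as a percentage of total traced vessel length, optionally
restricted by metadata filters (e.g. near amyloid plaques, within 65 µm).

Extravasation: leakage of an intravascular dye into the parenchyma is
quantified as the extravascular intensity of each region relative to the
first acquired frame, optionally stratified by cortical depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NEAR_PLAQUE_THRESHOLD_UM = 65.0  # "near plaque" = closer than this


@dataclass(frozen=True)
class VesselTraceTable:
    """Per-segment vessel trace export: length, patent flag, metadata.

    ``data`` columns: length_um (required), patent (bool, required);
    optional near_plaque (bool), region (label).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("length_um", "patent"):
            if col not in self.data.columns:
                raise ValueError(f"vessel table needs a {col!r} column")
        if (self.data["length_um"] <= 0).any():
            raise ValueError("segment lengths must be positive")


@dataclass(frozen=True)
class ExtravasationSeries:
    """Extravascular intensity per region over frames.

    ``intensities`` has shape (n_regions, n_frames); ``depths_um`` is an
    optional per-region cortical depth used for stratified output.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    depths_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        inten = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "intensities", inten)
        if inten.shape[1] != t.size or t.size < 2:
            raise ValueError("need >= 2 frames with matching times")
        if self.depths_um is not None:
            d = np.asarray(self.depths_um, dtype=float)
            object.__setattr__(self, "depths_um", d)
            if d.size != inten.shape[0]:
                raise ValueError("one depth per region required")


def patency_percent(table: VesselTraceTable, where=None) -> float:
    """Percent of total vessel length that is patent (dye-filled).

    ``where`` restricts to a subset: a boolean column name, a pandas query
    string, or a callable DataFrame -> boolean mask.
    """
    df = table.data
    if where is not None:
        if callable(where):
            df = df[where(df)]
        elif isinstance(where, str) and where in df.columns:
            df = df[df[where].astype(bool)]
        elif isinstance(where, str):
            df = df.query(where)
        else:
            raise TypeError("where must be a column name, query string or callable")
        if df.empty:
            raise ValueError(f"no segments remain after filter {where!r}")
    total = float(df["length_um"].sum())
    if total <= 0:
        raise ValueError("total vessel length is zero")
    patent = float(df.loc[df["patent"].astype(bool), "length_um"].sum())
    return 100.0 * patent / total


def extravasation_change(
    series: ExtravasationSeries,
    depth_strata_um: tuple[tuple[float, float], ...] = ((0.0, 40.0), (40.0, 126.0)),
) -> pd.DataFrame:
    """Per-region intensity ratios relative to the first acquired frame.

    Returns a tidy frame with region, frame, time_s, ratio and (when depths
    are available) the depth stratum label.  The overall per-frame mean is
    appended as region = "mean".  Invariant to a global intensity gain.
    """
    first = series.intensities[:, :1]
    if np.any(first == 0):
        raise ValueError("first-frame intensity is zero for some region")
    ratios = series.intensities / first
    n_regions, n_frames = ratios.shape
    rows = []
    for r in range(n_regions):
        stratum = None
        if series.depths_um is not None:
            for lo, hi in depth_strata_um:
                if lo <= series.depths_um[r] < hi:
                    stratum = f"{lo:g}-{hi:g}um"
                    break
        for f in range(n_frames):
            rows.append(
                {"region": str(r), "frame": f, "time_s": series.times_s[f],
                 "ratio": ratios[r, f], "depth_stratum": stratum}
            )
    for f in range(n_frames):
        rows.append(
            {"region": "mean", "frame": f, "time_s": series.times_s[f],
             "ratio": float(ratios[:, f].mean()), "depth_stratum": None}
        )
    return pd.DataFrame(rows)
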