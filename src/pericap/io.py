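"""CSV/YAML readers and writers for the pipeline's tabular formats.

All CSVs carry their metadata (pixel size, label kind, baseline window,
pericyte spacing ...) as leading ``# key = value`` comment lines, followed
by a normal header row, so files remain self-describing plain text.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import yaml

from .calcium import CalciumTrace
from .geometry import LineProfile
from .stalls import StallDataset


def _write_with_meta(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    return df, meta


def write_profile_csv(path, profile: LineProfile, pixel_size_um: float | None = None) -> None:
    meta = {"label_kind": profile.label_kind}
    if pixel_size_um is not None:
        meta["pixel_size_um"] = pixel_size_um
    df = pd.DataFrame({"position_um": profile.positions, "intensity": profile.intensities})
    _write_with_meta(path, df, meta)


def read_profile_csv(path) -> LineProfile:
    df, meta = _read_with_meta(path)
    if "position_um" in df.columns:
        pos = df["position_um"].to_numpy(float)
    elif "pixel" in df.columns and "pixel_size_um" in meta:
        pos = df["pixel"].to_numpy(float) * float(meta["pixel_size_um"])
    else:
        raise ValueError("profile CSV needs position_um, or pixel + pixel_size_um metadata")
    return LineProfile(
        positions=pos,
        intensities=df["intensity"].to_numpy(float),
        label_kind=meta.get("label_kind", "lumen"),
    )


def write_trace_csv(path, trace: CalciumTrace) -> None:
    lo, hi = trace.baseline_window_s
    meta = {"baseline_start_s": lo, "baseline_end_s": hi, "normalized": trace.normalized}
    df = pd.DataFrame({"time_s": trace.times_s, "value": trace.values})
    _write_with_meta(path, df, meta)


def read_trace_csv(path) -> CalciumTrace:
    df, meta = _read_with_meta(path)
    return CalciumTrace(
        times_s=df["time_s"].to_numpy(float),
        values=df["value"].to_numpy(float),
        baseline_window_s=(float(meta["baseline_start_s"]), float(meta["baseline_end_s"])),
        normalized=meta.get("normalized", "False") == "True",
    )


def write_stall_csv(path, dataset: StallDataset) -> None:
    _write_with_meta(path, dataset.data, {"spacing_um": dataset.spacing_um})


def read_stall_csv(path) -> StallDataset:
    df, meta = _read_with_meta(path)
    return StallDataset(data=df, spacing_um=float(meta.get("spacing_um", 144.0)))


def write_vessel_table_csv(path, table: pd.DataFrame) -> None:
    _write_with_meta(path, table, {})


def read_vessel_table_csv(path) -> pd.DataFrame:
    df, _ = _read_with_meta(path)
    return df


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out if out is not None else {}
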