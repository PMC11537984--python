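"""Seeded generators for every input class the analysis pipeline consumes.

Real inputs are two-photon measurements: intensity line profiles across
vessels, GCaMP fluorescence traces, stall tables, binarised microglial mask
stacks, slow drug-response timecourses and vessel-trace tables.  Each
generator here emulates one of these with a known ground truth (true sigma,
injected event times, stall distribution, sigmoid midpoint ...) attached,
so recovery can be tested end to end.  Effect-size presets encode the
measured disease contrasts: a 3.7-fold rise of the somatic calcium
transient rate (2.6-fold in processes), a 21% capillary constriction at
pericyte somata, one pericyte per 144 µm, and a 5.2% vs 0.47% fraction of
blocked capillary segments.

Noise is Gaussian by default (photomultiplier noise at typical two-photon
intensities is near-Gaussian); a Poisson option is provided.  All
generators are reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calcium import CalciumTrace
from .geometry import LineProfile
from .microglia import MaskStack
from .stalls import CELL_CLASSES, StallDataset

# ---------------------------------------------------------------------------
# printed effect sizes, kept as named constants so presets stay in one place
AD_SOMA_RATE_FOLD = 3.7          # somatic transient-rate elevation in AD
AD_PROCESS_RATE_FOLD = 2.6       # process transient-rate elevation in AD
AD_SOMA_CONSTRICTION = 0.21      # capillary diameter loss at somata in AD
WT_SOMA_DIAMETER_UM = 6.9        # capillary diameter at somata, WT
NIM_CAP_DIAMETER_RISE = 0.096    # drug-evoked lumen diameter rise at somata (AD)
NIM_CAP_OUTER_RISE = 0.169       # drug-evoked outer diameter rise at somata (AD)
NIM_ART_OUTER_RISE = 0.178       # drug-evoked arteriole outer diameter rise (AD)
PERICYTE_SPACING_UM = 144.0      # one pericyte soma per 144 µm of capillary
WT_CBF_RISE_PERCENT = 27.0       # drug-evoked CBF rise, WT
AD_CBF_RISE_PERCENT = 47.0       # drug-evoked CBF rise, AD
WT_PERCENT_BLOCKED = 0.47        # capillary segments with blocks, WT
AD_PERCENT_BLOCKED = 5.2         # capillary segments with blocks, AD
NEUTROPHIL_MONOCYTE_STALL_FOLD = 5.4


# ---------------------------------------------------------------------------
# line profiles

@dataclass(frozen=True)
class ProfileSpec:
    """Gaussian vessel cross-section: b + A exp(-(x-mu)^2/(2 sigma^2))."""

    amplitude: float = 100.0
    center_um: float = 0.0
    sigma_um: float = 2.0
    baseline: float = 10.0
    noise_sd: float = 0.0
    pixel_size_um: float = 0.3
    n_pixels: int = 101
    poisson_noise: bool = False

    def __post_init__(self) -> None:
        if self.sigma_um <= 0:
            raise ValueError("sigma must be positive")
        if self.n_pixels < 7:
            raise ValueError("need at least 7 pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD cannot be negative")


def gen_profile(spec: ProfileSpec, seed: int, label_kind: str = "lumen") -> LineProfile:
    """Sample the Gaussian cross-section at pixel centres, plus noise."""
    rng = np.random.default_rng(seed)
    pos = (np.arange(spec.n_pixels) - (spec.n_pixels - 1) / 2) * spec.pixel_size_um
    clean = spec.baseline + spec.amplitude * np.exp(
        -((pos - spec.center_um) ** 2) / (2.0 * spec.sigma_um**2)
    )
    if spec.poisson_noise:
        inten = rng.poisson(np.maximum(clean, 0)).astype(float)
    else:
        inten = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    return LineProfile(positions=pos, intensities=inten, label_kind=label_kind)


def gen_edge_accumulation_profile(
    spec: ProfileSpec, seed: int, edge_offset_um: float = 3.0, label_kind: str = "lumen"
) -> LineProfile:
    """Double-peaked profile mimicking dye accumulation at the vessel wall:
    two Gaussians at ±edge_offset from the centre (defeats a single-Gaussian
    fit, exercising the manual-fallback path)."""
    rng = np.random.default_rng(seed)
    pos = (np.arange(spec.n_pixels) - (spec.n_pixels - 1) / 2) * spec.pixel_size_um
    clean = spec.baseline + spec.amplitude * (
        np.exp(-((pos - spec.center_um - edge_offset_um) ** 2) / (2 * spec.sigma_um**2))
        + np.exp(-((pos - spec.center_um + edge_offset_um) ** 2) / (2 * spec.sigma_um**2))
    )
    inten = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    return LineProfile(positions=pos, intensities=inten, label_kind=label_kind)


# ---------------------------------------------------------------------------
# calcium traces

@dataclass(frozen=True)
class TraceSpec:
    """Baseline white noise plus Poisson-timed exponential-decay transients.

    ``transient_rate_per_30s`` is the Poisson event rate; each event is an
    instantaneous rise of ``transient_amp_sd`` times the baseline noise SD,
    decaying with time constant ``decay_tau_s``.  Sampling at 2 Hz matches
    typical transient acquisition.
    """

    duration_s: float = 300.0
    rate_hz: float = 2.0
    baseline_f0: float = 100.0
    baseline_sd: float = 5.0
    transient_rate_per_30s: float = 1.0
    transient_amp_sd: float = 10.0
    decay_tau_s: float = 2.0
    baseline_window_s: float = 60.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.transient_rate_per_30s < 0:
            raise ValueError("transient rate cannot be negative")
        if self.decay_tau_s <= 0:
            raise ValueError("decay tau must be positive")


# presets encoding the measured disease contrast (WT rates are the package's
# baseline choice; the AD values are the printed fold elevations applied to it)
WT_SOMA_TRACE = TraceSpec(transient_rate_per_30s=0.5)
AD_SOMA_TRACE = TraceSpec(transient_rate_per_30s=0.5 * AD_SOMA_RATE_FOLD)
WT_PROCESS_TRACE = TraceSpec(transient_rate_per_30s=1.0)
AD_PROCESS_TRACE = TraceSpec(transient_rate_per_30s=1.0 * AD_PROCESS_RATE_FOLD)


@dataclass(frozen=True)
class SyntheticTrace:
    trace: CalciumTrace
    event_times_s: np.ndarray   # ground-truth injected event times
    spec: TraceSpec
    overlap_warning: bool       # events overlap on > 50% of the record


def gen_trace(spec: TraceSpec, seed: int) -> SyntheticTrace:
    """Generate a noisy trace with Poisson-timed transients over the full
    record; event times are returned as ground truth."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz
    values = spec.baseline_f0 + rng.normal(0.0, spec.baseline_sd, size=n)
    lam = spec.transient_rate_per_30s * spec.duration_s / 30.0
    n_events = rng.poisson(lam)
    # event times snapped to the sampling grid so each event's first sample
    # carries the full amplitude (instantaneous rise at acquisition rate)
    raw = np.sort(rng.uniform(0.0, spec.duration_s, size=n_events))
    ks = np.unique(np.minimum(np.round(raw * spec.rate_hz).astype(int), n - 1))
    event_times = t[ks] if ks.size else np.array([])
    amp = spec.transient_amp_sd * spec.baseline_sd
    for k in ks:
        values[k:] += amp * np.exp(-(t[k:] - t[k]) / spec.decay_tau_s)
    # overlap flag: union of [t_i, t_i + 3 tau] covering > 50% of the record
    covered = 0.0
    end = 0.0
    for te in event_times:
        lo, hi = max(te, end), te + 3 * spec.decay_tau_s
        if hi > lo:
            covered += hi - lo
            end = hi
    overlap = covered > 0.5 * spec.duration_s
    if overlap:
        warnings.warn("transients overlap on more than half the trace", stacklevel=2)
    trace = CalciumTrace(
        times_s=t, values=values,
        baseline_window_s=(0.0, spec.baseline_window_s),
    )
    return SyntheticTrace(trace=trace, event_times_s=event_times, spec=spec,
                          overlap_warning=overlap)


# ---------------------------------------------------------------------------
# stall scenes

@dataclass(frozen=True)
class StallScene:
    """Stall-to-soma distance scene: uniform (random block positions) or
    soma-clustered (truncated exponential attraction to the soma)."""

    n_stalls: int = 119
    spacing_um: float = PERICYTE_SPACING_UM
    mode: str = "uniform"
    cluster_scale_um: float = 10.0

    def __post_init__(self) -> None:
        if self.n_stalls < 1:
            raise ValueError("need at least one stall")
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        if self.mode not in ("uniform", "clustered"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "clustered" and not (
            0 < self.cluster_scale_um < self.spacing_um / 2
        ):
            raise ValueError("cluster scale must lie in (0, spacing/2)")


def gen_stalls(scene: StallScene, seed: int) -> StallDataset:
    """Generate a stall table with distances, branch orders, cell classes
    and durations.

    Distances: uniform on [0, s/2], or Exp(cluster_scale) truncated to
    [0, s/2] via inverse-CDF sampling.  Metadata emulate the measured
    venule-end bias (87% of blocks within the first three orders from the
    ascending venule) and the neutrophil/monocyte stall-duration contrast.
    """
    rng = np.random.default_rng(seed)
    half = scene.spacing_um / 2.0
    if scene.mode == "uniform":
        d = rng.uniform(0.0, half, size=scene.n_stalls)
    else:
        u = rng.uniform(size=scene.n_stalls)
        cap = 1.0 - np.exp(-half / scene.cluster_scale_um)
        d = -scene.cluster_scale_um * np.log1p(-u * cap)
    # branch orders: blocks sit at the venule end of the bed
    order_av = np.where(
        rng.uniform(size=scene.n_stalls) < 0.87,
        rng.integers(1, 4, size=scene.n_stalls),
        rng.integers(4, 8, size=scene.n_stalls),
    )
    order_pa = rng.integers(3, 9, size=scene.n_stalls)
    cls = rng.choice(CELL_CLASSES, size=scene.n_stalls, p=(0.33, 0.17, 0.30, 0.20))
    mean_dur = {"neutrophil": 27.0, "monocyte": 5.0, "RBC": 10.0, "unknown": 10.0}
    dur = np.array([rng.exponential(mean_dur[c]) for c in cls])
    data = pd.DataFrame(
        {
            "segment_id": np.arange(scene.n_stalls),
            "distance_um": d,
            "branch_order_pa": order_pa,
            "branch_order_av": order_av,
            "cell_class": cls,
            "duration_s": dur,
        }
    )
    ds = StallDataset(data=data, spacing_um=scene.spacing_um)
    ds.data.attrs["mode"] = scene.mode
    return ds


# ---------------------------------------------------------------------------
# microglial mask stacks

def gen_mask_stack(
    seed: int,
    n_frames: int = 20,
    shape: tuple[int, int] = (64, 64),
    radius_px: float = 8.0,
    step_px: float = 2.0,
    radius_jitter: float = 0.1,
    pixel_size_um: float = 0.5,
    frame_interval_s: float = 60.0,
) -> MaskStack:
    """Binary disk that random-walks and deforms frame to frame, emulating a
    surveying microglial cell. ``step_px = 0`` gives a static cell."""
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    frames = np.zeros((n_frames, h, w), dtype=bool)
    for k in range(n_frames):
        r = radius_px * (1.0 + (radius_jitter * rng.standard_normal() if k else 0.0))
        r = max(r, 2.0)
        frames[k] = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        cy = float(np.clip(cy + step_px * rng.standard_normal(), radius_px, h - radius_px))
        cx = float(np.clip(cx + step_px * rng.standard_normal(), radius_px, w - radius_px))
    return MaskStack(frames, pixel_size_um=pixel_size_um,
                     frame_interval_s=frame_interval_s)


# ---------------------------------------------------------------------------
# slow drug-response timecourses

@dataclass(frozen=True)
class SyntheticTimecourse:
    times_min: np.ndarray
    values: np.ndarray
    onset_min: float
    midpoint_min: float   # ground-truth time from onset to half-peak


def gen_timecourse(
    seed: int,
    duration_min: float = 40.0,
    dt_min: float = 0.25,
    onset_min: float = 5.0,
    midpoint_min: float = 8.41,
    rise_time_min: float = 2.0,
    baseline: float = 1.0,
    plateau: float = 1.5,
    noise_sd: float = 0.01,
) -> SyntheticTimecourse:
    """Sigmoidal (logistic) response to an intervention at ``onset_min``;
    the logistic midpoint is the ground-truth time to half-peak."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + 1e-9, dt_min)
    sig = baseline + (plateau - baseline) / (
        1.0 + np.exp(-(t - onset_min - midpoint_min) / rise_time_min)
    )
    sig[t < onset_min] = baseline  # flat pre-onset baseline
    values = sig + rng.normal(0.0, noise_sd, size=t.shape)
    return SyntheticTimecourse(times_min=t, values=values, onset_min=onset_min,
                               midpoint_min=midpoint_min)


# ---------------------------------------------------------------------------
# vessel-trace tables

def gen_vessel_table(
    seed: int,
    n_segments: int = 250,
    percent_blocked: float = AD_PERCENT_BLOCKED,
    near_plaque_fraction: float = 0.3,
    mean_length_um: float = 60.0,
) -> pd.DataFrame:
    """Segment table with lengths, patent flags and plaque proximity.

    The non-patent fraction defaults to the diseased value (5.2% of
    segments blocked); pass 0.47 for the healthy preset.  Non-patent
    segments are preferentially near plaques.
    """
    rng = np.random.default_rng(seed)
    lengths = rng.lognormal(mean=np.log(mean_length_um), sigma=0.4, size=n_segments)
    near = rng.uniform(size=n_segments) < near_plaque_fraction
    p_block = percent_blocked / 100.0
    # blocks concentrate near plaques (3:1 odds) while matching the overall rate
    w = np.where(near, 3.0, 1.0)
    p = p_block * w / np.average(w)
    patent = rng.uniform(size=n_segments) >= p
    return pd.DataFrame(
        {
            "length_um": lengths,
            "patent": patent,
            "near_plaque": near,
            "region": "cortex",
        }
    )
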