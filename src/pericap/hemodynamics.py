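"""Two-compartment series vascular-resistance model of cerebral blood flow.

The cerebral vascular bed is reduced to two resistances in series:
arterioles carrying a fraction ``f_art`` (default 0.43) of the healthy
total resistance and capillaries the remaining ``f_cap`` (0.57).  Each
compartment obeys Poiseuille scaling, resistance proportional to
1/diameter^4.  Pericyte-mediated capillary constriction (and its relief by
a CaV blocker) is confined to a rectangular window of length ``L_c``
centred on each pericyte soma, with somata spaced ``s`` (144 µm) apart, so
the capillary resistance per pericyte unit is

    R_cap = L_c / d_soma^4 + (s - L_c) / d_off^4,

normalised to the healthy uniform-diameter unit.  The predicted percent
change in flow between two vascular states is 100 * (R_before/R_after - 1).

With the default window of 50 µm, a 21% baseline constriction at somata
relieved by a 16.9% capillary (in-window) and 17.8% arteriole dilation
predicts a 51% flow increase — the drug scenario the model was built for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class DiameterProfileSegment:
    """Piecewise-constant diameter profile along one pericyte unit.

    ``pieces`` is a list of (length_um, relative_diameter).
    """

    pieces: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pieces = tuple((float(l), float(d)) for l, d in self.pieces)
        object.__setattr__(self, "pieces", pieces)
        if not pieces:
            raise ValueError("profile needs at least one piece")
        for length, diam in pieces:
            if length <= 0:
                raise ValueError(f"piece length must be positive, got {length}")
            if diam <= 0:
                raise ValueError(f"diameter must be positive, got {diam}")

    @property
    def total_length_um(self) -> float:
        return sum(l for l, _ in self.pieces)


@dataclass(frozen=True)
class VascularState:
    """Multiplicative diameter factors relative to the healthy state."""

    cap_soma_factor: float = 1.0   # capillary diameter inside the soma window
    cap_off_factor: float = 1.0    # capillary diameter outside the window
    art_factor: float = 1.0        # arteriole diameter

    def __post_init__(self) -> None:
        for name in ("cap_soma_factor", "cap_off_factor", "art_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FlowPrediction:
    resistance_before: float
    resistance_after: float
    cbf_change_percent: float


@dataclass(frozen=True)
class HemodynamicModel:
    f_art: float = 0.43
    f_cap: float = 0.57
    window_um: float = 50.0     # length of the constriction window per soma
    spacing_um: float = 144.0   # inter-pericyte spacing

    def __post_init__(self) -> None:
        if not math.isclose(self.f_art + self.f_cap, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("arteriole and capillary fractions must sum to 1")
        if not (0.0 <= self.window_um <= self.spacing_um):
            raise ValueError("window length must lie in [0, spacing]")
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")

    def capillary_profile(self, state: VascularState) -> DiameterProfileSegment:
        """Diameter profile of one pericyte unit under ``state``."""
        pieces = []
        if self.window_um > 0:
            pieces.append((self.window_um, state.cap_soma_factor))
        if self.spacing_um - self.window_um > 0:
            pieces.append((self.spacing_um - self.window_um, state.cap_off_factor))
        return DiameterProfileSegment(tuple(pieces))

    def total_resistance(self, state: VascularState) -> float:
        """Normalised total resistance (healthy state = 1)."""
        r_cap = segment_resistance(self.capillary_profile(state)) / self.spacing_um
        return self.f_art / state.art_factor**4 + self.f_cap * r_cap


def segment_resistance(profile: DiameterProfileSegment) -> float:
    """Poiseuille resistance of a piecewise-constant diameter profile.

    R = sum_i length_i / diameter_i^4, so a uniform diameter-1 profile has
    resistance equal to its total length.
    """
    return sum(length / diam**4 for length, diam in profile.pieces)


def predict_flow_change(
    model: HemodynamicModel, before: VascularState, after: VascularState
) -> FlowPrediction:
    """Percent flow change between two vascular states at fixed pressure."""
    r_before = model.total_resistance(before)
    r_after = model.total_resistance(after)
    return FlowPrediction(
        resistance_before=r_before,
        resistance_after=r_after,
        cbf_change_percent=100.0 * (r_before / r_after - 1.0),
    )


def calibrate_window_length(
    model: HemodynamicModel,
    before: VascularState,
    after: VascularState,
    target_change_percent: float,
    tol_um: float = 0.01,
) -> float:
    """Window length L_c at which the predicted flow change hits the target.

    Verifies that the prediction is monotone in L_c over [0, spacing] on a
    grid before bisecting; raises with the achievable range when the target
    lies outside it.
    """

    def pred(lc: float) -> float:
        m = HemodynamicModel(
            f_art=model.f_art, f_cap=model.f_cap,
            window_um=lc, spacing_um=model.spacing_um,
        )
        return predict_flow_change(m, before, after).cbf_change_percent

    s = model.spacing_um
    grid = [pred(s * k / 16) for k in range(17)]
    diffs = [b - a for a, b in zip(grid[:-1], grid[1:])]
    if not (all(d >= -1e-12 for d in diffs) or all(d <= 1e-12 for d in diffs)):
        raise ValueError("prediction is not monotone in the window length")
    lo_val, hi_val = pred(0.0), pred(s)
    vmin, vmax = min(lo_val, hi_val), max(lo_val, hi_val)
    if not (vmin - 1e-9 <= target_change_percent <= vmax + 1e-9):
        raise ValueError(
            f"target {target_change_percent:.3f}% unachievable; the window "
            f"length spans predictions [{vmin:.3f}%, {vmax:.3f}%]"
        )
    increasing = hi_val >= lo_val
    lo, hi = 0.0, s
    while hi - lo > tol_um:
        mid = 0.5 * (lo + hi)
        v = pred(mid)
        if (v < target_change_percent) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# Printed effect sizes of the drug scenario, used as named states.
AD_BASELINE = VascularState(cap_soma_factor=0.79, cap_off_factor=1.0, art_factor=1.0)
AD_NIMODIPINE = VascularState(
    cap_soma_factor=0.79 * 1.169, cap_off_factor=1.0, art_factor=1.178
)
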