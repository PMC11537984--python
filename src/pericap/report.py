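"""End-to-end pipeline driver: synthetic scenario -> all analyses -> files.

``run_pipeline`` takes a validated :class:`RunConfig`, generates the healthy
vs diseased synthetic scenario from one seed, runs every analysis stage and
writes CSV/JSON outputs plus a machine-readable provenance record
sufficient to re-run the pipeline.  Identical seeds give byte-identical
numeric outputs.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium, geometry, hemodynamics, io as pio, microglia, stalls, synthetic


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration. Unknown keys are rejected at load time."""

    seed: int = 0
    outdir: str = "pericap_report"
    n_profiles: int = 50
    profile_noise_sd: float = 5.0
    quality_threshold: float = 0.90
    n_stalls: int = 119
    spacing_um: float = 144.0
    window_um: float = 50.0
    f_art: float = 0.43
    cap_soma_before: float = 1.0 - synthetic.AD_SOMA_CONSTRICTION
    cap_soma_drug_factor: float = 1.0 + synthetic.NIM_CAP_OUTER_RISE
    art_drug_factor: float = 1.0 + synthetic.NIM_ART_OUTER_RISE

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _provenance(config: RunConfig) -> dict:
    versions = {"python": platform.python_version()}
    for pkg in ("pericap", "numpy", "scipy", "pandas"):
        try:
            versions[pkg] = metadata.version(pkg)
        except metadata.PackageNotFoundError:  # editable/dev installs
            versions[pkg] = "unknown"
    record = asdict(config)
    record.pop("outdir")  # where the bundle lives, not what it contains
    return {"config": record, "versions": versions}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a seeded synthetic scenario; return the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {}

    # --- vessel diametry: healthy vs constricted scenes -------------------
    wt_sigma = synthetic.WT_SOMA_DIAMETER_UM / geometry.width_at_fraction(
        geometry.GaussianFit(1, 0, 1.0, 0, 1.0), 0.25
    )
    rows = []
    for cohort, sigma in (
        ("WT", wt_sigma),
        ("AD", wt_sigma * (1.0 - synthetic.AD_SOMA_CONSTRICTION)),
    ):
        for _ in range(config.n_profiles):
            spec = synthetic.ProfileSpec(
                sigma_um=sigma, noise_sd=config.profile_noise_sd, n_pixels=121
            )
            prof = synthetic.gen_profile(spec, seed=int(rng.integers(2**31)))
            m = geometry.measure_diameter(prof, config.quality_threshold)
            rows.append(
                {"cohort": cohort, "diameter_um": m.value_um, "mode": m.mode,
                 "method": m.method, "quality": m.quality}
            )
    diam = pd.DataFrame(rows)
    diam.to_csv(out / "diameters.csv", index=False)
    means = diam.groupby("cohort")["diameter_um"].mean()
    report["diameter_um_wt"] = float(means["WT"])
    report["diameter_um_ad"] = float(means["AD"])
    report["constriction_percent"] = 100.0 * (1.0 - means["AD"] / means["WT"])

    # --- calcium transients: healthy vs diseased rates ---------------------
    summaries = []
    for cohort, spec in (("WT", synthetic.WT_SOMA_TRACE), ("AD", synthetic.AD_SOMA_TRACE)):
        for _ in range(20):
            st = synthetic.gen_trace(spec, seed=int(rng.integers(2**31)))
            norm = calcium.normalize_trace(st.trace)
            events = calcium.detect_transients(norm)
            s = calcium.summarize_transients(events, spec.duration_s)
            summaries.append({"cohort": cohort, "rate_per_30s": s.rate_per_30s,
                              "n_events": s.n_events})
    rates = pd.DataFrame(summaries)
    rates.to_csv(out / "transient_rates.csv", index=False)
    by = rates.groupby("cohort")["rate_per_30s"].mean()
    report["transient_rate_wt"] = float(by["WT"])
    report["transient_rate_ad"] = float(by["AD"])

    # --- hemodynamic prediction for the drug scenario ----------------------
    model = hemodynamics.HemodynamicModel(
        f_art=config.f_art, f_cap=1.0 - config.f_art,
        window_um=config.window_um, spacing_um=config.spacing_um,
    )
    before = hemodynamics.VascularState(cap_soma_factor=config.cap_soma_before)
    after = hemodynamics.VascularState(
        cap_soma_factor=config.cap_soma_before * config.cap_soma_drug_factor,
        art_factor=config.art_drug_factor,
    )
    pred = hemodynamics.predict_flow_change(model, before, after)
    report["cbf_change_percent"] = pred.cbf_change_percent
    report["resistance_before"] = pred.resistance_before
    report["resistance_after"] = pred.resistance_after

    # --- stall statistics ---------------------------------------------------
    scene = synthetic.StallScene(
        n_stalls=config.n_stalls, spacing_um=config.spacing_um, mode="clustered"
    )
    ds = synthetic.gen_stalls(scene, seed=int(rng.integers(2**31)))
    pio.write_stall_csv(out / "stalls.csv", ds)
    ks = stalls.ks_uniform_test(ds)
    report["ks_statistic"] = ks.statistic
    report["ks_p_value"] = ks.p_value
    summary, folds = stalls.stall_duration_summary(ds)
    summary.to_csv(out / "stall_durations.csv")
    if {"neutrophil", "monocyte"} <= set(folds.index):
        report["neutrophil_monocyte_fold"] = float(
            folds.loc["neutrophil", "monocyte"]
        )

    # --- microglial surveillance -------------------------------------------
    stack = synthetic.gen_mask_stack(seed=int(rng.integers(2**31)))
    microglia.write_mask_stack(out / "mask_stack.tif", stack)
    surv = microglia.surveillance_curve(stack)
    pd.DataFrame(
        {
            "frame": np.arange(surv.cumulative_pixels.size),
            "cumulative_pixels": surv.cumulative_pixels,
            "cell_area": surv.cell_area,
            "motility_index": surv.motility_index,
        }
    ).to_csv(out / "surveillance.csv", index=False)
    report["surveillance_final"] = int(surv.cumulative_pixels[-1])
    report["motility_final"] = float(surv.motility_index[-1])

    # --- provenance ---------------------------------------------------------
    bundle = {"report": report, "provenance": _provenance(config)}
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    return bundle
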