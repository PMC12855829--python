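"""Shared builders for compact synthetic datasets used across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from moondvm import imaging, synthetic
from moondvm.assembly import SIZE_CLASS_RANGES


def make_small_night_table(
    seed: int = 0,
    n_dates: int = 3,
    profiles_per_date: int = 4,
    n_bins: int = 40,
    beta: dict | None = None,
    sigma_date: float = 0.2,
    sigma_profile: float = 0.14,
    gamma_shape: float = 2.0,
) -> pd.DataFrame:
    """A compact night-design table with simulated gamma densities.

    Covariates follow the same qualitative depth structure as the full
    generator (exponential light decay, thermocline, deep chlorophyll
    maximum) but at a size that keeps fits instantaneous.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_dates):
        for p in range(profiles_per_date):
            pid = f"d{d}_p{p}"
            surface_lx = rng.uniform(0.001, 0.3)
            for b in range(n_bins):
                z = (b + 0.5) * 0.1
                lx = surface_lx * np.exp(-0.25 * z)
                lx = 0.0 if lx < 0.001 else lx
                for cls in ("small", "medium", "large"):
                    rows.append(
                        {
                            "date": f"date{d}",
                            "profile_id": pid,
                            "bin_index": b,
                            "bin_mid_depth": z,
                            "size_class": cls,
                            "illuminance_lx": lx,
                            "temperature_C": 8 + 12 / (1 + np.exp((z - 2.0) / 0.8)),
                            "chl_a_ugL": 2 + 4 * np.exp(-((z - 2.5) ** 2) / 2.0),
                        }
                    )
    table = pd.DataFrame(rows)
    b = beta or synthetic.NIGHT_COEFFICIENTS["cladoceran"]
    return synthetic.simulate_bin_densities(
        table, b, sigma_date, sigma_profile, gamma_shape, seed=seed + 1
    )


def make_silhouette_sweep(
    n: int = 120, scale_factor: int = 1, seed: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Isolated rendered silhouettes with ground truth.

    Returns (truth, detections) matched by nearest depth; individuals are
    spaced 10 mm apart vertically with lateral margin so no two touch.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        taxon = "cladoceran" if i % 2 else "copepod"
        cls = ("small", "medium", "large")[i % 3]
        lo, hi = SIZE_CLASS_RANGES[taxon][cls]
        ratio = rng.uniform(1.2, 1.8) if taxon == "cladoceran" else rng.uniform(2.2, 3.0)
        rows.append(
            {
                "profile_id": "sweep",
                "taxon": taxon,
                "depth_m": 0.005 + i * 0.010,
                "esd_true_mm": rng.uniform(lo, hi),
                "lateral_mm": 6.0 + (i % 5) * 9.0,
                "axis_ratio": ratio,
                "antenna": taxon == "copepod",
                "size_class": cls,
            }
        )
    truth = pd.DataFrame(rows)
    lake = truth["depth_m"].max() + 0.05
    frames = synthetic.render_profile_frames(
        truth, synthetic.Optics(), lake_depth_m=lake, scale_factor=scale_factor, seed=seed + 1
    )
    det = imaging.detect_profile(frames, scale_factor=scale_factor)
    matched = []
    for _, d in det.iterrows():
        j = (truth["depth_m"] - d["depth_m"]).abs().idxmin()
        rec = d.to_dict()
        rec.update(
            true_taxon=truth.at[j, "taxon"],
            esd_true_mm=truth.at[j, "esd_true_mm"],
            true_depth_m=truth.at[j, "depth_m"],
        )
        matched.append(rec)
    m = pd.DataFrame(matched)
    # flag copies whose silhouette crosses a frame edge (clipped rendering):
    # the overlap of consecutive frames guarantees a complete copy elsewhere
    delta = synthetic.Optics().descent_per_frame_m
    height = frames[0].height_m
    top = m["frame_index"] * delta
    m["edge_clipped"] = ((m["depth_m"] - top) < 0.002) | ((top + height - m["depth_m"]) < 0.002)
    return truth, m
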