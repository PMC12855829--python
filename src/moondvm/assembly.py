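"""From frame-level detections to the depth-binned density table.

A profile is a descending stack of overlapping frames. Overlap is removed by
a deterministic keep-first rule; surviving detections are assigned to
taxon-specific ESD size classes, counted in half-open 10 cm depth bins, and
converted to densities using the exactly-sampled water volume per bin
(frame breadth × optical path × kept strip length). The resulting rows —
one per profile × taxon × size class × covered bin, zeros included — are
the input contract of the mixed models, after per-bin covariates
(illuminance, temperature, chlorophyll-a) are attached. Per-profile mean
depth summaries use raw individual depths, not the binned densities.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .lightfield import LightProfile

__all__ = [
    "SIZE_CLASS_RANGES",
    "SIZE_CLASSES",
    "TAXA",
    "BIN_TABLE_COLUMNS",
    "deoverlap",
    "drop_duplicate_detections",
    "assign_size_class",
    "bin_densities",
    "attach_covariates",
    "profile_mean_depth",
]

#: Closed ESD intervals (mm) of the three size classes per taxon, taken from
#: the modes of the observed ESD histograms; values between ranges are
#: "unclassified" and excluded from model rows.
SIZE_CLASS_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "cladoceran": {
        "small": (0.36, 0.39),
        "medium": (0.45, 0.53),
        "large": (0.70, 0.75),
    },
    "copepod": {
        "small": (0.36, 0.37),
        "medium": (0.45, 0.47),
        "large": (0.66, 0.68),
    },
}

SIZE_CLASSES = ("small", "medium", "large")
TAXA = ("cladoceran", "copepod")

BIN_TABLE_COLUMNS = (
    "profile_id",
    "time",
    "taxon",
    "size_class",
    "bin_index",
    "bin_mid_depth",
    "density",
    "sampled_volume_L",
    "illuminance_lx",
    "temperature_C",
    "chl_a_ugL",
)


# ---------------------------------------------------------------------------
# De-overlap
# ---------------------------------------------------------------------------

def deoverlap(frame_meta: pd.DataFrame, frame_height_m: float) -> pd.DataFrame:
    """Assign each frame the strip of depth it alone contributes (keep-first).

    ``frame_meta`` needs columns frame_index and top_depth_m, ordered by
    strictly increasing top depth. Frame k keeps the part of
    [top_k, top_k + height] not already covered by frame k−1's kept strip;
    for spacings no larger than the frame height the strips partition
    [first top, last bottom] with no gaps and no double coverage.

    Returns a frame with columns frame_index, keep_top_m, keep_bottom_m.
    """
    for col in ("frame_index", "top_depth_m"):
        if col not in frame_meta.columns:
            raise ValueError(f"frame metadata is missing column {col!r}")
    tops = frame_meta["top_depth_m"].to_numpy(dtype=float)
    if np.any(np.diff(tops) <= 0):
        raise ValueError("frames must be ordered by strictly increasing top depth")
    keep_top = np.empty_like(tops)
    keep_bottom = tops + frame_height_m
    prev_bottom = -np.inf
    for i, top in enumerate(tops):
        keep_top[i] = max(top, prev_bottom)
        prev_bottom = keep_bottom[i]
    return pd.DataFrame(
        {
            "frame_index": frame_meta["frame_index"].to_numpy(),
            "keep_top_m": keep_top,
            "keep_bottom_m": keep_bottom,
        }
    )


def drop_duplicate_detections(detections: pd.DataFrame, strips: pd.DataFrame) -> pd.DataFrame:
    """Drop detections whose depth falls outside their frame's kept strip.

    An organism in the overlap of consecutive frames is imaged twice; the
    keep-first strips make the copy in the earlier frame the canonical one.
    Kept strips are half-open [keep_top, keep_bottom) except the last, which
    is closed at the bottom.
    """
    if detections.empty:
        return detections.copy()
    s = strips.set_index("frame_index")
    last_frame = strips["frame_index"].iloc[-1]
    keep = []
    for _, det in detections.iterrows():
        fi = det["frame_index"]
        if fi not in s.index:
            keep.append(False)
            continue
        top, bottom = s.at[fi, "keep_top_m"], s.at[fi, "keep_bottom_m"]
        d = det["depth_m"]
        keep.append(top <= d < bottom or (fi == last_frame and d == bottom))
    return detections.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Size classes
# ---------------------------------------------------------------------------

def assign_size_class(esd_mm: float, taxon: str) -> str:
    """Closed-interval membership in the taxon's printed ESD ranges.

    ESDs that fall in the gaps between ranges return "unclassified"; such
    detections are tallied but excluded from the model rows.
    """
    if taxon not in SIZE_CLASS_RANGES:
        raise ValueError(f"unknown taxon {taxon!r}; expected one of {TAXA}")
    for cls, (lo, hi) in SIZE_CLASS_RANGES[taxon].items():
        if lo <= esd_mm <= hi:
            return cls
    return "unclassified"


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def _bin_coverage(strips: pd.DataFrame, n_bins: int, bin_height: float) -> np.ndarray:
    """Kept-strip length (m) intersecting each depth bin."""
    cov = np.zeros(n_bins)
    for top, bottom in strips[["keep_top_m", "keep_bottom_m"]].to_numpy():
        first = max(int(math.floor(top / bin_height)), 0)
        last = min(int(math.ceil(bottom / bin_height)), n_bins)
        for b in range(first, last):
            lo, hi = b * bin_height, (b + 1) * bin_height
            cov[b] += max(0.0, min(hi, bottom) - max(lo, top))
    return cov


def bin_densities(
    detections: pd.DataFrame,
    strips: pd.DataFrame,
    *,
    frame_breadth_mm: float = 52.0,
    path_mm: float = 100.0,
    lake_depth_m: float = 16.7,
    bin_height_m: float = 0.1,
    profile_id: str | None = None,
    time=None,
    taxa: tuple[str, ...] = TAXA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count detections into 10 cm bins and convert to densities (ind/L).

    The sampled volume of a bin is breadth × path × (kept strip length in
    the bin); a fully covered 10 cm bin holds 0.52 L. Every taxon × size
    class combination is emitted for every covered bin (zero counts become
    density 0); bins with zero kept coverage emit no row. Detections whose
    ESD falls between size-class ranges are excluded and tallied in the
    returned audit table.
    """
    n_bins = int(math.ceil(round(lake_depth_m / bin_height_m, 9)))
    cov = _bin_coverage(strips, n_bins, bin_height_m)
    breadth_m, path_m = frame_breadth_mm / 1000.0, path_mm / 1000.0
    volume_L = breadth_m * path_m * cov * 1000.0

    if profile_id is None:
        profile_id = (
            str(detections["profile_id"].iloc[0]) if len(detections) else "profile"
        )

    det = detections.copy()
    audit_rows = []
    if len(det):
        det = det.loc[det["taxon"].isin(taxa)].copy()
        det["size_class"] = [
            assign_size_class(e, t) for e, t in zip(det["esd_mm"], det["taxon"])
        ]
        n_unclassified = int((det["size_class"] == "unclassified").sum())
        audit_rows.append({"profile_id": profile_id, "n_unclassified": n_unclassified})
        det = det.loc[det["size_class"] != "unclassified"]
        det["bin_index"] = np.minimum(
            (det["depth_m"] / bin_height_m).astype(int), n_bins - 1
        )
    else:
        det["size_class"] = pd.Series(dtype=str)
        det["bin_index"] = pd.Series(dtype=int)
        audit_rows.append({"profile_id": profile_id, "n_unclassified": 0})

    counts = (
        det.groupby(["taxon", "size_class", "bin_index"]).size()
        if len(det)
        else pd.Series(dtype=int)
    )

    rows = []
    covered = np.flatnonzero(cov > 0)
    for b in covered:
        for taxon in taxa:
            for cls in SIZE_CLASSES:
                n = int(counts.get((taxon, cls, b), 0)) if len(det) else 0
                if n > 0 and volume_L[b] <= 0:
                    raise RuntimeError(
                        f"bin {b} has {n} detections but zero sampled volume"
                    )
                rows.append(
                    {
                        "profile_id": profile_id,
                        "time": time,
                        "taxon": taxon,
                        "size_class": cls,
                        "bin_index": int(b),
                        "bin_mid_depth": (b + 0.5) * bin_height_m,
                        "density": n / volume_L[b],
                        "sampled_volume_L": volume_L[b],
                    }
                )
    table = pd.DataFrame(rows)
    audit = pd.DataFrame(audit_rows)
    return table, audit


def attach_covariates(
    bins: pd.DataFrame,
    environment,
    light: LightProfile,
) -> pd.DataFrame:
    """Join illuminance by bin index and interpolate temperature/chl-a.

    ``environment`` must expose depth_grid, temperature and chl_a arrays
    spanning the binned depth range; environmental fields measured at 50 cm
    are linearly interpolated to the 10 cm bin midpoints.
    """
    out = bins.copy()
    grid = np.asarray(environment.depth_grid, dtype=float)
    mids = out["bin_mid_depth"].to_numpy(dtype=float)
    if len(mids) and (grid.min() > mids.min() or grid.max() < mids.max()):
        raise ValueError(
            f"environment grid [{grid.min()}, {grid.max()}] does not span "
            f"bin midpoints [{mids.min()}, {mids.max()}]"
        )
    out["temperature_C"] = np.interp(mids, grid, np.asarray(environment.temperature, float))
    out["chl_a_ugL"] = np.interp(mids, grid, np.asarray(environment.chl_a, float))
    lx = np.asarray(light.illuminance_lx, dtype=float)
    idx = out["bin_index"].to_numpy(dtype=int)
    if len(idx) and idx.max() >= len(lx):
        raise ValueError("light profile has fewer bins than the density table")
    out["illuminance_lx"] = lx[idx] if len(idx) else np.array([])
    return out


# ---------------------------------------------------------------------------
# Per-profile summaries
# ---------------------------------------------------------------------------

def profile_mean_depth(detections: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SE of raw individual depths per profile × taxon.

    SE = SD/√n with SD the n−1 sample estimate; a single detection reports
    SE 0. Groups with no detections emit no row.
    """
    if detections.empty:
        return pd.DataFrame(columns=["profile_id", "taxon", "mean_depth", "se_depth", "n_individuals"])
    rows = []
    for (pid, taxon), grp in detections.groupby(["profile_id", "taxon"]):
        d = grp["depth_m"].to_numpy(dtype=float)
        se = float(d.std(ddof=1) / math.sqrt(len(d))) if len(d) > 1 else 0.0
        rows.append(
            {
                "profile_id": pid,
                "taxon": taxon,
                "mean_depth": float(d.mean()),
                "se_depth": se,
                "n_individuals": len(d),
            }
        )
    return pd.DataFrame(rows)
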