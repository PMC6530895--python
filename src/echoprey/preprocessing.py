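"""Analysis-domain definition and range-dependent background-noise removal.

School detection must only see the usable water column: the acoustic
near-field above 3 m is excluded, the seafloor and everything below it
is excluded via a per-ping bottom line (with a small "backstep" above
the pick to clear side-lobe smear), and background noise — whose level
rises with range once TVG has been applied — is estimated and subtracted
in the linear domain, with low-SNR samples set to a floor sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._utils import FLOOR_DB, db_to_linear, linear_to_db
from .calibration import TVGFit, tvg_curve

__all__ = [
    "AnalysisDomain",
    "detect_bottom",
    "build_analysis_domain",
    "remove_background_noise",
    "NEARFIELD_DEPTH_M",
]

#: Fixed exclusion line for the transducer near-field (m).
NEARFIELD_DEPTH_M = 3.0


@dataclass
class AnalysisDomain:
    """Boolean mask of the usable water column, aligned to an echogram."""

    nearfield_depth_m: float
    bottom_line_m: np.ndarray  # per-ping seabed depth
    backstep_m: float
    mask: np.ndarray  # (n_pings, n_bins), True where usable

    def __post_init__(self):
        self.bottom_line_m = np.asarray(self.bottom_line_m, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape[0] != self.bottom_line_m.size:
            raise ValueError("mask and bottom line disagree on ping count")


def detect_bottom(echogram, min_bottom_depth_m=5.0, bottom_threshold_db=10.0,
                  median_window=9):
    """Pick the seabed line on a TVG-corrected echogram.

    Per ping the candidate is the shallowest local intensity maximum
    deeper than ``min_bottom_depth_m`` that lies within
    ``bottom_threshold_db`` of that ping's maximum intensity — a
    relative threshold, so the pick is invariant to the unknown constant
    offset of an uncalibrated system.  The default window (10 dB) sits
    above the intensity of any plausible prey school, which keeps
    strong mid-water schools from being mistaken for the seabed.  A cross-ping median filter
    (window ``median_window``) enforces continuity, and pings without a
    candidate inherit the interpolated line.  More than 50% of pings
    without candidates makes the transect unusable.
    """
    z = echogram.depth_axis
    picks = np.full(echogram.n_pings, np.nan)
    deep = z > min_bottom_depth_m
    if not deep.any():
        raise ValueError("echogram does not extend below min_bottom_depth")
    for p in range(echogram.n_pings):
        col = echogram.intensity[p]
        valid = col > FLOOR_DB
        if not valid.any():
            continue
        thr = col[valid].max() - bottom_threshold_db
        # a bottom echo must also stand out of the water-column background
        prominence = np.median(col[valid]) + 5.0
        left = np.r_[-np.inf, col[:-1]]
        right = np.r_[col[1:], -np.inf]
        is_peak = ((col >= left) & (col >= right) & (col >= thr)
                   & (col >= prominence) & deep & valid)
        idx = np.flatnonzero(is_peak)
        if idx.size:
            peak = idx[0]
            # walk up to the leading edge of the bottom echo: the pick is
            # where the seabed return starts, not the plateau maximum
            edge = peak
            while edge > 0 and col[edge - 1] >= col[peak] - 3.0:
                edge -= 1
            picks[p] = z[edge]
    bad = np.isnan(picks)
    if bad.mean() > 0.5:
        raise ValueError(
            f"bottom not detectable on {bad.mean():.0%} of pings: "
            "unusable transect")
    if bad.any():
        good = np.flatnonzero(~bad)
        picks = np.interp(np.arange(picks.size), good, picks[good])
    smoothed = ndimage.median_filter(picks, size=median_window,
                                     mode="nearest")
    return np.minimum(smoothed, float(z[-1]))


def build_analysis_domain(echogram, bottom_line_m, backstep_m=0.3,
                          nearfield_depth_m=NEARFIELD_DEPTH_M):
    """Mask the water column between the near-field line and the seabed.

    A sample at depth z on ping p is usable iff
    ``nearfield_depth < z < bottom_line[p] - backstep``.
    """
    if backstep_m < 0:
        raise ValueError("backstep must be non-negative")
    bottom = np.broadcast_to(np.asarray(bottom_line_m, dtype=float),
                             (echogram.n_pings,)).copy()
    z = echogram.depth_axis[None, :]
    upper = bottom[:, None] - backstep_m
    mask = (z > nearfield_depth_m) & (z < upper)
    if not mask.any():
        warnings.warn("analysis domain is empty (seabed shallower than the "
                      "near-field line plus backstep)")
    return AnalysisDomain(nearfield_depth_m, bottom, backstep_m, mask)


def remove_background_noise(echogram, fit: TVGFit, cell_pings=20, cell_bins=5,
                            max_snr_loss_db=3.0):
    """Estimate and subtract range-dependent background noise.

    Follows the standard minimum-cell estimator: the echogram is tiled
    into averaging cells (``cell_pings`` x ``cell_bins``); each cell's
    linear-mean intensity minus the TVG gain at its centre depth is a
    candidate for the noise level at source, and the minimum over cells
    is taken.  The implied per-sample noise (estimate + TVG at sample
    depth) is subtracted in the linear domain; samples whose
    signal-to-noise ratio falls below ``max_snr_loss_db`` are set to the
    floor sentinel and excluded from later means.
    """
    if cell_pings > echogram.n_pings or cell_bins > echogram.n_bins:
        raise ValueError("averaging cell larger than echogram")
    out = echogram.copy()
    z = out.depth_axis
    valid_z = z > 0
    gain = np.full(z.size, np.nan)
    gain[valid_z] = tvg_curve(z[valid_z], fit.xi_selected, fit.alpha_db_per_m)

    # Floor-sentinel samples carry no retained signal: they contribute
    # zero linear power, so a fully-floored cell drives the estimate to
    # -inf and a second pass over already-cleaned data is a no-op —
    # noise removal is idempotent.
    lin = db_to_linear(out.intensity)
    lin[out.intensity <= FLOOR_DB] = 0.0
    noise_at_source = np.inf
    for p0 in range(0, echogram.n_pings, cell_pings):
        for b0 in range(0, echogram.n_bins, cell_bins):
            zc = z[b0:min(b0 + cell_bins, z.size)]
            keep = zc > 0
            if not keep.any():
                continue
            cell_mean = float(np.mean(lin[p0:p0 + cell_pings,
                                          b0:b0 + cell_bins]))
            if cell_mean == 0.0:
                noise_at_source = -np.inf
                break
            g_center = float(np.interp(np.mean(zc[keep]), z[valid_z],
                                       gain[valid_z]))
            noise_at_source = min(noise_at_source,
                                  linear_to_db(cell_mean) - g_center)
        if noise_at_source == -np.inf:
            break
    if noise_at_source == np.inf:
        raise ValueError("no usable samples for noise estimation")

    out.meta = dict(out.meta)
    if noise_at_source == -np.inf:
        out.meta["noise_at_source_db"] = -np.inf
        return out

    noise_db = np.full(z.size, -np.inf)
    noise_db[valid_z] = noise_at_source + gain[valid_z]
    noise_lin = db_to_linear(noise_db)
    sig_lin = db_to_linear(out.intensity)
    clean_lin = sig_lin - noise_lin[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        clean_db = np.where(clean_lin > 0, 10.0 * np.log10(clean_lin),
                            FLOOR_DB)
    snr = clean_db - noise_db[None, :]
    floored = (clean_lin <= 0) | (snr < max_snr_loss_db)
    floored |= out.intensity <= FLOOR_DB
    out.intensity = np.where(floored, FLOOR_DB, clean_db)
    out.meta["noise_at_source_db"] = float(noise_at_source)
    return out
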