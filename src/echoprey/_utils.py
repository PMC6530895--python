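"""Shared numeric helpers: dB/linear conversion and geodesic distance."""

from __future__ import annotations

import numpy as np

#: Sentinel for samples removed by background-noise filtering.  Excluded
#: from every linear-domain mean in the pipeline.
FLOOR_DB = -999.0

#: IUGG mean Earth radius, metres.
EARTH_RADIUS_M = 6_371_008.8


def db_to_linear(db):
    """Relative dB -> linear power units (10^(dB/10))."""
    return np.power(10.0, np.asarray(db, dtype=float) / 10.0)


def linear_to_db(lin):
    """Linear power -> relative dB.  Non-positive input maps to the floor."""
    lin = np.asarray(lin, dtype=float)
    out = np.full(lin.shape, FLOOR_DB)
    pos = lin > 0
    out[pos] = 10.0 * np.log10(lin[pos])
    if out.ndim == 0:
        return float(out)
    return out


def linear_mean_db(db_values):
    """Mean of dB values taken in the linear (power) domain, in dB.

    Floor-sentinel samples are excluded; if every sample is at the floor
    the floor is returned.
    """
    db_values = np.asarray(db_values, dtype=float)
    keep = db_values > FLOOR_DB
    if not keep.any():
        return FLOOR_DB
    return float(linear_to_db(db_to_linear(db_values[keep]).mean()))


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between coordinate pairs (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(h))
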