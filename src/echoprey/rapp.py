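"""Relative-abundance-of-potential-prey (RAPP) metrics.

Without calibration the echosounder cannot yield density or biomass, so
prey availability per survey is summarised purely from corrected school
dimensions:

* ``c.SchA`` — cumulative school area: the sum of corrected school
  areas Ac over a survey, standardised by survey distance (m^2/km).
* ``Prop.Track`` — the proportion of the survey track over which
  schools were detected: the union of the schools' corrected
  along-track intervals divided by survey distance (dimensionless,
  always <= 1; overlapping schools are not double counted).

Only schools with valid (positive) corrected dimensions contribute;
invalid schools are reported in a diagnostics count.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RAPPSummary",
    "cumulative_school_area",
    "prop_track",
    "summarize_survey",
    "season_of",
]


@dataclass
class RAPPSummary:
    """Per-survey prey-availability snapshot."""

    survey_id: str
    region: str
    season: str
    survey_distance_km: float
    c_scha_m2_per_km: float
    prop_track: float
    n_schools: int
    n_invalid: int = 0

    def __post_init__(self):
        if self.survey_distance_km <= 0:
            raise ValueError("survey distance must be positive")
        if self.c_scha_m2_per_km < 0 or not (0 <= self.prop_track <= 1):
            raise ValueError("RAPP metrics out of range")


def _valid(schools):
    return [s for s in schools if s.valid]


def cumulative_school_area(schools, distance_km, use_corrected=True):
    """Sum of (corrected) school areas per km of track (m^2/km)."""
    if distance_km <= 0:
        raise ValueError("survey distance must be positive")
    vs = _valid(schools)
    if use_corrected:
        total = sum(s.corrected_area_m2 for s in vs)
    else:
        total = sum(s.area_m2 for s in vs)
    return float(total) / distance_km


def _union_length(intervals):
    """Total length of the union of (start, end) intervals."""
    ivs = sorted((lo, hi) for lo, hi in intervals if hi > lo)
    total = 0.0
    cur_lo = cur_hi = None
    for lo, hi in ivs:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total


def prop_track(schools, distance_m, merge_overlaps=True):
    """Fraction of the survey track over which schools were detected.

    Each valid school occupies a corrected along-track interval of
    length Lc centred on its detected position.  With
    ``merge_overlaps`` (default) overlapping intervals are merged before
    summation so the result is a true proportion <= 1; without it the
    plain sum of Lc is used.
    """
    if distance_m <= 0:
        raise ValueError("survey distance must be positive")
    vs = _valid(schools)
    intervals = []
    for s in vs:
        lo, hi = s.along_track_span_m
        if np.isnan(lo):
            mid = 0.0
        else:
            mid = 0.5 * (lo + hi)
        half = s.corrected_length_m / 2.0
        intervals.append((mid - half, mid + half))
    if merge_overlaps:
        covered = _union_length(intervals)
    else:
        covered = sum(hi - lo for lo, hi in intervals)
    return min(covered / distance_m, 1.0) if merge_overlaps else covered / distance_m


def season_of(date) -> str:
    """Survey season: Jan-Mar is summer, Aug-Oct is winter, else other."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if date.month in (1, 2, 3):
        return "summer"
    if date.month in (8, 9, 10):
        return "winter"
    warnings.warn(f"survey date {date} outside both season windows")
    return "other"


def summarize_survey(schools, survey_id, region, survey_distance_km,
                     date=None, season=None, use_corrected=True,
                     merge_overlaps=True):
    """Compute both RAPP metrics for one survey."""
    if season is None:
        season = season_of(date) if date is not None else "other"
    vs = _valid(schools)
    return RAPPSummary(
        survey_id=survey_id,
        region=region,
        season=season,
        survey_distance_km=survey_distance_km,
        c_scha_m2_per_km=cumulative_school_area(
            schools, survey_distance_km, use_corrected=use_corrected),
        prop_track=prop_track(schools, survey_distance_km * 1000.0,
                              merge_overlaps=merge_overlaps),
        n_schools=len(vs),
        n_invalid=len(schools) - len(vs),
    )
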