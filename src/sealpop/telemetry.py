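"""Seasonal movement and haulout analysis of satellite-tagged seals.

Positions are quality-filtered with the plausible-swim-speed rule
(implied speed between consecutive fixes must not exceed 2 m/s), then
summarized as distance from the animal's breeding/capture site. The
year splits into an ice-bound season (December–May, maximal ice extent)
and an open-water season (June–November); a permutation t-test compares
mean distance from the breeding site between the two. Hourly wet/dry
sensor data yield a circadian haulout summary: for each hour of day, the
proportion of days whose dry time exceeded that day's mid-range.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .datatypes import PermutationTestResult, TelemetryRecord, TelemetryTrack, permutation_p

EARTH_RADIUS_KM = 6371.0088
ICE_BOUND_MONTHS = frozenset({12, 1, 2, 3, 4, 5})


def great_circle_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    lat1, lon1, lat2, lon2 = map(np.radians, (*p1, *p2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def season_of(timestamp: datetime) -> str:
    """'ice_bound' for December–May, 'open_water' for June–November."""
    return "ice_bound" if timestamp.month in ICE_BOUND_MONTHS else "open_water"


# ---------------------------------------------------------------------------
# Speed filter


def _implied_speeds(records: list[TelemetryRecord]) -> np.ndarray:
    """m/s between consecutive records."""
    out = np.empty(max(len(records) - 1, 0))
    for i in range(len(records) - 1):
        a, b = records[i], records[i + 1]
        km = great_circle_km((a.lat, a.lon), (b.lat, b.lon))
        dt = (b.timestamp - a.timestamp).total_seconds()
        out[i] = np.inf if dt <= 0 else km * 1000.0 / dt
    return out


def speed_filter(track: TelemetryTrack, v_max: float = 2.0) -> TelemetryTrack:
    """Remove positions that imply swimming faster than ``v_max`` m/s.

    Greedy iterative removal: while any consecutive pair exceeds the
    limit, drop the single point whose removal most reduces the number of
    violating pairs (ties broken toward the point with the larger maximum
    adjacent implied speed, then the later timestamp). Recomputing speeds
    after each removal prevents stranded violations; the result satisfies
    the constraint exactly and the filter is idempotent on its own output.
    The removal log is recorded on the returned track.
    """
    if track.n_records < 2:
        return track
    records = list(track.records)
    log = list(track.filter_log)

    while True:
        speeds = _implied_speeds(records)
        violating = np.flatnonzero(speeds > v_max)
        if violating.size == 0:
            break
        # candidates: endpoints of violating pairs
        candidates = sorted({int(i) for v in violating for i in (v, v + 1)})
        best = None
        for i in candidates:
            trial = records[:i] + records[i + 1:]
            n_viol = int(np.sum(_implied_speeds(trial) > v_max))
            adj = [speeds[j] for j in (i - 1, i) if 0 <= j < len(speeds)]
            key = (n_viol, -max(adj), -records[i].timestamp.timestamp())
            if best is None or key < best[0]:
                best = (key, i)
        i = best[1]
        log.append(f"removed {records[i].timestamp.isoformat()} "
                   f"({records[i].lat:.4f}, {records[i].lon:.4f}): "
                   f"max adjacent speed {-best[0][1]:.2f} m/s")
        del records[i]
        if not records:
            raise ValueError(
                f"track {track.animal_id!r}: speed filter removed every point")
    return TelemetryTrack(animal_id=track.animal_id,
                          capture_site=track.capture_site, records=records,
                          sex=track.sex, age=track.age, filter_log=log)


# ---------------------------------------------------------------------------
# Seasonal distance comparison


@dataclass
class SeasonalComparison:
    """Per-season distance-from-breeding-site summary with permutation p."""

    animal_id: str
    mean_ice_bound: float | None
    max_ice_bound: float | None
    n_ice_bound: int
    mean_open_water: float | None
    max_open_water: float | None
    n_open_water: int
    p_value: float | None
    n_perm: int
    seed: int | None


def distances_from_capture(track: TelemetryTrack) -> np.ndarray:
    return np.array([great_circle_km(track.capture_site, (r.lat, r.lon))
                     for r in track.records])


def seasonal_distance_test(track: TelemetryTrack, n_perm: int = 10000,
                           seed: int = 0) -> SeasonalComparison:
    """Permutation t-test of seasonal difference in mean distance.

    The statistic is |mean(open-water) − mean(ice-bound)| distance from
    the breeding site; the null permutes season labels over the track's
    observations at the observed per-season counts. Two-sided p with the
    (1 + b)/(1 + n_perm) rule; NA when either season has no data (means
    and maxima are still reported for the observed season).
    """
    dists = distances_from_capture(track)
    ice = np.array([season_of(r.timestamp) == "ice_bound"
                    for r in track.records])
    d_ice, d_open = dists[ice], dists[~ice]

    def stats(d: np.ndarray) -> tuple[float | None, float | None]:
        if len(d) == 0:
            return None, None
        return float(d.mean()), float(d.max())

    mean_i, max_i = stats(d_ice)
    mean_o, max_o = stats(d_open)
    p_value = None
    if len(d_ice) > 0 and len(d_open) > 0:
        obs = abs(mean_o - mean_i)
        rng = np.random.default_rng(seed)
        n_i = len(d_ice)
        b = 0
        for _ in range(n_perm):
            perm = rng.permutation(dists)
            if abs(perm[n_i:].mean() - perm[:n_i].mean()) >= obs - 1e-12:
                b += 1
        p_value = permutation_p(b, n_perm)
    return SeasonalComparison(
        animal_id=track.animal_id,
        mean_ice_bound=mean_i, max_ice_bound=max_i, n_ice_bound=int(ice.sum()),
        mean_open_water=mean_o, max_open_water=max_o,
        n_open_water=int((~ice).sum()),
        p_value=p_value, n_perm=n_perm if p_value is not None else 0,
        seed=seed)


def seasonal_table(tracks: list[TelemetryTrack], n_perm: int = 10000,
                   seed: int = 0) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(tracks):
        r = seasonal_distance_test(t, n_perm=n_perm, seed=seed + i)
        rows.append(vars(r))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Haulout circadian summary


@dataclass
class HauloutSummary:
    """Circadian haulout structure from an hourly dry-fraction series."""

    animal_id: str
    n_days: int
    hours: list[int]
    mean_dry: list[float]           # per hour of day, over complete days
    range_dry: list[float]          # max - min per hour of day
    exceedance: list[float]         # P(day's value > day's mid-range)
    longest_wet_bout_hours: int
    min_dry_minutes: float


def haulout_summary(series: pd.Series, animal_id: str | None = None,
                    min_hours_per_day: int = 20) -> HauloutSummary:
    """Summarize circadian haulout from an hourly dry-fraction series.

    Days with fewer than ``min_hours_per_day`` of the 24 hourly values
    are excluded (gaps are left missing, not imputed). For each retained
    day the mid-range is (min + max)/2; the per-hour-of-day exceedance is
    the fraction of days whose value at that hour strictly exceeds the
    day's mid-range — a constant day therefore never exceeds. Also
    reported: the longest run of consecutive observed hours that are
    fully wet (dry fraction exactly 0) and the minimum dry minutes in any
    hour.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must be indexed by timestamps")
    series = series.dropna().sort_index()
    days = series.groupby(series.index.date)
    complete = [d for d, grp in days if len(grp) >= min_hours_per_day]
    if not complete:
        raise ValueError("no complete day (need >= "
                         f"{min_hours_per_day} hourly values)")
    kept = series[np.isin(series.index.date, complete)]
    frame = pd.DataFrame({"value": kept.to_numpy()},
                         index=kept.index)
    frame["day"] = kept.index.date
    frame["hour"] = kept.index.hour
    midrange = frame.groupby("day")["value"].agg(
        lambda v: (v.min() + v.max()) / 2)
    frame["exceeds"] = frame["value"] > frame["day"].map(midrange)

    by_hour = frame.groupby("hour")
    hours = sorted(by_hour.groups)
    mean_dry = [float(by_hour.get_group(h)["value"].mean()) for h in hours]
    range_dry = [float(by_hour.get_group(h)["value"].max()
                       - by_hour.get_group(h)["value"].min()) for h in hours]
    exceedance = [float(by_hour.get_group(h)["exceeds"].mean()) for h in hours]

    # longest fully-wet bout over consecutive observed hours
    values = kept.to_numpy()
    times = kept.index
    longest = run = 0
    for i, v in enumerate(values):
        contiguous = i > 0 and (times[i] - times[i - 1]) == pd.Timedelta(hours=1)
        run = (run if contiguous else 0) + 1 if v == 0 else 0
        longest = max(longest, run)
    return HauloutSummary(
        animal_id=animal_id or str(series.name or "unknown"),
        n_days=len(complete), hours=hours, mean_dry=mean_dry,
        range_dry=range_dry, exceedance=exceedance,
        longest_wet_bout_hours=longest,
        min_dry_minutes=float(values.min() * 60.0))


# ---------------------------------------------------------------------------
# Monthly localization


def monthly_localization(tracks: list[TelemetryTrack]) -> pd.DataFrame:
    """Per-animal, per-calendar-month mean distance from the capture site.

    Months with no observations for an animal are simply absent from the
    table (one row per animal x observed month).
    """
    rows = []
    for t in tracks:
        dists = distances_from_capture(t)
        months = np.array([r.timestamp.month for r in t.records])
        for m in sorted(set(months)):
            sel = months == m
            rows.append({"animal_id": t.animal_id, "month": int(m),
                         "mean_distance_km": float(dists[sel].mean()),
                         "n_obs": int(sel.sum()),
                         "season": ("ice_bound" if m in ICE_BOUND_MONTHS
                                    else "open_water")})
    return pd.DataFrame(rows)
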