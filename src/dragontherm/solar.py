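"""Sunrise/sunset from standard solar-position geometry.

Implements the NOAA solar-calculator equations (Fourier expansions of the
equation of time and solar declination in the fractional year) with the
conventional sunrise/sunset zenith of 90.833°, i.e. solar elevation −0.833°,
which folds in atmospheric refraction and the solar radius.  Accuracy is a
minute or two against the NOAA reference calculator for mid latitudes, which
is ample for windowing 10-min telemetry slots to daylight.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

from .config import SiteGeo

__all__ = ["DaylightWindow", "sunrise_sunset_utc", "daylight_window", "day_length_hours"]

_ZENITH_DEG = 90.833


@dataclass(frozen=True)
class DaylightWindow:
    """Daylight bounds for one site-local date.

    ``sunrise``/``sunset`` are naive UTC instants (the pipeline's internal
    convention); ``date`` is the site-local calendar date they belong to.
    """

    date: dt.date
    sunrise: dt.datetime
    sunset: dt.datetime

    def __post_init__(self) -> None:
        if self.sunrise >= self.sunset:
            raise ValueError("sunrise must precede sunset")

    @property
    def length_hours(self) -> float:
        return (self.sunset - self.sunrise).total_seconds() / 3600.0


def _solar_geometry(date: dt.date) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians) at local noon."""
    doy = date.timetuple().tm_yday
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + 0.5)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    return eqtime, decl


def _hour_angle_deg(latitude: float, decl: float) -> float:
    lat = math.radians(latitude)
    cos_ha = math.cos(math.radians(_ZENITH_DEG)) / (
        math.cos(lat) * math.cos(decl)
    ) - math.tan(lat) * math.tan(decl)
    if not -1.0 < cos_ha < 1.0:
        raise ValueError(
            "sun never rises/sets on this date at this latitude (polar regime)"
        )
    return math.degrees(math.acos(cos_ha))


def sunrise_sunset_utc(
    latitude: float, longitude: float, date: dt.date
) -> tuple[dt.datetime, dt.datetime]:
    """UTC sunrise and sunset for the given local calendar date.

    Longitude is east-positive; latitudes poleward of the polar circles are
    rejected (perpetual day/night days are outside this routine's scope).
    """
    if abs(latitude) >= 66.5:
        raise ValueError("polar latitudes (|lat| >= 66.5°) unsupported")
    eqtime, decl = _solar_geometry(date)
    ha = _hour_angle_deg(latitude, decl)
    midnight = dt.datetime.combine(date, dt.time())
    sunrise = midnight + dt.timedelta(minutes=720.0 - 4.0 * (longitude + ha) - eqtime)
    sunset = midnight + dt.timedelta(minutes=720.0 - 4.0 * (longitude - ha) - eqtime)
    return sunrise, sunset


def daylight_window(site: SiteGeo, date: dt.date) -> DaylightWindow:
    """Daylight window for a site-local date, with UTC sunrise/sunset.

    The UTC times are computed for the local date shifted by the configured
    offset, so a +11 h site's 21 Dec window starts late on 20 Dec UTC.
    """
    sunrise_utc, sunset_utc = sunrise_sunset_utc(site.latitude, site.longitude, date)
    # sunrise_sunset_utc anchors on the date's own UTC midnight; for eastern
    # longitudes the local date's daylight falls mostly on the previous UTC
    # day, which the longitude term already handles — no further shift needed.
    return DaylightWindow(date=date, sunrise=sunrise_utc, sunset=sunset_utc)


def day_length_hours(latitude: float, date: dt.date) -> float:
    """Sunrise-to-sunset duration in hours (longitude-independent)."""
    _, decl = _solar_geometry(date)
    return 8.0 * _hour_angle_deg(latitude, decl) / 60.0
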