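"""Atmospheric Δ¹⁴C forcing curves.

The single-pool turnover model is driven by a time series of atmospheric
radiocarbon content (Δ¹⁴C, per mil relative to the 1950 oxalic-acid
standard).  Published compilations (e.g. the Northern-Hemisphere zone-2
record) are distributed as two- or three-column delimited text; this module
reads them, interpolates them onto the model's monthly grid, extrapolates
past their end when the sampling year lies beyond the compilation, and can
generate a deterministic synthetic bomb-spike curve for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtmosphericCurve",
    "CurveParseError",
    "read_curve",
    "synth_bomb_curve",
]

#: Δ¹⁴C floor used when extrapolating: −1000‰ is radiocarbon-dead carbon.
DELTA_FLOOR = -1000.0


class CurveParseError(ValueError):
    """Raised when a curve file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class AtmosphericCurve:
    """Atmospheric Δ¹⁴C record on a strictly increasing decimal-year grid.

    Parameters
    ----------
    years
        Decimal calendar years CE, strictly increasing, length ≥ 2.
    delta14c
        Δ¹⁴C in per mil at each year.
    sigma
        Optional 1σ analytical uncertainty in per mil.
    """

    years: np.ndarray
    delta14c: np.ndarray
    sigma: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        delta = np.asarray(self.delta14c, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "delta14c", delta)
        if self.sigma is not None:
            object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if years.ndim != 1 or years.size < 2:
            raise CurveParseError("curve needs at least 2 (year, Δ14C) points")
        if delta.shape != years.shape:
            raise CurveParseError("years and delta14c must have the same length")
        if self.sigma is not None and self.sigma.shape != years.shape:
            raise CurveParseError("sigma must have the same length as years")
        if not np.all(np.diff(years) > 0):
            raise CurveParseError("years must be strictly increasing (no duplicates)")
        if not (np.all(np.isfinite(years)) and np.all(np.isfinite(delta))):
            raise CurveParseError("curve contains non-finite values")

    def __len__(self) -> int:
        return int(self.years.size)

    @property
    def start(self) -> float:
        return float(self.years[0])

    @property
    def end(self) -> float:
        return float(self.years[-1])

    def value_at(self, t) -> float | np.ndarray:
        """Δ¹⁴C at decimal year(s) ``t``.

        Linear interpolation inside the record's span.  Past the last knot
        the last segment is extended linearly (with a warning, floored at
        −1000‰); before the first knot is an error because model spin-up
        must start inside the record.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.years[0]):
            raise ValueError(
                f"year {float(np.min(t_arr)):.2f} precedes curve start "
                f"{self.years[0]:.2f}; spin-up must start inside the curve"
            )
        out = np.interp(t_arr, self.years, self.delta14c)
        beyond = t_arr > self.years[-1]
        if np.any(beyond):
            warnings.warn(
                f"extrapolating atmospheric Δ14C past curve end "
                f"({self.years[-1]:.2f}) from the last two knots",
                stacklevel=2,
            )
            slope = (self.delta14c[-1] - self.delta14c[-2]) / (
                self.years[-1] - self.years[-2]
            )
            extr = self.delta14c[-1] + slope * (t_arr - self.years[-1])
            out = np.where(beyond, np.maximum(extr, DELTA_FLOOR), out)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def value_at(curve: AtmosphericCurve, t) -> float | np.ndarray:
    """Functional alias for :meth:`AtmosphericCurve.value_at`."""
    return curve.value_at(t)


def read_curve(path) -> AtmosphericCurve:
    """Read an atmospheric Δ¹⁴C curve from delimited text.

    Accepts whitespace- or comma-delimited rows of ``year  delta14c [sigma]``;
    lines starting with ``#`` are comments.  Rows are sorted by year;
    duplicate years are rejected.
    """
    years: list[float] = []
    deltas: list[float] = []
    sigmas: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (2, 3):
                raise CurveParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise CurveParseError(f"{path}:{lineno}: non-numeric field") from exc
            years.append(vals[0])
            deltas.append(vals[1])
            if len(vals) == 3:
                sigmas.append(vals[2])
    if len(years) < 2:
        raise CurveParseError(f"{path}: fewer than 2 data rows")
    if sigmas and len(sigmas) != len(years):
        raise CurveParseError(f"{path}: sigma column present on only some rows")
    order = np.argsort(years, kind="stable")
    yr = np.asarray(years)[order]
    if np.any(np.diff(yr) == 0):
        dup = yr[np.where(np.diff(yr) == 0)[0][0]]
        raise CurveParseError(f"{path}: duplicate year {dup}")
    return AtmosphericCurve(
        years=yr,
        delta14c=np.asarray(deltas)[order],
        sigma=np.asarray(sigmas)[order] if sigmas else None,
    )


def write_curve(curve: AtmosphericCurve, path) -> None:
    """Write a curve back out as '# year delta14c [sigma]' delimited text."""
    with open(path, "w") as fh:
        fh.write("# year delta14c" + (" sigma" if curve.sigma is not None else "") + "\n")
        for i in range(len(curve)):
            row = f"{curve.years[i]:.6f} {curve.delta14c[i]:.6f}"
            if curve.sigma is not None:
                row += f" {curve.sigma[i]:.6f}"
            fh.write(row + "\n")


def synth_bomb_curve(
    peak_year: float = 1964.5,
    peak_delta: float = 1000.0,
    decay_rate: float = 0.06,
    start_year: float = 1900.0,
    end_year: float = 2015.0,
    step: float = 1.0 / 12.0,
    ramp_start: float = 1955.0,
) -> AtmosphericCurve:
    """Deterministic synthetic bomb-spike Δ¹⁴C curve.

    Shape: 0‰ before ``ramp_start`` (pre-bomb atmosphere), linear ramp up to
    ``peak_delta`` at ``peak_year``, then exponential relaxation
    ``peak_delta · exp(−decay_rate · (t − peak_year))``.  A stand-in for the
    published compilation with the same qualitative geometry (flat pre-bomb
    era, sharp mid-1960s peak, slow decline).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not (start_year < peak_year < end_year):
        raise ValueError("need start_year < peak_year < end_year")
    if peak_delta <= 0:
        raise ValueError("peak_delta must be positive")
    n = int(np.floor((end_year - start_year) / step)) + 1
    years = start_year + step * np.arange(n)
    # include the peak year exactly so value_at(peak_year) == peak_delta
    if not np.any(np.isclose(years, peak_year)):
        years = np.sort(np.append(years, peak_year))
    delta = np.zeros_like(years)
    ramp = (years > ramp_start) & (years <= peak_year)
    delta[ramp] = peak_delta * (years[ramp] - ramp_start) / (peak_year - ramp_start)
    post = years > peak_year
    delta[post] = peak_delta * np.exp(-decay_rate * (years[post] - peak_year))
    return AtmosphericCurve(years=years, delta14c=delta)
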