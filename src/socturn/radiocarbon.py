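"""Radiocarbon unit algebra.

Δ¹⁴C (per mil) ↔ absolute fraction modern conversion, decay correction of
standards from 1950 to the sampling year, and constant-contamination blank
correction with first-order (linearised) uncertainty propagation — the
bookkeeping that turns raw AMS output into model-ready numbers.

All model arithmetic elsewhere in the package runs in absolute
(sampling-year) fraction modern; Δ¹⁴C appears only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GODWIN_MEAN_LIFE",
    "LAMBDA_14C",
    "RadiocarbonMeasurement",
    "BlankModel",
    "delta_to_fm",
    "fm_to_delta",
    "decay_correct_to_year",
    "blank_correct",
]

#: Godwin mean life of ¹⁴C in years (based on the 5568 yr Libby half-life
#: convention used in radiocarbon reporting).
GODWIN_MEAN_LIFE = 8267.0

#: Radiocarbon decay constant λ = 1/8267 ≈ 1.21e-4 yr⁻¹.
LAMBDA_14C = 1.0 / GODWIN_MEAN_LIFE


def delta_to_fm(delta14c):
    """Convert Δ¹⁴C (per mil) to absolute fraction modern: F = Δ/1000 + 1."""
    d = np.asarray(delta14c, dtype=float)
    if np.any(d <= -1000.0):
        raise ValueError("Δ14C must exceed −1000‰ (fraction modern > 0)")
    out = d / 1000.0 + 1.0
    return float(out) if out.ndim == 0 else out


def fm_to_delta(fm):
    """Inverse of :func:`delta_to_fm`: Δ = 1000·(F − 1)."""
    f = np.asarray(fm, dtype=float)
    if np.any(f <= 0):
        raise ValueError("fraction modern must be positive")
    out = 1000.0 * (f - 1.0)
    return float(out) if out.ndim == 0 else out


def decay_correct_to_year(fm_1950, year, lam: float = LAMBDA_14C):
    """Decay-correct a 1950-referenced fraction modern to ``year``.

    Standards (OX-I/OX-II) are defined at 1950; by a sampling year y they
    have decayed by exp(−λ·(y − 1950)).
    """
    y = np.asarray(year, dtype=float)
    if np.any(y < 1950.0):
        raise ValueError("year must be ≥ 1950")
    out = np.asarray(fm_1950, dtype=float) * np.exp(-lam * (y - 1950.0))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RadiocarbonMeasurement:
    """One Δ¹⁴C determination: value, 1σ, sampling year, optional C mass (mg)."""

    delta14c: float
    sigma: float = 0.0
    sampling_year: float = 2014.5
    mass_c: float | None = None

    def __post_init__(self) -> None:
        if self.delta14c <= -1000.0:
            raise ValueError("Δ14C must exceed −1000‰")
        if self.sigma < 0:
            raise ValueError("sigma must be ≥ 0")

    @property
    def fm(self) -> float:
        """Absolute fraction modern."""
        return delta_to_fm(self.delta14c)


@dataclass(frozen=True)
class BlankModel:
    """Constant-contamination blank: every sample carries a fixed mass
    ``m_contaminant`` (mg C) of carbon with fraction modern ``f_contaminant``.
    """

    f_contaminant: float = 0.5
    m_contaminant: float = 0.001
    sigma_f: float = 0.0
    sigma_m: float = 0.0

    def __post_init__(self) -> None:
        if self.f_contaminant < 0:
            raise ValueError("contaminant fraction modern must be ≥ 0")
        if self.m_contaminant < 0:
            raise ValueError("contaminant mass must be ≥ 0")


def contaminate(f_true: float, m_true: float, blank: BlankModel) -> tuple[float, float]:
    """Forward mixing: add the blank to a clean sample.

    Returns the measured (fraction modern, total mass) a detector would see.
    Inverse of :func:`blank_correct`; used to build synthetic test cases.
    """
    m_meas = m_true + blank.m_contaminant
    f_meas = (f_true * m_true + blank.f_contaminant * blank.m_contaminant) / m_meas
    return f_meas, m_meas


def blank_correct(
    measured: RadiocarbonMeasurement, blank: BlankModel
) -> RadiocarbonMeasurement:
    """Remove a constant-contamination blank by isotope mass balance.

    F_s = (F_m·m_m − F_c·m_c) / (m_m − m_c), with the 1σ propagated to the
    corrected value by first-order error propagation over the measured
    fraction modern, the contaminant fraction modern, and the contaminant
    mass (the measured mass is treated as exact — it is a weighed quantity
    whose error is negligible next to the others).
    """
    if measured.mass_c is None:
        raise ValueError("blank correction needs the sample carbon mass (mass_c)")
    m_m = measured.mass_c
    m_c = blank.m_contaminant
    if m_m <= m_c:
        raise ValueError(
            f"sample mass {m_m} mg is not larger than contaminant mass {m_c} mg"
        )
    f_m = measured.fm
    f_c = blank.f_contaminant
    denom = m_m - m_c
    f_s = (f_m * m_m - f_c * m_c) / denom

    # partial derivatives of f_s
    d_fm = m_m / denom
    d_fc = -m_c / denom
    d_mc = (f_s - f_c) / denom  # from quotient rule at fixed f_m, f_c, m_m
    sigma_fm = measured.sigma / 1000.0  # per-mil → fraction-modern units
    var = (d_fm * sigma_fm) ** 2 + (d_fc * blank.sigma_f) ** 2 + (
        d_mc * blank.sigma_m
    ) ** 2
    sigma_out = 1000.0 * float(np.sqrt(var))
    return replace(
        measured,
        delta14c=fm_to_delta(f_s),
        sigma=sigma_out,
        mass_c=denom,
    )
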