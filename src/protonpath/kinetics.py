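"""Proteoliposome proton-transport kinetics from optical probes.

Pyranine (HPTS) is ratiometric: with R = I460/I405, the lumen pH follows
pH = a·log10(R) + b, with (a, b) from a calibration fit.  ΔpH for an
ATP-driven pumping assay is the difference between the baseline pH
(average before ATP addition) and the plateau of a single-exponential
fit to the post-addition decay.

Oxonol VI reports the membrane potential: Δψ is linear in the
differential absorbance ΔA = A588 − A625, calibrated against
valinomycin/K⁺ diffusion potentials set by the Nernst equation.  Initial
Δψ rates (linear fit over the first second) are converted to a
per-liposome proton flux through the membrane capacitance:
flux = C_m·(π d²)·(dΨ/dt)/e.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import AssayTrace, LiposomeSpec

__all__ = [
    "PyranineCalibration",
    "PsiCalibration",
    "KineticsResult",
    "fit_ph_calibration",
    "ph_trace",
    "extract_delta_ph",
    "nernst_potential",
    "fit_psi_calibration",
    "psi_trace",
    "initial_rate",
    "proton_flux",
]

GAS_CONSTANT = 8.31446261815324  # J mol⁻¹ K⁻¹
FARADAY = 96485.33212331  # C mol⁻¹
ELEMENTARY_CHARGE = 1.602176634e-19  # C


@dataclass
class PyranineCalibration:
    """pH = a·log10(I460/I405) + b."""

    a: float
    b: float
    fit_residual: float = 0.0  # RMS pH over the calibration points

    def __post_init__(self):
        if self.a == 0:
            raise ValueError("calibration slope a must be nonzero")

    def ph(self, ratio):
        return self.a * np.log10(ratio) + self.b

    def ratio(self, ph):
        return 10.0 ** ((np.asarray(ph, float) - self.b) / self.a)


@dataclass
class PsiCalibration:
    """Δψ [mV] = slope·(A588 − A625) + intercept."""

    slope: float
    intercept: float
    fit_residual: float = 0.0  # RMS mV

    def __post_init__(self):
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("calibration slope must be finite and nonzero")

    def psi(self, delta_a):
        return self.slope * np.asarray(delta_a, float) + self.intercept

    def delta_a(self, psi):
        return (np.asarray(psi, float) - self.intercept) / self.slope


@dataclass
class KineticsResult:
    """Derived kinetic quantities of one assay trace."""

    initial_pH: float | None = None
    final_pH: float | None = None
    delta_pH: float | None = None
    exp_rate_constant: float | None = None  # s⁻¹
    initial_rate_psi: float | None = None  # mV s⁻¹
    proton_flux: float | None = None  # H⁺ s⁻¹ per liposome
    fit_covariances: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def fit_ph_calibration(pairs) -> PyranineCalibration:
    """Least-squares fit of pH against log10(ratio) from calibration points.

    ``pairs`` is an iterable of (ratio, pH); at least two distinct ratios
    are required and ratios must be positive.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibration points")
    ratios = np.array([p[0] for p in pairs], float)
    phs = np.array([p[1] for p in pairs], float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    x = np.log10(ratios)
    if np.ptp(x) == 0:
        raise ValueError("calibration points share one ratio: fit is rank-deficient")
    a, b = np.polyfit(x, phs, 1)
    resid = float(np.sqrt(np.mean((a * x + b - phs) ** 2)))
    return PyranineCalibration(a=float(a), b=float(b), fit_residual=resid)


def ph_trace(trace: AssayTrace, calib: PyranineCalibration) -> AssayTrace:
    """Convert an (I405, I460) fluorescence trace to a pH time series."""
    i405 = trace["I405"]
    i460 = trace["I460"]
    bad = (i405 <= 0) | (i460 <= 0)
    if np.any(bad):
        t_bad = trace.time[np.argmax(bad)]
        raise ValueError(f"nonpositive intensity at t={t_bad:g} s")
    ph = calib.ph(i460 / i405)
    return AssayTrace(trace.time, {"pH": ph}, trace.sample_interval,
                      dict(trace.metadata))


def extract_delta_ph(
    ph: AssayTrace,
    event_time: float,
    baseline_window: float = 60.0,
    end_time: float | None = None,
) -> KineticsResult:
    """ΔpH = baseline pH − fitted exponential plateau after the event.

    The initial pH is the average over the first ``baseline_window``
    seconds (clipped to before ``event_time``); the post-event segment is
    fitted with pH(t) = pH∞ + (pH₀ − pH∞)·exp(−k·(t − event)), and the
    final pH is the fitted plateau pH∞.  A fitted k ≤ 0 (or an
    effectively flat trace) is flagged rather than treated as an error.
    """
    t = ph.time
    y = ph["pH"]
    base_mask = t <= min(baseline_window, event_time)
    if not np.any(base_mask):
        raise ValueError("no baseline points before the event")
    initial = float(np.mean(y[base_mask]))
    fit_mask = t >= event_time
    if end_time is not None:
        fit_mask &= t <= end_time
    tf = t[fit_mask] - event_time
    yf = y[fit_mask]
    if len(tf) < 10:
        raise ValueError("need at least 10 post-event points for the fit")

    flags: list[str] = []
    # initialisation: plateau from the last decile, amplitude from the first
    # post-event point, k from the log-linearised early decay
    p_inf0 = float(np.mean(yf[-max(len(yf) // 10, 1):]))
    p00 = float(yf[0])
    amp0 = p00 - p_inf0
    if abs(amp0) < 1e-12 or np.ptp(yf) < 1e-12:
        return KineticsResult(
            initial_pH=initial, final_pH=float(np.mean(yf)),
            delta_pH=initial - float(np.mean(yf)),
            exp_rate_constant=None, flags=["rate_unidentifiable"],
        )
    k0 = 1.0 / max(tf[-1] / 3.0, 1e-6)
    with np.errstate(over="ignore"):
        head = yf[: max(len(yf) // 4, 3)]
        th = tf[: len(head)]
        rel = (head - p_inf0) / amp0
        ok = rel > 1e-3
        if ok.sum() >= 3 and np.ptp(th[ok]) > 0:
            slope = np.polyfit(th[ok], np.log(rel[ok]), 1)[0]
            if slope < 0:
                k0 = -slope

    def model(tt, p_inf, amp, k):
        return p_inf + amp * np.exp(-k * tt)

    try:
        popt, pcov = curve_fit(
            model, tf, yf, p0=[p_inf0, amp0, k0], maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"exponential fit did not converge (p0={[p_inf0, amp0, k0]}): {exc}"
        ) from exc
    p_inf, amp, k = popt
    if k <= 0:
        flags.append("negative_rate_constant")
    final = float(p_inf)
    return KineticsResult(
        initial_pH=initial,
        final_pH=final,
        delta_pH=initial - final,
        exp_rate_constant=float(k),
        fit_covariances={"exp": pcov},
        flags=flags,
    )


def nernst_potential(k_out: float, k_in: float, temperature: float = 310.0) -> float:
    """K⁺ diffusion potential Δψ = (RT/F)·ln([K⁺]out/[K⁺]in) in mV."""
    if k_out <= 0 or k_in <= 0:
        raise ValueError("potassium concentrations must be positive")
    return (
        GAS_CONSTANT * temperature / FARADAY * np.log(k_out / k_in) * 1000.0
    )


def fit_psi_calibration(points) -> PsiCalibration:
    """Fit Δψ = slope·ΔA + intercept from K⁺-set Nernst potentials.

    ``points`` is an iterable of (delta_a, k_out_mM, k_in_mM, T_K); the
    known potential of each point is the valinomycin-mediated K⁺
    diffusion potential.
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points")
    da = np.array([p[0] for p in points], float)
    psi = np.array([nernst_potential(p[1], p[2], p[3]) for p in points])
    if np.ptp(psi) == 0:
        raise ValueError("all calibration potentials equal: fit is rank-deficient")
    if np.ptp(da) == 0:
        raise ValueError("all ΔA values equal: fit is rank-deficient")
    slope, intercept = np.polyfit(da, psi, 1)
    resid = float(np.sqrt(np.mean((slope * da + intercept - psi) ** 2)))
    return PsiCalibration(slope=float(slope), intercept=float(intercept),
                          fit_residual=resid)


def psi_trace(trace: AssayTrace, calib: PsiCalibration) -> AssayTrace:
    """Convert an (A588, A625) absorbance trace to a Δψ series (mV)."""
    psi = calib.psi(trace["A588"] - trace["A625"])
    return AssayTrace(trace.time, {"psi_mV": psi}, trace.sample_interval,
                      dict(trace.metadata))


def initial_rate(
    psi: AssayTrace, start: float = 0.0, window: float = 1.0
) -> float:
    """Initial Δψ formation rate: LS slope over [start, start+window], mV/s."""
    mask = (psi.time >= start) & (psi.time <= start + window)
    if mask.sum() < 5:
        raise ValueError(
            f"only {int(mask.sum())} points in the rate window; need ≥ 5"
        )
    slope = np.polyfit(psi.time[mask], psi["psi_mV"][mask], 1)[0]
    return float(slope)


def proton_flux(
    rate_mv_per_s: float,
    lip: LiposomeSpec,
    orientation_correct: bool = False,
) -> float:
    """Per-liposome proton flux implied by a Δψ formation rate.

    The liposome is a spherical capacitor of area π·d² and specific
    capacitance C_m, so dΨ/dt corresponds to a charging current
    I = C_m·π·d²·dΨ/dt, i.e. I/e protons per second.  Unit bookkeeping:
    C_m [μF cm⁻²]·1e−6 → F cm⁻²; d [nm]·1e−7 → cm; rate [mV/s]·1e−3 → V/s.
    With ``orientation_correct`` the flux is divided by the fraction of
    transporters with their uptake side facing the lumen.
    """
    d_cm = lip.diameter * 1e-7
    c_farad = lip.specific_capacitance * 1e-6 * np.pi * d_cm**2
    flux = c_farad * (rate_mv_per_s * 1e-3) / ELEMENTARY_CHARGE
    if orientation_correct:
        if lip.orientation_fraction_n_inside <= 0:
            raise ValueError("orientation fraction must be positive to correct")
        flux /= lip.orientation_fraction_n_inside
    return float(flux)
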