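"""1:1 Langmuir binding kinetics: single-cycle sensorgrams and isotherms.

Single-cycle kinetics (SCK) injects the analyte at stepwise increasing
concentrations without regeneration between injections, ending in a long
dissociation phase. Under the 1:1 Langmuir model with constant per-phase
concentration C the response follows the closed-form piecewise exponential

    R(t) = R_eq + (R_0 - R_eq) * exp(-k_obs (t - t_0)),
    R_eq = R_max * C / (C + K_D),   k_obs = k_a C + k_d,

continuous across phase boundaries; for C = 0 this reduces to pure
exponential dissociation R(t) = R_0 exp(-k_d (t - t_0)). Fitting is
nonlinear least squares over (k_a, k_d, R_max) with an automatic initial
guess taken from a log-linear fit of the dissociation tail (k_d) and from
the early-association slope (k_a). The equilibrium constant is always
reported as K_D = k_d / k_a.

An ELISA-style saturation curve is fit with the Langmuir isotherm
signal = B_max * C / (K_D + C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares


@dataclass
class KineticParams:
    """1:1 Langmuir parameters; ka in 1/(M s), kd in 1/s, Rmax in
    instrument response units."""

    ka: float
    kd: float
    Rmax: float

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.Rmax <= 0 or self.kd < 0:
            raise ValueError("require ka > 0, Rmax > 0, kd >= 0")

    @property
    def KD(self) -> float:
        return self.kd / self.ka


def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant K_D = kd / ka (M)."""
    if ka <= 0:
        raise ValueError("ka must be positive")
    return kd / ka


@dataclass
class InjectionSchedule:
    """Contiguous phases of (start_s, end_s, concentration_M); SCK ends in a
    zero-concentration dissociation phase."""

    phases: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("empty schedule")
        prev_end = None
        for start, end, conc in self.phases:
            if end <= start:
                raise ValueError("phase must have end > start")
            if conc < 0:
                raise ValueError("negative analyte concentration")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise ValueError("phases must be contiguous")
            prev_end = end
        concs = [c for _, _, c in self.phases if c > 0]
        if any(b < a for a, b in zip(concs, concs[1:])):
            raise ValueError("SCK injection concentrations must be non-decreasing")

    @property
    def t_end(self) -> float:
        return self.phases[-1][1]

    @classmethod
    def single_cycle(
        cls,
        concentrations_M: Sequence[float] = (2.5e-9, 5e-9, 10e-9, 15e-9, 20e-9),
        injection_s: float = 105.0,
        dissociation_s: float = 600.0,
    ) -> "InjectionSchedule":
        """Default SCK design: stepwise injections spanning 2.5-20 nM, 105 s
        each, followed by a 10 min dissociation."""
        phases = []
        t = 0.0
        for c in concentrations_M:
            phases.append((t, t + injection_s, float(c)))
            t += injection_s
        phases.append((t, t + dissociation_s, 0.0))
        return cls(phases)


@dataclass
class Sensorgram:
    time: np.ndarray
    response: np.ndarray
    schedule: InjectionSchedule
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("non-finite response values")


def _piecewise_response(t: np.ndarray, params: KineticParams,
                        schedule: InjectionSchedule) -> np.ndarray:
    """Closed-form 1:1 response at times t (R = 0 before the first phase)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    r0 = 0.0
    last = len(schedule.phases) - 1
    for k, (start, end, conc) in enumerate(schedule.phases):
        k_obs = params.ka * conc + params.kd
        r_eq = (params.ka * conc * params.Rmax / k_obs) if k_obs > 0 else r0
        in_phase = (t >= start) & ((t <= end) if k == last else (t < end))
        dt = t[in_phase] - start
        out[in_phase] = r_eq + (r0 - r_eq) * np.exp(-k_obs * dt)
        r0 = r_eq + (r0 - r_eq) * np.exp(-k_obs * (end - start))
    return out


def simulate_sck(
    params: KineticParams,
    schedule: InjectionSchedule,
    sampling_rate_hz: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Sensorgram:
    """Simulate a sensorgram; Gaussian noise of the given s.d. is added when
    noise_sd > 0 (deterministic output at noise_sd = 0)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = int(round(schedule.t_end * sampling_rate_hz))
    t = np.arange(1, n + 1) / sampling_rate_hz
    r = _piecewise_response(t, params, schedule)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(t, r, schedule, noise_sd)


@dataclass
class FitDiagnostics:
    rss: float
    n_points: int
    success: bool
    message: str = ""


def _auto_initial_guess(sg: Sensorgram) -> KineticParams:
    """kd from the log-linear dissociation tail, ka from the first-injection
    initial slope, Rmax from the response scale."""
    phases = sg.schedule.phases
    rmax0 = max(float(np.max(sg.response)), 1e-12) * 2.0
    kd0 = 1e-4
    if phases[-1][2] == 0.0:
        start = phases[-1][0]
        tail = sg.time >= start
        r = sg.response[tail]
        good = r > max(1e-3 * rmax0, 1e-12)
        if np.count_nonzero(good) >= 3:
            slope = np.polyfit(sg.time[tail][good], np.log(r[good]), 1)[0]
            kd0 = max(-slope, 1e-7)
    first = next((p for p in phases if p[2] > 0), None)
    ka0 = 1e5
    if first is not None:
        t0, t1, conc = first
        early = (sg.time >= t0) & (sg.time <= t0 + 0.2 * (t1 - t0))
        if np.count_nonzero(early) >= 3:
            slope = np.polyfit(sg.time[early], sg.response[early], 1)[0]
            # dR/dt at R=0 is ka * C * Rmax
            ka0 = max(slope / (conc * rmax0), 1e2)
    return KineticParams(ka0, kd0, rmax0)


def fit_sck(
    sensorgram: Sensorgram,
    initial_guess: KineticParams | str = "auto",
) -> tuple[KineticParams, FitDiagnostics]:
    """Least-squares fit of (ka, kd, Rmax) to a single-cycle sensorgram.

    Requires at least two phases with distinct concentrations (a lone
    dissociation phase leaves ka unidentifiable). Parameters are optimized
    in log space to enforce positivity.
    """
    concs = {c for _, _, c in sensorgram.schedule.phases}
    if len({c for c in concs if c > 0}) < 1 or len(concs) < 2:
        raise ValueError("need >=2 phases with distinct concentrations to identify ka")
    guess = _auto_initial_guess(sensorgram) if initial_guess == "auto" else initial_guess

    def residuals(logp: np.ndarray) -> np.ndarray:
        # clamp to keep exploratory LM steps finite
        p = KineticParams(*np.exp(np.clip(logp, -60.0, 60.0)))
        return _piecewise_response(sensorgram.time, p, sensorgram.schedule) - sensorgram.response

    x0 = np.log([guess.ka, max(guess.kd, 1e-9), guess.Rmax])
    result = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    fitted = KineticParams(*np.exp(result.x))
    diag = FitDiagnostics(float(np.sum(result.fun**2)), len(sensorgram.time),
                          bool(result.success), result.message)
    if not result.success:
        raise RuntimeError(
            f"SCK fit did not converge: {result.message}; last iterate "
            f"ka={fitted.ka:.3g}, kd={fitted.kd:.3g}, Rmax={fitted.Rmax:.3g}")
    return fitted, diag


def fit_langmuir_isotherm(
    concentrations_M: Sequence[float],
    signal: Sequence[float],
) -> tuple[float, float]:
    """Fit signal = Bmax * C / (KD + C); returns (KD, Bmax)."""
    c = np.asarray(concentrations_M, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.allclose(y, y[0]):
        raise ValueError("all signals equal; isotherm unidentifiable")

    def model(cc, kd, bmax):
        return bmax * cc / (kd + cc)

    half = c[np.argmin(np.abs(y - np.max(y) / 2))]
    popt, _ = curve_fit(model, c, y, p0=[max(half, np.min(c[c > 0], initial=1e-12)), np.max(y)],
                        maxfev=20000)
    kd, bmax = float(popt[0]), float(popt[1])
    return kd, bmax
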