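"""1:1 Langmuir binding kinetics: closed-form simulation and global fitting.

Model
-----
Reversible single-site binding of an analyte at concentration ``C`` to an
immobilised ligand, observed as a response ``R`` (RU):

    dR/dt = kon * C * (Rmax - R) - koff * R

Association from R(0)=0 has the closed form

    R(t) = C*kon*Rmax / (C*kon + koff) * (1 - exp(-(C*kon + koff)*t))

and dissociation from a level ``R0`` is ``R0 * exp(-koff*t)``.  The
equilibrium dissociation constant is KD = koff/kon.

Fitting is global: one (kon, koff, Rmax) triple is shared across all
concentrations, in log space for the rate constants, by trust-region
nonlinear least squares.  Mass-transport limitation and baseline drift are
not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "Sensorgram",
    "FitDiagnostics",
    "simulate_association",
    "simulate_dissociation",
    "simulate_series",
    "fit_1to1_global",
    "kd_of",
    "round_sig",
]

KON_BOUNDS = (1e2, 1e9)    # M^-1 s^-1
KOFF_BOUNDS = (1e-6, 1.0)  # s^-1


@dataclass(frozen=True)
class KineticParams:
    kon: float   # M^-1 s^-1
    koff: float  # s^-1
    rmax: float  # RU

    def __post_init__(self):
        if self.kon <= 0 or self.koff <= 0 or self.rmax <= 0:
            raise ValueError("kon, koff and rmax must all be positive")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant koff/kon, in M."""
        return self.koff / self.kon


@dataclass
class Sensorgram:
    analyte_conc: float      # M
    t_assoc_end: float       # s
    times: np.ndarray        # s, strictly increasing, spans both phases
    responses: np.ndarray    # RU
    noise_sd: float = 0.0    # RU, known for synthetic data

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def simulate_association(params: KineticParams, conc: float,
                         times: np.ndarray) -> np.ndarray:
    """Closed-form association response at analyte concentration ``conc``."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative time")
    if conc < 0:
        raise ValueError("negative concentration")
    if conc == 0:
        return np.zeros_like(times)
    kobs = conc * params.kon + params.koff
    req = conc * params.kon * params.rmax / kobs
    return req * (1.0 - np.exp(-kobs * times))


def simulate_dissociation(params: KineticParams, r_start: float,
                          times: np.ndarray) -> np.ndarray:
    """Exponential decay from ``r_start`` with rate koff."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative time")
    if r_start < 0:
        raise ValueError("negative starting response")
    return r_start * np.exp(-params.koff * times)


def _trace(params: KineticParams, conc: float, times: np.ndarray,
           t_assoc_end: float) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    assoc = times <= t_assoc_end
    out = np.empty_like(times)
    out[assoc] = simulate_association(params, conc, times[assoc])
    r_end = simulate_association(params, conc, np.array([t_assoc_end]))[0]
    out[~assoc] = simulate_dissociation(params, r_end, times[~assoc] - t_assoc_end)
    return out


def simulate_series(params: KineticParams, concs: list[float],
                    t_assoc: float = 300.0, t_dissoc: float = 300.0,
                    dt: float = 1.0, noise_sd: float = 0.0,
                    seed: int | None = None) -> list[Sensorgram]:
    """A multi-concentration sensorgram series with optional Gaussian noise.

    The zero-concentration trace is pure noise around zero (the blank).
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    series = []
    for conc in concs:
        clean = _trace(params, conc, times, t_assoc)
        noisy = clean + rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else clean
        series.append(Sensorgram(conc, t_assoc, times.copy(), noisy, noise_sd))
    return series


@dataclass
class FitDiagnostics:
    residual_sd: float
    param_stderr: dict[str, float]
    n_points: int
    cost: float
    success: bool
    message: str = ""


def _initial_guess(series: list[Sensorgram]) -> tuple[float, float, float]:
    """koff from the dissociation tail log-slope; kon from the observed
    association rate of the highest concentration; rmax from the maximum
    response with 20% headroom."""
    nonzero = [s for s in series if s.analyte_conc > 0]
    top = max(nonzero, key=lambda s: s.analyte_conc)
    rmax0 = max(float(np.max(s.responses)) for s in nonzero) * 1.2

    dis = top.times > top.t_assoc_end
    t_d = top.times[dis] - top.t_assoc_end
    r_d = top.responses[dis]
    pos = r_d > max(1e-3, 0.01 * np.max(np.abs(r_d) + 1e-12))
    if pos.sum() >= 3:
        slope = np.polyfit(t_d[pos], np.log(r_d[pos]), 1)[0]
        koff0 = float(np.clip(-slope, *KOFF_BOUNDS))
    else:
        koff0 = 1e-3

    assoc = top.times <= top.t_assoc_end
    r_a = top.responses[assoc]
    t_a = top.times[assoc]
    plateau = float(r_a[-1]) if r_a.size else rmax0
    half_idx = np.argmax(r_a >= 0.5 * plateau) if plateau > 0 else 0
    t_half = max(float(t_a[half_idx]), t_a[1] if t_a.size > 1 else 1.0)
    kobs = math.log(2.0) / t_half
    kon0 = float(np.clip((kobs - koff0) / top.analyte_conc, *KON_BOUNDS))
    return kon0, koff0, rmax0


def fit_1to1_global(series: list[Sensorgram]) -> tuple[KineticParams, FitDiagnostics]:
    """Global 1:1 fit of a sensorgram series; one shared (kon, koff, Rmax).

    A zero-concentration trace, when present, is subtracted from every other
    trace as blank/baseline before fitting.  Rates are fitted in log space
    within [1e2, 1e9] M⁻¹s⁻¹ and [1e-6, 1] s⁻¹.
    """
    blanks = [s for s in series if s.analyte_conc == 0]
    traces = [s for s in series if s.analyte_conc > 0]
    if len(traces) < 2:
        raise ValueError("need at least two nonzero analyte concentrations")
    if all(np.allclose(s.responses, 0) for s in traces):
        raise ValueError("all responses are zero: nothing to fit")

    corrected = []
    for s in traces:
        resp = s.responses
        if blanks:
            blank = blanks[0]
            resp = resp - np.interp(s.times, blank.times, blank.responses)
        corrected.append((s.analyte_conc, s.times, resp, s.t_assoc_end))

    def residuals(x):
        p = KineticParams(10 ** x[0], 10 ** x[1], x[2])
        return np.concatenate([
            _trace(p, conc, times, t_end) - resp
            for conc, times, resp, t_end in corrected
        ])

    kon0, koff0, rmax0 = _initial_guess(traces)
    x0 = np.array([math.log10(kon0), math.log10(koff0), rmax0])
    lower = [math.log10(KON_BOUNDS[0]), math.log10(KOFF_BOUNDS[0]), 1e-6]
    upper = [math.log10(KON_BOUNDS[1]), math.log10(KOFF_BOUNDS[1]), np.inf]
    result = least_squares(residuals, x0, bounds=(lower, upper),
                           method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not result.success:
        raise RuntimeError(
            f"global fit did not converge: {result.message}; last iterate "
            f"kon={10**result.x[0]:.3g}, koff={10**result.x[1]:.3g}, "
            f"rmax={result.x[2]:.3g}. Check phase boundaries and that the "
            "concentration ladder spans KD.")

    params = KineticParams(10 ** result.x[0], 10 ** result.x[1], result.x[2])
    res = result.fun
    n = res.size
    dof = max(n - 3, 1)
    residual_sd = float(np.sqrt(np.sum(res ** 2) / dof))
    # Parameter covariance from the Jacobian at the solution (delta method
    # for the log-space rate parameters).
    try:
        jtj = result.jac.T @ result.jac
        cov = np.linalg.inv(jtj) * residual_sd ** 2
        se_log_kon, se_log_koff, se_rmax = np.sqrt(np.diag(cov))
        stderr = {
            "kon": params.kon * math.log(10) * se_log_kon,
            "koff": params.koff * math.log(10) * se_log_koff,
            "rmax": float(se_rmax),
        }
    except np.linalg.LinAlgError:
        stderr = {"kon": float("nan"), "koff": float("nan"), "rmax": float("nan")}
    diag = FitDiagnostics(residual_sd, stderr, n, float(result.cost),
                          True, result.message)
    return params, diag


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def kd_of(kon: float, koff: float) -> tuple[float, float]:
    """KD = koff/kon in M: (exact quotient, value at 2 significant figures)."""
    if kon <= 0:
        raise ValueError("kon must be positive")
    kd = koff / kon
    return kd, round_sig(kd, 2)
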