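"""Compartmental kinetics of chemolithoautotrophic HgS-nanoparticle transformation.

Mercury in an incubation is tracked through four pools (all in uM as Hg):

    n_ex  extracellular particulate HgS_NP
    n_in  intracellular particulate HgS_NP (after uptake)
    d_in  intracellular dissolved Hg(II) (after oxidative dissolution)
    e     cumulative volatile Hg0 released (after enzymatic/abiotic reduction)

coupled to cumulative oxidized-sulfur products (sulfate, an intermediate pool
covering thiosulfate/sulfite, and elemental sulfur; 1:1 S per Hg dissolved)
and to cell density B.  The model is the minimal linear chain consistent with
an uptake -> dissolution -> reduction narrative, with biomass-proportional
uptake and logistic growth supplemented by a sulfur-oxidation yield term:

    dB/dt    = r B (1 - B/K) + y k_diss n_in
    dn_ex/dt = -k_up B n_ex
    dn_in/dt =  k_up B n_ex - k_diss n_in
    dd_in/dt =  k_diss n_in - k_red d_in
    de/dt    =  k_red d_in
    dS_j/dt  =  f_j k_diss n_in          (j = sulfate, intermediate, zero)

With biomass held constant the Hg chain is a three-step first-order cascade
whose Bateman closed form serves as the integration oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "HgCompartmentState",
    "TimeCourse",
    "FitResult",
    "simulate_timecourse",
    "closed_form_cascade",
    "fit_params",
    "transformation_efficiency",
    "mass_balance_residual",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "DEFAULT_PARAMS",
]

_SERIES = (
    "cell_density", "n_ex", "n_in", "d_in", "e",
    "s_sulfate", "s_intermediate", "s_zero",
)

_CSV_COLS = {
    "cell_density": "cell_density",
    "n_ex": "n_ex_uM",
    "n_in": "n_in_uM",
    "d_in": "d_in_uM",
    "e": "e_uM",
    "s_sulfate": "s_sulfate_uM",
    "s_intermediate": "s_intermediate_uM",
    "s_zero": "s_zero_uM",
}


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and growth parameters of the compartmental model.

    k_up is second-order (per cell-density unit per h); k_diss and k_red are
    first-order (1/h); k_red lumps the merA, superoxide and cytochrome-c
    reduction routes.  r, K are logistic growth rate (1/h) and carrying
    capacity; y couples growth to sulfur oxidation (cell-density per uM S).
    f_* are the sulfur branching fractions and must sum to 1.
    """

    k_up: float
    k_diss: float
    k_red: float
    r: float = 0.0
    K: float = 1.0
    y: float = 0.0
    f_sulfate: float = 1.0
    f_intermediate: float = 0.0
    f_zero: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_up", "k_diss", "k_red", "r", "y",
                     "f_sulfate", "f_intermediate", "f_zero"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.K <= 0:
            raise ValueError("K must be > 0")
        fsum = self.f_sulfate + self.f_intermediate + self.f_zero
        if abs(fsum - 1.0) > 1e-9:
            raise ValueError(f"branching fractions sum to {fsum:g}, expected 1")

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in (
            "k_up", "k_diss", "k_red", "r", "K", "y",
            "f_sulfate", "f_intermediate", "f_zero")}


#: T. thioparus-like defaults: 50 uM HgS_NP dose, growth over ~160 h, and
#: roughly a tenth of the mercury volatilized within the first 18 h.
DEFAULT_PARAMS = KineticParams(
    k_up=0.135, k_diss=0.35, k_red=0.25,
    r=0.03, K=0.6, y=0.004,
    f_sulfate=0.6, f_intermediate=0.25, f_zero=0.15,
)


@dataclass(frozen=True)
class HgCompartmentState:
    """Mercury pool masses (uM as Hg); fields may be scalars or arrays."""

    n_ex: float | np.ndarray
    n_in: float | np.ndarray
    d_in: float | np.ndarray
    e: float | np.ndarray

    def total(self) -> float | np.ndarray:
        return self.n_ex + self.n_in + self.d_in + self.e


@dataclass
class TimeCourse:
    """Observed or simulated trajectories on a strictly increasing time grid.

    ``sd`` optionally maps series names (as in the field list) to per-time
    standard deviations used as least-squares weights.
    """

    times: np.ndarray
    cell_density: np.ndarray
    n_ex: np.ndarray
    n_in: np.ndarray
    d_in: np.ndarray
    e: np.ndarray
    s_sulfate: np.ndarray
    s_intermediate: np.ndarray
    s_zero: np.ndarray
    total_hg: float
    sd: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in _SERIES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} length differs from times")
            setattr(self, name, arr)
        if self.times.size == 0:
            raise ValueError("empty time course")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.total_hg <= 0:
            raise ValueError("total_hg must be positive")

    def hg_state(self) -> HgCompartmentState:
        return HgCompartmentState(self.n_ex, self.n_in, self.d_in, self.e)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times}
        for name in _SERIES:
            data[_CSV_COLS[name]] = getattr(self, name)
        for name, arr in self.sd.items():
            data[_CSV_COLS[name] + "_sd"] = np.asarray(arr, dtype=float)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, total_hg: float | None = None) -> "TimeCourse":
        missing = [c for c in ["time_h", *_CSV_COLS.values()] if c not in df.columns]
        if missing:
            raise ValueError(f"missing time-course columns: {missing}")
        kwargs = {name: df[_CSV_COLS[name]].to_numpy(float) for name in _SERIES}
        sd = {}
        for name, col in _CSV_COLS.items():
            if col + "_sd" in df.columns:
                sd[name] = df[col + "_sd"].to_numpy(float)
        if total_hg is None:
            row0 = df.iloc[0]
            total_hg = float(row0["n_ex_uM"] + row0["n_in_uM"]
                             + row0["d_in_uM"] + row0["e_uM"])
        return cls(times=df["time_h"].to_numpy(float), total_hg=total_hg,
                   sd=sd, **kwargs)


def read_timecourse_csv(path, total_hg: float | None = None) -> TimeCourse:
    return TimeCourse.from_frame(pd.read_csv(path), total_hg=total_hg)


def write_timecourse_csv(tc: TimeCourse, path) -> None:
    tc.to_frame().to_csv(path, index=False)


def _rhs(t, yv, p: KineticParams):
    B, n_ex, n_in, d_in, e, s1, s2, s3 = yv
    diss = p.k_diss * n_in
    return (
        p.r * B * (1.0 - B / p.K) + p.y * diss,
        -p.k_up * B * n_ex,
        p.k_up * B * n_ex - diss,
        diss - p.k_red * d_in,
        p.k_red * d_in,
        p.f_sulfate * diss,
        p.f_intermediate * diss,
        p.f_zero * diss,
    )


def simulate_timecourse(
    params: KineticParams,
    total_hg: float,
    b0: float,
    times: Sequence[float] | np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TimeCourse:
    """Integrate the compartmental model from (total_hg, 0, 0, 0) at t=0.

    Integration uses a stiff-capable solver (LSODA) at rtol 1e-8 / atol 1e-12.
    Tiny negative excursions (>= -1e-12 uM) are clipped to zero; anything
    below that is reported as a solver failure.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if times[0] < 0:
        raise ValueError("times must be non-negative")
    if total_hg <= 0:
        raise ValueError("total_hg must be positive")
    if b0 <= 0:
        raise ValueError("b0 must be positive")

    y0 = [b0, total_hg, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    if times[-1] == 0.0:
        ys = np.asarray(y0, dtype=float)[:, None]
    else:
        sol = solve_ivp(
            _rhs, (0.0, float(times[-1])), y0, t_eval=times,
            args=(params,), method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed near t={sol.t[-1]:g} h: {sol.message}")
        ys = sol.y

    if np.min(ys) < -1e-12:
        raise RuntimeError(
            f"integration produced a negative pool ({np.min(ys):.3e}); "
            "tighten tolerances"
        )
    ys = np.clip(ys, 0.0, None)
    return TimeCourse(
        times=times, cell_density=ys[0],
        n_ex=ys[1], n_in=ys[2], d_in=ys[3], e=ys[4],
        s_sulfate=ys[5], s_intermediate=ys[6], s_zero=ys[7],
        total_hg=float(total_hg),
    )


def closed_form_cascade(
    k1: float, k_diss: float, k_red: float, total: float,
    t: float | np.ndarray,
) -> HgCompartmentState:
    """Bateman solution of the chain n_ex -> n_in -> d_in -> e.

    ``k1`` is the effective first-order uptake rate (k_up * B with B held
    constant).  Rates must be pairwise distinct for the general formula;
    callers hitting a repeated-rate case should perturb one rate by ~1e-9
    of its value or take the limit separately.
    """
    rates = (k1, k_diss, k_red)
    if any(k < 0 for k in rates):
        raise ValueError("rates must be >= 0")
    scale = max(abs(k) for k in rates) or 1.0
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(rates[i] - rates[j]) <= 1e-12 * scale:
                raise ValueError(
                    "repeated rates: the general Bateman formula is singular; "
                    "perturb one rate by ~1e-9 relative"
                )
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")

    e1, e2, e3 = np.exp(-k1 * t), np.exp(-k_diss * t), np.exp(-k_red * t)
    n_ex = total * e1
    n_in = total * k1 * (e1 - e2) / (k_diss - k1)
    d_in = total * k1 * k_diss * (
        e1 / ((k_diss - k1) * (k_red - k1))
        + e2 / ((k1 - k_diss) * (k_red - k_diss))
        + e3 / ((k1 - k_red) * (k_diss - k_red))
    )
    e = total - n_ex - n_in - d_in
    if t.ndim == 0:
        return HgCompartmentState(float(n_ex), float(n_in), float(d_in), float(e))
    return HgCompartmentState(n_ex, n_in, d_in, e)


def transformation_efficiency(tc: TimeCourse, t: float) -> float:
    """Fraction of total mercury volatilized by time ``t`` (linear interpolation)."""
    if t < tc.times[0] or t > tc.times[-1]:
        raise ValueError(
            f"t={t:g} outside the sampled range [{tc.times[0]:g}, {tc.times[-1]:g}]"
        )
    return float(np.interp(t, tc.times, tc.e) / tc.total_hg)


def mass_balance_residual(tc: TimeCourse) -> float:
    """Max over time of |sum of Hg pools - total| / total."""
    if tc.total_hg == 0:
        raise ValueError("zero total mercury")
    pools = tc.n_ex + tc.n_in + tc.d_in + tc.e
    return float(np.max(np.abs(pools - tc.total_hg)) / tc.total_hg)


# ---------------------------------------------------------------------------
# Fitting

_FITTABLE = ("k_up", "k_diss", "k_red", "r", "K", "y",
             "f_sulfate", "f_intermediate")


@dataclass
class FitResult:
    params: KineticParams
    residual_norm: float
    param_sd: dict[str, float]
    at_bounds: dict[str, bool]
    n_starts: int
    success: bool
    message: str = ""


def _params_from_vector(theta, free, base: KineticParams) -> KineticParams:
    d = base.to_dict()
    for name, val in zip(free, theta):
        d[name] = float(val)
    if "f_sulfate" in free or "f_intermediate" in free:
        d["f_zero"] = max(0.0, 1.0 - d["f_sulfate"] - d["f_intermediate"])
        s = d["f_sulfate"] + d["f_intermediate"] + d["f_zero"]
        d["f_sulfate"] /= s
        d["f_intermediate"] /= s
        d["f_zero"] /= s
    return KineticParams(**d)


def fit_params(
    tc: TimeCourse,
    init: KineticParams,
    bounds: Mapping[str, tuple[float, float]],
    b0: float | None = None,
    free: Sequence[str] | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Bounded weighted least squares over all observed series.

    ``bounds`` maps parameter names to (lo, hi); its keys define the free
    parameters unless ``free`` restricts them further.  Weights are 1/SD
    where the time course carries SDs, else uniform.  Multi-start (default 8,
    log-uniform within bounds plus the supplied init) with best-residual
    selection; deterministic given ``seed``.  Per-parameter SDs come from the
    local curvature (Gauss-Newton covariance) at the optimum.
    """
    free = tuple(free) if free is not None else tuple(
        n for n in _FITTABLE if n in bounds)
    if not free:
        raise ValueError("no free parameters")
    unknown = [n for n in free if n not in _FITTABLE]
    if unknown:
        raise ValueError(f"cannot fit parameters: {unknown}")
    for n in free:
        lo, hi = bounds[n]
        v = getattr(init, n)
        if not (lo <= v <= hi):
            raise ValueError(f"init.{n}={v:g} outside bounds [{lo:g}, {hi:g}]")

    if tc.times.size < 6:
        raise ValueError("need at least 6 time points")
    n_obs = tc.times.size * len(_SERIES)
    if n_obs <= len(free):
        raise ValueError("under-determined fit: fewer observations than parameters")
    if b0 is None:
        b0 = float(tc.cell_density[0])

    obs = np.concatenate([getattr(tc, name) for name in _SERIES])
    wts = []
    for name in _SERIES:
        if name in tc.sd:
            sd = np.asarray(tc.sd[name], dtype=float)
            floor = max(np.max(sd) * 1e-6, 1e-12)
            wts.append(1.0 / np.maximum(sd, floor))
        else:
            scale = max(float(np.max(np.abs(getattr(tc, name)))), 1e-12)
            wts.append(np.full(tc.times.size, 1.0 / scale))
    w = np.concatenate(wts)

    def residuals(theta):
        try:
            p = _params_from_vector(theta, free, init)
            sim = simulate_timecourse(p, tc.total_hg, b0, tc.times)
        except (ValueError, RuntimeError):
            return np.full(n_obs, 1e6)
        pred = np.concatenate([getattr(sim, name) for name in _SERIES])
        res = w * (pred - obs)
        return np.where(np.isfinite(res), res, 1e6)

    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])
    rng = np.random.default_rng(seed)
    starts = [np.array([getattr(init, n) for n in free], dtype=float)]
    lo_s = np.maximum(lo, 1e-8 * np.maximum(hi, 1e-8))
    for _ in range(max(0, n_starts - 1)):
        u = rng.uniform(size=len(free))
        starts.append(np.exp(np.log(lo_s) + u * (np.log(hi) - np.log(lo_s))))

    best = None
    for x0 in starts:
        sol = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                            method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10)
        if best is None or sol.cost < best.cost:
            best = sol

    p_hat = _params_from_vector(best.x, free, init)
    m = n_obs - len(free)
    s2 = 2.0 * best.cost / max(m, 1)
    try:
        JTJ = best.jac.T @ best.jac
        cov = np.linalg.pinv(JTJ) * s2
        sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        sds = np.full(len(free), np.nan)
    tol = 1e-8 * np.maximum(np.abs(hi - lo), 1e-12)
    at_bounds = {n: bool(best.x[i] - lo[i] <= tol[i] or hi[i] - best.x[i] <= tol[i])
                 for i, n in enumerate(free)}
    return FitResult(
        params=p_hat,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        param_sd={n: float(sds[i]) for i, n in enumerate(free)},
        at_bounds=at_bounds,
        n_starts=len(starts),
        success=bool(best.success),
        message=str(best.message),
    )
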