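"""Coupled-assay enzyme kinetics: calibration, initial rates and full
progress-curve analysis.

The kinetic model is the five-rate-constant single-substrate scheme

    E + S  <-> ES  <-> EP  -> E + P
          k1/k-1  k2/k-2   k3

with the other substrates held saturating, as in an NADH-coupled ATPase
assay where ADP formation is reported 1:1 by NADH oxidation (absorbance
at 340 nm).  Steady-state Michaelis-Menten parameters follow from the
elementary constants:

    kcat      = k2*k3 / (k2 + k-2 + k3)
    kcat/KM   = k1*k2*k3 / (k2*k3 + k-1*(k-2 + k3))
    KM        = kcat / (kcat/KM)

Full progress curves (complete substrate-depletion time courses) are fit
globally across starting substrate concentrations by weighted nonlinear
least squares on log-transformed rate constants.  Only the steady-state
combinations (kcat, KM, kcat/KM) are generally identifiable from such
data; elementary constants with flat likelihood profiles are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "MichaelisParameters",
    "ProgressCurve",
    "AssayCalibration",
    "RateMeasurement",
    "FitResult",
    "NADH_EXTINCTION_340",
    "calibrate_pathlength",
    "signal_to_concentration",
    "concentration_to_signal",
    "average_replicates",
    "fit_initial_rates",
    "simulate_progress",
    "fit_progress_curves",
    "derive_steady_state",
]

#: NADH molar extinction coefficient at 340 nm (per-molar per-cm), used only
#: when no empirical pathlength titration is available.
NADH_EXTINCTION_340 = 6220.0


class KineticsError(ValueError):
    """Raised for invalid kinetics inputs."""


@dataclass(frozen=True)
class RateConstants:
    """Elementary rate constants of the three-step catalytic scheme.

    Parameters
    ----------
    k1 : float
        Second-order substrate association rate (/M/s).
    k_minus1 : float
        ES dissociation rate (/s).
    k2 : float
        Forward chemistry rate ES -> EP (/s).
    k_minus2 : float
        Reverse chemistry rate EP -> ES (/s).
    k3 : float
        Irreversible product-release rate (/s).
    """

    k1: float
    k_minus1: float
    k2: float
    k_minus2: float
    k3: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0 and self.k3 > 0):
            raise KineticsError("k1, k2 and k3 must be strictly positive")
        if self.k_minus1 < 0 or self.k_minus2 < 0:
            raise KineticsError("k_minus1 and k_minus2 must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.k1, self.k_minus1, self.k2, self.k_minus2, self.k3], float
        )

    @classmethod
    def from_array(cls, k: np.ndarray) -> "RateConstants":
        return cls(*np.asarray(k, float))

    names = ("k1", "k_minus1", "k2", "k_minus2", "k3")


@dataclass(frozen=True)
class MichaelisParameters:
    """Steady-state parameters with standard errors.

    kcat in /s, KM in M, kcat_over_KM in /M/s.
    """

    kcat: float
    KM: float
    kcat_over_KM: float
    kcat_se: float = np.nan
    KM_se: float = np.nan
    kcat_over_KM_se: float = np.nan

    def __post_init__(self) -> None:
        if not (self.kcat > 0 and self.KM > 0 and self.kcat_over_KM > 0):
            raise KineticsError("steady-state parameters must be positive")


@dataclass
class AssayCalibration:
    """Empirical signal coefficient: absorbance units per molar NADH.

    The coefficient is the product of the extinction coefficient and the
    optical pathlength, determined per experiment by NADH titration.
    """

    coefficient: float
    se: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise KineticsError("calibration coefficient must be positive")


@dataclass(frozen=True)
class RateMeasurement:
    """Enzyme-normalised initial velocity at one substrate concentration."""

    substrate: float  # M
    v0: float  # /s
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.substrate < 0:
            raise KineticsError("substrate concentration must be non-negative")


@dataclass
class ProgressCurve:
    """A time course of the coupled-assay observable.

    ``trace`` holds absorbance when ``units == 'absorbance'`` and product
    concentration (M) when ``units == 'molar'``.
    """

    time: np.ndarray
    trace: np.ndarray
    s0: float
    e0: float
    units: str = "molar"
    sd: np.ndarray | None = None
    replicate: str | int | None = None
    condition: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.trace = np.asarray(self.trace, float)
        if self.time.ndim != 1 or self.time.shape != self.trace.shape:
            raise KineticsError("time and trace must be 1-D and equal length")
        if np.any(np.diff(self.time) <= 0):
            raise KineticsError("time grid must be strictly increasing")
        if self.units not in ("absorbance", "molar"):
            raise KineticsError("units must be 'absorbance' or 'molar'")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, float)
            if self.sd.shape != self.trace.shape:
                raise KineticsError("sd must match trace shape")
            if np.any(self.sd < 0):
                raise KineticsError("sd must be non-negative")


@dataclass
class FitResult:
    """Outcome of a least-squares fit."""

    params: dict
    covariance: np.ndarray
    wrss: float
    dof: int
    converged: bool
    nfev: int
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dof < 1:
            raise KineticsError("degrees of freedom must be >= 1")


# ---------------------------------------------------------------------------
# Calibration and unit handling
# ---------------------------------------------------------------------------


def calibrate_pathlength(
    titration: list[tuple[float, float]],
) -> AssayCalibration:
    """Least-squares slope of absorbance vs. NADH concentration.

    A line with free intercept is fit to ``(concentration_M, absorbance)``
    points; the slope is the effective signal coefficient (AU per molar),
    i.e. extinction coefficient times pathlength.
    """
    if len(titration) < 3:
        raise KineticsError("need at least 3 titration points")
    conc = np.array([p[0] for p in titration], float)
    absb = np.array([p[1] for p in titration], float)
    if np.any(conc < 0):
        raise KineticsError("NADH concentrations must be non-negative")
    if np.ptp(conc) == 0:
        raise KineticsError("degenerate titration: all concentrations equal")
    X = np.column_stack([conc, np.ones_like(conc)])
    beta, res, *_ = np.linalg.lstsq(X, absb, rcond=None)
    slope = beta[0]
    resid = absb - X @ beta
    dof = len(conc) - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    if slope <= 0:
        raise KineticsError(f"non-positive calibration slope {slope:g}")
    return AssayCalibration(coefficient=float(slope), se=se, n_points=len(conc))


def signal_to_concentration(
    curve: ProgressCurve, cal: AssayCalibration
) -> ProgressCurve:
    """Convert an absorbance trace to molar product concentration.

    NADH depletion is stoichiometric with product (ADP) formation under the
    coupled-assay contract, so absorbance/coefficient maps directly to molar.
    """
    if curve.units != "absorbance":
        raise KineticsError("curve is already in molar units")
    return replace(
        curve,
        trace=curve.trace / cal.coefficient,
        sd=None if curve.sd is None else curve.sd / cal.coefficient,
        units="molar",
    )


def concentration_to_signal(
    curve: ProgressCurve, cal: AssayCalibration
) -> ProgressCurve:
    """Inverse of :func:`signal_to_concentration`."""
    if curve.units != "molar":
        raise KineticsError("curve is already in absorbance units")
    return replace(
        curve,
        trace=curve.trace * cal.coefficient,
        sd=None if curve.sd is None else curve.sd * cal.coefficient,
        units="absorbance",
    )


def average_replicates(curves: list[ProgressCurve]) -> ProgressCurve:
    """Pointwise mean and sample SD over replicate curves.

    All curves must share the time grid, S0, E0 and units.  The scalar mean
    of per-point SDs (the "average standard deviation") is stored in
    ``meta['average_sd']``; it is the single weight value some global-fit
    software imports per curve.
    """
    if len(curves) < 2:
        raise KineticsError("need at least 2 replicates to average")
    ref = curves[0]
    for c in curves[1:]:
        if c.time.shape != ref.time.shape or not np.allclose(
            c.time, ref.time, rtol=0, atol=1e-12
        ):
            raise KineticsError("replicates must share an identical time grid")
        if c.s0 != ref.s0 or c.e0 != ref.e0 or c.units != ref.units:
            raise KineticsError("replicates must share S0, E0 and units")
    traces = np.stack([c.trace for c in curves])
    mean = traces.mean(axis=0)
    sd = traces.std(axis=0, ddof=1)
    return ProgressCurve(
        time=ref.time.copy(),
        trace=mean,
        sd=sd,
        s0=ref.s0,
        e0=ref.e0,
        units=ref.units,
        condition=ref.condition,
        meta={"n_replicates": len(curves), "average_sd": float(sd.mean())},
    )


# ---------------------------------------------------------------------------
# Initial-rate Michaelis-Menten fitting
# ---------------------------------------------------------------------------


def _mm_velocity(s, kcat, km):
    return kcat * s / (km + s)


def fit_initial_rates(
    measurements: list[RateMeasurement],
) -> tuple[MichaelisParameters, FitResult]:
    """Fit v0 = kcat*[S]/(KM+[S]) to enzyme-normalised initial velocities.

    Standard errors come from the covariance of the nonlinear fit; the
    specificity constant kcat/KM and its SE follow by first-order (delta
    method) propagation including the kcat-KM covariance.
    """
    s = np.array([m.substrate for m in measurements], float)
    v = np.array([m.v0 for m in measurements], float)
    if len(np.unique(s)) < 4:
        raise KineticsError("need >= 4 distinct substrate concentrations")
    vmax0 = max(v.max(), 1e-12)
    # half-saturation guess: [S] where v first crosses vmax/2
    order = np.argsort(s)
    km0 = float(np.interp(vmax0 / 2, v[order], s[order])) or float(np.median(s))
    km0 = max(km0, s[s > 0].min() * 1e-2)
    converged = True
    try:
        popt, pcov, info, _, ier = optimize.curve_fit(
            _mm_velocity, s, v, p0=[vmax0, km0], maxfev=10000, full_output=True
        )
        nfev = info["nfev"]
        converged = ier in (1, 2, 3, 4)
    except RuntimeError:
        popt, pcov, nfev, converged = (
            np.array([vmax0, km0]),
            np.full((2, 2), np.inf),
            0,
            False,
        )
    kcat, km = popt
    # no curvature: KM escapes far beyond the sampled range, or negative
    if not np.isfinite(pcov).all() or km <= 0 or km > 100 * s.max():
        converged = False
        pcov = np.where(np.isfinite(pcov), pcov, 0.0)
    resid = v - _mm_velocity(s, kcat, km)
    dof = len(s) - 2
    kcat_se = float(np.sqrt(max(pcov[0, 0], 0)))
    km_se = float(np.sqrt(max(pcov[1, 1], 0)))
    ratio = kcat / km
    # delta method on kcat/KM: grad = (1/KM, -kcat/KM^2)
    g = np.array([1.0 / km, -kcat / km**2])
    ratio_var = float(g @ pcov @ g)
    mm = MichaelisParameters(
        kcat=float(kcat),
        KM=float(abs(km)),
        kcat_over_KM=float(abs(ratio)),
        kcat_se=kcat_se,
        KM_se=km_se,
        kcat_over_KM_se=float(np.sqrt(max(ratio_var, 0))),
    )
    fit = FitResult(
        params={"kcat": float(kcat), "KM": float(km)},
        covariance=pcov,
        wrss=float(resid @ resid),
        dof=dof,
        converged=bool(converged),
        nfev=int(nfev),
        flags={} if converged else {"no_curvature": True},
    )
    return mm, fit


# ---------------------------------------------------------------------------
# ODE simulation of the full scheme
# ---------------------------------------------------------------------------


def _scheme_rhs(t, y, k1, km1, k2, km2, k3, e0):
    s, es, ep, p = y
    e = e0 - es - ep
    v_bind = k1 * e * s - km1 * es
    v_chem = k2 * es - km2 * ep
    v_rel = k3 * ep
    return (-v_bind, v_bind - v_chem, v_chem - v_rel, v_rel)


def _scheme_jac(t, y, k1, km1, k2, km2, k3, e0):
    s, es, ep, p = y
    e = e0 - es - ep
    return np.array(
        [
            [-k1 * e, k1 * s + km1, k1 * s, 0],
            [k1 * e, -k1 * s - km1 - k2, -k1 * s + km2, 0],
            [0, k2, -km2 - k3, 0],
            [0, 0, k3, 0],
        ]
    )


def simulate_progress(
    params: RateConstants,
    e0: float,
    s0: float,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> tuple[ProgressCurve, np.ndarray]:
    """Integrate the scheme and return the product trace P(t).

    Returns the curve (product concentration, molar) and the full state
    trajectory as an array of rows [S, ES, EP, P] per time point (E follows
    from conservation, E = E0 - ES - EP).  A stiff-capable adaptive
    integrator is used: the binding pseudo-rate k1*S can exceed the chemical
    rates by orders of magnitude.
    """
    if e0 <= 0 or s0 < 0:
        raise KineticsError("E0 must be positive and S0 non-negative")
    times = np.asarray(times, float)
    if times.ndim != 1 or times[0] != 0 or np.any(np.diff(times) <= 0):
        raise KineticsError("times must be strictly increasing from 0")
    k = params
    sol = solve_ivp(
        _scheme_rhs,
        (0.0, float(times[-1])),
        [s0, 0.0, 0.0, 0.0],
        t_eval=times,
        method="LSODA",
        jac=_scheme_jac,
        args=(k.k1, k.k_minus1, k.k2, k.k_minus2, k.k3, e0),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.isfinite(sol.y).all():
        raise KineticsError(f"ODE integration failed: {sol.message}")
    states = sol.y.T.copy()
    curve = ProgressCurve(
        time=times.copy(),
        trace=states[:, 3],
        s0=s0,
        e0=e0,
        units="molar",
    )
    return curve, states


# ---------------------------------------------------------------------------
# Global progress-curve fitting
# ---------------------------------------------------------------------------

_LOG_BOUNDS = (
    (2.0, 9.0),  # log10 k1 (/M/s)
    (-3.0, 5.0),  # log10 k_minus1
    (-3.0, 5.0),  # log10 k2
    (-3.0, 5.0),  # log10 k_minus2
    (-3.0, 5.0),  # log10 k3
)


def _weighted_residuals(logk, curves, sds):
    k = RateConstants.from_array(10.0**logk)
    out = []
    for curve, sd in zip(curves, sds):
        try:
            model, _ = simulate_progress(
                k, curve.e0, curve.s0, curve.time, rtol=1e-8, atol=1e-12
            )
        except KineticsError:
            out.append(np.full(curve.trace.shape, 1e6))
            continue
        out.append((model.trace - curve.trace) / sd)
    return np.concatenate(out)


def fit_progress_curves(
    curves: list[ProgressCurve],
    start: RateConstants | None = None,
    n_starts: int = 8,
    seed: int | None = 0,
    sd_floor_frac: float = 1e-3,
) -> tuple[RateConstants, FitResult]:
    """Global weighted least-squares fit of the scheme to progress curves.

    Chi-square sum((model-data)/SD)^2 over all curves is minimised with a
    trust-region least-squares optimiser on log10-transformed rate constants,
    with seeded multi-start (default 8 starts) against local minima; starts
    after the first stop early once a start reaches reduced chi-square <= 1.2.
    The covariance is estimated in log-space and mapped back to the natural
    scale.  Elementary constants whose quadratic likelihood profile changes
    chi-square by < 2 within +-1 log10 unit are flagged non-identifiable;
    only the derived steady-state parameters are guaranteed deliverables.
    """
    if len(curves) < 2 or len({c.s0 for c in curves}) < 2:
        raise KineticsError("need >= 2 curves at distinct S0")
    for c in curves:
        if c.units != "molar":
            raise KineticsError("progress curves must be in molar units")
    sds = []
    for c in curves:
        rng_span = float(np.ptp(c.trace)) or 1.0
        floor = sd_floor_frac * rng_span
        if c.sd is None:
            raise KineticsError("per-point SD required for weighting")
        sd = c.sd.copy()
        if np.any(sd < floor):
            warnings.warn(
                f"SD values below floor {floor:.3g} replaced (curve S0={c.s0:g})"
            )
            sd = np.maximum(sd, floor)
        sds.append(sd)

    rng = np.random.default_rng(seed)
    if start is None:
        start = RateConstants(1e6, 100.0, 10.0, 1.0, 10.0)
    starts = [np.log10(start.as_array())]
    lo = np.array([b[0] for b in _LOG_BOUNDS])
    hi = np.array([b[1] for b in _LOG_BOUNDS])
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.uniform(-1.5, 1.5, size=5)
        starts.append(np.clip(starts[0] + jitter, lo, hi))

    n_data = sum(len(c.trace) for c in curves)
    dof = max(n_data - 5, 1)
    best = None
    nfev = 0
    for x0 in starts:
        res = optimize.least_squares(
            _weighted_residuals,
            x0,
            args=(curves, sds),
            bounds=(lo, hi),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
        )
        nfev += res.nfev
        if best is None or res.cost < best.cost:
            best = res
        if 2 * best.cost / dof <= 1.2:
            break

    chi2 = 2 * best.cost
    logk = best.x
    k_nat = 10.0**logk
    # covariance in log10-space from a central-difference Jacobian with a
    # fixed 1e-3 log10 step: the optimizer's ~1e-8 steps sit below the ODE
    # solver's noise floor and would fake curvature along flat directions.
    # Inversion is by eigendecomposition with a tiny relative floor so
    # nearly-flat directions keep their (huge) variance.
    h = 1e-3
    cols = []
    for i in range(5):
        xp, xm = logk.copy(), logk.copy()
        xp[i] += h
        xm[i] -= h
        cols.append(
            (_weighted_residuals(xp, curves, sds)
             - _weighted_residuals(xm, curves, sds)) / (2 * h)
        )
    J = np.column_stack(cols)
    JTJ = J.T @ J
    lam, V = linalg.eigh((JTJ + JTJ.T) / 2)
    lam = np.maximum(lam, max(lam.max(), 1.0) * 1e-14)
    cov_log = (V / lam) @ V.T
    # scale by reduced chi-square so SEs reflect actual residual scatter
    red = max(chi2 / dof, 1e-30)
    cov_log = cov_log * red
    # Var(log10 k) -> Var(k): dk/dlog10k = k ln10
    scale = k_nat * np.log(10.0)
    cov_nat = cov_log * np.outer(scale, scale)
    # quadratic profile proxy: moving log10 k_i by +-1 with the rest
    # re-optimised changes chi2 by ~ 1/Var(log10 k_i)
    flat = {}
    for i, name in enumerate(RateConstants.names):
        var_i = cov_log[i, i] / red if red > 0 else np.inf
        d_chi2 = 1.0 / var_i if var_i > 0 else np.inf
        flat[name] = bool(d_chi2 < 2.0)
    converged = bool(best.status > 0)
    fit = FitResult(
        params=dict(zip(RateConstants.names, map(float, k_nat))),
        covariance=cov_nat,
        wrss=float(chi2),
        dof=dof,
        converged=converged,
        nfev=int(nfev),
        flags={
            "non_identifiable": [n for n, f in flat.items() if f],
            "log10_covariance": cov_log,
        },
    )
    return RateConstants.from_array(k_nat), fit


# ---------------------------------------------------------------------------
# Steady-state algebra and uncertainty propagation
# ---------------------------------------------------------------------------


def _steady_state_values(k: np.ndarray) -> np.ndarray:
    k1, km1, k2, km2, k3 = k
    kcat = k2 * k3 / (k2 + km2 + k3)
    kcat_over_km = k1 * k2 * k3 / (k2 * k3 + km1 * (km2 + k3))
    km = kcat / kcat_over_km
    return np.array([kcat, km, kcat_over_km])


def derive_steady_state(
    params: RateConstants,
    covariance: np.ndarray | None = None,
    method: str = "delta",
    n_mc: int = 10000,
    seed: int | None = None,
) -> MichaelisParameters:
    """Steady-state parameters from elementary constants, with uncertainty.

    kcat = k2*k3/(k2+k-2+k3); kcat/KM = k1*k2*k3/(k2*k3 + k-1*(k-2+k3));
    KM = kcat/(kcat/KM).  Uncertainties propagate from the rate-constant
    covariance by the delta method (default) or by Monte-Carlo resampling of
    the constants from a multivariate normal (``method='mc'``, seeded).
    """
    kvec = params.as_array()
    vals = _steady_state_values(kvec)
    ses = np.full(3, np.nan)
    if covariance is not None:
        cov = np.asarray(covariance, float)
        if cov.shape != (5, 5):
            raise KineticsError("covariance must be 5x5")
        if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
            raise KineticsError("covariance must be symmetric")
        eig = np.linalg.eigvalsh((cov + cov.T) / 2)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise KineticsError("covariance not positive semi-definite")
        if method == "delta":
            # central-difference gradient of each derived parameter
            G = np.zeros((3, 5))
            for j in range(5):
                h = 1e-6 * kvec[j]
                kp, km_ = kvec.copy(), kvec.copy()
                kp[j] += h
                km_[j] -= h
                G[:, j] = (_steady_state_values(kp) - _steady_state_values(km_)) / (
                    2 * h
                )
            var = np.einsum("ij,jk,ik->i", G, cov, G)
            ses = np.sqrt(np.maximum(var, 0.0))
        elif method == "mc":
            rng = np.random.default_rng(seed)
            draws = rng.multivariate_normal(kvec, cov, size=n_mc)
            ok = (draws[:, [0, 2, 4]] > 0).all(axis=1) & (
                draws[:, [1, 3]] >= 0
            ).all(axis=1)
            draws = draws[ok]
            if len(draws) < 2:
                raise KineticsError("Monte-Carlo resampling produced no valid draws")
            samples = np.array([_steady_state_values(d) for d in draws])
            ses = samples.std(axis=0, ddof=1)
        else:
            raise KineticsError(f"unknown method {method!r}")
    return MichaelisParameters(
        kcat=float(vals[0]),
        KM=float(vals[1]),
        kcat_over_KM=float(vals[2]),
        kcat_se=float(ses[0]),
        KM_se=float(ses[1]),
        kcat_over_KM_se=float(ses[2]),
    )
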