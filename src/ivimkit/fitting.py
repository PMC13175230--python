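"""Consensus IVIM fitting routines.

Three estimators are provided, per current community recommendations:

* :func:`fit_loglinear_wlls` — iterative weighted linear least squares (WLLS)
  of the log-signal against b, the recommended high-b mono-exponential step.
* :func:`segmented_fit` — the two-step ("segmented") estimator: D and the
  b=0 intercept from the high-b WLLS, f from the intercept deficit relative
  to the measured b=0 signal, then D* from a constrained nonlinear fit of the
  full biexponential with D (and, in the default variant, also f and S0)
  frozen.  D* is initialised at 10 * D.
* :func:`full_nlls_fit` — simultaneous bounded nonlinear least squares over
  all four parameters (S0, f, D, D*).

Segmented fitting assumes Dstar >> D; a finite pseudo-diffusion component
above the threshold produces a small positive bias in D and negative bias in
f, which shrinks as Dstar * b_threshold grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .signal import IVIMParams, ivim_jacobian, ivim_signal

__all__ = [
    "FitOptions",
    "FitResult",
    "fit_loglinear_wlls",
    "segmented_fit",
    "full_nlls_fit",
]

#: Default parameter bounds; generous enough to cover every organ preset.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "f": (0.0, 1.0),
    "D": (1e-5, 5e-3),
    "Dstar": (1e-5, 0.5),  # lower bound tightened to D at fit time
    "S0": (1e-12, np.inf),  # upper set to 2 * max(signal) at fit time
}

METHODS = ("segmented_fix_df", "segmented_refit_f", "full_nlls")


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the segmented / nonlinear fitting routines.

    b_threshold is in s/mm**2 (200 for most organs, 300 for brain);
    dstar_init_multiplier sets the D* initial guess as a multiple of the
    fitted D (recommended 10).
    """

    method: str = "segmented_fix_df"
    b_threshold: float = 200.0
    wlls_iterations: int = 2
    dstar_init_multiplier: float = 10.0
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.b_threshold < 0:
            raise ValueError("b_threshold must be >= 0")
        if self.wlls_iterations < 1:
            raise ValueError("wlls_iterations must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name!r} must satisfy low < high")
        flo, fhi = self.bounds.get("f", (0.0, 1.0))
        if flo < 0 or fhi > 1:
            raise ValueError("f bounds must lie within [0, 1]")


@dataclass
class FitResult:
    """Outcome of a single-curve IVIM fit."""

    params: IVIMParams
    converged: dict[str, bool]
    rss: float
    options: FitOptions | None = None
    flags: tuple[str, ...] = ()
    #: high-b intercept from the WLLS step (segmented methods only)
    intercept: float | None = None

    @property
    def dstar_defined(self) -> bool:
        return "f_clipped_to_zero" not in self.flags


def fit_loglinear_wlls(bvalues, signals, iterations: int = 2, initial_weights=None):
    """Iteratively weighted linear regression of ln(S) on b.

    Weights equal the squared model-predicted signals (the correct first-order
    weighting for log-transformed data with additive noise): the first pass
    uses the observed signals (or ``initial_weights`` if given), each further
    iteration refreshes the weights from the fitted values.  Returns
    ``(D, intercept)`` where D is the decay rate (mm**2/s; the fitted slope of
    -ln S against b) and intercept the extrapolated signal at b = 0.

    Non-positive signals are excluded with a warning (the log is undefined
    there); at least two usable samples at distinct b are required.
    """
    b = np.asarray(bvalues, dtype=float)
    s = np.asarray(signals, dtype=float)
    if b.shape != s.shape:
        raise ValueError("bvalues and signals must have the same length")
    ok = s > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} non-positive signal sample(s) from WLLS",
            stacklevel=2,
        )
        b, s = b[ok], s[ok]
        if initial_weights is not None:
            initial_weights = np.asarray(initial_weights, dtype=float)[ok]
    if np.unique(b).size < 2:
        raise ValueError("WLLS requires at least 2 samples at distinct b-values")

    y = np.log(s)
    X = np.column_stack([np.ones_like(b), -b])
    w = s**2 if initial_weights is None else np.asarray(initial_weights, dtype=float)
    for _ in range(int(iterations)):
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
        w = np.exp(coef[0] - coef[1] * b) ** 2
    intercept = float(np.exp(coef[0]))
    D = float(coef[1])
    return D, intercept


def _bounds_arrays(options: FitOptions, smax: float):
    lo_f, hi_f = options.bounds["f"]
    lo_d, hi_d = options.bounds["D"]
    lo_ds, hi_ds = options.bounds["Dstar"]
    lo_s, hi_s = options.bounds["S0"]
    if not np.isfinite(hi_s):
        hi_s = 2.0 * smax
    return (lo_s, lo_f, lo_d, lo_ds), (hi_s, hi_f, hi_d, hi_ds)


def _clip(x, lo, hi):
    return float(min(max(x, lo), hi))


def segmented_fit(bvalues, signals, options: FitOptions | None = None) -> FitResult:
    """Two-step segmented IVIM fit.

    Step 1: WLLS on b >= b_threshold yields D and the b=0 intercept;
    f = 1 - intercept / mean(signal at b = 0).  Step 2: nonlinear least
    squares of the full biexponential over all b with D frozen — and, for the
    ``segmented_fix_df`` method, f frozen and S0 fixed to the measured mean
    b=0 signal, leaving D* as the single free parameter.  The
    ``segmented_refit_f`` variant re-solves f jointly with D* and S0.

    A negative f estimate is clipped to 0 and flagged; D* is then undefined
    (the fast compartment is absent) and step 2 is skipped.
    """
    if options is None:
        options = FitOptions()
    b = np.asarray(bvalues, dtype=float)
    s = np.asarray(signals, dtype=float)
    bt = options.b_threshold

    high = b >= bt
    if np.unique(b[high]).size < 2:
        raise ValueError(
            f"segmented fit needs >= 2 distinct b-values at or above the "
            f"threshold {bt}; got {np.unique(b[high]).size}"
        )
    at_zero = b == 0
    if not at_zero.any():
        raise ValueError("segmented fit requires at least one b = 0 measurement")
    if not ((b > 0) & (b < bt)).any():
        raise ValueError(
            f"segmented fit requires at least one b-value in (0, {bt}) "
            "to inform the pseudo-diffusion component"
        )

    D, intercept = fit_loglinear_wlls(b[high], s[high], options.wlls_iterations)
    s0_meas = float(s[at_zero].mean())
    f = 1.0 - intercept / s0_meas

    flags: list[str] = []
    lo, hi = _bounds_arrays(options, float(s.max()))
    D = _clip(D, lo[2], hi[2])
    if f < 0:
        flags.append("f_clipped_to_zero")
        params = IVIMParams(f=0.0, D=D, Dstar=hi[3], S0=s0_meas)
        return FitResult(
            params=params,
            converged={"D": True, "f": True, "Dstar": False, "S0": True},
            rss=float(np.sum((ivim_signal(params, b) - s) ** 2)),
            options=options,
            flags=tuple(flags),
            intercept=intercept,
        )
    f = _clip(f, lo[1], hi[1])

    dstar0 = _clip(options.dstar_init_multiplier * D, max(lo[3], D), hi[3])
    converged = {"D": True, "f": True, "S0": True, "Dstar": True}

    if options.method == "segmented_refit_f":
        # free: S0, f, Dstar; frozen: D
        def resid(x):
            s0x, fx, dsx = x
            p = IVIMParams(f=fx, D=D, Dstar=dsx, S0=s0x)
            return ivim_signal(p, b) - s

        def jac(x):
            s0x, fx, dsx = x
            p = IVIMParams(f=fx, D=D, Dstar=dsx, S0=s0x)
            return ivim_jacobian(p, b)[:, [0, 1, 3]]

        x0 = [s0_meas, f, dstar0]
        lbs = [lo[0], lo[1], max(lo[3], D)]
        ubs = [hi[0], hi[1], hi[3]]
        sol = least_squares(resid, x0, jac=jac, bounds=(lbs, ubs), x_scale=np.abs(x0))
        s0_fit, f_fit, dstar = sol.x
        if not sol.success:
            flags.append("step2_not_converged")
            converged = {"D": True, "f": False, "S0": False, "Dstar": False}
            s0_fit, f_fit, dstar = x0
        params = IVIMParams(f=float(f_fit), D=D, Dstar=float(dstar), S0=float(s0_fit))
        rss = float(np.sum(resid([s0_fit, f_fit, dstar]) ** 2))
    else:  # segmented_fix_df
        # single free parameter Dstar; D, f frozen, S0 = measured b=0 mean
        def resid1(x):
            p = IVIMParams(f=f, D=D, Dstar=x[0], S0=s0_meas)
            return ivim_signal(p, b) - s

        def jac1(x):
            p = IVIMParams(f=f, D=D, Dstar=x[0], S0=s0_meas)
            return ivim_jacobian(p, b)[:, [3]]

        sol = least_squares(
            resid1, [dstar0], jac=jac1,
            bounds=([max(lo[3], D)], [hi[3]]), x_scale=[dstar0],
        )
        dstar = float(sol.x[0])
        if not sol.success:
            flags.append("step2_not_converged")
            converged["Dstar"] = False
            dstar = dstar0
        params = IVIMParams(f=f, D=D, Dstar=dstar, S0=s0_meas)
        rss = float(np.sum(resid1([dstar]) ** 2))

    return FitResult(
        params=params, converged=converged, rss=rss,
        options=options, flags=tuple(flags), intercept=intercept,
    )


def full_nlls_fit(
    bvalues,
    signals,
    init: IVIMParams | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Simultaneous bounded nonlinear least squares over (S0, f, D, D*).

    With four free parameters at least four distinct b-values are required.
    When no explicit initial guess is supplied, the segmented fit provides it
    (falling back to a generic guess if the b-set lacks the structure the
    segmented fit needs).
    """
    if options is None:
        options = FitOptions(method="full_nlls")
    b = np.asarray(bvalues, dtype=float)
    s = np.asarray(signals, dtype=float)
    if np.unique(b).size < 4:
        raise ValueError(
            f"full NLLS needs >= 4 distinct b-values for 4 free parameters; "
            f"got {np.unique(b).size}"
        )
    lo, hi = _bounds_arrays(options, float(s.max()))

    if init is None:
        try:
            init = segmented_fit(b, s, replace(options, method="segmented_fix_df")).params
        except ValueError:
            smax = float(s.max())
            init = IVIMParams(f=0.1, D=1e-3, Dstar=1e-2, S0=smax)
    x0 = np.clip(init.as_array(), np.array(lo) * (1 + 1e-12), hi)
    # keep Dstar init strictly inside its box
    x0[3] = min(max(x0[3], lo[3] * 1.01), hi[3] * 0.99)

    def resid(x):
        return ivim_signal(IVIMParams.from_array(x), b) - s

    def jac(x):
        return ivim_jacobian(IVIMParams.from_array(x), b)

    sol = least_squares(
        resid, x0, jac=jac, bounds=(lo, hi),
        x_scale=np.maximum(np.abs(x0), 1e-8), xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    flags: tuple[str, ...] = ()
    if sol.success:
        params = IVIMParams.from_array(sol.x)
        conv = dict.fromkeys(("S0", "f", "D", "Dstar"), True)
        rss = float(2 * sol.cost)
    else:
        params = init
        conv = dict.fromkeys(("S0", "f", "D", "Dstar"), False)
        flags = ("not_converged",)
        rss = float(np.sum(resid(x0) ** 2))
    return FitResult(params=params, converged=conv, rss=rss, options=options, flags=flags)
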