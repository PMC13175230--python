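"""Model/Results interface over the IVIM estimators.

``IVIMModel`` binds one decay curve (b-values and signals, e.g. an
ROI-averaged trace) and ``fit()`` returns :class:`IVIMFitResults` carrying
the estimates, CRLB-based standard errors at the observed residual noise
level, diagnostics and a ``summary()`` table — the workflow familiar from
statsmodels estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crlb import crlb_uncertainties
from .fitting import FitOptions, FitResult, full_nlls_fit, segmented_fit
from .signal import IVIMParams, ivim_signal

__all__ = ["IVIMModel", "IVIMFitResults"]


class IVIMModel:
    """Biexponential IVIM model bound to a single signal-decay curve.

    Parameters
    ----------
    bvalues : array-like
        Diffusion weightings in s/mm**2 (repeats allowed).
    signals : array-like
        Measured (trace-weighted) signal per b-value, same length.
    """

    def __init__(self, bvalues, signals):
        self.bvalues = np.asarray(bvalues, dtype=float)
        self.signals = np.asarray(signals, dtype=float)
        if self.bvalues.shape != self.signals.shape:
            raise ValueError("bvalues and signals must have equal length")
        if (self.bvalues < 0).any():
            raise ValueError("b-values must be >= 0")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, b_col: str = "b", signal_col: str = "signal"):
        return cls(df[b_col].to_numpy(), df[signal_col].to_numpy())

    def predict(self, params: IVIMParams, bvalues=None) -> np.ndarray:
        b = self.bvalues if bvalues is None else bvalues
        return ivim_signal(params, b)

    def fit(self, method: str = "segmented_fix_df", options: FitOptions | None = None,
            **kwargs) -> "IVIMFitResults":
        """Fit the curve and return results.

        ``method`` is one of ``segmented_fix_df`` (recommended: D and f
        frozen from the high-b step), ``segmented_refit_f`` or ``full_nlls``.
        Extra keyword arguments are forwarded to :class:`FitOptions`.
        """
        if options is None:
            options = FitOptions(method=method, **kwargs)
        if options.method == "full_nlls":
            raw = full_nlls_fit(self.bvalues, self.signals, options=options)
        else:
            raw = segmented_fit(self.bvalues, self.signals, options=options)
        return IVIMFitResults(self, raw)


class IVIMFitResults:
    """Fitted IVIM parameters with uncertainties and diagnostics.

    Standard errors are CRLB predictions evaluated at the estimates with the
    noise level taken from the residual standard deviation — the asymptotic
    (Gaussian-noise) covariance of an efficient estimator, undefined when the
    fast compartment is absent (f clipped to 0) or the design is singular.
    """

    def __init__(self, model: IVIMModel, raw: FitResult):
        self.model = model
        self.raw = raw
        self.params = raw.params
        self.method = raw.options.method if raw.options else "unknown"
        self.flags = raw.flags
        n = model.bvalues.size
        self.df_resid = max(n - 4, 1)
        self.rss = raw.rss
        self.sigma_hat = float(np.sqrt(raw.rss / self.df_resid))
        self.bse = self._standard_errors()

    def _standard_errors(self) -> dict[str, float]:
        nan = dict.fromkeys(("S0", "f", "D", "Dstar"), float("nan"))
        if self.sigma_hat == 0 or not self.raw.dstar_defined:
            return nan
        p = self.params
        snr = p.S0 / self.sigma_hat
        try:
            c = crlb_uncertainties(p, self.model.bvalues, snr)
        except ValueError:
            return nan
        return {"S0": c.sigma_S0, "f": c.sigma_f, "D": c.sigma_D, "Dstar": c.sigma_Dstar}

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.signals - self.fittedvalues

    @property
    def converged(self) -> bool:
        return all(self.raw.converged.values())

    def to_frame(self) -> pd.DataFrame:
        p = self.params
        return pd.DataFrame(
            {
                "estimate": [p.S0, p.f, p.D, p.Dstar],
                "std_err": [self.bse[k] for k in ("S0", "f", "D", "Dstar")],
                "unit": ["a.u.", "", "mm^2/s", "mm^2/s"],
            },
            index=["S0", "f", "D", "Dstar"],
        )

    def summary(self) -> str:
        p = self.params
        tbl = self.to_frame()
        lines = [
            "IVIM biexponential fit",
            "=" * 54,
            f"method: {self.method}    n_obs: {self.model.bvalues.size}"
            f"    converged: {self.converged}",
            f"RSS: {self.rss:.4g}    residual sigma: {self.sigma_hat:.4g}",
        ]
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        lines.append("-" * 54)
        lines.append(f"{'param':>6} {'estimate':>12} {'std err':>12}  unit")
        for name, row in tbl.iterrows():
            lines.append(
                f"{name:>6} {row['estimate']:>12.5g} {row['std_err']:>12.4g}  {row['unit']}"
            )
        lines.append("-" * 54)
        lines.append(
            f"D x1e-3 = {p.D * 1e3:.3f}, D* x1e-3 = {p.Dstar * 1e3:.2f} mm^2/s, "
            f"f = {p.f:.3f}"
        )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Semilog decay plot of the data and fitted curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        b = self.model.bvalues
        order = np.argsort(b)
        bf = np.linspace(0, b.max(), 200)
        ax.semilogy(b[order], self.model.signals[order], "o", label="data")
        ax.semilogy(bf, ivim_signal(self.params, bf), "-", label=f"fit ({self.method})")
        ax.set_xlabel("b (s/mm$^2$)")
        ax.set_ylabel("signal")
        ax.legend()
        return ax
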