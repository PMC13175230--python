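"""Forward IVIM signal model, noise generation and scalar utilities.

The intravoxel incoherent motion (IVIM) model describes the diffusion-weighted
MRI signal of a voxel containing both Brownian water diffusion and
perfusion-driven incoherent flow as a biexponential decay,

    S(b) / S0 = f * exp(-b * Dstar) + (1 - f) * exp(-b * D),

where ``f`` is the pseudo-diffusion signal fraction, ``Dstar`` the
pseudo-diffusion coefficient of the fast (microvascular) compartment and ``D``
the tissue diffusion coefficient of the slow compartment.  Units follow the
field convention: b in s/mm**2, D and Dstar in mm**2/s (typical tissue D is
about 1e-3 mm**2/s).  ``Dstar`` is the total pseudo-diffusion coefficient; the
blood diffusivity is not modelled separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IVIMParams",
    "NoiseSpec",
    "ivim_signal",
    "ivim_jacobian",
    "add_noise",
    "t2_corrected_f",
    "suppression_bvalue",
]


@dataclass(frozen=True)
class IVIMParams:
    """The IVIM parameter set (f, D, D*) plus the b=0 scale S0.

    Parameters
    ----------
    f : float
        Pseudo-diffusion signal fraction, dimensionless in [0, 1].
    D : float
        Tissue diffusion coefficient in mm**2/s (must be > 0).
    Dstar : float
        Pseudo-diffusion coefficient in mm**2/s (must be > 0).
    S0 : float
        Signal at b = 0 in arbitrary units (must be > 0).
    """

    f: float
    D: float
    Dstar: float
    S0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.Dstar <= 0:
            raise ValueError(f"Dstar must be > 0, got {self.Dstar}")
        if self.S0 <= 0:
            raise ValueError(f"S0 must be > 0, got {self.S0}")

    @property
    def identifiable(self) -> bool:
        """True when Dstar > D, required for segmented-fit interpretation
        and for a non-singular Fisher information matrix."""
        return self.Dstar > self.D

    def as_array(self) -> np.ndarray:
        """Return (S0, f, D, Dstar) as a float array (free-parameter order)."""
        return np.array([self.S0, self.f, self.D, self.Dstar], dtype=float)

    @classmethod
    def from_array(cls, x) -> "IVIMParams":
        s0, f, d, dstar = np.asarray(x, dtype=float)
        return cls(f=float(f), D=float(d), Dstar=float(dstar), S0=float(s0))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model specification.

    SNR is defined at b = 0: the noise standard deviation is sigma = S0/snr,
    constant across b-values.  ``model`` is ``"gaussian"`` (additive) or
    ``"rician"`` (magnitude of a complex signal with independent Gaussian
    noise on both channels).
    """

    model: str = "gaussian"
    snr: float = 25.0
    seed: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "rician"):
            raise ValueError(
                f"unknown noise model {self.model!r}; expected 'gaussian' or 'rician'"
            )
        if not self.snr > 0:
            raise ValueError(f"snr must be > 0, got {self.snr}")

    def sigma(self, s0: float) -> float:
        return float(s0) / self.snr

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _check_bvalues(bvalues) -> np.ndarray:
    b = np.atleast_1d(np.asarray(bvalues, dtype=float))
    neg = np.flatnonzero(b < 0)
    if neg.size:
        raise ValueError(
            f"b-values must be >= 0; negative value {b[neg[0]]} at index {neg[0]}"
        )
    return b


def ivim_signal(params: IVIMParams, bvalues) -> np.ndarray:
    """Evaluate the biexponential IVIM signal S(b) at the given b-values.

    Returns ``S0 * (f * exp(-b*Dstar) + (1-f) * exp(-b*D))`` per b-value.
    Strictly decreasing in b whenever D > 0 and either compartment is present.
    """
    b = _check_bvalues(bvalues)
    return params.S0 * (
        params.f * np.exp(-b * params.Dstar)
        + (1.0 - params.f) * np.exp(-b * params.D)
    )


def ivim_jacobian(params: IVIMParams, bvalues) -> np.ndarray:
    """Partial derivatives of S(b) w.r.t. (S0, f, D, Dstar), shape (nb, 4).

    Used by the Fisher-information machinery and as the analytic Jacobian for
    nonlinear least squares.
    """
    b = _check_bvalues(bvalues)
    ef = np.exp(-b * params.Dstar)
    ed = np.exp(-b * params.D)
    dS0 = params.f * ef + (1.0 - params.f) * ed
    df = params.S0 * (ef - ed)
    dD = -params.S0 * (1.0 - params.f) * b * ed
    dDstar = -params.S0 * params.f * b * ef
    return np.stack([dS0, df, dD, dDstar], axis=-1)


def add_noise(signal, spec: NoiseSpec, s0: float, rng: np.random.Generator | None = None) -> np.ndarray:
    """Add Gaussian or Rician noise at sigma = s0/snr.

    Gaussian: s + eps with eps ~ N(0, sigma^2).  Rician: the magnitude
    sqrt((s + eps1)^2 + eps2^2) of a complex signal with independent Gaussian
    noise on the real and imaginary channels, which is the distribution of
    magnitude-reconstructed MRI data.  A generator may be passed explicitly
    (shared streams across conditions); otherwise one is built from
    ``spec.seed`` so a fixed seed gives identical output.
    """
    s = np.asarray(signal, dtype=float)
    sigma = spec.sigma(s0)
    if rng is None:
        rng = spec.rng()
    if sigma == 0.0:
        return s.copy()
    if spec.model == "gaussian":
        return s + rng.normal(0.0, sigma, size=s.shape)
    # rician
    real = s + rng.normal(0.0, sigma, size=s.shape)
    imag = rng.normal(0.0, sigma, size=s.shape)
    return np.hypot(real, imag)


def t2_corrected_f(f_measured: float, te: float, t2_tissue: float, t2_blood: float) -> float:
    """Convert the measured pseudo-diffusion signal fraction to a blood
    (volume) fraction by inverting two-compartment T2 relaxation weighting.

    At echo time TE the measured fraction relates to the underlying volume
    fraction f by

        f_meas = f * e1 / (f * e1 + (1 - f) * e2),

    with e1 = exp(-TE/T2_blood), e2 = exp(-TE/T2_tissue).  Solving for f:

        f = f_meas * e2 / (f_meas * e2 + (1 - f_meas) * e1).

    All T2 values and TE in ms (any consistent unit works).
    """
    if te < 0:
        raise ValueError("te must be >= 0")
    if t2_tissue <= 0 or t2_blood <= 0:
        raise ValueError("T2 values must be > 0")
    if not 0.0 <= f_measured <= 1.0:
        raise ValueError("f_measured must lie in [0, 1]")
    e_blood = np.exp(-te / t2_blood)
    e_tissue = np.exp(-te / t2_tissue)
    num = f_measured * e_tissue
    den = num + (1.0 - f_measured) * e_blood
    return float(num / den)


def suppression_bvalue(dstar: float, factor: float = 20.0) -> float:
    """b-value at which the pseudo-diffusion term is attenuated by ``factor``.

    Solves exp(-b * Dstar) = 1/factor, i.e. b = ln(factor)/Dstar; with the
    conventional factor 20 this is approximately 3/Dstar and defines the
    segmented-fit threshold above which the perfusion compartment is
    negligible.
    """
    if dstar <= 0:
        raise ValueError(f"dstar must be > 0, got {dstar}")
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    return float(np.log(factor) / dstar)
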