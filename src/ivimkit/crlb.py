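"""Cramér-Rao lower-bound (CRLB) uncertainty prediction and b-value design.

Under additive Gaussian noise with standard deviation sigma, the Fisher
information of the biexponential IVIM signal with free parameters
theta = (S0, f, D, D*) is

    I(theta) = (1/sigma^2) * sum_b  dS(b)/dtheta  dS(b)/dtheta^T,

summed over the acquired b-values (repeats contribute additively).  The CRLB
standard deviations are the square roots of the diagonal of I^-1 and scale
exactly as 1/SNR.  The design cost of a candidate b-value multiset is the sum
of the relative uncertainties in D and D* and the absolute uncertainty in f
(absolute for f to avoid divergence as f -> 0), averaged over a small prior
grid spanning the organ's literature mean +/- one standard deviation per
parameter.  Minimising this cost by exhaustive search over a rounded
candidate grid (repetition allowed, so a repeated b = 0 can win) reproduces
the consensus-style minimal b-value tiers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal import IVIMParams, ivim_jacobian

__all__ = [
    "CRLBResult",
    "DesignSpec",
    "fisher_information",
    "crlb_uncertainties",
    "design_cost",
    "grid_averaged_uncertainties",
    "optimize_bvalues",
]

_F_FLOOR = 0.01  # floor for f when building prior grids, avoids singularity


@dataclass(frozen=True)
class CRLBResult:
    """Lower-bound standard deviations for one (params, b-set, SNR) triple."""

    sigma_S0: float
    sigma_f: float
    sigma_D: float
    sigma_Dstar: float
    rel_D: float      # sigma_D / D
    rel_Dstar: float  # sigma_Dstar / Dstar
    abs_f: float      # sigma_f
    cost: float       # rel_D + rel_Dstar + abs_f

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma_S0": self.sigma_S0, "sigma_f": self.sigma_f,
            "sigma_D": self.sigma_D, "sigma_Dstar": self.sigma_Dstar,
            "rel_D": self.rel_D, "rel_Dstar": self.rel_Dstar,
            "abs_f": self.abs_f, "cost": self.cost,
        }


@dataclass(frozen=True)
class DesignSpec:
    """Specification of a b-value design problem.

    ``prior`` maps each of 'f', 'D', 'Dstar' to ``{'mean': m, 'sd': s}``;
    the evaluation grid takes ``grid_points`` equally spaced values per
    parameter across mean +/- 1 sd (default 3: mean - sd, mean, mean + sd).
    ``fixed_b`` (typically the abbreviated tier) is always part of the
    design; the optimizer fills the remaining ``n_total - len(fixed_b)``
    slots from ``candidate_b`` with repetition.
    """

    prior: dict[str, dict[str, float]]
    fixed_b: tuple[float, ...] = ()
    n_total: int = 6
    snr: float = 25.0
    candidate_b: tuple[float, ...] = field(
        default_factory=lambda: tuple(float(b) for b in range(0, 1010, 10))
    )
    grid_points: int = 3
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.n_total < len(self.fixed_b):
            raise ValueError("n_total must be >= number of fixed b-values")
        if not self.candidate_b:
            raise ValueError("candidate grid must be non-empty")
        missing = set(self.fixed_b) - set(self.candidate_b)
        if missing:
            raise ValueError(f"fixed b-values {sorted(missing)} not on the candidate grid")

    def prior_grid(self) -> list[IVIMParams]:
        """Cartesian mean±sd grid over (f, D, Dstar); f floored at 0.01."""
        axes = {}
        for name in ("f", "D", "Dstar"):
            m, s = self.prior[name]["mean"], self.prior[name]["sd"]
            vals = np.linspace(m - s, m + s, self.grid_points)
            if name == "f":
                if (vals < _F_FLOOR).any():
                    warnings.warn(
                        "prior grid f values below 0.01 floored to keep the "
                        "information matrix non-singular",
                        stacklevel=2,
                    )
                vals = np.maximum(vals, _F_FLOOR)
            elif (vals <= 0).any():
                raise ValueError(f"prior grid for {name} reaches <= 0; shrink the sd")
            axes[name] = vals
        return [
            IVIMParams(f=float(fv), D=float(dv), Dstar=float(sv), S0=self.s0)
            for fv, dv, sv in itertools.product(axes["f"], axes["D"], axes["Dstar"])
        ]


def fisher_information(params: IVIMParams, bvalues, sigma: float) -> np.ndarray:
    """4x4 Gaussian-noise Fisher information over (S0, f, D, Dstar).

    Repeated b-values contribute additively.  Raises on structurally singular
    designs: f = 0 (no fast compartment, dS/dDstar vanishes identically),
    D = Dstar (compartments indistinguishable) or fewer than 4 distinct
    b-values.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    b = np.atleast_1d(np.asarray(bvalues, dtype=float))
    if params.f <= 0 or params.f >= 1:
        raise ValueError(
            f"singular design: f = {params.f} makes a compartment's "
            "sensitivity vanish identically"
        )
    if params.D == params.Dstar:
        raise ValueError("singular design: D == Dstar, compartments indistinguishable")
    if np.unique(b).size < 4:
        raise ValueError(
            f"singular design: {np.unique(b).size} distinct b-values < 4 free parameters"
        )
    J = ivim_jacobian(params, b)  # (nb, 4)
    return (J.T @ J) / sigma**2


def crlb_uncertainties(params: IVIMParams, bvalues, snr: float) -> CRLBResult:
    """CRLB standard deviations at sigma = S0/snr, plus the scalar cost."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    sigma = params.S0 / snr
    info = fisher_information(params, bvalues, sigma)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"information matrix is singular: {err}") from err
    sd = np.sqrt(np.diag(cov))
    rel_D = float(sd[2] / params.D)
    rel_Dstar = float(sd[3] / params.Dstar)
    abs_f = float(sd[1])
    return CRLBResult(
        sigma_S0=float(sd[0]), sigma_f=abs_f, sigma_D=float(sd[2]),
        sigma_Dstar=float(sd[3]), rel_D=rel_D, rel_Dstar=rel_Dstar,
        abs_f=abs_f, cost=rel_D + rel_Dstar + abs_f,
    )


def _grid_jacobians(grid: list[IVIMParams], candidates: np.ndarray) -> np.ndarray:
    """Per prior point, per candidate b: outer products of the signal
    gradient, shape (n_grid, n_candidates, 4, 4)."""
    out = np.empty((len(grid), candidates.size, 4, 4))
    for gi, p in enumerate(grid):
        J = ivim_jacobian(p, candidates)  # (nc, 4)
        out[gi] = J[:, :, None] * J[:, None, :]
    return out


def design_cost(bvalues, spec: DesignSpec, grid: list[IVIMParams] | None = None) -> float:
    """Mean over the prior grid of [sigma_D/D + sigma_Dstar/Dstar + sigma_f]
    for the given b-value multiset at the spec's SNR.  Order-invariant."""
    if grid is None:
        grid = spec.prior_grid()
    costs = [crlb_uncertainties(p, bvalues, spec.snr).cost for p in grid]
    return float(np.mean(costs))


def grid_averaged_uncertainties(bvalues, spec: DesignSpec) -> dict[str, float]:
    """Grid-averaged per-parameter uncertainties for a b-set: relative for
    D and D*, both absolute and relative for f, plus the scalar cost."""
    grid = spec.prior_grid()
    res = [crlb_uncertainties(p, bvalues, spec.snr) for p in grid]
    return {
        "rel_D": float(np.mean([r.rel_D for r in res])),
        "rel_Dstar": float(np.mean([r.rel_Dstar for r in res])),
        "abs_f": float(np.mean([r.abs_f for r in res])),
        "rel_f": float(np.mean([r.abs_f / p.f for r, p in zip(res, grid)])),
        "cost": float(np.mean([r.cost for r in res])),
    }


def optimize_bvalues(spec: DesignSpec, chunk_size: int = 20000):
    """Exhaustive search for the b-value multiset minimising the design cost.

    Enumerates all combinations-with-repetition of the free slots over the
    candidate grid (the fixed set is always included), computing the CRLB
    cost fully vectorised per prior point.  Deterministic: ties are broken by
    the lexicographically smallest sorted multiset, independent of
    enumeration order.

    Returns ``(bvalues, mean_cost)`` where ``bvalues`` is the sorted optimal
    multiset.
    """
    n_free = spec.n_total - len(spec.fixed_b)
    grid = spec.prior_grid()
    if n_free == 0:
        try:
            cost = design_cost(spec.fixed_b, spec, grid)
        except ValueError:  # e.g. a 3-value tier: singular for 4 parameters
            cost = float("inf")
        return tuple(sorted(spec.fixed_b)), cost

    cand = np.asarray(spec.candidate_b, dtype=float)
    outer = _grid_jacobians(grid, cand)  # (ng, nc, 4, 4)
    fixed = np.asarray(spec.fixed_b, dtype=float)
    base = np.zeros((len(grid), 4, 4))
    for gi, p in enumerate(grid):
        if fixed.size:
            J = ivim_jacobian(p, fixed)
            base[gi] = J.T @ J

    combos = np.array(
        list(itertools.combinations_with_replacement(range(cand.size), n_free)),
        dtype=np.intp,
    )  # (ncomb, n_free)
    ncomb = combos.shape[0]
    total_cost = np.zeros(ncomb)
    valid = np.ones(ncomb, dtype=bool)
    sigma = spec.s0 / spec.snr

    for gi, p in enumerate(grid):
        for start in range(0, ncomb, chunk_size):
            idx = combos[start:start + chunk_size]
            info = base[gi] + outer[gi][idx].sum(axis=1)  # (chunk, 4, 4)
            info = info / sigma**2
            with np.errstate(invalid="ignore"):
                sign, logdet = np.linalg.slogdet(info)
            ok = (sign > 0) & np.isfinite(logdet)
            cov_diag = np.full((idx.shape[0], 4), np.inf)
            if ok.any():
                cov = np.linalg.inv(info[ok])
                cov_diag[ok] = np.einsum("kii->ki", cov)
            sd = np.sqrt(np.maximum(cov_diag, 0.0))
            cost = sd[:, 1] + sd[:, 2] / p.D + sd[:, 3] / p.Dstar
            total_cost[start:start + chunk_size] += cost
            valid[start:start + chunk_size] &= ok

    total_cost[~valid] = np.inf
    if not np.isfinite(total_cost).any():
        raise ValueError("no feasible design on the candidate grid (all singular)")
    mean_cost = total_cost / len(grid)
    best = float(mean_cost.min())
    # deterministic tie-break: lexicographically smallest sorted multiset
    tied = np.flatnonzero(mean_cost <= best * (1 + 1e-12))
    tied_sets = sorted(
        tuple(sorted(np.concatenate([fixed, cand[combos[i]]]).tolist()))
        for i in tied
    )
    return tied_sets[0], best
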