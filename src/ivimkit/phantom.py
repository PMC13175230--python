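"""Digital IVIM phantoms and ROI statistics.

A phantom is a small 4D series whose per-voxel ground-truth parameters are
drawn from an organ preset's literature prior (truncated to valid ranges),
passed through the biexponential forward model, and degraded with Gaussian
or Rician noise at a stated SNR — the simulation substrate on which fitting
pipelines are validated end to end, with the truth maps as oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dwi import DWISeries
from .presets import OrganPreset
from .signal import NoiseSpec

__all__ = ["PhantomTruth", "generate_phantom", "roi_stats"]

# truncation ranges keeping drawn parameters physically valid
_TRUNC = {"f": (0.01, 0.7), "D": (2e-4, 4e-3), "Dstar": (3e-3, 0.3)}


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    maps: dict[str, np.ndarray]  # per-voxel f, D, Dstar, S0
    labels: np.ndarray           # ROI label map (0 = background)
    noise: NoiseSpec
    organ: str
    tier: str


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw-until-accepted truncated normal; sd = 0 collapses to the mean."""
    lo = min(lo, mean)
    hi = max(hi, mean)
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_phantom(
    preset: OrganPreset,
    shape: tuple[int, int, int] = (10, 10, 5),
    labels: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(model="rician", snr=50, seed=0),
    tier: str = "minimal",
    n_directions: int = 0,
    s0: float = 1000.0,
    prior_spread: float = 0.5,
) -> tuple[DWISeries, PhantomTruth]:
    """Generate a seeded digital phantom for an organ preset.

    Per-voxel (f, D, D*) inside labelled ROIs are drawn from the preset prior
    with standard deviations scaled by ``prior_spread`` (within-organ spread
    is smaller than the between-study literature spread) and truncated to
    valid ranges; the b-table is the preset tier's set.  With
    ``n_directions = 3``, each b > 0 is acquired along three orthogonal axes
    (three volumes); the signal model is isotropic so direction volumes
    differ only by their noise.  Background voxels are signal-free (pure
    noise under the Rician model).  Fixed seed => bit-identical phantom.
    """
    if labels is None:
        # one-voxel background rim along axes long enough to afford one
        labels = np.zeros(shape, dtype=int)
        sl = tuple(slice(1, n - 1) if n > 2 else slice(0, n) for n in shape)
        labels[sl] = 1
    labels = np.asarray(labels, dtype=int)
    shape = labels.shape
    rng = noise.rng()

    bset = preset.bvalues(tier)
    bvalues, directions = [], []
    axes = np.eye(3)
    for b in bset:
        if n_directions and b > 0:
            for k in range(n_directions):
                bvalues.append(b)
                directions.append(axes[k % 3])
        else:
            bvalues.append(b)
            directions.append(np.zeros(3))
    bvalues = np.array(bvalues, dtype=float)
    directions = np.array(directions) if n_directions else None

    maps = {k: np.zeros(shape) for k in ("f", "D", "Dstar", "S0")}
    inside = labels > 0
    n_in = int(inside.sum())
    for name in ("f", "D", "Dstar"):
        m = preset.prior[name]["mean"]
        sd = preset.prior[name]["sd"] * prior_spread
        lo, hi = _TRUNC[name]
        maps[name][inside] = _truncated_normal(rng, m, sd, lo, hi, n_in)
    maps["S0"][inside] = s0

    data = np.zeros(shape + (bvalues.size,))
    fv = maps["f"][inside][:, None]
    dv = maps["D"][inside][:, None]
    sv = maps["Dstar"][inside][:, None]
    clean = s0 * (fv * np.exp(-bvalues * sv) + (1 - fv) * np.exp(-bvalues * dv))
    sigma = noise.sigma(s0)
    if sigma == 0:
        noisy = clean
        bg = np.zeros((int((~inside).sum()), bvalues.size))
    else:
        if noise.model == "gaussian":
            noisy = clean + rng.normal(0, sigma, clean.shape)
            bg = np.zeros((int((~inside).sum()), bvalues.size))
        else:
            noisy = np.hypot(clean + rng.normal(0, sigma, clean.shape),
                             rng.normal(0, sigma, clean.shape))
            bg = np.hypot(rng.normal(0, sigma, (int((~inside).sum()), bvalues.size)),
                          rng.normal(0, sigma, (int((~inside).sum()), bvalues.size)))
    data[inside] = np.maximum(noisy, 0.0)
    data[~inside] = np.maximum(bg, 0.0)

    series = DWISeries(
        data=data, bvalues=bvalues, directions=directions, mask=inside.copy()
    )
    truth = PhantomTruth(maps=maps, labels=labels, noise=noise,
                         organ=preset.organ, tier=tier)
    return series, truth


def roi_stats(
    maps: dict[str, np.ndarray],
    labels: np.ndarray,
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-ROI, per-parameter mean, SD, median and interquartile range.

    ``valid`` optionally masks out flagged voxels (failed fits).  Quantiles
    use linear interpolation (IQR = Q3 - Q1), so values are comparable across
    implementations.  Empty labels are omitted with a warning.  Returns a
    tidy DataFrame indexed by (roi, parameter).
    """
    import warnings

    labels = np.asarray(labels, dtype=int)
    rows = []
    for roi in sorted(np.unique(labels[labels > 0])):
        sel = labels == roi
        if valid is not None:
            sel = sel & valid
        if not sel.any():
            warnings.warn(f"ROI {roi} has no valid voxels; omitted", stacklevel=2)
            continue
        for name, arr in maps.items():
            vals = np.asarray(arr)[sel].astype(float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
            rows.append({
                "roi": int(roi), "parameter": name,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "median": float(med), "iqr": float(q3 - q1),
                "n_voxels": int(vals.size),
            })
    return pd.DataFrame(rows).set_index(["roi", "parameter"]) if rows else pd.DataFrame(
        columns=["roi", "parameter", "mean", "sd", "median", "iqr", "n_voxels"]
    ).set_index(["roi", "parameter"])
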