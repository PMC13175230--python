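"""Voxelwise fitting of 4D DWI series.

Direction volumes acquired at the same b are first collapsed to a
rotation-invariant trace-weighted signal by geometric mean (equivalently the
arithmetic mean of log-signals, matching the log-linear structure of the
fits); excluded volumes are dropped; then the chosen estimator runs per
voxel inside the mask, producing parameter maps plus a fit-flag map.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .dwi import DWISeries
from .fitting import FitOptions, full_nlls_fit, segmented_fit
from .presets import OrganPreset

__all__ = ["collapse_directions", "fit_volume", "MISSING"]

log = logging.getLogger(__name__)

#: map value for voxels that were not fitted (outside mask or flagged)
MISSING = -1.0


def collapse_directions(series: DWISeries) -> tuple[np.ndarray, np.ndarray]:
    """Collapse direction volumes to trace-weighted signals.

    Returns ``(data, bvalues)`` where, per b-value, all kept volumes with a
    non-zero direction vector are combined by voxelwise geometric mean into
    one trace volume; volumes without directions (b = 0 repeats, or series
    lacking a .bvec) pass through unchanged.  Excluded volumes are dropped
    first; if all volumes at some b are excluded that b disappears with a
    warning.
    """
    keep = series.kept_indices()
    if keep.size < series.n_volumes:
        gone = sorted(set(range(series.n_volumes)) - set(keep.tolist()))
        dropped_b = sorted(
            set(series.bvalues.tolist()) - set(series.bvalues[keep].tolist())
        )
        if dropped_b:
            warnings.warn(
                f"all volumes at b = {dropped_b} excluded; those b-values are dropped",
                stacklevel=2,
            )
        log.info("dropping excluded volumes %s", gone)
    data = series.data[..., keep]
    bvals = series.bvalues[keep]
    if series.directions is None:
        return data, bvals
    dirs = series.directions[keep]
    has_dir = np.linalg.norm(dirs, axis=1) > 0

    out_vols, out_b = [], []
    done = np.zeros(bvals.size, dtype=bool)
    for i in range(bvals.size):
        if done[i]:
            continue
        if not has_dir[i]:
            out_vols.append(data[..., i])
            out_b.append(bvals[i])
            done[i] = True
            continue
        group = np.flatnonzero((bvals == bvals[i]) & has_dir & ~done)
        # geometric mean across the direction volumes at this b
        with np.errstate(divide="ignore"):
            gm = np.exp(np.mean(np.log(np.maximum(data[..., group], 0)), axis=-1))
        out_vols.append(np.nan_to_num(gm, nan=0.0, neginf=0.0))
        out_b.append(bvals[i])
        done[group] = True
    return np.stack(out_vols, axis=-1), np.asarray(out_b, dtype=float)


def fit_volume(
    series: DWISeries,
    options: FitOptions | None = None,
    preset: OrganPreset | None = None,
) -> dict[str, np.ndarray]:
    """Fit every masked voxel of a series and return parameter maps.

    The b-threshold defaults to the preset's when one is given.  Returns maps
    for ``f``, ``D``, ``Dstar``, ``S0`` (value :data:`MISSING` where not
    fitted) and an integer ``flags`` map: 0 ok, 1 outside mask/skipped,
    2 f clipped to zero (D* undefined), 3 non-convergence.
    """
    if options is None:
        bt = preset.b_threshold if preset is not None else 200.0
        options = FitOptions(b_threshold=bt)
    data, bvals = collapse_directions(series)

    n_high = np.unique(bvals[bvals >= options.b_threshold]).size
    if n_high < 2 or not (bvals == 0).any():
        raise ValueError(
            f"b-table {sorted(set(bvals.tolist()))} cannot support a segmented fit: "
            f"needs b = 0 and >= 2 distinct b >= {options.b_threshold}"
        )

    mask = series.mask if series.mask is not None else np.ones(data.shape[:3], bool)
    shape = data.shape[:3]
    maps = {k: np.full(shape, MISSING) for k in ("f", "D", "Dstar", "S0")}
    flags = np.ones(shape, dtype=int)  # 1 = not fitted
    n_bad = 0
    for idx in zip(*np.nonzero(mask)):
        sig = data[idx]
        if (sig <= 0).any():
            n_bad += 1
            continue  # log-domain steps undefined; skip and leave flagged
        try:
            if options.method == "full_nlls":
                res = full_nlls_fit(bvals, sig, options=options)
            else:
                res = segmented_fit(bvals, sig, options=options)
        except ValueError:
            n_bad += 1
            continue
        p = res.params
        maps["f"][idx] = p.f
        maps["D"][idx] = p.D
        maps["S0"][idx] = p.S0
        if res.dstar_defined:
            maps["Dstar"][idx] = p.Dstar
        if "f_clipped_to_zero" in res.flags:
            flags[idx] = 2
        elif not all(res.converged.values()):
            flags[idx] = 3
        else:
            flags[idx] = 0
    if n_bad:
        log.info("%d voxel(s) skipped (non-positive signal or fit failure)", n_bad)
    maps["flags"] = flags
    return maps
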