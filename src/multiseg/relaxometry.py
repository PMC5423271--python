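"""R2* relaxometry from multi-echo magnitude series.

The magnitude signal of a gradient-echo acquisition decays with echo time as

    S(TE) = S0 * exp(-R2* * TE)

where R2* (in 1/ms) is the apparent transverse relaxation rate and
T2* = 1/R2* the corresponding relaxation time.  The estimator is ordinary
least squares on the log-signal, log S = log S0 - R2* * TE, optionally
weighted by the squared signal (which approximates maximum likelihood for
Gaussian noise on the linear scale).  Magnitude (Rician) data are assumed;
the noise floor is handled by a minimum-signal threshold rather than a noise
model, and negative fitted rates are retained (flagged in a logged count) so
downstream density models see the estimator's true distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import Volume, check_grid, write_volume

logger = logging.getLogger(__name__)


@dataclass
class MultiEchoSeries:
    """Ordered magnitude echoes with their echo times (ms)."""

    echoes: list[Volume]
    echo_times: list[float]

    def __post_init__(self) -> None:
        if len(self.echoes) != len(self.echo_times):
            raise ValueError("one echo time per echo volume required")
        te = np.asarray(self.echo_times, dtype=float)
        if len(te) and (np.any(te <= 0) or len(np.unique(te)) != len(te)):
            raise ValueError("echo_times must be positive and distinct")
        ref = self.echoes[0]
        for e in self.echoes[1:]:
            check_grid(ref, e)

    @property
    def n_echoes(self) -> int:
        return len(self.echoes)

    def signal_array(self) -> np.ndarray:
        """(n_echoes, X, Y, Z) stacked magnitudes."""
        return np.stack([e.data for e in self.echoes], axis=0).astype(float)

    def reordered(self, order: list[int]) -> "MultiEchoSeries":
        return MultiEchoSeries(
            [self.echoes[i] for i in order],
            [self.echo_times[i] for i in order],
        )


@dataclass
class R2StarMap:
    """Per-voxel mono-exponential fit: rate (1/ms), S0, and validity."""

    rate: Volume
    s0: Volume
    valid: Volume

    def to_files(self, outdir: str | Path, prefix: str = "r2star") -> dict:
        outdir = Path(outdir)
        return {
            "rate": str(write_volume(self.rate, outdir / f"{prefix}_rate.nii.gz")),
            "s0": str(write_volume(self.s0, outdir / f"{prefix}_s0.nii.gz")),
            "valid": str(
                write_volume(
                    Volume(self.valid.data.astype(np.int16), self.valid.affine),
                    outdir / f"{prefix}_valid.nii.gz",
                )
            ),
        }


def fit_r2star(
    series: MultiEchoSeries,
    min_signal: float = 0.0,
    weighted: bool = False,
) -> R2StarMap:
    """Fit S(TE) = S0·exp(−R2*·TE) per voxel by log-linear least squares.

    Parameters
    ----------
    series
        ≥ 2 echoes with strictly increasing echo times.
    min_signal
        Voxels with any echo magnitude ≤ ``min_signal`` (or non-finite) are
        marked invalid; a sensible choice is ~3× the background noise SD.
    weighted
        Weight the log-domain residuals by the squared signal, down-weighting
        late low-SNR echoes.  Default off (plain OLS on the log points).
    """
    if series.n_echoes < 2:
        raise ValueError("R2* fitting needs at least 2 echoes")
    if np.any(np.diff(series.echo_times) <= 0):
        raise ValueError("echo_times must be strictly increasing for fitting")
    if min_signal < 0:
        raise ValueError("min_signal must be >= 0")

    S = series.signal_array()  # (E, X, Y, Z)
    te = np.asarray(series.echo_times, dtype=float)
    shape = S.shape[1:]
    E = len(te)

    valid = np.all(np.isfinite(S), axis=0) & np.all(S > min_signal, axis=0)
    # guard log() even at invalid voxels
    logS = np.log(np.where(S > 0, S, 1.0))

    te_b = te.reshape(E, 1, 1, 1)
    if weighted:
        w = S**2
    else:
        w = np.ones_like(S)
    sw = w.sum(axis=0)
    sx = (w * te_b).sum(axis=0)
    sy = (w * logS).sum(axis=0)
    sxx = (w * te_b**2).sum(axis=0)
    sxy = (w * te_b * logS).sum(axis=0)
    denom = sw * sxx - sx**2
    denom = np.where(denom == 0, np.nan, denom)
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / sw

    rate = -slope
    s0 = np.exp(intercept)
    bad = ~np.isfinite(rate) | ~np.isfinite(s0)
    valid &= ~bad
    rate = np.where(valid, rate, np.nan)
    s0 = np.where(valid, s0, np.nan)

    n_neg = int(np.sum(rate[valid & np.isfinite(rate)] < 0)) if valid.any() else 0
    if n_neg:
        logger.info("fit_r2star: %d voxels with negative fitted R2* retained", n_neg)

    grid = series.echoes[0]
    return R2StarMap(
        rate=grid.like(rate.reshape(shape)),
        s0=grid.like(s0.reshape(shape)),
        valid=grid.like(valid.reshape(shape)),
    )


def combine_echoes_mean(series: MultiEchoSeries) -> Volume:
    """Voxel-wise arithmetic mean across echoes (the echo-combined T1w image)."""
    if series.n_echoes < 1:
        raise ValueError("need at least one echo")
    return series.echoes[0].like(series.signal_array().mean(axis=0))


def r2star_to_t2star(r2map: R2StarMap, rate_floor: float = 1e-6) -> Volume:
    """T2* = 1/max(R2*, rate_floor) in ms; invalid voxels become NaN."""
    if rate_floor <= 0:
        raise ValueError("rate_floor must be > 0")
    valid = r2map.valid.data.astype(bool)
    rate = np.where(valid, r2map.rate.data, np.nan)
    t2 = 1.0 / np.maximum(rate, rate_floor)
    return r2map.rate.like(np.where(valid, t2, np.nan))


def read_multi_echo(
    paths: str | Path | list[str | Path],
    echo_times: list[float],
) -> MultiEchoSeries:
    """Load a series from one 4D NIfTI or an ordered list of 3D NIfTIs."""
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        data = np.asarray(img.get_fdata(dtype=np.float64))
        if data.ndim != 4:
            raise ValueError(f"{paths} is not 4D; give a list of 3D files instead")
        if data.shape[3] != len(echo_times):
            raise ValueError(
                f"{data.shape[3]} volumes but {len(echo_times)} echo times"
            )
        aff = np.asarray(img.affine)
        echoes = [Volume(data[..., i], aff.copy()) for i in range(data.shape[3])]
    else:
        from .volumes import read_volume

        echoes = [read_volume(p) for p in paths]
    return MultiEchoSeries(echoes, list(echo_times))


def write_multi_echo(series: MultiEchoSeries, path: str | Path) -> Path:
    """Write the series as one 4D NIfTI (echo index last)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.stack([e.data for e in series.echoes], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, series.echoes[0].affine), str(path))
    return path
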