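"""Fourier Shell Correlation resolution estimation and radial PSD.

Two independently acquired half-volumes of the same tissue (odd/even
projection-angle half-tomograms, or odd/even EM slices) share signal but
carry independent noise.  Their per-frequency-shell normalised cross
correlation,

    FSC(r) = Re( sum_shell F_a F_b* ) / sqrt( sum_shell |F_a|^2 * sum_shell |F_b|^2 ),

decays from 1 toward 0 with spatial frequency; crossing it against a
resolution criterion (1-bit, half-bit, 3-sigma information thresholds, or
the fixed 1/7 level) reads out the spatial resolution.  Shells are one
frequency voxel wide (rounded radius); for non-cubic volumes frequencies
are normalised per axis before binning so "radius" is in cycles per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "VolumePair",
    "FSCCurve",
    "ResolutionEstimate",
    "BEYOND_NYQUIST",
    "split_half_em",
    "compute_fsc",
    "criterion_threshold",
    "resolution_from_curve",
    "normalise_high_freq",
    "average_curves",
    "radial_psd",
]

CRITERIA = ("one_bit", "half_bit", "three_sigma", "fixed_1_7")

#: Sentinel resolution when the curve never crosses the criterion.
BEYOND_NYQUIST = "beyond_nyquist"

#: Default ROI edge lengths (voxels) per modality, used by the CLI and
#: convenience wrappers; 100 for low-resolution lab micro-CT, 500 otherwise.
DEFAULT_ROI_VOXELS = {"lxrt": 100, "default": 500}


@dataclass
class VolumePair:
    """Two half-volumes of identical shape with isotropic voxel size (nm)."""

    half_a: np.ndarray
    half_b: np.ndarray
    voxel_size: float

    def __post_init__(self):
        self.half_a = np.asarray(self.half_a, dtype=float)
        self.half_b = np.asarray(self.half_b, dtype=float)
        if self.half_a.shape != self.half_b.shape:
            raise ValueError("half volumes must have identical shape")
        if not (np.all(np.isfinite(self.half_a)) and np.all(np.isfinite(self.half_b))):
            raise ValueError("half volumes must be finite")


@dataclass
class FSCCurve:
    """Per-shell correlation. shell_radii in cycles/voxel, counts per shell."""

    shell_radii: np.ndarray
    fsc: np.ndarray
    shell_counts: np.ndarray

    def __post_init__(self):
        self.shell_radii = np.asarray(self.shell_radii, dtype=float)
        self.fsc = np.asarray(self.fsc, dtype=float)
        self.shell_counts = np.asarray(self.shell_counts)
        if not (len(self.shell_radii) == len(self.fsc) == len(self.shell_counts)):
            raise ValueError("shell arrays must have equal length")


@dataclass
class ResolutionEstimate:
    criterion: str
    crossing_frequency: float | None  # cycles/voxel; None when beyond Nyquist
    resolution: float | str           # nm, or BEYOND_NYQUIST


def split_half_em(volume: np.ndarray, voxel_size: float, axis: int = 0) -> VolumePair:
    """Odd/even slice split plus 2x2 in-plane mean pooling.

    Mirrors the half-dataset construction for serial-section EM: slices of
    one parity per half, then downscaling by 2 in the two in-plane axes so
    the pair becomes isotropic when the slice pitch is twice the pixel
    size.  The returned pair's voxel size is doubled.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.shape[axis] < 2:
        raise ValueError("need at least 2 slices along the split axis")
    vol = np.moveaxis(vol, axis, 0)
    even, odd = vol[0::2], vol[1::2]
    n = min(len(even), len(odd))
    even, odd = even[:n], odd[:n]

    def pool(v: np.ndarray) -> np.ndarray:
        ny, nx = (v.shape[1] // 2) * 2, (v.shape[2] // 2) * 2
        v = v[:, :ny, :nx]
        return v.reshape(v.shape[0], ny // 2, 2, nx // 2, 2).mean(axis=(2, 4))

    return VolumePair(pool(even), pool(odd), 2.0 * voxel_size)


def _shell_index(shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Rounded-radius shell index per FFT voxel and number of shells.

    Frequencies are normalised per axis (cycles/voxel) then scaled by the
    largest axis length so shell width is one frequency voxel of that axis.
    """
    n_ref = max(shape)
    grids = np.meshgrid(
        *[np.fft.fftfreq(n) * n_ref for n in shape], indexing="ij", sparse=True
    )
    r = np.sqrt(sum(g * g for g in grids))
    return np.rint(r).astype(np.int64), n_ref


def compute_fsc(pair: VolumePair) -> FSCCurve:
    """FSC over integer-radius shells (shell 0 = DC kept separately)."""
    a, b = pair.half_a, pair.half_b
    if not (np.any(a) and np.any(b)):
        raise ValueError("FSC undefined for an all-zero half volume")
    Fa = np.fft.fftn(a)
    Fb = np.fft.fftn(b)
    shell, n_ref = _shell_index(a.shape)
    n_shells = n_ref // 2 + 1  # up to Nyquist of the reference axis
    flat = shell.ravel()
    keep = flat < n_shells
    flat = flat[keep]

    cross = np.bincount(flat, weights=(Fa * np.conj(Fb)).real.ravel()[keep],
                        minlength=n_shells)
    pa = np.bincount(flat, weights=(np.abs(Fa) ** 2).ravel()[keep], minlength=n_shells)
    pb = np.bincount(flat, weights=(np.abs(Fb) ** 2).ravel()[keep], minlength=n_shells)
    counts = np.bincount(flat, minlength=n_shells)

    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = np.where(denom > 0, cross / denom, 0.0)
    radii = np.arange(n_shells) / n_ref  # cycles per voxel
    return FSCCurve(radii, fsc, counts)


def criterion_threshold(criterion: str, shell_counts: np.ndarray,
                        sigma_plus_one: bool = True) -> np.ndarray:
    """Per-shell threshold curves for the four standard criteria.

    one_bit and half_bit are the information-content thresholds for a full
    and half bit of information per voxel; three_sigma is the noise
    significance threshold 3/(sqrt(n/2)+1) (set ``sigma_plus_one=False``
    for the 3/sqrt(n/2) variant); fixed_1_7 is the constant 1/7 level.
    """
    n = np.asarray(shell_counts, dtype=float)
    if np.any(n < 1):
        raise ValueError("shell counts must be >= 1")
    if criterion == "one_bit":
        return (0.5 + 2.4142 / np.sqrt(n)) / (1.5 + 1.4142 / np.sqrt(n))
    if criterion == "half_bit":
        return (0.2071 + 1.9102 / np.sqrt(n)) / (1.2071 + 0.9102 / np.sqrt(n))
    if criterion == "three_sigma":
        root = np.sqrt(n / 2.0)
        return 3.0 / (root + 1.0) if sigma_plus_one else 3.0 / root
    if criterion == "fixed_1_7":
        return np.full_like(n, 1.0 / 7.0)
    raise ValueError(f"unknown criterion {criterion!r}")


def resolution_from_curve(
    curve: FSCCurve, criterion: str, voxel_size: float, **kw
) -> ResolutionEstimate:
    """First sub-threshold crossing, linearly interpolated between shells.

    Resolution = voxel_size / crossing_frequency.  Shell 0 (DC) is skipped.
    If the curve never falls below the criterion within Nyquist the
    estimate carries the beyond-Nyquist sentinel.
    """
    thr = criterion_threshold(criterion, np.maximum(curve.shell_counts, 1), **kw)
    fsc, radii = curve.fsc, curve.shell_radii
    for i in range(1, len(fsc)):
        if fsc[i] < thr[i]:
            # interpolate between shells i-1 and i on (fsc - thr)
            d0 = fsc[i - 1] - thr[i - 1]
            d1 = fsc[i] - thr[i]
            frac = d0 / (d0 - d1) if d0 > 0 else 0.0
            freq = radii[i - 1] + frac * (radii[i] - radii[i - 1])
            freq = max(freq, radii[1] * 1e-9)  # guard zero-frequency division
            return ResolutionEstimate(criterion, float(freq), float(voxel_size / freq))
    return ResolutionEstimate(criterion, None, BEYOND_NYQUIST)


def average_curves(curves: Sequence[FSCCurve]) -> FSCCurve:
    """Pointwise mean curve; shell counts are summed."""
    if not curves:
        raise ValueError("no curves")
    r0 = curves[0].shell_radii
    for c in curves[1:]:
        if not np.array_equal(c.shell_radii, r0):
            raise ValueError("curves must share a shell grid")
    fsc = np.mean([c.fsc for c in curves], axis=0)
    counts = np.sum([c.shell_counts for c in curves], axis=0)
    return FSCCurve(r0.copy(), fsc, counts)


def normalise_high_freq(
    curves: Sequence[FSCCurve],
    pixel_band: tuple[float, float] = (1.0 / 3.0, 1.0 / 2.0),
    mode: str = "rescale",
) -> list[FSCCurve]:
    """Remove an artifactual high-frequency correlation floor.

    The mean FSC ``m`` of the *averaged* curve inside ``pixel_band``
    (cycles/voxel; default [1/(3 px), 1/(2 px)]) is taken as the spurious
    floor, assumed to be zero for truly independent halves.  In "rescale"
    mode every curve is mapped through (fsc - m)/(1 - m), which pins 1 and
    sends the band mean to 0; "subtract" mode applies fsc - m only.
    """
    avg = average_curves(curves)
    lo, hi = pixel_band
    band = (avg.shell_radii >= lo) & (avg.shell_radii <= hi)
    if not np.any(band):
        raise ValueError("normalisation band contains no shells")
    m = float(avg.fsc[band].mean())
    if m >= 1.0:
        raise ValueError("band mean >= 1; normalisation undefined")
    out = []
    for c in curves:
        if mode == "rescale":
            fsc = (c.fsc - m) / (1.0 - m)
        elif mode == "subtract":
            fsc = c.fsc - m
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out.append(FSCCurve(c.shell_radii.copy(), fsc, c.shell_counts.copy()))
    return out


def radial_psd(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectral density of a 2D image.

    Returns (normalised frequency, mean power) with the DC term excluded;
    the frequency axis is the radial bin index divided by N/2 (N = FFT
    size), i.e. 1.0 at Nyquist.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("radial_psd expects a 2D image")
    F = np.fft.fftn(img)
    power = np.abs(F) ** 2
    shell, n_ref = _shell_index(img.shape)
    n_shells = n_ref // 2 + 1
    flat = shell.ravel()
    keep = flat < n_shells
    sums = np.bincount(flat[keep], weights=power.ravel()[keep], minlength=n_shells)
    counts = np.bincount(flat[keep], minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_power = np.where(counts > 0, sums / counts, 0.0)
    freq = np.arange(n_shells) / (n_ref / 2.0)
    return freq[1:], mean_power[1:]
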