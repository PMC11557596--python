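"""Even/odd Fourier shell correlation and resolution estimation.

Two statistically independent reconstructions (from even- and odd-indexed
projections) are compared shell-by-shell in Fourier space:

    FSC(k) = Re sum F G* / sqrt(sum |F|^2 sum |G|^2),

summed over voxels in the shell R(k).  Because each half-series
reconstruction is noisier than the full reconstruction, the corrected
correlation  FSC'(k) = 2 FSC / (FSC + 1)  estimates the full-map quality;
the resolution is reported as the half-pitch at the first crossing of the
criterion (0.5 by default; 0.143 and half-bit conventions are available
through ``criterion``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FSCCurve", "fsc_curve", "fsc_resolution", "corrected_fsc"]


def corrected_fsc(fsc: np.ndarray) -> np.ndarray:
    """Half-map correction FSC' = 2 FSC / (FSC + 1); monotone on (-1, 1]."""
    fsc = np.asarray(fsc, dtype=float)
    return 2.0 * fsc / (fsc + 1.0)


@dataclass
class FSCCurve:
    shell_freq: np.ndarray        # cycles / nm at shell centres
    fsc: np.ndarray
    fsc_corrected: np.ndarray
    shell_counts: np.ndarray
    resolution_nm: float | None   # half-pitch at criterion crossing
    criterion: float


def fsc_curve(volume_even: np.ndarray, volume_odd: np.ndarray,
              voxel_nm: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw shell-wise FSC of two equal-shape volumes.

    Returns (shell spatial frequencies in 1/nm, FSC per shell, voxel count
    per shell).  Shells are unit-width in FFT index radius out to Nyquist.
    """
    e = np.asarray(volume_even, dtype=float)
    o = np.asarray(volume_odd, dtype=float)
    if e.shape != o.shape:
        raise ValueError("volume shapes must match")
    f = np.fft.fftn(e)
    g = np.fft.fftn(o)
    freqs = [np.fft.fftfreq(n) for n in e.shape]
    kgrid = np.sqrt(sum(
        np.meshgrid(*[fq**2 for fq in freqs], indexing="ij")[i]
        for i in range(e.ndim)
    ))
    nmax = min(e.shape) // 2
    # shell index by radius in cycles/box-edge of the smallest axis
    shell = np.rint(kgrid * min(e.shape)).astype(int)
    num = np.real(f * np.conj(g))
    den_f = np.abs(f) ** 2
    den_g = np.abs(g) ** 2
    idx = shell.ravel()
    nshell = nmax + 1
    sums_num = np.bincount(idx, num.ravel(), minlength=nshell)[:nshell]
    sums_f = np.bincount(idx, den_f.ravel(), minlength=nshell)[:nshell]
    sums_g = np.bincount(idx, den_g.ravel(), minlength=nshell)[:nshell]
    counts = np.bincount(idx, minlength=nshell)[:nshell]
    with np.errstate(divide="ignore", invalid="ignore"):
        fsc = sums_num / np.sqrt(sums_f * sums_g)
    fsc = np.where(np.isfinite(fsc), fsc, 0.0)
    shell_freq = np.arange(nshell) / (min(e.shape) * voxel_nm)
    return shell_freq, fsc, counts


def fsc_resolution(volume_even: np.ndarray, volume_odd: np.ndarray,
                   voxel_nm: float, criterion: float = 0.5,
                   use_corrected: bool = True) -> FSCCurve:
    """FSC curve plus the half-pitch resolution at the criterion crossing.

    The crossing frequency is linearly interpolated between the shells
    bracketing the first descent through ``criterion``; resolution (nm,
    half-pitch) is 1/(2 f_cross).  ``None`` when the curve never crosses.
    """
    shell_freq, fsc, counts = fsc_curve(volume_even, volume_odd, voxel_nm)
    fsc_c = corrected_fsc(fsc)
    curve = fsc_c if use_corrected else fsc
    resolution = None
    for i in range(1, len(curve)):
        if curve[i] < criterion <= curve[i - 1]:
            f0, f1 = shell_freq[i - 1], shell_freq[i]
            c0, c1 = curve[i - 1], curve[i]
            fx = f0 + (criterion - c0) * (f1 - f0) / (c1 - c0)
            if fx > 0:
                resolution = float(1.0 / (2.0 * fx))
            break
    return FSCCurve(shell_freq, fsc, fsc_c, counts, resolution, criterion)
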