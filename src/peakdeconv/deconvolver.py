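"""Sparse non-negative deconvolution of coverage profiles against a kernel.

The genome is tiled into overlapping windows (default 20 kb, overlapping by
at least one kernel support so no peak straddles a seam unseen).  Within a
window the binned signal is decomposed greedily into a non-negative sum of
shifted kernel copies: at each step the shift maximizing the residual-kernel
inner product is added and all coefficients are refit jointly by
non-negative least squares (matching pursuit with joint refit).  A final
cyclic-replacement polish relocates atoms while this lowers the residual sum
of squares, which makes small noiseless instances agree with exhaustive
least squares over position subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, List, Optional, Sequence

import numpy as np
from scipy.optimize import nnls

if TYPE_CHECKING:  # pragma: no cover
    from .kernel_model import PeakKernel

logger = logging.getLogger("peakdeconv")


@dataclass(frozen=True)
class Window:
    """A deconvolution window and the core zone it is authoritative for."""

    chrom: str
    start: int
    end: int
    core_start: int
    core_end: int


@dataclass(frozen=True)
class CandidateSite:
    """A fitted kernel placement: position of the kernel mode (0-based bp)
    and its non-negative coefficient (peak height, kernel max being 1)."""

    chrom: Optional[str]
    position: int
    coefficient: float
    rss_share: float = 0.0


def tile_windows(
    chrom_len: int,
    kernel_support: int,
    window_len: int = 20000,
    bin_size: int = 10,
    chrom: str = "",
    core_offset: Optional[int] = None,
) -> List[Window]:
    """Tile a chromosome with overlapping windows.

    Consecutive windows overlap by one kernel support; each window owns a
    half-open "core" interval, and the cores tile ``[0, chrom_len)`` exactly.

    ``core_offset`` places the core boundaries inside the overlap zone
    (default: half the support).  When deconvolving with a skewed kernel it
    must equal the kernel's mode offset (mode_bin x bin_size): a kernel can
    only place its mode at least ``mode_offset`` from the window start and
    at most ``support - mode_offset`` from its end, and with the default
    window/overlap geometry those placeable ranges of consecutive windows
    meet exactly at ``start + step + mode_offset`` -- any other core
    boundary leaves a stripe of positions that no owning window can fit.
    """
    if window_len <= 2 * kernel_support:
        raise ValueError(
            f"window_len {window_len} must exceed twice the kernel support "
            f"{kernel_support}; increase the window length"
        )
    if chrom_len <= window_len:
        return [Window(chrom, 0, chrom_len, 0, chrom_len)]
    step = window_len - kernel_support
    if core_offset is None:
        core_offset = kernel_support // 2
    core_off = min(core_offset, kernel_support) // bin_size * bin_size
    starts = list(range(0, chrom_len - window_len, step))
    # one extra window to reach the chromosome end
    starts.append(starts[-1] + step)
    windows = []
    for i, s in enumerate(starts):
        e = min(s + window_len, chrom_len)
        cs = 0 if i == 0 else s + core_off
        ce = chrom_len if i == len(starts) - 1 else s + step + core_off
        windows.append(Window(chrom, s, e, cs, ce))
    return windows


def _design(n: int, h: np.ndarray, shifts: Sequence[int]) -> np.ndarray:
    A = np.zeros((n, len(shifts)))
    m = len(h)
    for j, s in enumerate(shifts):
        A[s : s + m, j] = h
    return A


def _refit(y: np.ndarray, h: np.ndarray, shifts: List[int]):
    """Joint NNLS refit over the selected shifts; drops zero coefficients."""
    A = _design(len(y), h, shifts)
    coefs, _ = nnls(A, y)
    # drop exact zeros and numerical dust relative to the largest coefficient
    keep = coefs > 1e-9 * (coefs.max() if len(coefs) else 0.0)
    if not keep.all():
        shifts = [s for s, k in zip(shifts, keep) if k]
        coefs = coefs[keep]
        A = A[:, keep]
    resid = y - A @ coefs
    return shifts, coefs, resid, float(resid @ resid)


def _polish(y, h, shifts, coefs, rss, max_passes=4):
    """Cyclic replacement: try relocating each atom to the best shift given
    the others; accept moves that strictly lower the RSS."""
    m = len(h)
    for _ in range(max_passes):
        improved = False
        for j in range(len(shifts)):
            others = shifts[:j] + shifts[j + 1 :]
            model_wo = np.zeros_like(y)
            for s, c in zip(shifts, coefs):
                if s == shifts[j]:
                    continue
                model_wo[s : s + m] += c * h
            corr = np.correlate(y - model_wo, h, mode="valid")
            if others:
                corr[np.asarray(others)] = -np.inf
            s_new = int(np.argmax(corr))
            if s_new == shifts[j] or corr[s_new] <= 0:
                continue
            trial = others + [s_new]
            t_shifts, t_coefs, t_resid, t_rss = _refit(y, h, trial)
            if t_rss < rss - 1e-12:
                shifts, coefs, rss = t_shifts, t_coefs, t_rss
                improved = True
        if not improved:
            break
    return shifts, coefs, rss


def deconvolve_window(
    signal: np.ndarray,
    kernel: "PeakKernel",
    min_coef: float = 0.0,
    tol: float = 1e-4,
    max_sites: int = 200,
    offset: int = 0,
    chrom: Optional[str] = None,
    polish: bool = True,
) -> List[CandidateSite]:
    """Deconvolve a binned signal into non-negative shifted kernel copies.

    Parameters
    ----------
    signal : 1-D array of binned intensities (length >= kernel length).
    min_coef : stop adding atoms once the best univariate coefficient
        estimate falls below this intensity.
    tol : stop once the relative RSS improvement of a step drops below tol.
    offset : genomic bp of the first bin, used to place reported positions.

    Returns candidate sites sorted by position; an all-zero signal yields [].
    """
    y = np.ascontiguousarray(signal, dtype=np.float64)
    h = kernel.values
    m = len(h)
    if len(y) < m:
        raise ValueError(f"signal length {len(y)} shorter than kernel length {m}")
    if not np.any(y):
        return []
    hh = float(h @ h)
    ss0 = float(y @ y)

    shifts: List[int] = []
    coefs = np.zeros(0)
    resid = y.copy()
    rss = ss0
    while len(shifts) < max_sites:
        corr = np.correlate(resid, h, mode="valid")
        if shifts:
            corr[np.asarray(shifts)] = -np.inf
        s = int(np.argmax(corr))
        best = corr[s] / hh
        if best <= 0 or best < min_coef:
            break
        shifts, coefs, resid, new_rss = _refit(y, h, shifts + [s])
        gain = rss - new_rss
        rss = new_rss
        if gain < tol * max(rss, 1e-300):
            break
    if polish and shifts:
        shifts, coefs, rss = _polish(y, h, list(shifts), coefs, rss)

    bs = kernel.bin_size
    mode = kernel.mode_bin
    sites = [
        CandidateSite(
            chrom=chrom,
            position=offset + (s + mode) * bs,
            coefficient=float(c),
            rss_share=float(c * c * hh / ss0),
        )
        for s, c in zip(shifts, coefs)
    ]
    sites.sort(key=lambda x: x.position)
    return sites


def merge_window_calls(
    per_window: Sequence[Sequence[CandidateSite]],
    windows: Sequence[Window],
    bin_size: int,
) -> List[CandidateSite]:
    """Deduplicate candidates from overlapping windows of one chromosome.

    Only candidates inside their window's half-open core survive; afterwards
    sites within one bin of each other collapse to the larger coefficient.
    """
    kept: List[CandidateSite] = []
    for win, sites in zip(windows, per_window):
        for s in sites:
            if win.core_start <= s.position < win.core_end:
                kept.append(s)
    kept.sort(key=lambda s: s.position)
    merged: List[CandidateSite] = []
    for s in kept:
        if merged and s.position - merged[-1].position <= bin_size:
            if s.coefficient > merged[-1].coefficient:
                merged[-1] = s
        else:
            merged.append(s)
    return merged


def brute_force_deconvolve(
    signal: np.ndarray,
    kernel: "PeakKernel",
    max_sites: int = 3,
    offset: int = 0,
    chrom: Optional[str] = None,
) -> List[CandidateSite]:
    """Exhaustive least-squares oracle over all shift subsets of size
    ``<= max_sites`` (non-negative coefficients).  Exponential in max_sites;
    for validating :func:`deconvolve_window` on tiny instances only.
    """
    from itertools import combinations

    y = np.ascontiguousarray(signal, dtype=np.float64)
    h = kernel.values
    m = len(h)
    nshift = len(y) - m + 1
    best_rss = float(y @ y)
    best: tuple = ()
    best_coefs = np.zeros(0)
    for k in range(1, max_sites + 1):
        for subset in combinations(range(nshift), k):
            A = _design(len(y), h, subset)
            coefs, rnorm = nnls(A, y)
            rss = rnorm * rnorm
            if rss < best_rss - 1e-12:
                best_rss, best, best_coefs = rss, subset, coefs
    bs = kernel.bin_size
    mode = kernel.mode_bin
    sites = [
        CandidateSite(chrom, offset + (s + mode) * bs, float(c))
        for s, c in zip(best, best_coefs)
        if c > 0
    ]
    sites.sort(key=lambda x: x.position)
    return sites
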