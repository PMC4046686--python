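"""Bootstrap confidence assessment of candidate binding sites.

Each candidate coefficient is compared against a null distribution of the
largest coefficient the kernel can spuriously attain on background: the
profile around the site -- with only the tested site's own fitted component
removed, so every other pattern the data contain stays in the background
model -- is resampled by drawing moving blocks (one kernel length) with
replacement and superposing them at random positions, and each
pseudo-segment is deconvolved against the kernel; the maximum fitted
coefficient per replicate forms the null.  Block resampling preserves the
bin-to-bin correlation of elongated reads, and the additive superposition
lets background clumps stack, giving the null the extreme-value tail of the
observed background.  Each site gets empirical p-values against three local
windows centered on it (default 5, 10 and 15 kb) and one global
(genome-wide sampled) background, combined by Fisher's method.  When a
control sample is available, the same kernel fit in the control window
either vetoes the site or contributes an additional p-value to the
combination.  No default significance threshold is applied; all sites
complying with the kernel are reported.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .alignment_io import CoverageProfile
from .deconvolver import CandidateSite, deconvolve_window
from .kernel_model import PeakKernel

logger = logging.getLogger("peakdeconv")


@dataclass
class NullDistribution:
    """Sorted bootstrap maxima of spurious kernel-fit coefficients."""

    values: np.ndarray
    n_boot: int
    seed: Optional[object]
    source: str = "local"

    def __post_init__(self) -> None:
        assert len(self.values) == self.n_boot


@dataclass
class PeakCall:
    """A called binding site with its confidence descriptors."""

    chrom: str
    position: int  # 0-based bp of the kernel mode
    coefficient: float
    p_local: Dict[int, float] = field(default_factory=dict)
    p_global: float = 1.0
    p_combined: float = 1.0
    p_corrected: Optional[float] = None


def derive_rng(master_seed: int, *tokens) -> np.random.Generator:
    """Deterministic sub-stream keyed by (master seed, tokens).

    Sub-seeds depend only on the site/window identity, never on execution
    order, so parallel scheduling cannot change any draw.
    """
    key = ":".join(str(t) for t in tokens)
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, zlib.crc32(key.encode())])
    )


def compute_residuals(
    profile: CoverageProfile,
    calls: Sequence[CandidateSite],
    kernel: PeakKernel,
) -> Dict[str, np.ndarray]:
    """Profile minus the sum of fitted kernel components, bin-exact."""
    resid = {c: v.astype(np.float64).copy() for c, v in profile.data.items()}
    h = kernel.values
    m = len(h)
    q = kernel.mode_bin
    bs = kernel.bin_size
    for call in calls:
        v = resid[call.chrom]
        a = call.position // bs - q
        lo, hi = max(0, a), min(len(v), a + m)
        if hi > lo:
            v[lo:hi] -= call.coefficient * h[lo - a : hi - a]
    return resid


def bootstrap_null(
    segment: np.ndarray,
    kernel: PeakKernel,
    n_boot: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    block: Optional[int] = None,
    max_sites: int = 8,
    tol: float = 1e-3,
    source: str = "local",
) -> NullDistribution:
    """Null distribution of the maximum kernel-fit coefficient.

    Per replicate, moving blocks (one kernel length by default) are drawn
    with replacement from the segment and added onto a zero pseudo-segment
    of equal length at uniformly random positions, so overlapping blocks
    superpose; total mass is preserved on average while clumps of background
    mass can stack, which gives the null the same extreme-value behaviour as
    the observed background.  Each pseudo-segment is deconvolved with
    ``min_coef=0`` and the largest fitted coefficient (0 if none) recorded.
    """
    seg = np.ascontiguousarray(segment, dtype=np.float64)
    m = len(kernel.values)
    L = len(seg)
    if L < 2 * m:
        raise ValueError(
            f"residual segment of {L} bins is shorter than twice the kernel "
            f"length ({m} bins)"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    if block is None:
        block = m
    block = max(1, min(int(block), L))

    maxima = np.zeros(n_boot)
    if np.any(seg):
        nblocks = -(-L // block)
        for b in range(n_boot):
            src = rng.integers(0, L - block + 1, size=nblocks)
            dst = rng.integers(0, L - block + 1, size=nblocks)
            pseudo = np.zeros(L)
            for s, d in zip(src, dst):
                pseudo[d : d + block] += seg[s : s + block]
            sites = deconvolve_window(
                pseudo, kernel, min_coef=0.0, tol=tol, max_sites=max_sites, polish=False
            )
            if sites:
                maxima[b] = max(s.coefficient for s in sites)
    return NullDistribution(np.sort(maxima), n_boot=n_boot, seed=seed, source=source)


def empirical_p(coefficient: float, null: NullDistribution) -> float:
    """Add-one empirical upper-tail p-value: never 0, floor 1/(1+n_boot)."""
    exceed = int(np.count_nonzero(null.values >= coefficient))
    return (1 + exceed) / (1 + null.n_boot)


def _subtract_component(
    seg: np.ndarray, lo_bin: int, site: CandidateSite, kernel: PeakKernel
) -> np.ndarray:
    """Segment with the site's own fitted kernel component removed."""
    out = seg.astype(np.float64).copy()
    h = kernel.values
    a = site.position // kernel.bin_size - kernel.mode_bin - lo_bin
    s0, s1 = max(0, a), min(len(out), a + len(h))
    if s1 > s0:
        out[s0:s1] -= site.coefficient * h[s0 - a : s1 - a]
    return out


def local_pvalues(
    site: CandidateSite,
    profile_data: Dict[str, np.ndarray],
    kernel: PeakKernel,
    window_sizes: Sequence[int] = (5000, 10000, 15000),
    n_boot: int = 100,
    seed: int = 0,
) -> Dict[int, float]:
    """Empirical p-values against local background windows centered on the site.

    The null for each window resamples the observed profile with only the
    tested site's own fitted component removed, so everything else the data
    contain at that scale -- including other kernel-compatible background
    patterns -- stays in the background model.  Windows clipped at
    chromosome ends that end up shorter than twice the kernel length yield
    p = 1 (logged).
    """
    bs = kernel.bin_size
    m = len(kernel.values)
    v = profile_data[site.chrom]
    out: Dict[int, float] = {}
    for w in window_sizes:
        lo = max(0, (site.position - w // 2) // bs)
        hi = min(len(v), -(-(site.position + w // 2) // bs))
        seg = _subtract_component(v[lo:hi], lo, site, kernel)
        if len(seg) < 2 * m:
            logger.warning(
                "local window %d at %s:%d too short after clipping; p set to 1",
                w,
                site.chrom,
                site.position,
            )
            out[w] = 1.0
            continue
        rng = derive_rng(seed, "local", site.chrom, site.position, w)
        null = bootstrap_null(seg, kernel, n_boot=n_boot, rng=rng, source=f"local{w}")
        out[w] = empirical_p(site.coefficient, null)
    return out


def build_global_null(
    profile_data: Dict[str, np.ndarray],
    kernel: PeakKernel,
    sample_len: int = 200_000,
    n_boot: int = 100,
    seed: int = 0,
    segment_len: int = 10_000,
) -> NullDistribution:
    """Bootstrap null from a seeded uniform sample of the genome-wide profile.

    Segments are drawn uniformly (chromosomes weighted by length) and
    concatenated to ``sample_len`` bp; if less than that exists, everything
    is used (logged).
    """
    bs = kernel.bin_size
    rng = derive_rng(seed, "global")
    chroms = [c for c in profile_data if len(profile_data[c]) > 0]
    total_bp = sum(len(profile_data[c]) for c in chroms) * bs
    if total_bp <= sample_len:
        logger.info("global null: only %d bp of profile available; using all", total_bp)
        sample = np.concatenate([profile_data[c] for c in chroms])
    else:
        seg_bins = max(2 * len(kernel.values), segment_len // bs)
        n_seg = -(-sample_len // (seg_bins * bs))
        weights = np.array([len(profile_data[c]) for c in chroms], dtype=float)
        weights /= weights.sum()
        parts = []
        for _ in range(n_seg):
            c = chroms[int(rng.choice(len(chroms), p=weights))]
            v = profile_data[c]
            if len(v) <= seg_bins:
                parts.append(v)
                continue
            s = int(rng.integers(0, len(v) - seg_bins + 1))
            parts.append(v[s : s + seg_bins])
        sample = np.concatenate(parts)[: sample_len // bs]
    return bootstrap_null(sample, kernel, n_boot=n_boot, rng=rng, source="global")


def global_pvalue(
    site: CandidateSite,
    profile_data: Dict[str, np.ndarray],
    kernel: PeakKernel,
    sample_len: int = 200_000,
    n_boot: int = 100,
    seed: int = 0,
    null: Optional[NullDistribution] = None,
) -> float:
    """p-value against the genome-wide background (the null may be passed in
    so one bootstrap serves every site)."""
    if null is None:
        null = build_global_null(profile_data, kernel, sample_len, n_boot, seed)
    return empirical_p(site.coefficient, null)


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: -2 Σ ln p ~ chi-square with 2k df."""
    ps = np.asarray(p_values, dtype=np.float64)
    if len(ps) == 0:
        raise ValueError("need at least one p-value")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * float(np.sum(np.log(ps)))
    return float(chi2.sf(x2, 2 * len(ps)))


def control_correct(
    site: CandidateSite,
    p_combined_ip: float,
    control: CoverageProfile,
    kernel: PeakKernel,
    n_boot: int = 100,
    seed: int = 0,
    window: int = 10_000,
) -> float:
    """Correct a site's combined confidence against a control sample.

    The control coverage in the site's window is deconvolved with the same
    kernel.  If the largest control coefficient within half a kernel support
    of the site reaches the IP coefficient, the site is vetoed (p = 1);
    otherwise the IP coefficient is tested against a bootstrap null of the
    control-window residuals and the resulting p is Fisher-combined with the
    IP p-value.  Assumes comparable sequencing depths between IP and control.
    """
    bs = control.bin_size
    m = len(kernel.values)
    v = control.data[site.chrom]
    lo = max(0, (site.position - window // 2) // bs)
    hi = min(len(v), -(-(site.position + window // 2) // bs))
    seg = np.asarray(v[lo:hi], dtype=np.float64)
    if len(seg) < 2 * m:
        logger.warning(
            "control window at %s:%d unusable; p_combined returned unchanged",
            site.chrom,
            site.position,
        )
        return p_combined_ip

    ctrl_sites = deconvolve_window(
        seg, kernel, min_coef=0.0, tol=1e-4, max_sites=50, offset=lo * bs, polish=False
    )
    veto_dist = kernel.support_len / 2
    near = [s.coefficient for s in ctrl_sites if abs(s.position - site.position) <= veto_dist]
    beta_c = max(near) if near else 0.0
    if beta_c >= site.coefficient:
        return 1.0

    model = np.zeros_like(seg)
    h = kernel.values
    q = kernel.mode_bin
    for s in ctrl_sites:
        a = s.position // bs - lo - q
        llo, lhi = max(0, a), min(len(seg), a + m)
        if lhi > llo:
            model[llo:lhi] += s.coefficient * h[llo - a : lhi - a]
    resid_c = seg - model
    rng = derive_rng(seed, "control", site.chrom, site.position)
    null = bootstrap_null(resid_c, kernel, n_boot=n_boot, rng=rng, source="control")
    p_ctrl = empirical_p(site.coefficient, null)
    return fisher_combine([p_combined_ip, p_ctrl])


def pvalue_summary(
    p_combined: Sequence[float],
    quantiles: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    thresholds: Sequence[float] = (1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.1),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Quantile table of combined p-values plus counts at usual thresholds.

    No default threshold is applied anywhere in the package; this table is
    the aid for users choosing their own.
    """
    ps = np.asarray(list(p_combined), dtype=np.float64)
    if len(ps) == 0:
        raise ValueError("need at least one call to summarize")
    qtab = pd.DataFrame(
        {"quantile": list(quantiles), "p_combined": np.quantile(ps, list(quantiles))}
    )
    ttab = pd.DataFrame(
        {
            "threshold": list(thresholds),
            "n_p_le_threshold": [int(np.count_nonzero(ps <= t)) for t in thresholds],
        }
    )
    return qtab, ttab
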