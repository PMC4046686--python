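"""End-to-end peak calling: coverage -> kernel -> deconvolution -> confidence.

This module glues the stages together behind one function,
:func:`call_peaks`, and owns the run configuration and the output writers.
Work is distributed over windows (and then over sites) across threads; every
random draw comes from a sub-stream keyed by site/window identity, so the
thread count and scheduling order never change any output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .alignment_io import ChromSizes, CoverageProfile, ReadAlignment, build_coverage, dedup_reads
from .deconvolver import CandidateSite, Window, deconvolve_window, merge_window_calls, tile_windows
from .fragment_length import ElongationEstimate, infer_elongation
from .kernel_model import PeakKernel, learn_kernel, select_training_regions
from .significance import (
    PeakCall,
    build_global_null,
    control_correct,
    empirical_p,
    fisher_combine,
    local_pvalues,
)

logger = logging.getLogger("peakdeconv")

Region = Tuple[str, int, int]


@dataclass
class RunConfig:
    """Run parameters; defaults follow the method's stated defaults
    (elongation 150 nt, 10-nt bins, 20-kb windows, 5/10/15-kb local
    background windows, 100 bootstrap replicates)."""

    elongation: object = 150  # bp, or "auto"
    bin_size: int = 10
    window_len: int = 20_000
    local_windows: Tuple[int, ...] = (5_000, 10_000, 15_000)
    n_boot: int = 100
    seed: int = 0
    threads: int = 1
    cutoff: Optional[float] = None
    quantile: Optional[float] = 0.998
    max_regions: int = 100
    half_width: int = 2_000
    min_regions: int = 30
    min_coef: Optional[float] = None
    global_sample_len: int = 200_000
    dedup: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.md5(self.to_json().encode()).hexdigest()[:10]


@dataclass
class PeakCallingResult:
    calls: List[PeakCall]
    kernel: PeakKernel
    elongation: int
    config: RunConfig
    elongation_estimate: Optional[ElongationEstimate] = None
    n_candidates: int = 0

    def table(self) -> pd.DataFrame:
        """Peak table; start/end span one kernel support around the summit."""
        support = self.kernel.support_len
        mode_off = self.kernel.mode_bin * self.kernel.bin_size
        rows = []
        for c in self.calls:
            row = {
                "chrom": c.chrom,
                "start": max(0, c.position - mode_off),
                "end": max(0, c.position - mode_off) + support,
                "summit": c.position + 1,  # 1-based bp of the kernel mode
                "height": c.coefficient,
            }
            for w in sorted(c.p_local):
                row[f"p_local_{w // 1000}k"] = c.p_local[w]
            row["p_global"] = c.p_global
            row["p_combined"] = c.p_combined
            if c.p_corrected is not None:
                row["p_corrected"] = c.p_corrected
            rows.append(row)
        return pd.DataFrame(rows)


def default_min_coef(window_signal: np.ndarray) -> float:
    """Per-window coefficient floor: max(2, 3 x median nonzero intensity)."""
    nz = window_signal[window_signal > 0]
    med = float(np.median(nz)) if len(nz) else 0.0
    return max(2.0, 3.0 * med)


def _window_intersects(win: Window, regions: Sequence[Region]) -> bool:
    return any(c == win.chrom and s < win.end and win.start < e for c, s, e in regions)


def _map(fn, items, threads: int):
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            return list(pool.map(fn, items))
    return [fn(x) for x in items]


def find_candidates(
    coverage: CoverageProfile,
    kernel: PeakKernel,
    window_len: int = 20_000,
    min_coef: Optional[float] = None,
    threads: int = 1,
    regions: Optional[Sequence[Region]] = None,
) -> List[CandidateSite]:
    """Windowed deconvolution of the whole profile, merged across overlaps."""
    bs = coverage.bin_size
    jobs = []
    for chrom, length in coverage.sizes.items():
        windows = tile_windows(
            length, kernel.support_len, window_len, bs, chrom,
            core_offset=kernel.mode_bin * bs,
        )
        if regions is not None:
            windows = [w for w in windows if _window_intersects(w, regions)]
        jobs.append((chrom, windows))

    def run_window(win: Window) -> List[CandidateSite]:
        sig = coverage.segment(win.chrom, win.start, win.end)
        if len(sig) < len(kernel.values):
            return []
        mc = default_min_coef(sig) if min_coef is None else float(min_coef)
        return deconvolve_window(
            sig, kernel, min_coef=mc, offset=win.start, chrom=win.chrom
        )

    candidates: List[CandidateSite] = []
    for chrom, windows in jobs:
        per_window = _map(run_window, windows, threads)
        candidates.extend(merge_window_calls(per_window, windows, bs))
    return candidates


def call_peaks(
    ip_reads: Sequence[ReadAlignment],
    sizes: ChromSizes,
    control_reads: Optional[Sequence[ReadAlignment]] = None,
    config: Optional[RunConfig] = None,
    kernel: Optional[PeakKernel] = None,
    regions: Optional[Sequence[Region]] = None,
) -> PeakCallingResult:
    """Run the full pipeline on in-memory reads.

    Stages: coverage reconstruction, (optionally automatic) read elongation,
    kernel learning (unless a kernel is supplied), windowed deconvolution
    with overlap merging, and bootstrap confidence assessment with optional
    control correction.  Every stage failure is re-raised with its stage
    name prepended.
    """
    cfg = config or RunConfig()
    if cfg.dedup:
        ip_reads = dedup_reads(ip_reads)
        if control_reads is not None:
            control_reads = dedup_reads(control_reads)

    # -- elongation ---------------------------------------------------------
    estimate = None
    try:
        if cfg.elongation == "auto":
            estimate = infer_elongation(ip_reads, sizes, bin_size=cfg.bin_size)
            elongation = estimate.combined
        else:
            elongation = int(cfg.elongation)
    except Exception as exc:
        raise RuntimeError(f"[elongation] {exc}") from exc

    # -- coverage -----------------------------------------------------------
    try:
        coverage = build_coverage(ip_reads, sizes, elongation, cfg.bin_size)
    except Exception as exc:
        raise RuntimeError(f"[coverage] {exc}; check input reads and sizes") from exc

    # -- kernel -------------------------------------------------------------
    try:
        if kernel is None:
            training = select_training_regions(
                coverage,
                cutoff=cfg.cutoff,
                quantile=cfg.quantile if cfg.cutoff is None else None,
                max_regions=cfg.max_regions,
                half_width=cfg.half_width,
            )
            kernel, _report = learn_kernel(
                coverage, training, min_regions=cfg.min_regions
            )
    except Exception as exc:
        raise RuntimeError(f"[kernel] {exc}; consider lowering the cutoff") from exc

    # -- deconvolution ------------------------------------------------------
    try:
        candidates = find_candidates(
            coverage,
            kernel,
            window_len=cfg.window_len,
            min_coef=cfg.min_coef,
            threads=cfg.threads,
            regions=regions,
        )
    except Exception as exc:
        raise RuntimeError(f"[deconvolution] {exc}") from exc

    # -- significance -------------------------------------------------------
    try:
        gnull = build_global_null(
            coverage.data,
            kernel,
            sample_len=cfg.global_sample_len,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
        )
        control_cov = None
        if control_reads is not None:
            control_cov = build_coverage(control_reads, sizes, elongation, cfg.bin_size)

        def assess(site: CandidateSite) -> PeakCall:
            p_loc = local_pvalues(
                site,
                coverage.data,
                kernel,
                window_sizes=cfg.local_windows,
                n_boot=cfg.n_boot,
                seed=cfg.seed,
            )
            p_glob = empirical_p(site.coefficient, gnull)
            p_comb = fisher_combine(list(p_loc.values()) + [p_glob])
            call = PeakCall(
                chrom=site.chrom,
                position=site.position,
                coefficient=site.coefficient,
                p_local=p_loc,
                p_global=p_glob,
                p_combined=p_comb,
            )
            if control_cov is not None:
                call.p_corrected = control_correct(
                    site, p_comb, control_cov, kernel, n_boot=cfg.n_boot, seed=cfg.seed
                )
            return call

        calls = _map(assess, candidates, cfg.threads)
    except Exception as exc:
        raise RuntimeError(f"[significance] {exc}") from exc

    calls.sort(key=lambda c: (c.chrom, c.position))
    return PeakCallingResult(
        calls=calls,
        kernel=kernel,
        elongation=elongation,
        config=cfg,
        elongation_estimate=estimate,
        n_candidates=len(candidates),
    )


def _header_lines(result: PeakCallingResult) -> List[str]:
    cfg = result.config
    return [
        f"# peakdeconv v{__version__}",
        f"# config: {cfg.to_json()}",
        f"# config_hash: {cfg.config_hash} seed: {cfg.seed}",
        f"# elongation_used: {result.elongation} "
        f"kernel: shape={result.kernel.shape:.4f} scale={result.kernel.scale:.4f} "
        f"support={result.kernel.support_len}",
    ]


def write_peak_table(result: PeakCallingResult, path: str) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(result):
            fh.write(line + "\n")
        result.table().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_summits_bed(result: PeakCallingResult, path: str) -> None:
    """BED6 of summits +/- half a bin; score = -10 log10(p_combined), capped
    at 1000 (narrowPeak-style scaling)."""
    half = result.kernel.bin_size // 2
    with open(path, "w") as fh:
        for line in _header_lines(result):
            fh.write(line + "\n")
        for i, c in enumerate(result.calls):
            score = min(1000, int(round(-10.0 * np.log10(c.p_combined))))
            fh.write(
                f"{c.chrom}\t{max(0, c.position - half)}\t{c.position + half}\t"
                f"peak_{i + 1}\t{score}\t.\n"
            )


def read_regions_bed(path: str) -> List[Region]:
    """Minimal BED3 reader for region-restricted calling."""
    out: List[Region] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.split()
            out.append((p[0], int(p[1]), int(p[2])))
    return out
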