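"""Synthetic ChIP-seq read simulator with known ground truth.

Emulates the standard ChIP fragmentation model: each binding site yields a
number of immunoprecipitated fragments whose lengths are (truncated) normal
and which contain the site at a uniformly random internal position; the
sequencer reports the 5' ``read_len`` prefix of each fragment on a random
strand.  Uniform Poisson background reads are added to the IP sample, and
the control sample contains background only (optionally plus shared
kernel-shaped artifacts, to exercise control-based vetoing).  Reads are
positions, not sequences; sequencing error and mappability are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alignment_io import ChromSizes, ReadAlignment


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth description of a synthetic ChIP-seq experiment.

    Rates are reads per kb (Poisson).  ``sites`` is a sequence of
    (position bp, fragment count) pairs; ``shared_artifacts`` are planted in
    both IP and control samples.
    """

    chrom: str = "chrSim"
    length: int = 2_000_000
    sites: Tuple[Tuple[int, int], ...] = ()
    fragment_len_mean: float = 200.0
    fragment_len_sd: float = 20.0
    read_len: int = 36
    background_rate: float = 0.5
    control_rate: float = 0.5
    seed: int = 0
    shared_artifacts: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.fragment_len_mean <= self.read_len:
            raise ValueError("fragment_len_mean must exceed read_len")
        if self.background_rate < 0 or self.control_rate < 0:
            raise ValueError("rates must be >= 0")
        margin = self.edge_margin
        for pos, _ in tuple(self.sites) + tuple(self.shared_artifacts):
            if not (margin <= pos <= self.length - margin):
                raise ValueError(
                    f"site at {pos} is too close to a chromosome edge "
                    f"(need {margin} bp of clearance) for any fragment"
                )

    @property
    def edge_margin(self) -> int:
        return int(np.ceil(self.fragment_len_mean + 6 * self.fragment_len_sd)) + 1

    @property
    def sizes(self) -> ChromSizes:
        return {self.chrom: self.length}


@dataclass
class TruthTable:
    sites: List[Tuple[int, int]]
    total_ip_reads: int
    total_control_reads: int


def _site_reads(
    rng: np.random.Generator, spec: SimulationSpec, pos: int, n_frag: int
) -> List[ReadAlignment]:
    """Reads for one site: fragments containing the site, 5' prefix reads."""
    lens = rng.normal(spec.fragment_len_mean, spec.fragment_len_sd, size=n_frag)
    low = spec.read_len + 1
    while np.any(lens < low):  # truncate the length distribution at read_len+1
        bad = lens < low
        lens[bad] = rng.normal(spec.fragment_len_mean, spec.fragment_len_sd, size=bad.sum())
    lens = np.rint(lens).astype(np.int64)
    offsets = rng.integers(0, lens)  # site uniformly placed within the fragment
    starts = pos - offsets
    ends = starts + lens
    fwd = rng.random(n_frag) < 0.5
    reads = []
    rl = spec.read_len
    for s, e, f in zip(starts, ends, fwd):
        if f:
            rs, re = s, s + rl
            strand = "+"
        else:
            rs, re = e - rl, e
            strand = "-"
        rs = max(0, int(rs))
        re = min(spec.length, int(re))
        reads.append(ReadAlignment(spec.chrom, rs, re, strand))
    return reads


def _background_reads(
    rng: np.random.Generator, spec: SimulationSpec, rate: float
) -> List[ReadAlignment]:
    n = int(rng.poisson(rate * spec.length / 1000.0))
    starts = rng.integers(0, spec.length - spec.read_len, size=n)
    fwd = rng.random(n) < 0.5
    return [
        ReadAlignment(spec.chrom, int(s), int(s) + spec.read_len, "+" if f else "-")
        for s, f in zip(starts, fwd)
    ]


def simulate_reads(
    spec: SimulationSpec,
) -> Tuple[List[ReadAlignment], List[ReadAlignment], TruthTable]:
    """Generate (IP reads, control reads, truth) from a seeded generator.

    Identical spec (including seed) always yields identical read lists.
    """
    rng = np.random.default_rng(spec.seed)
    ip: List[ReadAlignment] = []
    for pos, n_frag in spec.sites:
        ip.extend(_site_reads(rng, spec, pos, n_frag))
    for pos, n_frag in spec.shared_artifacts:
        ip.extend(_site_reads(rng, spec, pos, n_frag))
    ip.extend(_background_reads(rng, spec, spec.background_rate))

    ctrl: List[ReadAlignment] = []
    for pos, n_frag in spec.shared_artifacts:
        ctrl.extend(_site_reads(rng, spec, pos, n_frag))
    ctrl.extend(_background_reads(rng, spec, spec.control_rate))

    truth = TruthTable(
        sites=list(spec.sites),
        total_ip_reads=len(ip),
        total_control_reads=len(ctrl),
    )
    return ip, ctrl, truth


def random_sites(
    rng: np.random.Generator,
    length: int,
    n_sites: int,
    min_height: int = 30,
    max_height: int = 100,
    min_separation: int = 8000,
    margin: int = 5000,
) -> Tuple[Tuple[int, int], ...]:
    """Draw site positions with a minimum pairwise separation and edge margin."""
    positions: List[int] = []
    attempts = 0
    while len(positions) < n_sites:
        attempts += 1
        if attempts > 100 * n_sites:
            raise ValueError("cannot place sites; relax separation or enlarge chrom")
        p = int(rng.integers(margin, length - margin))
        if all(abs(p - q) >= min_separation for q in positions):
            positions.append(p)
    positions.sort()
    heights = rng.integers(min_height, max_height + 1, size=n_sites)
    return tuple((p, int(h)) for p, h in zip(positions, heights))


def write_bed(reads: Sequence[ReadAlignment], path: str) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}\n")


def simulate_to_files(spec: SimulationSpec, out_prefix: str) -> TruthTable:
    """Write IP/control BED files, the truth table and a chrom.sizes file."""
    ip, ctrl, truth = simulate_reads(spec)
    write_bed(ip, out_prefix + ".ip.bed")
    write_bed(ctrl, out_prefix + ".control.bed")
    with open(out_prefix + ".truth.tsv", "w") as fh:
        fh.write("position\tn_fragments\n")
        for pos, n in truth.sites:
            fh.write(f"{pos}\t{n}\n")
    with open(out_prefix + ".chrom.sizes", "w") as fh:
        fh.write(f"{spec.chrom}\t{spec.length}\n")
    return truth
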