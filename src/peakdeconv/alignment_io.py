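"""Mapped-read parsing and binned read-count intensity profiles.

ChIP-seq reads are the sequenced 5' ends of immunoprecipitated chromatin
fragments.  Before counting, each read is computationally elongated (in its
own orientation) to the expected fragment length and the elongated intervals
are accumulated into fixed-width bins -- by default 10 bp, the resolution of
the wiggle/bedGraph tracks this module reads and writes.

Coordinates are 0-based half-open everywhere internally and in BED/bedGraph
output; wiggle output follows the 1-based fixedStep convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

logger = logging.getLogger("peakdeconv")

ChromSizes = Dict[str, int]


class BedParseError(ValueError):
    """A malformed line in a BED file (carries the 1-based line number)."""


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped read: 0-based half-open interval plus strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid read interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageProfile:
    """Per-chromosome vectors of binned read-count intensities.

    ``data[chrom][i]`` is the number of elongated reads overlapping the
    genomic interval ``[i * bin_size, (i + 1) * bin_size)`` by at least 1 bp.
    """

    bin_size: int
    data: Dict[str, np.ndarray]
    elongation_used: int
    strand_filter: str = "both"
    sizes: ChromSizes = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    def segment(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Bins fully or partially covering [start_bp, end_bp), clipped."""
        v = self.data[chrom]
        lo = max(0, start_bp // self.bin_size)
        hi = min(len(v), -(-end_bp // self.bin_size))
        return v[lo:hi]

    def total_count(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


def read_chrom_sizes(path: str) -> ChromSizes:
    """Parse a two-column ``name<TAB>length`` chromosome-sizes table."""
    sizes: ChromSizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
            name, length = parts[0], int(parts[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {name}")
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name}")
            sizes[name] = length
    return sizes


def read_bed(path: str, sizes: ChromSizes) -> List[ReadAlignment]:
    """Parse a BED6 file of mapped reads.

    Reads on chromosomes absent from *sizes* are dropped (the count is
    logged); malformed lines raise :class:`BedParseError` naming the line.
    """
    reads: List[ReadAlignment] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 6 BED columns, got {len(parts)}"
                )
            chrom, strand = parts[0], parts[5]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise BedParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if chrom not in sizes:
                dropped += 1
                continue
            if end > sizes[chrom]:
                raise BedParseError(
                    f"{path}:{lineno}: read end {end} beyond {chrom} length {sizes[chrom]}"
                )
            reads.append(ReadAlignment(chrom, start, end, strand))
    if dropped:
        logger.info("read_bed: dropped %d reads on chromosomes absent from sizes", dropped)
    return reads


def read_bam(path: str, sizes: ChromSizes) -> List[ReadAlignment]:
    """Optional BAM/SAM adapter (requires pysam); unmapped reads are skipped."""
    import pysam  # deferred: core package works without it

    reads: List[ReadAlignment] = []
    dropped = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            if aln.reference_name not in sizes:
                dropped += 1
                continue
            reads.append(
                ReadAlignment(
                    aln.reference_name,
                    int(aln.reference_start),
                    int(aln.reference_end),
                    "-" if aln.is_reverse else "+",
                )
            )
    if dropped:
        logger.info("read_bam: dropped %d reads on chromosomes absent from sizes", dropped)
    return reads


def elongate_read(read: ReadAlignment, L: int, sizes: ChromSizes) -> Tuple[int, int]:
    """Extend *read* to length *L* in its orientation, clipped to the chromosome.

    Returns the 0-based half-open elongated interval.  ``L`` must be at least
    the read length (reads are never shrunk).
    """
    if L < read.length:
        raise ValueError(
            f"elongation {L} shorter than read length {read.length}; cannot shrink reads"
        )
    chrom_len = sizes[read.chrom]
    if read.strand == "+":
        s, e = read.start, read.start + L
    else:
        s, e = read.end - L, read.end
    return max(0, s), min(chrom_len, e)


def dedup_reads(reads: Iterable[ReadAlignment]) -> List[ReadAlignment]:
    """Remove exact duplicates (same chrom/start/end/strand), keeping order."""
    seen = set()
    out = []
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def build_coverage(
    reads: Iterable[ReadAlignment],
    sizes: ChromSizes,
    elongation: int,
    bin_size: int = 10,
    strand_filter: str = "both",
) -> CoverageProfile:
    """Elongate reads and count per-bin overlaps into a CoverageProfile.

    A bin is counted once per elongated read whose interval overlaps it by at
    least 1 bp.  Raises ``ValueError`` if no reads survive strand filtering.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if strand_filter not in ("both", "+", "-"):
        raise ValueError(f"strand_filter must be 'both', '+' or '-', got {strand_filter!r}")

    by_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in sizes}
    n_used = 0
    for r in reads:
        if strand_filter != "both" and r.strand != strand_filter:
            continue
        if r.chrom not in sizes:
            continue
        by_chrom[r.chrom].append(elongate_read(r, elongation, sizes))
        n_used += 1
    if n_used == 0:
        raise ValueError("no reads left after strand filtering; cannot build coverage")

    data: Dict[str, np.ndarray] = {}
    for chrom, length in sizes.items():
        nbins = -(-length // bin_size)
        diff = np.zeros(nbins + 1, dtype=np.float64)
        ivals = by_chrom[chrom]
        if ivals:
            arr = np.asarray(ivals, dtype=np.int64)
            b0 = arr[:, 0] // bin_size
            b1 = (arr[:, 1] - 1) // bin_size
            np.add.at(diff, b0, 1.0)
            np.add.at(diff, b1 + 1, -1.0)
        data[chrom] = np.cumsum(diff)[:nbins]
    return CoverageProfile(
        bin_size=bin_size,
        data=data,
        elongation_used=elongation,
        strand_filter=strand_filter,
        sizes=dict(sizes),
    )


def _runs(values: np.ndarray):
    """Yield (start_bin, end_bin, value) for maximal runs of equal value."""
    if len(values) == 0:
        return
    change = np.nonzero(np.diff(values))[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(values)]))
    for s, e in zip(starts, ends):
        yield int(s), int(e), float(values[s])


def write_track(profile: CoverageProfile, path: str, fmt: str = "bedGraph") -> None:
    """Write the profile as a bedGraph or fixedStep wiggle track.

    Zero bins are omitted; both formats round-trip through
    :func:`read_track` to an identical profile given the same sizes table.
    """
    if fmt not in ("bedGraph", "wiggle"):
        raise ValueError(f"unknown track format {fmt!r}")
    bs = profile.bin_size

    def fmt_val(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    with open(path, "w") as fh:
        if fmt == "bedGraph":
            fh.write("track type=bedGraph\n")
            for chrom in profile.data:
                chrom_len = profile.sizes.get(chrom, profile.n_bins(chrom) * bs)
                for s, e, v in _runs(profile.data[chrom]):
                    if v == 0:
                        continue
                    fh.write(
                        f"{chrom}\t{s * bs}\t{min(e * bs, chrom_len)}\t{fmt_val(v)}\n"
                    )
        else:
            fh.write("track type=wiggle_0\n")
            for chrom in profile.data:
                v = profile.data[chrom]
                nz = v != 0
                # contiguous nonzero blocks, one fixedStep header each
                for s, e, flag in _runs(nz.astype(np.float64)):
                    if not flag:
                        continue
                    fh.write(
                        f"fixedStep chrom={chrom} start={s * bs + 1} "
                        f"step={bs} span={bs}\n"
                    )
                    for i in range(s, e):
                        fh.write(fmt_val(v[i]) + "\n")


def read_track(
    path: str,
    sizes: ChromSizes,
    bin_size: int = 10,
    elongation_used: int = 0,
    strand_filter: str = "both",
) -> CoverageProfile:
    """Read a bedGraph or fixedStep wiggle track back into a CoverageProfile."""
    data = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.float64)
        for chrom, length in sizes.items()
    }
    cur_chrom: Optional[str] = None
    cur_bin = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=", 1) for p in line.split()[1:])
                cur_chrom = kv["chrom"]
                if int(kv["step"]) != bin_size or int(kv["span"]) != bin_size:
                    raise ValueError("wiggle step/span does not match bin_size")
                cur_bin = (int(kv["start"]) - 1) // bin_size
                continue
            parts = line.split()
            if len(parts) >= 4:  # bedGraph line
                chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                b0 = s // bin_size
                b1 = -(-e // bin_size)
                data[chrom][b0:b1] = v
            else:  # wiggle value line
                if cur_chrom is None:
                    raise ValueError("wiggle value before fixedStep header")
                data[cur_chrom][cur_bin] = float(parts[0])
                cur_bin += 1
    return CoverageProfile(
        bin_size=bin_size,
        data=data,
        elongation_used=elongation_used,
        strand_filter=strand_filter,
        sizes=dict(sizes),
    )
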