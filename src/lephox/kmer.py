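"""K-mer spectrum genome profiling.

Counts k-mers in shotgun reads, finds the coverage peak of the
multiplicity histogram, converts k-mer coverage C_k to per-base
coverage C via C_k = C * (L - k + 1) / L, and estimates genome size as
total sequenced bases divided by C. Low-multiplicity k-mers arise from
sequencing errors and are excluded from peak finding by a multiplicity
floor; high-multiplicity k-mers reflect repeats and are ignored by the
local-maximum rule.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from ._seq import encode, iter_fastq_seqs


@dataclass
class KmerSpectrum:
    k: int
    histogram: dict[int, int]
    total_kmers: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.histogram.values()):
            raise ValueError("histogram counts must be non-negative")
        expected = sum(m * c for m, c in self.histogram.items())
        if expected != self.total_kmers:
            raise ValueError("total_kmers inconsistent with histogram")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("multiplicity\tcount\n")
            for m in sorted(self.histogram):
                fh.write(f"{m}\t{self.histogram[m]}\n")


@dataclass
class CoverageEstimate:
    ck: float
    c: float
    read_length: int
    k: int


@dataclass
class GenomeSizeEstimate:
    total_bases: int
    coverage: float
    genome_size: float


def _codes_iter(reads) -> Iterable[np.ndarray]:
    """Yield 2-bit code arrays, one per read (255 = non-ACGT)."""
    if isinstance(reads, (str, Path)):
        reads = iter_fastq_seqs(reads)
    if isinstance(reads, np.ndarray):
        yield from reads
        return
    for r in reads:
        if isinstance(r, np.ndarray):
            yield r
        else:
            yield encode(r)


def count_kmers(reads, k: int = 17, canonical: bool = True) -> KmerSpectrum:
    """Exact hash-based k-mer counting over a read set.

    ``reads`` may be a FASTQ(.gz) path, an iterable of strings, or 2-bit
    code arrays (e.g. :class:`~lephox.synthetic.ReadSet` matrices).
    Canonical mode pools each k-mer with its reverse complement.
    K-mers containing non-ACGT characters are skipped; reads shorter
    than k contribute nothing (an empty spectrum triggers a warning).
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31] (2-bit packing guard)")
    if k % 2 == 0 and canonical:
        warnings.warn("even k makes some k-mers their own reverse complement peers")
    # concatenate with a sentinel separator so windows never span reads
    chunks = []
    sep = np.full(1, 255, dtype=np.uint8)
    for codes in _codes_iter(reads):
        chunks.append(codes)
        chunks.append(sep)
    if not chunks:
        warnings.warn("no reads supplied; empty spectrum")
        return KmerSpectrum(k=k, histogram={}, total_kmers=0)
    cat = np.concatenate(chunks)
    n = cat.size
    if n < k:
        warnings.warn("k exceeds read length; empty spectrum")
        return KmerSpectrum(k=k, histogram={}, total_kmers=0)
    valid_base = cat != 255
    base = np.where(valid_base, cat, 0).astype(np.int64)
    W = n - k + 1
    fwd = np.zeros(W, dtype=np.int64)
    rev = np.zeros(W, dtype=np.int64)
    ok = np.ones(W, dtype=bool)
    for i in range(k):
        seg = base[i : i + W]
        fwd += seg << (2 * (k - 1 - i))
        rev += (3 - seg) << (2 * i)
        ok &= valid_base[i : i + W]
    codes = np.minimum(fwd, rev) if canonical else fwd
    codes = codes[ok]
    if codes.size == 0:
        warnings.warn("no valid k-mers found; empty spectrum")
        return KmerSpectrum(k=k, histogram={}, total_kmers=0)
    _, counts = np.unique(codes, return_counts=True)
    mults, mult_counts = np.unique(counts, return_counts=True)
    histogram = {int(m): int(c) for m, c in zip(mults, mult_counts)}
    return KmerSpectrum(k=k, histogram=histogram, total_kmers=int(codes.size))


def find_peak(spectrum: KmerSpectrum, min_multiplicity: int = 4) -> float:
    """Locate the k-mer coverage peak of the spectrum.

    The peak is the local maximum of the count histogram at multiplicity
    >= ``min_multiplicity`` (skipping the error ramp at low
    multiplicity) with the highest count, refined to sub-integer
    resolution by 3-point quadratic interpolation over its neighbours.
    Raises ``ValueError`` if no local maximum exists above the floor.
    """
    if not spectrum.histogram:
        raise ValueError("empty spectrum has no peak")
    max_mult = max(spectrum.histogram)
    dense = np.zeros(max_mult + 2, dtype=float)
    for m, c in spectrum.histogram.items():
        dense[m] = c
    best = None
    for m in range(max(1, min_multiplicity), max_mult + 1):
        left = dense[m - 1] if m > 1 else -np.inf
        if dense[m] > left and dense[m] >= dense[m + 1] and dense[m] > 0:
            if best is None or dense[m] > dense[best]:
                best = m
    if best is None:
        raise ValueError(
            "no coverage peak above the error-ramp floor; "
            "spectrum is uninterpretable"
        )
    ym1, y0, yp1 = dense[best - 1] if best > 1 else 0.0, dense[best], dense[best + 1]
    denom = ym1 - 2 * y0 + yp1
    if denom < 0:
        return float(best + 0.5 * (ym1 - yp1) / denom)
    return float(best)


def kmer_to_base_coverage(ck: float, read_length: int, k: int) -> float:
    """Convert k-mer coverage to base coverage: C = C_k * L / (L - k + 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if read_length <= k:
        raise ValueError("read length must exceed k")
    return ck * read_length / (read_length - k + 1)


def estimate_genome_size(total_bases: int, coverage: float) -> float:
    """Genome size = total sequenced bases / per-base coverage."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    return total_bases / coverage


def peak_region_coverage(
    spectrum: KmerSpectrum,
    min_multiplicity: int = 4,
    region_factor: float = 2.5,
) -> tuple[float, int]:
    """Refined k-mer coverage and k-mer mass of the genomic peak region.

    :func:`find_peak` locates the mode of the multiplicity histogram,
    but for a Poisson-like sampling distribution the mode sits about
    half a unit below the mean multiplicity, which is the quantity the
    coverage formula wants. This refines the estimate to the mean
    multiplicity over the peak region [min_multiplicity,
    region_factor * peak] — excluding the error ramp below and deep
    repeat k-mers above — and also returns the total k-mer mass
    (sum of multiplicity x count) of that region.
    """
    peak = find_peak(spectrum, min_multiplicity=min_multiplicity)
    hi = math.ceil(region_factor * peak)
    mass = distinct = 0
    for m, c in spectrum.histogram.items():
        if min_multiplicity <= m <= hi:
            mass += m * c
            distinct += c
    if distinct == 0:
        raise ValueError("no k-mers in the peak region")
    return mass / distinct, mass


def profile_reads(
    reads,
    total_bases: int,
    read_length: int,
    k: int = 17,
    canonical: bool = True,
    min_multiplicity: int = 4,
) -> dict:
    """Run the full chain count -> peak -> convert -> genome size.

    Coverage comes from the mean multiplicity of the genomic peak
    region (see :func:`peak_region_coverage`), and the base count fed
    to the genome-size formula is the k-mer mass of that region
    converted to base space — i.e. sequencing errors, which spill
    genomic k-mers into the low-multiplicity ramp, are excluded from
    both numerator and denominator. ``total_bases`` (the raw sequenced
    bases) is echoed in the report as ``input_bases``.

    Returns a JSON-ready report with k, ck, c, total_bases,
    genome_size, input_bases.
    """
    spectrum = count_kmers(reads, k=k, canonical=canonical)
    ck, mass = peak_region_coverage(spectrum, min_multiplicity=min_multiplicity)
    c = kmer_to_base_coverage(ck, read_length, k)
    genomic_bases = mass * read_length / (read_length - k + 1)
    size = estimate_genome_size(genomic_bases, c)
    return {
        "k": k,
        "ck": ck,
        "c": c,
        "total_bases": genomic_bases,
        "genome_size": size,
        "input_bases": total_bases,
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
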