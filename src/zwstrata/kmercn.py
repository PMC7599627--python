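"""Gene copy-number estimation from k-mer depth.

A gene present at c copies per haploid genome contributes k-mers at c times
the haploid coverage. Counting canonical k-mers (k = 27 by default) in
whole-genome reads gives a spectrum whose homozygous peak sits at the
diploid coverage; half of that peak is the haploid coverage, and the median
count of the gene's own k-mers divided by the haploid coverage estimates the
copy number.

Counting is vectorized: bases are 2-bit encoded and k-mers accumulated with
a rolling shift, so k is limited to 31 (2k + 2 bits must fit an unsigned
64-bit integer). k must be odd so no k-mer equals its own reverse complement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np


@dataclass(frozen=True)
class KmerConfig:
    k: int = 27
    canonical: bool = True
    error_floor: int = 4  # lowest multiplicity eligible as the spectrum peak

    def __post_init__(self) -> None:
        if not (1 < self.k <= 31):
            raise ValueError("k must be in (1, 31]")
        if self.k % 2 == 0:
            raise ValueError("k must be odd (avoids palindromic k-mers)")


@dataclass
class KmerTable:
    """Distinct canonical k-mers (sorted 2-bit encodings) and their counts."""

    kmers: np.ndarray
    counts: np.ndarray

    def lookup(self, queries: np.ndarray) -> np.ndarray:
        """Counts for encoded k-mers; absent k-mers count 0."""
        idx = np.searchsorted(self.kmers, queries)
        idx = np.clip(idx, 0, self.kmers.size - 1) if self.kmers.size else idx
        if self.kmers.size == 0:
            return np.zeros(queries.size, dtype=np.int64)
        hit = self.kmers[idx] == queries
        out = np.zeros(queries.size, dtype=np.int64)
        out[hit] = self.counts[idx[hit]]
        return out

    def histogram(self) -> dict[int, int]:
        mult, n = np.unique(self.counts, return_counts=True)
        return {int(m): int(c) for m, c in zip(mult, n)}


@dataclass(frozen=True)
class CopyNumberEstimate:
    gene_id: str
    haploid_coverage: float
    median_gene_kmer_count: float
    copy_number: float
    rounded_copy_number: int


_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[ord(chr(_b).lower())] = _i


def _encode_sequences(seqs: Iterable[str]) -> np.ndarray:
    """Concatenate sequences into one code array with 255 separators."""
    parts = []
    for s in seqs:
        parts.append(_LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)])
        parts.append(np.array([255], dtype=np.uint8))
    if not parts:
        return np.array([], dtype=np.uint8)
    return np.concatenate(parts)


def _window_kmers(codes: np.ndarray, k: int, canonical: bool) -> np.ndarray:
    """All valid k-mer encodings from a code array (255 = invalid base)."""
    n = codes.size
    if n < k:
        return np.array([], dtype=np.uint64)
    nwin = n - k + 1
    valid = codes != 255
    bad = (~valid).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    window_ok = (cum[k:] - cum[:-k]) == 0  # no invalid base inside window
    c64 = codes.astype(np.uint64)
    fwd = np.zeros(nwin, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | np.where(valid[j : j + nwin], c64[j : j + nwin], 0)
    if not canonical:
        return fwd[window_ok]
    rc_codes = np.where(valid, np.uint64(3) - c64, np.uint64(0))
    rev = np.zeros(nwin, dtype=np.uint64)
    for j in range(k - 1, -1, -1):
        rev = (rev << np.uint64(2)) | rc_codes[j : j + nwin]
    canon = np.minimum(fwd, rev)
    return canon[window_ok]


def count_kmers(
    reads: Iterable[str], config: KmerConfig = KmerConfig(), chunk_bases: int = 20_000_000
) -> KmerTable:
    """Count canonical k-mers across reads (k-mers containing N are skipped)."""
    chunks: list[np.ndarray] = []
    counts_chunks: list[np.ndarray] = []
    buf: list[str] = []
    size = 0

    def flush():
        nonlocal buf, size
        if not buf:
            return
        codes = _encode_sequences(buf)
        km = _window_kmers(codes, config.k, config.canonical)
        if km.size:
            u, c = np.unique(km, return_counts=True)
            chunks.append(u)
            counts_chunks.append(c.astype(np.int64))
        buf, size = [], 0

    for r in reads:
        buf.append(r)
        size += len(r)
        if size >= chunk_bases:
            flush()
    flush()
    if not chunks:
        return KmerTable(np.array([], dtype=np.uint64), np.array([], dtype=np.int64))
    if len(chunks) == 1:
        return KmerTable(chunks[0], counts_chunks[0])
    allk = np.concatenate(chunks)
    allc = np.concatenate(counts_chunks)
    u, inv = np.unique(allk, return_inverse=True)
    tot = np.zeros(u.size, dtype=np.int64)
    np.add.at(tot, inv, allc)
    return KmerTable(u, tot)


def haploid_coverage(
    histogram: dict[int, int],
    config: KmerConfig = KmerConfig(),
    smooth_width: int = 3,
    peak: str = "mode",
) -> float:
    """Half the k-mer coverage at the spectrum peak.

    The sequencing-error spike at low multiplicity is excluded by
    ``error_floor``; the remaining spectrum is smoothed with a width-3
    moving average and its mode (default) taken as the homozygous-peak
    coverage. ``peak='mean'`` instead uses the count-weighted mean
    multiplicity above the floor. Haploid coverage is half the peak.
    """
    if not histogram:
        raise ValueError("empty k-mer histogram")
    max_mult = max(histogram)
    dense = np.zeros(max_mult + 1, dtype=float)
    for m, c in histogram.items():
        if m < 0:
            raise ValueError("negative multiplicity")
        dense[m] = c
    eligible = np.arange(max_mult + 1) >= config.error_floor
    if not np.any(eligible & (dense > 0)):
        raise ValueError("no k-mer multiplicity at or above error_floor: coverage too low")
    if peak == "mean":
        mult = np.arange(max_mult + 1, dtype=float)
        w = np.where(eligible, dense, 0.0)
        return float((mult * w).sum() / w.sum() / 2.0)
    if peak != "mode":
        raise ValueError("peak must be 'mode' or 'mean'")
    kernel = np.ones(smooth_width) / smooth_width
    smoothed = np.convolve(dense, kernel, mode="same")
    smoothed[~eligible] = -1.0
    return float(np.argmax(smoothed)) / 2.0


def gene_kmer_counts(
    cds_sequence: str, table: KmerTable, config: KmerConfig = KmerConfig()
) -> np.ndarray:
    """Genomic counts of each distinct canonical k-mer of a CDS (0 if absent)."""
    if len(cds_sequence) < config.k:
        raise ValueError("CDS shorter than k")
    codes = _LUT[np.frombuffer(cds_sequence.encode("ascii"), dtype=np.uint8)]
    km = _window_kmers(codes, config.k, config.canonical)
    if km.size == 0:
        raise ValueError("CDS contains no valid k-mer")
    distinct = np.unique(km)
    return table.lookup(distinct)


def estimate_copy_number(
    counts: np.ndarray, haploid_cov: float, gene_id: str = "gene"
) -> CopyNumberEstimate:
    """Copy number = median gene-k-mer count / haploid coverage.

    Zero counts (k-mers absent from the reads) stay in the median so a
    deleted gene estimates 0. Rounding is to the nearest integer, ties
    half up.
    """
    if len(counts) == 0:
        raise ValueError("no gene k-mer counts")
    if haploid_cov <= 0:
        raise ValueError("haploid coverage must be positive")
    med = float(np.median(counts))
    cn = med / haploid_cov
    return CopyNumberEstimate(gene_id, haploid_cov, med, cn, int(math.floor(cn + 0.5)))


def copy_number_from_reads(
    reads: Iterable[str], cds_sequence: str, config: KmerConfig = KmerConfig(),
    gene_id: str = "gene", peak: str = "mode",
) -> CopyNumberEstimate:
    """End-to-end: count read k-mers, locate the peak, estimate copy number."""
    table = count_kmers(reads, config)
    hap = haploid_coverage(table.histogram(), config, peak=peak)
    counts = gene_kmer_counts(cds_sequence, table, config)
    return estimate_copy_number(counts, hap, gene_id)
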