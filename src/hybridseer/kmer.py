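"""Canonical k-mer spectra, coverage-peak detection, and genome sizing.

A diploid read set produces a bimodal k-mer multiplicity histogram: k-mers
spanning a heterozygous site occur on one haplotype only and pile up at the
heterozygous depth ``c_het``, while k-mers shared by both haplotypes pile up
at ``c_hom ~ 2 c_het``. The haploid genome size follows by dividing the
k-mer volume (or the total read length, converted between base and k-mer
depth) by the homozygous peak depth; dividing by the heterozygous peak depth
instead bounds the diploid size, counting both haplotypes of every
heterozygous region separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_K = 17
DEFAULT_MAX_MULTIPLICITY = 10_000

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i


class SpectrumError(ValueError):
    pass


@dataclass
class KmerSpectrum:
    """Histogram of canonical k-mer multiplicities.

    ``histogram[m]`` is the number of distinct canonical k-mers seen exactly
    ``m`` times; the last bin is an overflow bin collecting multiplicities
    beyond it (repeats contribute volume there, never peaks).
    """

    k: int
    histogram: np.ndarray  # index = multiplicity, 0..max_multiplicity
    total_kmer_instances: int
    total_read_bases: int
    n_reads: int
    n_short_reads_skipped: int = 0

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 11:
            raise SpectrumError("k must be odd and >= 11")
        if (self.histogram < 0).any():
            raise SpectrumError("negative histogram counts")
        volume = int((np.arange(len(self.histogram)) * self.histogram).sum())
        # exact when the overflow bin is empty; the overflow bin undercounts
        if self.histogram[-1] == 0 and volume != self.total_kmer_instances:
            raise SpectrumError(
                f"histogram volume {volume} != instances {self.total_kmer_instances}"
            )

    @property
    def mean_read_length(self) -> float:
        return self.total_read_bases / self.n_reads if self.n_reads else 0.0

    def to_tsv(self, path) -> None:
        """Write ``multiplicity<TAB>count`` (JELLYFISH-histo compatible)."""
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\n")
            fh.write(f"# total_kmer_instances={self.total_kmer_instances}\n")
            fh.write(f"# total_read_bases={self.total_read_bases}\n")
            fh.write(f"# n_reads={self.n_reads}\n")
            for m in np.flatnonzero(self.histogram):
                fh.write(f"{m}\t{self.histogram[m]}\n")

    @classmethod
    def from_tsv(cls, path, k: int | None = None) -> "KmerSpectrum":
        meta = {}
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("# ")
                    if "=" in body:
                        key, val = body.split("=", 1)
                        meta[key.strip()] = val.strip()
                    continue
                m, c = line.split("\t")
                pairs.append((int(m), int(c)))
        if not pairs:
            raise SpectrumError(f"{path}: empty histogram")
        max_m = max(m for m, _ in pairs)
        hist = np.zeros(max_m + 1, np.int64)
        for m, c in pairs:
            hist[m] += c
        instances = int(meta.get("total_kmer_instances",
                                 (np.arange(max_m + 1) * hist).sum()))
        return cls(
            k=int(meta.get("k", k or DEFAULT_K)),
            histogram=hist,
            total_kmer_instances=instances,
            total_read_bases=int(meta.get("total_read_bases", 0)),
            n_reads=int(meta.get("n_reads", 0)),
        )


def count_kmers(
    source,
    k: int = DEFAULT_K,
    max_multiplicity: int = DEFAULT_MAX_MULTIPLICITY,
) -> KmerSpectrum:
    """Count canonical k-mers exactly from reads.

    *source* may be a FASTQ path (optionally gzipped), an iterable of
    sequences (str/bytes), or a :class:`~hybridseer.simulate.ReadSet`. Each
    k-mer is counted under the lexicographic minimum of itself and its
    reverse complement, encoded as a 2k-bit integer; windows containing a
    non-ACGT base are skipped, and reads shorter than k are skipped with a
    logged count.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise SpectrumError("k must be odd, 11 <= k <= 31")
    if isinstance(source, (str, Path)):
        from hybridseer.io import iter_fastq

        seq_iter: Iterable = (seq for _t, seq, _q in iter_fastq(source))
    elif hasattr(source, "iter_seq_bytes"):
        seq_iter = source.iter_seq_bytes()
    else:
        seq_iter = source

    chunks: list[np.ndarray] = []
    buf: list[bytes] = []
    buf_len = 0
    total_bases = 0
    n_reads = 0
    n_short = 0
    CHUNK = 8 << 20

    def flush() -> None:
        nonlocal buf, buf_len
        if not buf:
            return
        arr = np.frombuffer(b"N".join(buf), dtype=np.uint8)
        codes = _ENC[arr]
        n_win = len(codes) - k + 1
        if n_win > 0:
            bad = (codes > 3).astype(np.int64)
            badcum = np.concatenate([[0], np.cumsum(bad)])
            valid = (badcum[k:] - badcum[:-k]) == 0
            c = np.where(codes > 3, 0, codes).astype(np.int64)
            fwd = np.zeros(n_win, np.int64)
            for j in range(k):
                fwd = (fwd << 2) | c[j : j + n_win]
            rc = np.zeros(n_win, np.int64)
            for j in range(k - 1, -1, -1):
                rc = (rc << 2) | (3 - c[j : j + n_win])
            canon = np.minimum(fwd, rc)[valid]
            if canon.size:
                chunks.append(canon)
        buf, buf_len = [], 0

    for seq in seq_iter:
        if isinstance(seq, str):
            seq = seq.encode()
        if len(seq) < k:
            n_short += 1
            continue
        total_bases += len(seq)
        n_reads += 1
        buf.append(seq)
        buf_len += len(seq) + 1
        if buf_len >= CHUNK:
            flush()
    flush()

    if n_short:
        logger.info("count_kmers: skipped %d reads shorter than k=%d", n_short, k)
    if chunks:
        all_codes = np.concatenate(chunks)
        chunks.clear()
        _vals, counts = np.unique(all_codes, return_counts=True)
        instances = int(all_codes.size)
        del all_codes
        hist = np.bincount(
            np.minimum(counts, max_multiplicity), minlength=max_multiplicity + 1
        ).astype(np.int64)
        hist[0] = 0
    else:
        instances = 0
        hist = np.zeros(max_multiplicity + 1, np.int64)
    return KmerSpectrum(
        k=k,
        histogram=hist,
        total_kmer_instances=instances,
        total_read_bases=total_bases,
        n_reads=n_reads,
        n_short_reads_skipped=n_short,
    )


# ---------------------------------------------------------------------------
# Peak fitting


@dataclass
class PeakModel:
    """Fitted error trough and het/hom coverage peaks of a spectrum."""

    error_trough: int
    hom_peak_depth: int
    hom_peak_height: float
    het_peak_depth: int | None = None
    het_peak_height: float | None = None
    error_volume: int = 0
    het_volume: int = 0
    hom_volume: int = 0
    haploid_size: float | None = None
    diploid_size: float | None = None

    @property
    def has_het_peak(self) -> bool:
        return self.het_peak_depth is not None

    @property
    def het_volume_fraction(self) -> float:
        genuine = self.het_volume + self.hom_volume
        return self.het_volume / genuine if genuine else 0.0

    def to_dict(self) -> dict:
        return {
            "error_trough": self.error_trough,
            "het_peak_depth": self.het_peak_depth,
            "hom_peak_depth": self.hom_peak_depth,
            "het_peak_height": self.het_peak_height,
            "hom_peak_height": self.hom_peak_height,
            "error_volume": self.error_volume,
            "het_volume": self.het_volume,
            "hom_volume": self.hom_volume,
            "het_volume_fraction": self.het_volume_fraction,
            "haploid_size": self.haploid_size,
            "diploid_size": self.diploid_size,
        }


class InsufficientCoverageError(SpectrumError):
    """No coverage peak beyond the error trough."""


HET_WINDOW = (0.35, 0.65)  # accepted c_het / c_hom range
_MIN_PEAK_FRACTION = 0.01  # candidate height floor vs tallest candidate
_SMOOTH_WINDOW = 3


def _smooth(y: np.ndarray, w: int = _SMOOTH_WINDOW) -> np.ndarray:
    kernel = np.ones(w) / w
    return np.convolve(y, kernel, mode="same")


def fit_peaks(spectrum: KmerSpectrum) -> PeakModel:
    """Locate the error trough and the het/hom coverage peaks.

    The histogram is smoothed with a 3-bin moving average; the error trough
    is the end of the initial descent; candidate peaks are smoothed local
    maxima beyond it (the overflow bin excluded). The homozygous peak is the
    greater-multiplicity member of the two tallest candidates; the
    heterozygous peak is the candidate nearest ``c_hom/2`` inside the
    ``[0.35, 0.65] x c_hom`` window and at least 1% of the tallest
    candidate's height — absent otherwise.
    """
    hist = spectrum.histogram.astype(float)
    M = len(hist) - 1  # overflow bin index, excluded from peak search
    if hist[1:M].sum() == 0:
        raise InsufficientCoverageError("empty spectrum")
    padded = hist.copy()
    padded[0] = padded[1]  # multiplicity 0 never exists; avoid an edge dip
    smooth = _smooth(padded)

    t = 1
    while t + 1 < M and smooth[t + 1] < smooth[t]:
        t += 1
    trough = t

    cand = [
        m
        for m in range(trough + 1, M - 1)
        if smooth[m] >= smooth[m - 1] and smooth[m] > smooth[m + 1]
    ]
    if not cand:
        raise InsufficientCoverageError(
            f"no coverage peak beyond error trough at {trough}"
        )
    heights = {m: smooth[m] for m in cand}
    top2 = sorted(cand, key=lambda m: heights[m], reverse=True)[:2]
    hom = max(top2)
    min_height = _MIN_PEAK_FRACTION * max(heights.values())

    lo, hi = HET_WINDOW[0] * hom, HET_WINDOW[1] * hom
    het_cands = [
        m for m in cand if m != hom and lo <= m <= hi and heights[m] >= min_height
    ]
    het = min(het_cands, key=lambda m: (abs(m - hom / 2), -heights[m])) if het_cands else None

    mult = np.arange(len(hist))
    vol = mult * spectrum.histogram
    error_volume = int(vol[:trough].sum())
    if het is not None:
        boundary = int(round((het + hom) / 2))
        het_volume = int(vol[trough:boundary].sum())
        hom_volume = int(vol[boundary:].sum())
    else:
        het_volume = 0
        hom_volume = int(vol[trough:].sum())
    return PeakModel(
        error_trough=trough,
        hom_peak_depth=int(hom),
        hom_peak_height=float(smooth[hom]),
        het_peak_depth=int(het) if het is not None else None,
        het_peak_height=float(smooth[het]) if het is not None else None,
        error_volume=error_volume,
        het_volume=het_volume,
        hom_volume=hom_volume,
    )


def estimate_genome_size(
    spectrum: KmerSpectrum, peaks: PeakModel, basis: str = "kmers"
) -> tuple[float, float]:
    """Estimate haploid and maximum diploid genome size from fitted peaks.

    ``basis="kmers"`` (default) divides the genuine k-mer volume (instances
    minus the error volume below the trough) by the peak depth:
    ``haploid = volume / c_hom`` and, when a heterozygous peak exists,
    ``diploid = volume / c_het`` — the heterozygous depth counts each
    haplotype of a heterozygous region once, so dividing by it bounds the
    two-haplotype total. ``basis="read_length"`` divides the total read
    length by the peak depth converted from k-mer to base coverage via
    ``R / (R - k + 1)``. Updates *peaks* in place and returns
    ``(haploid_size, diploid_size)``.
    """
    if peaks.hom_peak_depth is None or peaks.hom_peak_depth <= 0:
        raise SpectrumError("homozygous peak absent")
    c_hom = float(peaks.hom_peak_depth)
    c_het = float(peaks.het_peak_depth) if peaks.has_het_peak else None
    if basis == "kmers":
        volume = spectrum.total_kmer_instances - peaks.error_volume
        haploid = volume / c_hom
        diploid = volume / c_het if c_het else haploid
    elif basis == "read_length":
        R = spectrum.mean_read_length
        if R <= spectrum.k:
            raise SpectrumError("mean read length must exceed k")
        factor = R / (R - spectrum.k + 1)  # k-mer depth -> base depth
        haploid = spectrum.total_read_bases / (c_hom * factor)
        diploid = spectrum.total_read_bases / (c_het * factor) if c_het else haploid
    else:
        raise ValueError(f"unknown basis {basis!r}")
    peaks.haploid_size = haploid
    peaks.diploid_size = diploid
    return haploid, diploid
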