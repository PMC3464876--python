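"""Sequence composition analyses: cut-site base preference, GC content and
profiles, CpG-island calling and hotspot/island overlap.

The cut-site readout is strand-relative: for a minus-strand tag the window
around the 5' end is read on the reverse complement, so offset 0 is always
the first sequenced base and negative offsets lie upstream of the cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BASE_CODES, GenomeSequence, GenomicInterval, TagLibrary

__all__ = [
    "BaseFrequencyProfile",
    "GcProfile",
    "cut_site_base_frequency",
    "gc_content",
    "gc_profile_around",
    "find_cpg_islands",
    "cpg_overlap_fraction",
]

_A, _C, _G, _T, _N = (BASE_CODES[b] for b in "ACGTN")
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


@dataclass
class BaseFrequencyProfile:
    """Per-offset base frequencies around tag 5' ends.

    ``frequencies`` is a DataFrame indexed by offset (-k .. k-1, 0 = cut
    base) with columns A, C, G, T summing to 1 per offset; tags whose window
    leaves the contig, or with N at an offset, are excluded from that
    offset's denominator (tracked in ``counts``).
    """

    frequencies: pd.DataFrame
    counts: pd.Series
    n_tags: int

    def modal_base(self, offset: int = 0) -> str:
        return str(self.frequencies.loc[offset].idxmax())


@dataclass
class GcProfile:
    """Mean GC fraction per positional bin around anchor midpoints."""

    bin_starts: np.ndarray  # offset of each bin's left edge
    mean_gc: np.ndarray
    n_anchors: int


def cut_site_base_frequency(
    library: TagLibrary, genome: GenomeSequence, k: int = 10
) -> BaseFrequencyProfile:
    """Base frequencies at offsets -k..k-1 around every tag's cut site.

    The 2k-base window is read in the tag's strand orientation (reverse
    complement for minus-strand tags); offset 0 is the first base of the
    tag. Tags too close to a contig edge contribute only their in-range
    offsets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    offsets = np.arange(-k, k)
    tally = np.zeros((2 * k, 5), dtype=np.int64)
    df = library.frame
    contigs = df["contig"].to_numpy()
    cuts = library.cut_sites_per_tag()
    strands = df["strand"].to_numpy()
    for name in pd.unique(contigs):
        codes = genome.encoded(name)
        L = len(codes)
        sel = contigs == name
        for strand in ("+", "-"):
            ssel = sel & (strands == strand)
            if not ssel.any():
                continue
            c = cuts[ssel]
            if strand == "+":
                # offset o -> plus position c + o
                pos = c[:, None] + offsets[None, :]
            else:
                # offset o -> plus position (c - 1) - o, complemented
                pos = (c[:, None] - 1) - offsets[None, :]
            valid = (pos >= 0) & (pos < L)
            codes_at = np.full(pos.shape, _N, dtype=np.uint8)
            codes_at[valid] = codes[pos[valid]]
            if strand == "-":
                codes_at = _COMP_CODE[codes_at]
            codes_at[~valid] = _N  # out-of-range: excluded, not counted as N base
            for col in range(2 * k):
                tally[col] += np.bincount(codes_at[:, col], minlength=5)
    acgt = tally[:, :4].astype(float)
    denom = acgt.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = acgt / denom[:, None]
    frequencies = pd.DataFrame(freq, index=offsets, columns=list("ACGT"))
    frequencies.index.name = "offset"
    return BaseFrequencyProfile(
        frequencies=frequencies,
        counts=pd.Series(denom.astype(np.int64), index=offsets, name="n"),
        n_tags=library.size,
    )


def gc_content(
    intervals: list[GenomicInterval], genome: GenomeSequence
) -> np.ndarray:
    """(G+C)/(A+C+G+T) per interval; N bases excluded from the denominator.

    An interval consisting entirely of N returns NaN.
    """
    out = np.empty(len(intervals))
    for i, iv in enumerate(intervals):
        codes = genome.encoded(iv.contig)[iv.start : iv.end]
        known = codes != _N
        denom = int(known.sum())
        if denom == 0:
            out[i] = np.nan
            continue
        gc = int(((codes == _C) | (codes == _G)).sum())
        out[i] = gc / denom
    return out


def gc_profile_around(
    anchors: list[GenomicInterval],
    genome: GenomeSequence,
    flank: int = 2000,
    bin_width: int = 10,
) -> GcProfile:
    """Mean GC fraction per bin across anchors, spanning +/- flank around
    each anchor's midpoint."""
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin_width")
    bin_starts = np.arange(-flank, flank, bin_width)
    sums = np.zeros(len(bin_starts))
    counts = np.zeros(len(bin_starts))
    for iv in anchors:
        codes = genome.encoded(iv.contig)
        mid = iv.midpoint
        for bi, off in enumerate(bin_starts):
            s, e = mid + off, mid + off + bin_width
            if s < 0 or e > len(codes):
                continue
            seg = codes[s:e]
            known = seg != _N
            if not known.any():
                continue
            gc = ((seg == _C) | (seg == _G)).sum()
            sums[bi] += gc / known.sum()
            counts[bi] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    return GcProfile(bin_starts=bin_starts, mean_gc=mean, n_anchors=len(anchors))


def find_cpg_islands(
    genome: GenomeSequence,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    window: int = 200,
) -> list[GenomicInterval]:
    """CpG islands by sliding-window composition criteria.

    A window of ``window`` bp (step 1) qualifies when its GC fraction is at
    least ``min_gc`` and its CpG observed/expected ratio
    ``(#CG * window) / (#C * #G)`` is at least ``min_oe``; qualifying
    windows are merged into maximal regions, which are kept when at least
    ``min_len`` bp long. These are the classical Gardiner-Garden–Frommer
    criteria. Contigs shorter than the window are skipped.
    """
    islands: list[GenomicInterval] = []
    for name, length in genome.lengths.items():
        if length < window:
            continue
        codes = genome.encoded(name)
        c = (codes == _C).astype(np.int64)
        g = (codes == _G).astype(np.int64)
        cg = ((codes[:-1] == _C) & (codes[1:] == _G)).astype(np.int64)
        ccum = np.concatenate([[0], np.cumsum(c)])
        gcum = np.concatenate([[0], np.cumsum(g)])
        cgcum = np.concatenate([[0], np.cumsum(cg)])
        starts = np.arange(0, length - window + 1)
        nC = ccum[starts + window] - ccum[starts]
        nG = gcum[starts + window] - gcum[starts]
        # dinucleotides fully inside the window start at s .. s+window-2
        nCG = cgcum[starts + window - 1] - cgcum[starts]
        gc_ok = (nC + nG) >= min_gc * window
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = np.where(nC * nG > 0, nCG * window / (nC * nG), 0.0)
        qual = gc_ok & (oe >= min_oe)
        qs = starts[qual]
        if len(qs) == 0:
            continue
        # merge overlapping qualifying windows
        breaks = np.flatnonzero(np.diff(qs) > window) + 1
        for lo, hi in zip(
            np.concatenate([[0], breaks]), np.concatenate([breaks, [len(qs)]])
        ):
            s, e = int(qs[lo]), int(qs[hi - 1]) + window
            if e - s >= min_len:
                islands.append(GenomicInterval(name, s, e))
    return islands


def cpg_overlap_fraction(
    hotspots, islands: list[GenomicInterval]
) -> float:
    """Share of hotspots overlapping (>= 1 bp) any CpG island."""
    intervals = [h.interval for h in hotspots] if hasattr(hotspots, "hotspots") else list(hotspots)
    if len(intervals) == 0:
        return 0.0
    by_contig: dict[str, np.ndarray] = {}
    for name in {iv.contig for iv in islands}:
        arr = np.array(
            sorted((iv.start, iv.end) for iv in islands if iv.contig == name),
            dtype=np.int64,
        )
        by_contig[name] = arr
    hit = 0
    for iv in intervals:
        arr = by_contig.get(iv.contig)
        if arr is None or len(arr) == 0:
            continue
        k = np.searchsorted(arr[:, 0], iv.end, side="left")
        if k and (arr[:k, 1] > iv.start).any():
            hit += 1
    return hit / len(intervals)
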