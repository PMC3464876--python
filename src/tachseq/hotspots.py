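"""Hotspot calling: binomial local-background scan with empirical FDR-0.

The scan statistic follows the classical hotspot approach for nuclease-
cleavage tag data: for every ``small_window`` bp window (stepped by
``step``) the tag count ``n`` is compared with the count ``N`` in a large
centred ``background_window``, under the null that each background tag
falls in the small window independently with probability
``p = small_window / effective background length``:

    z = (n - N p) / sqrt(N p (1 - p))

The calling threshold is empirical: tags are placed uniformly at random
over the genome ``n_randomizations`` times and the threshold is set just
above the largest z observed in any randomization, so the expected number
of passing windows under the null is zero ("FDR of 0%"). Windows above
threshold are merged, trimmed to the span of their cut sites, and finally
filtered by a tag-density threshold at the mode of the log-density
histogram.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import GenomicInterval, Hotspot, HotspotSet, TagLibrary

__all__ = [
    "HotspotParams",
    "scan_zscores",
    "estimate_fdr0_threshold",
    "call_hotspots",
    "apply_mode_threshold",
    "mito_fraction",
]


@dataclass(frozen=True)
class HotspotParams:
    """Tunables of the scan; defaults are the method's canonical scales."""

    small_window: int = 250
    background_window: int = 200_000
    step: int = 50
    n_randomizations: int = 20
    merge_gap: int | None = None  # None -> small_window
    mode_bin_width: float = 0.1  # log10 density units
    mito_contig: str = "chrM"

    def __post_init__(self):
        if not self.small_window < self.background_window:
            raise ValueError("small_window must be < background_window")
        if not (0 < self.step <= self.small_window):
            raise ValueError("step must satisfy 0 < step <= small_window")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")

    @property
    def gap(self) -> int:
        return self.small_window if self.merge_gap is None else self.merge_gap


def _contig_lengths(genome_lengths) -> dict[str, int]:
    if hasattr(genome_lengths, "lengths"):  # GenomeSequence
        return dict(genome_lengths.lengths)
    return dict(genome_lengths)


def _scan_contig(
    cuts: np.ndarray, length: int, params: HotspotParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised window scan of one contig.

    Returns (window_starts, n, N, z) for windows with N > 0. Windows whose
    clipped background is not longer than the small window are skipped
    (the binomial model degenerates at p >= 1).
    """
    small, bg, step = params.small_window, params.background_window, params.step
    if length < small:
        empty = np.empty(0)
        return empty.astype(np.int64), empty, empty, empty
    starts = np.arange(0, length - small + 1, step, dtype=np.int64)
    n = (
        np.searchsorted(cuts, starts + small, side="left")
        - np.searchsorted(cuts, starts, side="left")
    ).astype(np.float64)
    center = starts + small / 2.0
    bg_lo = np.maximum(center - bg / 2.0, 0.0)
    bg_hi = np.minimum(center + bg / 2.0, float(length))
    eff = bg_hi - bg_lo
    N = (
        np.searchsorted(cuts, bg_hi, side="left")
        - np.searchsorted(cuts, bg_lo, side="left")
    ).astype(np.float64)
    p = np.divide(small, eff, out=np.zeros_like(eff), where=eff > 0)
    valid = (N > 0) & (p < 1.0)
    mean = N * p
    var = N * p * (1.0 - p)
    z = np.full(starts.shape, -np.inf)
    z[valid] = (n[valid] - mean[valid]) / np.sqrt(var[valid])
    return starts[valid], n[valid], N[valid], z[valid]


def scan_zscores(
    library: TagLibrary,
    genome_lengths,
    small_window: int = 250,
    background_window: int = 200_000,
    step: int = 50,
) -> pd.DataFrame:
    """Per-window binomial z-scores for every contig carrying tags.

    Returns a DataFrame with columns contig, start, end, n, N, z; windows
    with an empty background (N = 0) are omitted.
    """
    if library.size == 0:
        raise ValueError("no tags in library")
    params = HotspotParams(small_window, background_window, step)
    lengths = _contig_lengths(genome_lengths)
    rows = []
    cut_map = library.cut_sites()
    for contig, length in lengths.items():
        cuts = cut_map.get(contig, np.empty(0, dtype=np.int64))
        starts, n, N, z = _scan_contig(cuts, length, params)
        if len(starts):
            rows.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "start": starts,
                        "end": starts + small_window,
                        "n": n.astype(np.int64),
                        "N": N.astype(np.int64),
                        "z": z,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["contig", "start", "end", "n", "N", "z"])
    return pd.concat(rows, ignore_index=True)


def _max_scan_z(cut_map: Mapping[str, np.ndarray], lengths, params) -> float:
    best = -np.inf
    for contig, length in lengths.items():
        cuts = cut_map.get(contig)
        if cuts is None or len(cuts) == 0:
            continue
        _, _, _, z = _scan_contig(cuts, length, params)
        if len(z):
            best = max(best, float(z.max()))
    return best


def _uniform_cut_map(
    rng: np.random.Generator, library_size: int, lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    names = list(lengths)
    sizes = np.array([lengths[n] for n in names], dtype=float)
    counts = rng.multinomial(library_size, sizes / sizes.sum())
    return {
        name: np.sort(rng.integers(0, lengths[name], size=int(c)))
        for name, c in zip(names, counts)
        if c > 0
    }


def estimate_fdr0_threshold(
    library_size: int,
    genome_lengths,
    params: HotspotParams | None = None,
    n_randomizations: int | None = None,
    seed: int = 0,
) -> float:
    """Empirical FDR-0 z threshold by uniform random tag placement.

    Places ``library_size`` tags uniformly over the genome
    ``n_randomizations`` times, scans each placement, and returns the
    largest z observed plus one ulp — the smallest threshold at which the
    expected number of passing windows in a random library is zero.
    """
    params = params or HotspotParams()
    n_rand = n_randomizations if n_randomizations is not None else params.n_randomizations
    if n_rand < 1:
        raise ValueError("n_randomizations must be >= 1")
    lengths = _contig_lengths(genome_lengths)
    lengths = {k: v for k, v in lengths.items() if k != params.mito_contig}
    rng = np.random.default_rng(seed)
    best = -np.inf
    for _ in range(n_rand):
        cut_map = _uniform_cut_map(rng, library_size, lengths)
        best = max(best, _max_scan_z(cut_map, lengths, params))
    return float(np.nextafter(best, np.inf))


def apply_mode_threshold(hotspots: list[Hotspot], bin_width: float = 0.1) -> tuple[list[Hotspot], float]:
    """Density-threshold-at-the-mode filter.

    Builds a histogram of log10(density) with the given bin width, finds the
    modal bin (ties resolved toward the lowest bin), and discards hotspots
    whose density falls below the modal bin's lower edge. Returns the
    surviving hotspots and the density cutoff. A single hotspot is returned
    unchanged (its own bin is the mode).
    """
    if len(hotspots) == 0:
        raise ValueError("apply_mode_threshold requires at least one hotspot")
    dens = np.array([h.density for h in hotspots])
    logd = np.log10(dens)
    idx = np.floor(logd / bin_width + 1e-9).astype(np.int64)
    values, counts = np.unique(idx, return_counts=True)
    modal = values[np.argmax(counts)]  # np.argmax -> first (lowest) on ties
    cutoff = 10.0 ** (modal * bin_width)
    kept = [h for h, ld in zip(hotspots, logd) if ld >= modal * bin_width - 1e-9]
    return kept, float(cutoff)


def call_hotspots(
    library: TagLibrary,
    genome_lengths,
    params: HotspotParams | None = None,
    seed: int = 0,
    z_threshold: float | None = None,
    mode_filter: bool = True,
) -> HotspotSet:
    """Call hotspots: scan, FDR-0 threshold, merge, trim, mode filter.

    Tags on ``params.mito_contig`` are excluded before calling (the
    mitochondrial fraction is reported separately, see
    :func:`mito_fraction`). ``z_threshold`` overrides the randomization
    estimate when given.
    """
    params = params or HotspotParams()
    if library.size == 0:
        raise ValueError("no tags in library")
    lengths = _contig_lengths(genome_lengths)
    lengths.pop(params.mito_contig, None)
    lib = library.exclude_contig(params.mito_contig)
    if lib.size == 0:
        raise ValueError("no non-mitochondrial tags in library")
    if z_threshold is None:
        z_threshold = estimate_fdr0_threshold(
            lib.size, lengths, params, params.n_randomizations, seed
        )

    lib_millions = lib.size / 1e6
    cut_map = lib.cut_sites()
    hotspots: list[Hotspot] = []
    for contig, length in lengths.items():
        cuts = cut_map.get(contig)
        if cuts is None or len(cuts) == 0:
            continue
        starts, n, N, z = _scan_contig(cuts, length, params)
        hot = z >= z_threshold
        if not hot.any():
            continue
        ws, wz = starts[hot], z[hot]
        # merge passing windows whose gaps are <= merge gap
        w_end = ws + params.small_window
        breaks = np.flatnonzero(ws[1:] - w_end[:-1] > params.gap) + 1
        for lo, hi in zip(
            np.concatenate([[0], breaks]), np.concatenate([breaks, [len(ws)]])
        ):
            m_start, m_end = int(ws[lo]), int(w_end[hi - 1])
            i0 = np.searchsorted(cuts, m_start, side="left")
            i1 = np.searchsorted(cuts, m_end, side="left")
            if i1 <= i0:
                continue
            t_start, t_end = int(cuts[i0]), int(cuts[i1 - 1]) + 1
            count = int(i1 - i0)
            density = count / ((t_end - t_start) / 1000.0) / lib_millions
            hotspots.append(
                Hotspot(
                    GenomicInterval(contig, t_start, t_end),
                    tag_count=count,
                    density=density,
                    z_score=float(wz[lo:hi].max()),
                )
            )

    recorded = asdict(params)
    recorded["z_threshold"] = float(z_threshold)
    recorded["library_size"] = lib.size
    if hotspots and mode_filter:
        hotspots, cutoff = apply_mode_threshold(hotspots, params.mode_bin_width)
        recorded["mode_density_cutoff"] = cutoff
    return HotspotSet(hotspots, params=recorded, label=library.label)


def mito_fraction(library: TagLibrary, mito_contig: str = "chrM") -> float:
    """Share of tags aligned to the mitochondrial contig."""
    if library.size == 0:
        return 0.0
    return float((library.frame["contig"] == mito_contig).sum() / library.size)
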