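"""Cross-library hotspot comparison: union/Venn overlap, quartile parsing,
quartile-resolved uniqueness and density correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, HotspotSet, TagLibrary

__all__ = [
    "UnionInterval",
    "OverlapSummary",
    "QuartileParsing",
    "union_merge",
    "overlap_summary",
    "quartile_partition",
    "quartile_overlap",
    "density_correlation",
    "region_density",
]


@dataclass(frozen=True)
class UnionInterval:
    interval: GenomicInterval
    sources: frozenset  # labels of the sets contributing a hotspot


@dataclass
class OverlapSummary:
    """Membership-pattern counts over merged union intervals."""

    source_counts: dict  # label -> number of hotspots in that input set
    union_count: int
    pattern_counts: dict  # frozenset of labels -> count of union intervals
    pattern_percent: dict  # same keys, percentage of the union


@dataclass
class QuartileParsing:
    """Four density-ordered subsets, quartile 1 the most intense."""

    quartiles: list  # list of four lists of Hotspot

    def __post_init__(self):
        sizes = [len(q) for q in self.quartiles]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("quartile sizes must differ by at most 1")


def _labels(sets: list[HotspotSet]) -> list[str]:
    labels = [s.label or f"set{i + 1}" for i, s in enumerate(sets)]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}#{i + 1}" for i, lab in enumerate(labels)]
    return labels


def union_merge(sets: list[HotspotSet]) -> list[UnionInterval]:
    """Merge hotspots from all sets wherever they overlap by >= 1 bp.

    Each union interval carries the labels of every source set contributing
    at least one hotspot to it. Output is sorted and non-overlapping and
    covers exactly the union of input bases.
    """
    labels = _labels(sets)
    records = []
    for lab, hs in zip(labels, sets):
        for h in hs:
            records.append((h.interval.contig, h.interval.start, h.interval.end, lab))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    out: list[UnionInterval] = []
    cur = None  # [contig, start, end, set of labels]
    for contig, start, end, lab in records:
        if cur is not None and contig == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(lab)
        else:
            if cur is not None:
                out.append(
                    UnionInterval(GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3]))
                )
            cur = [contig, start, end, {lab}]
    if cur is not None:
        out.append(UnionInterval(GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3])))
    return out


def overlap_summary(sets: list[HotspotSet]) -> OverlapSummary:
    """Venn-style membership pattern counts over merged union intervals."""
    if len(sets) < 2:
        raise ValueError("overlap_summary needs at least two hotspot sets")
    labels = _labels(sets)
    union = union_merge(sets)
    pattern_counts: dict[frozenset, int] = {}
    for ui in union:
        pattern_counts[ui.sources] = pattern_counts.get(ui.sources, 0) + 1
    total = len(union)
    pattern_percent = {
        k: 100.0 * v / total if total else 0.0 for k, v in pattern_counts.items()
    }
    return OverlapSummary(
        source_counts={lab: len(s) for lab, s in zip(labels, sets)},
        union_count=total,
        pattern_counts=pattern_counts,
        pattern_percent=pattern_percent,
    )


def quartile_partition(hotspot_set: HotspotSet) -> QuartileParsing:
    """Split a hotspot set into four density quartiles, most intense first.

    Hotspots are sorted by density descending with ties broken by
    (contig, start) ascending; group sizes are near-equal (the first
    ``n mod 4`` quartiles get the extra member).
    """
    n = len(hotspot_set)
    if n < 4:
        raise ValueError("quartile partition needs at least 4 hotspots")
    ordered = sorted(
        hotspot_set.hotspots,
        key=lambda h: (-h.density, h.interval.contig, h.interval.start),
    )
    base, extra = divmod(n, 4)
    sizes = [base + (1 if k < extra else 0) for k in range(4)]
    quartiles, pos = [], 0
    for s in sizes:
        quartiles.append(ordered[pos : pos + s])
        pos += s
    return QuartileParsing(quartiles)


def _interval_arrays(sets: list[HotspotSet]) -> dict[str, np.ndarray]:
    """Sorted (start, end) arrays per contig pooled over the given sets."""
    pool: dict[str, list] = {}
    for s in sets:
        for h in s:
            pool.setdefault(h.interval.contig, []).append((h.interval.start, h.interval.end))
    out = {}
    for contig, ivs in pool.items():
        arr = np.array(sorted(ivs), dtype=np.int64)
        out[contig] = arr
    return out


def _overlaps_any(iv: GenomicInterval, pool: dict[str, np.ndarray]) -> bool:
    arr = pool.get(iv.contig)
    if arr is None or len(arr) == 0:
        return False
    # hotspot sets are non-overlapping per set but the pool may interleave;
    # check every pooled interval whose start precedes iv.end
    k = np.searchsorted(arr[:, 0], iv.end, side="left")
    return bool((arr[:k, 1] > iv.start).any())


def quartile_overlap(
    hotspot_set: HotspotSet, other_sets: list[HotspotSet]
) -> pd.DataFrame:
    """Per-quartile fraction of hotspots shared with any other set.

    Overlap criterion is >= 1 bp. Returns a DataFrame with one row per
    quartile (1 = most intense) and columns n, common_fraction,
    unique_fraction.
    """
    parsing = quartile_partition(hotspot_set)
    pool = _interval_arrays(other_sets)
    rows = []
    for k, quartile in enumerate(parsing.quartiles, start=1):
        n = len(quartile)
        common = sum(_overlaps_any(h.interval, pool) for h in quartile)
        rows.append(
            {
                "quartile": k,
                "n": n,
                "common_fraction": common / n if n else 0.0,
                "unique_fraction": 1.0 - common / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def region_density(library: TagLibrary, regions: list[GenomicInterval]) -> np.ndarray:
    """Tag density (tags/kb/million) of each region in the given library."""
    cut_map = library.cut_sites()
    millions = library.size / 1e6
    out = np.zeros(len(regions))
    for i, iv in enumerate(regions):
        cuts = cut_map.get(iv.contig)
        if cuts is None:
            continue
        c = np.searchsorted(cuts, iv.end, side="left") - np.searchsorted(
            cuts, iv.start, side="left"
        )
        out[i] = c / (len(iv) / 1000.0) / millions
    return out


def density_correlation(
    lib_a: TagLibrary,
    lib_b: TagLibrary,
    regions: list[GenomicInterval],
    pseudocount: float = 0.1,
) -> float:
    """Pearson r between the two libraries' log10 region densities.

    Densities are tags/kb/million (depth-invariant); the correlation is
    computed on ``log10(density + pseudocount)`` because hotspot densities
    span decades.
    """
    if len(regions) == 0:
        raise ValueError("no regions given")
    da = np.log10(region_density(lib_a, regions) + pseudocount)
    db = np.log10(region_density(lib_b, regions) + pseudocount)
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        raise ValueError("degenerate: zero variance in region densities")
    r, _ = stats.pearsonr(da, db)
    return float(r)
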