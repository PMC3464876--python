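"""Feature annotation: hotspot classification against gene models,
expression binning, TSS occupancy, and tag-density aggregation profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, GeneModel, Hotspot, HotspotSet, TagLibrary

__all__ = [
    "CATEGORIES",
    "FeatureDistribution",
    "AggregationProfile",
    "ExpressionBinning",
    "classify_hotspot",
    "feature_distribution",
    "bin_expression",
    "tss_occupancy",
    "aggregate_density",
    "density_heatmap_matrix",
]

CATEGORIES = ("promoter", "exon", "intron", "downstream", "distal")

# eight unit-log2 bins over detected genes, top bin open-ended; "nd" separate
DEFAULT_LOG2_EDGES = (-2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0)


@dataclass
class FeatureDistribution:
    counts: dict  # category -> count
    fractions: dict  # category -> fraction of total

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class AggregationProfile:
    """Mean tag density (tags/bp/million, per anchor) in offset bins."""

    bin_starts: np.ndarray
    density: np.ndarray
    n_anchors: int
    bin_width: int


@dataclass
class ExpressionBinning:
    """Gene -> ordered bin label; ``labels_ordered`` runs low to high."""

    assignment: pd.Series  # index gene_id, values label
    labels_ordered: list
    scheme: str


def _promoter_window(g: GeneModel, promoter_len: int) -> tuple[int, int]:
    """Half-open midpoint window upstream of the TSS, strand-aware."""
    if g.strand == "+":
        return g.tss - promoter_len, g.tss
    return g.tss + 1, g.tss + 1 + promoter_len


def _downstream_window(g: GeneModel, downstream_len: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.tts + 1, g.tts + 1 + downstream_len
    return g.tts - downstream_len, g.tts


def classify_hotspot(
    hotspot: Hotspot | GenomicInterval,
    genes: list[GeneModel],
    promoter_len: int = 2000,
    downstream_len: int = 2000,
) -> str:
    """Classify a hotspot by its midpoint.

    Priority: promoter > exon > intron > downstream > distal, evaluated
    over all genes (so a midpoint in one gene's exon and another gene's
    intron is an exon). Promoter means within ``promoter_len`` bp upstream
    of a TSS (strand-aware); downstream means within ``downstream_len`` bp
    past a TTS.
    """
    iv = hotspot.interval if isinstance(hotspot, Hotspot) else hotspot
    mid = iv.midpoint
    flags = {cat: False for cat in CATEGORIES}
    for g in genes:
        if g.contig != iv.contig:
            continue
        ps, pe = _promoter_window(g, promoter_len)
        if ps <= mid < pe:
            flags["promoter"] = True
        lo, hi = min(g.tss, g.tts), max(g.tss, g.tts)
        if lo <= mid <= hi:
            if any(s <= mid < e for s, e in g.exons):
                flags["exon"] = True
            else:
                flags["intron"] = True
        ds, de = _downstream_window(g, downstream_len)
        if ds <= mid < de:
            flags["downstream"] = True
    for cat in CATEGORIES[:-1]:
        if flags[cat]:
            return cat
    return "distal"


def feature_distribution(
    hotspots,
    genes: list[GeneModel],
    promoter_len: int = 2000,
    downstream_len: int = 2000,
) -> FeatureDistribution:
    """Category counts and fractions over a hotspot collection."""
    items = list(hotspots)
    counts = {cat: 0 for cat in CATEGORIES}
    for h in items:
        counts[classify_hotspot(h, genes, promoter_len, downstream_len)] += 1
    total = len(items)
    fractions = {cat: (c / total if total else 0.0) for cat, c in counts.items()}
    return FeatureDistribution(counts=counts, fractions=fractions)


def bin_expression(
    expression: pd.DataFrame,
    scheme: str = "log2",
    log2_edges=DEFAULT_LOG2_EDGES,
) -> ExpressionBinning:
    """Assign each gene to an expression bin.

    ``log2`` scheme: genes with zero (or missing) transcripts are "nd";
    detected genes fall into eight unit-log2 bins of transcripts per cell
    with open-ended extremes (default edges -2..4, so the top bin holds
    genes with more than 16 transcripts per cell).

    ``decile`` scheme: genes ranked by transcripts descending, split into
    ten near-equal groups d01 (highest) .. d10; undetected genes rank last,
    ties broken by gene id.
    """
    t = expression.set_index("gene_id")["transcripts_per_cell"].astype(float)
    if (t.fillna(0) < 0).any():
        raise ValueError("negative expression")
    if scheme == "log2":
        edges = list(log2_edges)
        labels = (
            [f"<= {edges[0]:g}"]
            + [f"({lo:g}, {hi:g}]" for lo, hi in zip(edges[:-1], edges[1:])]
            + [f"> {edges[-1]:g}"]
        )
        def assign(v):
            if pd.isna(v) or v == 0:
                return "nd"
            lv = np.log2(v)
            if lv <= edges[0]:
                return labels[0]
            for lo, hi, lab in zip(edges[:-1], edges[1:], labels[1:-1]):
                if lo < lv <= hi:
                    return lab
            return labels[-1]
        assignment = t.map(assign)
        return ExpressionBinning(assignment, ["nd"] + labels, "log2")
    if scheme == "decile":
        order = sorted(
            t.index, key=lambda gid: (-(t[gid] if pd.notna(t[gid]) else 0.0), gid)
        )
        n = len(order)
        base, extra = divmod(n, 10)
        labels_ordered = [f"d{k:02d}" for k in range(10, 0, -1)]  # low .. high
        assignment = {}
        pos = 0
        for k in range(10):
            size = base + (1 if k < extra else 0)
            for gid in order[pos : pos + size]:
                assignment[gid] = f"d{k + 1:02d}"
            pos += size
        return ExpressionBinning(
            pd.Series(assignment).reindex(t.index), labels_ordered, "decile"
        )
    raise ValueError(f"unknown binning scheme {scheme!r}")


def tss_occupancy(
    genes: list[GeneModel],
    hotspot_sets: list[HotspotSet],
    binning: ExpressionBinning,
) -> pd.DataFrame:
    """Per expression bin, the fraction of genes with a hotspot at >= 1 TSS.

    A gene (grouped over its TSS records) is scored occupied when at least
    one of its TSS positions falls inside a hotspot of any provided set.
    """
    pool: dict[str, np.ndarray] = {}
    for s in hotspot_sets:
        for h in s:
            pool.setdefault(h.interval.contig, []).append(
                (h.interval.start, h.interval.end)
            )
    pool = {k: np.array(sorted(v), dtype=np.int64) for k, v in pool.items()}

    def tss_occupied(g: GeneModel) -> bool:
        arr = pool.get(g.contig)
        if arr is None or len(arr) == 0:
            return False
        k = np.searchsorted(arr[:, 0], g.tss, side="right")
        return bool((arr[:k, 1] > g.tss).any())

    per_gene: dict[str, bool] = {}
    for g in genes:
        per_gene[g.gene_id] = per_gene.get(g.gene_id, False) or tss_occupied(g)

    rows = []
    for label in binning.labels_ordered:
        gids = [gid for gid, lab in binning.assignment.items() if lab == label]
        gids = [gid for gid in gids if gid in per_gene]
        occ = sum(per_gene[gid] for gid in gids)
        rows.append(
            {
                "bin": label,
                "n_genes": len(gids),
                "occupied_fraction": occ / len(gids) if gids else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _anchor_points(anchors, anchor_mode: str):
    """(contig, point, flip) triples for each anchor."""
    out = []
    for a in anchors:
        if isinstance(a, GeneModel):
            contig, point, strand = a.contig, a.tss, a.strand
        else:
            contig, point, strand = a.contig, a.midpoint, a.strand
        flip = anchor_mode == "tss-strand-oriented" and strand == "-"
        out.append((contig, point, flip))
    return out


def aggregate_density(
    anchors,
    library: TagLibrary,
    flank: int = 3000,
    bin_width: int = 50,
    anchor_mode: str = "midpoint",
) -> AggregationProfile:
    """Mean tag density in offset bins spanning +/- flank around anchors.

    ``anchors`` may be intervals (midpoint-anchored) or gene models
    (TSS-anchored). In ``tss-strand-oriented`` mode offsets are flipped for
    minus-strand anchors so positive offsets always point downstream.
    Densities are tags per bp per million library tags, averaged per anchor.
    """
    if anchor_mode not in ("midpoint", "tss-strand-oriented"):
        raise ValueError("anchor_mode must be 'midpoint' or 'tss-strand-oriented'")
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin_width")
    points = _anchor_points(anchors, anchor_mode)
    if not points:
        raise ValueError("no anchors given")
    n_bins = 2 * flank // bin_width
    counts = np.zeros(n_bins)
    cut_map = library.cut_sites()
    for contig, point, flip in points:
        cuts = cut_map.get(contig)
        if cuts is None or len(cuts) == 0:
            continue
        i0 = np.searchsorted(cuts, point - flank, side="left")
        i1 = np.searchsorted(cuts, point + flank, side="left")
        off = cuts[i0:i1] - point
        if flip:
            off = -off - 1  # mirror so offset 0 stays the first downstream base
        idx = (off + flank) // bin_width
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts += np.bincount(idx, minlength=n_bins)
    millions = library.size / 1e6
    density = counts / (len(points) * bin_width * millions)
    return AggregationProfile(
        bin_starts=np.arange(-flank, flank, bin_width),
        density=density,
        n_anchors=len(points),
        bin_width=bin_width,
    )


def density_heatmap_matrix(
    anchors_ranked,
    library: TagLibrary,
    flank: int = 3000,
    bin_width: int = 50,
    anchor_mode: str = "tss-strand-oriented",
) -> np.ndarray:
    """Per-anchor rows of binned tag density, in the given (rank) order.

    Cells are tags per bp per million for that anchor, i.e. the quantity
    :func:`aggregate_density` averages: column means of this matrix equal
    the aggregate profile.
    """
    points = _anchor_points(anchors_ranked, anchor_mode)
    n_bins = 2 * flank // bin_width
    mat = np.zeros((len(points), n_bins))
    cut_map = library.cut_sites()
    millions = library.size / 1e6
    for row, (contig, point, flip) in enumerate(points):
        cuts = cut_map.get(contig)
        if cuts is None or len(cuts) == 0:
            continue
        i0 = np.searchsorted(cuts, point - flank, side="left")
        i1 = np.searchsorted(cuts, point + flank, side="left")
        off = cuts[i0:i1] - point
        if flip:
            off = -off - 1
        idx = (off + flank) // bin_width
        idx = idx[(idx >= 0) & (idx < n_bins)]
        mat[row] = np.bincount(idx, minlength=n_bins) / (bin_width * millions)
    return mat
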