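"""Synthetic nuclease-digestion data with known ground truth.

The generator produces, in order of dependency:

1. a genome of i.i.d.-base blocks with per-block GC content drawn from a
   configurable set of levels, CpG-depleted outside planted CpG islands;
2. an accessibility landscape — non-overlapping accessible regions with
   log-normal cut-rate multipliers — plus gene models whose promoters sit in
   a subset of regions and whose expression is coupled to region intensity;
3. tag libraries from a two-cut fragment model: both cut positions are drawn
   with probability proportional to landscape rate times the enzyme's base
   preference at the cut base (read on the strand being cut), fragments are
   size-selected to [min_len, max_len], and a single tag is sequenced from a
   randomly chosen fragment end, its 5' end marking the cut.

Everything is deterministic under a seed (numpy PCG64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BASE_CODES, GenomeSequence, GenomicInterval, GeneModel, TagLibrary

__all__ = [
    "EnzymeBiasModel",
    "AccessibleRegion",
    "AccessibilityLandscape",
    "FragmentModel",
    "LogNormalIntensity",
    "preset_bias",
    "generate_genome",
    "generate_landscape",
    "simulate_digestion",
    "MITO_CONTIG",
    "MITO_LENGTH",
]

MITO_CONTIG = "chrM"
MITO_LENGTH = 16_000

_BASES = ("A", "C", "G", "T")
# complement code lookup for A=0,C=1,G=2,T=3,N=4
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


@dataclass(frozen=True)
class EnzymeBiasModel:
    """Per-base relative cut propensity at the cleaved position (offset 0)."""

    name: str
    base_weights: dict

    def __post_init__(self):
        w = self.base_weights
        if set(w) != set(_BASES):
            raise ValueError("base_weights must map exactly A, C, G, T")
        if any(v < 0 for v in w.values()):
            raise ValueError("base weights must be non-negative")
        if not math.isclose(sum(w.values()), 1.0, abs_tol=1e-9):
            raise ValueError("base weights must sum to 1")

    def weight_array(self) -> np.ndarray:
        """Weights indexed by base code (A,C,G,T,N); N gets weight 0."""
        return np.array([self.base_weights[b] for b in _BASES] + [0.0])


_PRESETS = {
    "uniform": {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
    "benzonase": {"A": 0.15, "C": 0.30, "G": 0.40, "T": 0.15},
    "cyanase": {"A": 0.15, "C": 0.30, "G": 0.40, "T": 0.15},
    "dnase1": {"A": 0.20, "C": 0.15, "G": 0.15, "T": 0.50},
}


def preset_bias(name: str) -> EnzymeBiasModel:
    """Named enzyme presets.

    Benzonase and Cyanase share a G/C-skewed preference; DNase I prefers T.
    Only the direction of these preferences is established experimentally;
    the magnitudes are calibration defaults and fully configurable via
    :class:`EnzymeBiasModel`.
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown bias preset {name!r}; available: {sorted(_PRESETS)}"
        )
    return EnzymeBiasModel(name=name, base_weights=dict(_PRESETS[name]))


@dataclass(frozen=True)
class AccessibleRegion:
    interval: GenomicInterval
    intensity: float  # cut-rate multiplier relative to baseline, >= 1
    klass: str = "background"  # promoter | enhancer | background

    def __post_init__(self):
        if not (math.isfinite(self.intensity) and self.intensity >= 1):
            raise ValueError("region intensity must be finite and >= 1")
        if self.klass not in ("promoter", "enhancer", "background"):
            raise ValueError(f"unknown region class {self.klass!r}")


@dataclass
class AccessibilityLandscape:
    regions: list
    baseline_rate: float = 1.0

    def __post_init__(self):
        by_contig: dict[str, list] = {}
        for r in self.regions:
            by_contig.setdefault(r.interval.contig, []).append(r)
        for regs in by_contig.values():
            regs = sorted(regs, key=lambda r: r.interval.start)
            for a, b in zip(regs, regs[1:]):
                if a.interval.end > b.interval.start:
                    raise ValueError("accessible regions must not overlap")

    def rate_array(self, contig: str, length: int) -> np.ndarray:
        """Per-base relative cut rate for one contig."""
        rate = np.full(length, self.baseline_rate, dtype=np.float64)
        for r in self.regions:
            if r.interval.contig == contig:
                rate[r.interval.start : r.interval.end] *= r.intensity
        return rate


@dataclass(frozen=True)
class FragmentModel:
    """Size-selection bounds of the sequenced fragments, in bp."""

    min_len: int = 100
    max_len: int = 500

    def __post_init__(self):
        if not (0 < self.min_len < self.max_len):
            raise ValueError("require 0 < min_len < max_len")


@dataclass(frozen=True)
class LogNormalIntensity:
    """Intensity law: multiplier = offset + LogNormal(mean_log, sigma_log).

    Defaults give a median enrichment of ~11x over baseline with a heavy
    upper tail, the shape typical of accessible-chromatin hotspot intensity
    distributions.
    """

    mean_log: float = math.log(10.0)
    sigma_log: float = 1.5
    offset: float = 1.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.offset + rng.lognormal(self.mean_log, self.sigma_log, size=n)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def _iid_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _deplete_cpg(codes: np.ndarray, rng: np.random.Generator, q: float = 0.9,
                 passes: int = 6) -> np.ndarray:
    """Suppress CG dinucleotides by swapping CG -> GC in place.

    Swaps preserve base composition exactly, so block GC content is
    untouched; only the dinucleotide structure changes (observed/expected
    CpG drops well below the island threshold).
    """
    C, G = BASE_CODES["C"], BASE_CODES["G"]
    for _ in range(passes):
        is_cg = (codes[:-1] == C) & (codes[1:] == G)
        idx = np.flatnonzero(is_cg)
        if idx.size == 0:
            break
        idx = idx[rng.random(idx.size) < q]
        # drop overlapping pairs (CGCG): keep the first of any adjacent run
        if idx.size > 1:
            keep = np.ones(idx.size, dtype=bool)
            keep[1:] = np.diff(idx) > 1
            idx = idx[keep]
        codes[idx], codes[idx + 1] = G, C
    return codes


_CODE_TO_CHAR = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _CODE_TO_CHAR[codes].tobytes().decode("ascii")


def generate_genome(
    n_contigs: int = 1,
    contig_len: int = 1_000_000,
    gc_block_len: int = 10_000,
    gc_levels: tuple = (0.3, 0.5, 0.7),
    n_cpg_islands: int = 0,
    seed: int = 0,
    mito: bool = False,
    cpg_depletion: float = 0.9,
) -> tuple[GenomeSequence, list[GenomicInterval]]:
    """Generate a block-structured genome with optional planted CpG islands.

    Each contig is assembled from i.i.d.-base blocks of ``gc_block_len`` bp
    whose GC fraction is drawn from ``gc_levels``; background CpG is depleted
    (composition-preserving) so that planted islands — 500-1500 bp segments
    with GC >= 0.6 and CpG obs/exp ~1 — are the only island-like sequence.

    Returns the genome and the list of planted island intervals. With
    ``mito=True`` a 16 kb uniform 'chrM' contig is appended.
    """
    if contig_len <= 0 or gc_block_len <= 0 or n_contigs <= 0:
        raise ValueError("lengths and counts must be positive")
    if not all(0 < g < 1 for g in gc_levels):
        raise ValueError("gc_levels must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    levels = np.array(sorted(gc_levels), dtype=float)
    contigs: dict[str, str] = {}
    islands: list[GenomicInterval] = []
    island_lengths = None
    for ci in range(n_contigs):
        name = f"chr{ci + 1}"
        n_blocks = -(-contig_len // gc_block_len)
        block_gc = levels[rng.integers(0, len(levels), size=n_blocks)]
        parts = []
        for gc in block_gc:
            parts.append(_iid_bases(rng, gc_block_len, gc))
        codes = np.concatenate(parts)[:contig_len]
        codes = _deplete_cpg(codes, rng, q=cpg_depletion)
        # plant islands: high-GC i.i.d. segments (obs/exp CpG ~ 1, not depleted)
        n_isl = n_cpg_islands if ci == 0 else 0
        if n_isl:
            lengths = rng.integers(500, 1501, size=n_isl)
            if lengths.sum() * 3 > contig_len:
                raise ValueError("island total length exceeds contig capacity")
            placed: list[tuple[int, int]] = []
            for L in lengths:
                for _ in range(1000):
                    s = int(rng.integers(0, contig_len - L))
                    if all(s + L + 200 <= a or s >= b + 200 for a, b in placed):
                        placed.append((s, s + int(L)))
                        break
                else:
                    raise ValueError("could not place CpG islands without overlap")
            for s, e in sorted(placed):
                gc = float(rng.uniform(0.62, 0.75))
                codes[s:e] = _iid_bases(rng, e - s, gc)
                islands.append(GenomicInterval(name, s, e))
        contigs[name] = _codes_to_str(codes)
    if mito:
        mito_codes = _deplete_cpg(_iid_bases(rng, MITO_LENGTH, 0.5), rng, q=cpg_depletion)
        contigs[MITO_CONTIG] = _codes_to_str(mito_codes)
    return GenomeSequence(contigs), islands


# ---------------------------------------------------------------------------
# landscape + genes
# ---------------------------------------------------------------------------


def _place_nonoverlapping(
    rng: np.random.Generator,
    contig_lengths: dict,
    lengths: np.ndarray,
    occupied: dict,
    margin: int = 0,
    max_tries: int = 500,
) -> list[GenomicInterval]:
    """Uniformly place intervals of given lengths avoiding ``occupied`` spans."""
    names = [n for n in contig_lengths if n != MITO_CONTIG]
    sizes = np.array([contig_lengths[n] for n in names], dtype=float)
    placed = []
    for L in lengths:
        ok = False
        for _ in range(max_tries):
            ci = rng.choice(len(names), p=sizes / sizes.sum())
            name = names[ci]
            hi = contig_lengths[name] - int(L) - margin
            if hi <= margin:
                continue
            s = int(rng.integers(margin, hi))
            spans = occupied.setdefault(name, [])
            if all(s + L + margin <= a or s >= b + margin for a, b in spans):
                spans.append((s, s + int(L)))
                placed.append(GenomicInterval(name, s, s + int(L)))
                ok = True
                break
        if not ok:
            raise RuntimeError("failed to place region after bounded retries")
    return placed


def generate_landscape(
    genome: GenomeSequence,
    n_regions: int = 200,
    intensity_law: LogNormalIntensity | None = None,
    promoter_fraction: float = 0.5,
    expression_coupling: float = 1.0,
    seed: int = 0,
    region_len_range: tuple = (250, 1000),
    expression_noise_sd: float = 0.5,
) -> tuple[AccessibilityLandscape, list[GeneModel], pd.DataFrame]:
    """Plant accessible regions and expression-coupled genes.

    A ``promoter_fraction`` share of regions each spawn a gene whose TSS lies
    inside the region and whose expression is
    ``transcripts_per_cell = expression_coupling * intensity * exp(eps)``
    with ``eps ~ Normal(0, expression_noise_sd)``. An equal number of silent
    genes (zero transcripts) is placed in unplanted sequence.
    """
    rng = np.random.default_rng(seed)
    law = intensity_law or LogNormalIntensity()
    lengths = rng.integers(region_len_range[0], region_len_range[1] + 1, size=n_regions)
    occupied: dict[str, list] = {}
    intervals = _place_nonoverlapping(rng, genome.lengths, lengths, occupied, margin=1000)
    intensities = law.sample(rng, n_regions)
    n_prom = int(round(promoter_fraction * n_regions))
    promoter_idx = set(rng.choice(n_regions, size=n_prom, replace=False).tolist())

    regions: list[AccessibleRegion] = []
    genes: list[GeneModel] = []
    expr_rows = []
    gene_no = 0
    for i, (iv, inten) in enumerate(zip(intervals, intensities)):
        klass = "promoter" if i in promoter_idx else "enhancer"
        regions.append(AccessibleRegion(iv, float(inten), klass))
        if klass != "promoter":
            continue
        gene_no += 1
        gid = f"gene_{gene_no:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(iv.start, iv.end))
        glen = int(rng.integers(2000, 20001))
        contig_len = genome.lengths[iv.contig]
        if strand == "+":
            tts = min(tss + glen, contig_len - 1)
        else:
            tts = max(tss - glen, 0)
            if tts >= tss:  # TSS at contig start; flip to fit
                strand, tts = "+", min(tss + glen, contig_len - 1)
        exons = _random_exons(rng, tss, tts)
        t = expression_coupling * float(inten) * math.exp(
            rng.normal(0.0, expression_noise_sd)
        )
        genes.append(GeneModel(gid, iv.contig, strand, tss, tts, exons, t))
        expr_rows.append({"gene_id": gid, "transcripts_per_cell": t})

    # silent genes in unplanted sequence, same count as expressed genes
    silent_lengths = rng.integers(2000, 8001, size=len(genes))
    silent_spans = _place_nonoverlapping(
        rng, genome.lengths, silent_lengths, occupied, margin=500
    )
    for iv in silent_spans:
        gene_no += 1
        gid = f"gene_{gene_no:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tts = (iv.start, iv.end - 1) if strand == "+" else (iv.end - 1, iv.start)
        exons = _random_exons(rng, tss, tts)
        genes.append(GeneModel(gid, iv.contig, strand, tss, tts, exons, 0.0))
        expr_rows.append({"gene_id": gid, "transcripts_per_cell": 0.0})

    expression = pd.DataFrame(expr_rows, columns=["gene_id", "transcripts_per_cell"])
    return AccessibilityLandscape(regions), genes, expression


def _random_exons(rng: np.random.Generator, tss: int, tts: int) -> list:
    """2-4 non-overlapping exons inside the gene body."""
    lo, hi = min(tss, tts), max(tss, tts)
    span = hi - lo
    n_exons = int(rng.integers(2, 5))
    if span <= 2 * n_exons:
        return [(lo, hi)]
    cuts = np.sort(rng.choice(span, size=2 * n_exons, replace=False))
    exons = []
    for k in range(n_exons):
        s, e = lo + int(cuts[2 * k]), lo + int(cuts[2 * k + 1])
        if e > s:
            exons.append((s, e))
    return exons or [(lo, hi)]


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------


def simulate_digestion(
    genome: GenomeSequence,
    landscape: AccessibilityLandscape,
    bias: EnzymeBiasModel,
    n_fragments: int,
    fragment_model: FragmentModel | None = None,
    tag_len: int = 36,
    mito_fraction: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> TagLibrary:
    """Digest the genome and sequence one tag per size-selected fragment.

    Cut-position sampling: the first (upstream) cut at plus-strand position
    ``i`` has probability proportional to ``rate(i) * w(base[i])``; the
    second cut is drawn from admissible positions ``j`` with fragment length
    ``j - i + 1`` in ``[min_len, max_len]``, weighted by
    ``rate(j) * w(complement(base[j]))`` — the base preference is always read
    on the strand being cut. A fair coin picks which fragment end is
    sequenced: the tag's 5' end equals the chosen cut, strand set
    accordingly. A ``mito_fraction`` Bernoulli share of fragments is drawn
    uniformly from the dedicated 'chrM' contig instead.
    """
    frag = fragment_model or FragmentModel()
    if not tag_len < frag.min_len:
        raise ValueError("tag_len must be smaller than the minimum fragment length")
    if not (0 <= mito_fraction < 1):
        raise ValueError("mito_fraction must lie in [0, 1)")
    if mito_fraction > 0 and MITO_CONTIG not in genome:
        raise ValueError("mito_fraction > 0 requires a 'chrM' contig in the genome")

    rng = np.random.default_rng(seed)
    if n_fragments == 0:
        return TagLibrary.from_arrays([], [], [], [], label=label or bias.name)

    wvec = bias.weight_array()
    names = [n for n in genome.lengths if n != MITO_CONTIG]
    # per-contig weight arrays and cumulative sums
    plus_cum: dict[str, np.ndarray] = {}
    minus_cum: dict[str, np.ndarray] = {}
    totals = []
    for name in names:
        codes = genome.encoded(name)
        rate = landscape.rate_array(name, len(codes))
        w_plus = rate * wvec[codes]
        w_minus = rate * wvec[_COMP_CODE[codes]]
        w_plus[max(0, len(codes) - frag.min_len):] = 0.0  # fragment must fit
        plus_cum[name] = np.cumsum(w_plus)
        minus_cum[name] = np.cumsum(w_minus)
        totals.append(plus_cum[name][-1])
    totals = np.array(totals)
    if totals.sum() <= 0:
        raise ValueError("no admissible first-cut positions (all weights zero)")

    is_mito = rng.random(n_fragments) < mito_fraction if mito_fraction > 0 else np.zeros(
        n_fragments, dtype=bool
    )
    n_nuc = int((~is_mito).sum())

    # assign nuclear fragments to contigs proportionally to total weight
    contig_idx = rng.choice(len(names), size=n_nuc, p=totals / totals.sum())
    out_contig: list[np.ndarray] = []
    out_start: list[np.ndarray] = []
    out_end: list[np.ndarray] = []
    out_strand: list[np.ndarray] = []

    for ci, name in enumerate(names):
        m = int((contig_idx == ci).sum())
        if m == 0:
            continue
        cp, cm = plus_cum[name], minus_cum[name]
        L = len(cp)
        first = np.searchsorted(cp, rng.random(m) * cp[-1], side="right")
        # second cut window [first+min_len-1, min(first+max_len-1, L-1)]
        for _ in range(100):  # bounded retry for zero-mass windows
            lo = first + frag.min_len - 1
            hi = np.minimum(first + frag.max_len - 1, L - 1)
            base = np.where(lo > 0, cm[np.clip(lo - 1, 0, L - 1)], 0.0)
            base = np.where(lo > 0, base, 0.0)
            mass = cm[hi] - base
            bad = mass <= 0
            if not bad.any():
                break
            first[bad] = np.searchsorted(
                cp, rng.random(int(bad.sum())) * cp[-1], side="right"
            )
        else:
            raise RuntimeError("no admissible second cut after bounded retries")
        u = base + rng.random(m) * mass
        second = np.searchsorted(cm, u, side="left")
        upstream_end = rng.random(m) < 0.5  # True -> sequence from the first cut
        starts = np.where(upstream_end, first, second + 1 - tag_len)
        ends = np.where(upstream_end, first + tag_len, second + 1)
        strands = np.where(upstream_end, "+", "-")
        out_contig.append(np.full(m, name, dtype=object))
        out_start.append(starts)
        out_end.append(ends)
        out_strand.append(strands.astype(object))

    n_mito = int(is_mito.sum())
    if n_mito:
        Lm = genome.lengths[MITO_CONTIG]
        first = rng.integers(0, Lm - frag.min_len, size=n_mito)
        hi = np.minimum(first + frag.max_len - 1, Lm - 1)
        lo = first + frag.min_len - 1
        second = (lo + rng.random(n_mito) * (hi - lo + 1)).astype(np.int64)
        upstream_end = rng.random(n_mito) < 0.5
        starts = np.where(upstream_end, first, second + 1 - tag_len)
        ends = np.where(upstream_end, first + tag_len, second + 1)
        strands = np.where(upstream_end, "+", "-")
        out_contig.append(np.full(n_mito, MITO_CONTIG, dtype=object))
        out_start.append(starts)
        out_end.append(ends)
        out_strand.append(strands.astype(object))

    lib = TagLibrary.from_arrays(
        np.concatenate(out_contig),
        np.concatenate(out_start),
        np.concatenate(out_end),
        np.concatenate(out_strand),
        label=label or bias.name,
    )
    lib.validate_against(genome.lengths)
    return lib
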