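"""Core in-memory containers: genome, intervals, tag libraries, genes, hotspots.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
A sequencing *tag* is a single aligned read whose 5' end marks the nuclease
cut site — position ``start`` for a plus-strand tag and position ``end`` for a
minus-strand tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GenomeSequence",
    "TagLibrary",
    "GeneModel",
    "Hotspot",
    "HotspotSet",
    "BASE_CODES",
    "revcomp",
]

# fixed base encoding used by all vectorised sequence routines
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_BASES = np.array(list("ACGTN"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand ('+', '-' or '.')."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.contig:
            raise ValueError("contig name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class GenomeSequence:
    """An ordered collection of named DNA contigs.

    Sequences are stored upper-case; characters outside {A,C,G,T,N} are
    mapped to N on construction.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if len(contigs) == 0:
            raise ValueError("genome must contain at least one contig")
        self._contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            if name in self._contigs:
                raise ValueError(f"duplicate contig name {name!r}")
            if len(seq) == 0:
                raise ValueError(f"contig {name!r} has zero length")
            seq = seq.upper()
            if any(c not in BASE_CODES for c in set(seq)):
                seq = "".join(c if c in BASE_CODES else "N" for c in seq)
            self._contigs[name] = seq
        self._codes: dict[str, np.ndarray] = {}

    @property
    def contigs(self) -> dict[str, str]:
        return self._contigs

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __getitem__(self, name: str) -> str:
        return self._contigs[name]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)`` clipped to the contig bounds."""
        seq = self._contigs[contig]
        return seq[max(0, start) : min(len(seq), end)]

    def encoded(self, contig: str) -> np.ndarray:
        """uint8 code array (A=0, C=1, G=2, T=3, N=4), cached per contig."""
        if contig not in self._codes:
            raw = np.frombuffer(self._contigs[contig].encode("ascii"), dtype=np.uint8)
            lut = np.full(256, BASE_CODES["N"], dtype=np.uint8)
            for base, code in BASE_CODES.items():
                lut[ord(base)] = code
            self._codes[contig] = lut[raw]
        return self._codes[contig]


class TagLibrary:
    """A library of aligned single-end tags (columnar storage).

    Parameters
    ----------
    frame
        DataFrame with columns ``contig`` (str), ``start``/``end`` (int),
        ``strand`` ('+' or '-').
    label
        Free-text provenance, e.g. enzyme name and concentration.
    """

    COLUMNS = ("contig", "start", "end", "strand")

    def __init__(self, frame: pd.DataFrame, label: str = ""):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"tag frame missing columns {sorted(missing)}")
        frame = frame[list(self.COLUMNS)].reset_index(drop=True)
        if len(frame) and not ((frame["start"] < frame["end"]).all()):
            raise ValueError("all tags must satisfy start < end")
        if len(frame) and not frame["strand"].isin(["+", "-"]).all():
            raise ValueError("tag strand must be '+' or '-'")
        self.frame = frame
        self.label = label
        self._cut_cache: dict[str, np.ndarray] | None = None

    @classmethod
    def from_arrays(cls, contig, start, end, strand, label: str = "") -> "TagLibrary":
        return cls(
            pd.DataFrame(
                {
                    "contig": np.asarray(contig, dtype=object),
                    "start": np.asarray(start, dtype=np.int64),
                    "end": np.asarray(end, dtype=np.int64),
                    "strand": np.asarray(strand, dtype=object),
                }
            ),
            label=label,
        )

    @property
    def size(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def cut_sites_per_tag(self) -> np.ndarray:
        """Per-tag cut-site position (5' end): start for '+', end for '-'."""
        s = self.frame["strand"].to_numpy()
        return np.where(
            s == "+", self.frame["start"].to_numpy(), self.frame["end"].to_numpy()
        ).astype(np.int64)

    def cut_sites(self) -> dict[str, np.ndarray]:
        """Sorted cut-site positions per contig (cached)."""
        if self._cut_cache is None:
            cuts = self.cut_sites_per_tag()
            contigs = self.frame["contig"].to_numpy()
            cache: dict[str, np.ndarray] = {}
            for name in pd.unique(contigs):
                cache[name] = np.sort(cuts[contigs == name], kind="stable")
            self._cut_cache = cache
        return self._cut_cache

    def exclude_contig(self, contig: str) -> "TagLibrary":
        keep = self.frame["contig"] != contig
        return TagLibrary(self.frame[keep].reset_index(drop=True), label=self.label)

    def validate_against(self, lengths: Mapping[str, int]) -> None:
        """Raise if any tag falls outside the given contig lengths."""
        for name, group in self.frame.groupby("contig", sort=False):
            if name not in lengths:
                raise ValueError(f"tag on unknown contig {name!r}")
            if int(group["end"].max()) > lengths[name] or int(group["start"].min()) < 0:
                raise ValueError(f"tag outside contig {name!r} bounds")


@dataclass
class GeneModel:
    """A gene (one TSS record); multiple records may share a ``gene_id``.

    The TSS is the 5' end of the gene respecting strand, so ``tss > tts``
    on the minus strand.
    """

    gene_id: str
    contig: str
    strand: str
    tss: int
    tts: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    transcripts_per_cell: float | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: + strand gene requires TSS < TTS")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: - strand gene requires TSS > TTS")
        if self.transcripts_per_cell is not None and self.transcripts_per_cell < 0:
            raise ValueError("transcripts_per_cell must be non-negative")
        lo, hi = min(self.tss, self.tts), max(self.tss, self.tts)
        prev_end = None
        for s, e in sorted(self.exons):
            if s < lo or e > hi + 1:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene body")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def body(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tts), max(self.tss, self.tts)
        return GenomicInterval(self.contig, lo, hi + 1, self.strand)


@dataclass(frozen=True)
class Hotspot:
    """A called accessible interval."""

    interval: GenomicInterval
    tag_count: int
    density: float  # tags per kb per million library tags
    z_score: float

    def __post_init__(self):
        if self.tag_count < 1:
            raise ValueError("hotspot must contain at least one tag")
        if not self.density > 0:
            raise ValueError("hotspot density must be positive")


class HotspotSet:
    """A sorted, non-overlapping collection of hotspots plus call parameters."""

    def __init__(
        self,
        hotspots: Sequence[Hotspot],
        params: dict | None = None,
        label: str = "",
    ):
        hotspots = sorted(
            hotspots, key=lambda h: (h.interval.contig, h.interval.start)
        )
        for a, b in zip(hotspots, hotspots[1:]):
            if a.interval.overlaps(b.interval):
                raise ValueError("hotspots must be non-overlapping")
        self.hotspots = list(hotspots)
        self.params = dict(params or {})
        self.label = label

    def __len__(self) -> int:
        return len(self.hotspots)

    def __iter__(self) -> Iterator[Hotspot]:
        return iter(self.hotspots)

    def __getitem__(self, i) -> Hotspot:
        return self.hotspots[i]

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [h.interval for h in self.hotspots]

    def densities(self) -> np.ndarray:
        return np.array([h.density for h in self.hotspots], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [h.interval.contig for h in self.hotspots],
                "start": [h.interval.start for h in self.hotspots],
                "end": [h.interval.end for h in self.hotspots],
                "tag_count": [h.tag_count for h in self.hotspots],
                "density": [h.density for h in self.hotspots],
                "z_score": [h.z_score for h in self.hotspots],
            }
        )
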