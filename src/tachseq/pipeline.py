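"""End-to-end orchestration: simulate -> call -> compare -> bias -> annotate.

Every run writes a JSON manifest (config snapshot, derived per-stage seeds,
output paths with SHA-256 checksums, per-stage summary numbers). Runs are
fully deterministic: re-running from the same config reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .annotate import aggregate_density, bin_expression, feature_distribution, tss_occupancy
from .compare import density_correlation, overlap_summary, quartile_overlap, union_merge
from .config import RunConfig
from .core import GenomeSequence
from .hotspots import call_hotspots, mito_fraction
from .seqbias import cpg_overlap_fraction, cut_site_base_frequency, find_cpg_islands, gc_content
from .simulate import (
    FragmentModel,
    LogNormalIntensity,
    generate_genome,
    generate_landscape,
    preset_bias,
    simulate_digestion,
)

__all__ = ["run_pipeline", "stage_seed"]

_STAGE_IDS = {"simulate": 1, "callhotspots": 2, "compare": 3, "bias": 4, "annotate": 5}


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed: a documented expansion of the global
    seed so individual stages can be re-run in isolation.

    ``seed * 1000 + stage_id * 10 + index`` (kept below 2**31).
    """
    return (int(global_seed) * 1000 + _STAGE_IDS[stage] * 10 + index) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the configured stages in order and return the manifest.

    Stage outputs are flat files in ``outdir`` (FASTA genome, TSV truth
    tables, BED tags/hotspots/islands, TSV summaries). Any stage error
    aborts the run with the stage name attached.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "tachseq",
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }
    state: dict = {}
    for stage in config.stages:
        if stage not in _STAGE_IDS:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            summary = _RUNNERS[stage](config, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = summary
    for path in sorted(out.glob("*")):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    g = config.genome
    genome, islands = generate_genome(
        n_contigs=g.n_contigs,
        contig_len=g.contig_len,
        gc_block_len=g.gc_block_len,
        gc_levels=tuple(g.gc_levels),
        n_cpg_islands=g.n_cpg_islands,
        seed=stage_seed(config.seed, "simulate", 0),
        mito=g.mito,
    )
    lc = config.landscape
    landscape, genes, expression = generate_landscape(
        genome,
        n_regions=lc.n_regions,
        intensity_law=LogNormalIntensity(lc.intensity_mean_log, lc.intensity_sigma_log),
        promoter_fraction=lc.promoter_fraction,
        expression_coupling=lc.expression_coupling,
        seed=stage_seed(config.seed, "simulate", 1),
        region_len_range=(lc.region_len_min, lc.region_len_max),
    )
    libraries = {}
    for i, libcfg in enumerate(config.libraries):
        lib = simulate_digestion(
            genome,
            landscape,
            preset_bias(libcfg.bias),
            n_fragments=libcfg.n_fragments,
            fragment_model=FragmentModel(libcfg.fragment_min, libcfg.fragment_max),
            tag_len=libcfg.tag_len,
            mito_fraction=libcfg.mito_fraction if g.mito else 0.0,
            seed=stage_seed(config.seed, "simulate", 2 + i),
            label=libcfg.label,
        )
        libraries[libcfg.label] = lib
        tio.write_tags_bed(lib, out / f"tags_{libcfg.label}.bed")
    tio.write_fasta(genome, out / "genome.fa")
    tio.write_intervals_bed(
        [r.interval for r in landscape.regions], out / "regions_truth.bed"
    )
    pd.DataFrame(
        {
            "contig": [r.interval.contig for r in landscape.regions],
            "start": [r.interval.start for r in landscape.regions],
            "end": [r.interval.end for r in landscape.regions],
            "intensity": [r.intensity for r in landscape.regions],
            "klass": [r.klass for r in landscape.regions],
        }
    ).to_csv(out / "regions_truth.tsv", sep="\t", index=False)
    tio.write_gene_table(genes, out / "genes.tsv")
    tio.write_expression_table(expression, out / "expression.tsv")
    tio.write_intervals_bed(islands, out / "cpg_islands_truth.bed", "island")
    state.update(
        genome=genome, islands=islands, landscape=landscape, genes=genes,
        expression=expression, libraries=libraries,
    )
    return {
        "contigs": len(genome.lengths),
        "regions": len(landscape.regions),
        "genes": len(genes),
        "libraries": {k: v.size for k, v in libraries.items()},
    }


def _stage_callhotspots(config: RunConfig, out: Path, state: dict) -> dict:
    genome: GenomeSequence = state["genome"]
    summary = {}
    hotspot_sets = {}
    for i, (label, lib) in enumerate(state["libraries"].items()):
        mito = mito_fraction(lib, config.hotspots.mito_contig)
        hs = call_hotspots(
            lib,
            genome.lengths,
            config.hotspots,
            seed=stage_seed(config.seed, "callhotspots", i),
        )
        hotspot_sets[label] = hs
        tio.write_hotspots_bed(hs, out / f"hotspots_{label}.bed")
        summary[label] = {
            "mito_fraction": round(mito, 4),
            "n_hotspots": len(hs),
            "z_threshold": hs.params["z_threshold"],
            "mode_density_cutoff": hs.params.get("mode_density_cutoff"),
        }
    state["hotspot_sets"] = hotspot_sets
    return summary


def _stage_compare(config: RunConfig, out: Path, state: dict) -> dict:
    sets = list(state["hotspot_sets"].values())
    labels = list(state["hotspot_sets"])
    if len(sets) < 2:
        return {"skipped": "needs >= 2 libraries"}
    summary = overlap_summary(sets)
    rows = [
        {
            "pattern": "+".join(sorted(k)),
            "count": v,
            "percent": round(summary.pattern_percent[k], 2),
        }
        for k, v in sorted(summary.pattern_counts.items(), key=lambda kv: -kv[1])
    ]
    pd.DataFrame(rows).to_csv(out / "overlap_patterns.tsv", sep="\t", index=False)
    qtables = []
    for label, hs in state["hotspot_sets"].items():
        if len(hs) >= 4:
            others = [s for lab, s in state["hotspot_sets"].items() if lab != label]
            qt = quartile_overlap(hs, others)
            qt.insert(0, "set", label)
            qtables.append(qt)
    if qtables:
        pd.concat(qtables, ignore_index=True).to_csv(
            out / "quartile_overlap.tsv", sep="\t", index=False
        )
    libs = list(state["libraries"].values())
    union = union_merge(sets)
    r = density_correlation(libs[0], libs[1], [u.interval for u in union])
    return {
        "union_count": summary.union_count,
        "density_pearson_r_log10": round(r, 4),
        "patterns": {("+".join(sorted(k))): v for k, v in summary.pattern_counts.items()},
    }


def _stage_bias(config: RunConfig, out: Path, state: dict) -> dict:
    genome = state["genome"]
    summary = {}
    for label, lib in state["libraries"].items():
        prof = cut_site_base_frequency(lib, genome, k=config.bias_flank_k)
        prof.frequencies.to_csv(out / f"base_frequency_{label}.tsv", sep="\t")
        summary[label] = {"modal_base_offset0": prof.modal_base(0)}
    islands = find_cpg_islands(genome)
    tio.write_intervals_bed(islands, out / "cpg_islands_called.bed", "island")
    for label, hs in state.get("hotspot_sets", {}).items():
        gcs = gc_content(hs.intervals, genome)
        summary[label]["median_hotspot_gc"] = (
            round(float(np.nanmedian(gcs)), 4) if len(gcs) else None
        )
        summary[label]["cpg_island_overlap_fraction"] = round(
            cpg_overlap_fraction(hs, islands), 4
        )
    summary["n_cpg_islands_called"] = len(islands)
    return summary


def _stage_annotate(config: RunConfig, out: Path, state: dict) -> dict:
    genes = tio.attach_expression(state["genes"], state["expression"])
    summary: dict = {}
    dist_rows = []
    for label, hs in state.get("hotspot_sets", {}).items():
        dist = feature_distribution(hs, genes, config.promoter_len, config.downstream_len)
        for cat, c in dist.counts.items():
            dist_rows.append(
                {"set": label, "category": cat, "count": c,
                 "fraction": round(dist.fractions[cat], 4)}
            )
        summary[label] = {"promoter_fraction": round(dist.fractions["promoter"], 4)}
    pd.DataFrame(dist_rows).to_csv(out / "feature_distribution.tsv", sep="\t", index=False)
    binning = bin_expression(state["expression"], scheme="log2")
    occ = tss_occupancy(genes, list(state.get("hotspot_sets", {}).values()), binning)
    occ.to_csv(out / "tss_occupancy.tsv", sep="\t", index=False)
    lib0 = next(iter(state["libraries"].values()))
    profile = aggregate_density(
        genes, lib0, flank=config.aggregation_flank,
        bin_width=config.aggregation_bin, anchor_mode="tss-strand-oriented",
    )
    pd.DataFrame(
        {"offset": profile.bin_starts, "density": profile.density}
    ).to_csv(out / "tss_aggregate_density.tsv", sep="\t", index=False)
    summary["occupancy"] = {
        row["bin"]: None if pd.isna(row["occupied_fraction"])
        else round(float(row["occupied_fraction"]), 4)
        for _, row in occ.iterrows()
    }
    return summary


_RUNNERS = {
    "simulate": _stage_simulate,
    "callhotspots": _stage_callhotspots,
    "compare": _stage_compare,
    "bias": _stage_bias,
    "annotate": _stage_annotate,
}
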