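"""Run the whole pipeline from one config and inspect the manifest.

Equivalent to `tachseq run --seed 1 --out demo_run` with the same config;
all stage outputs are flat files and the manifest records checksums, so a
re-run from the same config is byte-identical.
"""

import json
from pathlib import Path

import tachseq as tq
from tachseq.config import GenomeConfig, LandscapeConfig, LibraryConfig, RunConfig

config = RunConfig(
    seed=1,
    genome=GenomeConfig(contig_len=1_000_000, n_cpg_islands=4, mito=True),
    landscape=LandscapeConfig(n_regions=40),
    libraries=(
        LibraryConfig(label="benzonase", bias="benzonase", n_fragments=60_000),
        LibraryConfig(label="dnase1", bias="dnase1", n_fragments=60_000),
    ),
)
outdir = Path("demo_run")
manifest = tq.run_pipeline(config, outdir)

print("stage summaries:")
print(json.dumps(manifest["stages"], indent=2, sort_keys=True))
print(f"\n{len(manifest['outputs'])} output files in {outdir}/ (see manifest.json)")
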