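"""GWAS SNP-locus permutation enrichment: disease vs control traits across
the SE DHS / SE non-DHS interval and motif-site feature sets."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, ensure_dirs

from stretchmotif.gwas import (
    build_loci,
    filter_genomewide,
    permutation_enrichment,
    results_to_frame,
)
from stretchmotif.pipeline import gwas_feature_sets
from stretchmotif.simulate import SyntheticConfig, generate_dataset

ensure_dirs()
cfg = SyntheticConfig(seed=SEED)
ds = generate_dataset(cfg, with_gwas=True)
cell = cfg.cells[0]
features = gwas_feature_sets(ds, cell, list(ds.pwms()))

loci = filter_genomewide(build_loci(ds.snp_table, ds.ld_table))
results = []
for fname, ivs in features.items():
    for trait in ("disease", "control"):
        trait_loci = [loc for loc in loci if loc.trait == trait]
        results.append(
            permutation_enrichment(
                trait_loci, loci, ivs, n_iter=10_000, seed=SEED,
                trait=trait, cell=cell, feature_set=fname,
            )
        )
df = results_to_frame(results)
df.to_csv(RESULTS / "gwas_enrichment.tsv", sep="\t", index=False)
print(df.to_string(index=False))
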