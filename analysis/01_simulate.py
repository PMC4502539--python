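"""Generate the synthetic corpus and write every input file the pipeline
consumes, plus the truth tables downstream recovery checks read."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CORPUS, SEED, ensure_dirs

from stretchmotif import io as smio
from stretchmotif.simulate import SyntheticConfig, generate_dataset

ensure_dirs()
cfg = SyntheticConfig(seed=SEED)
ds = generate_dataset(cfg, with_gwas=True, with_signal=True)

smio.write_fasta(CORPUS / "genome.fasta", ds.genome)
smio.write_meme_motifs(CORPUS / "motifs.meme", ds.motif_records)
smio.write_expression_table(CORPUS / "expression.tsv", ds.expression)
ds.snp_table.to_csv(CORPUS / "snps.tsv", sep="\t", index=False)
ds.ld_table.to_csv(CORPUS / "ld.tsv", sep="\t", index=False)
ds.enhancer_truth.to_csv(CORPUS / "enhancer_truth.tsv", sep="\t", index=False)
ds.site_truth.to_csv(CORPUS / "site_truth.tsv", sep="\t", index=False)
with open(CORPUS / "motif2tf.tsv", "w") as fh:
    fh.write("motif\ttf\trole\n")
    for motif, tf in ds.motif_to_tf.items():
        fh.write(f"{motif}\t{tf}\t{ds.motif_roles[motif]}\n")
for cell in cfg.cells:
    smio.write_bed(CORPUS / f"segmentation_{cell}.bed", ds.segmentations[cell])
    smio.write_narrowpeak(CORPUS / f"dhs_{cell}.narrowPeak", ds.peaks[cell])
import numpy as np

for assay, arrays in ds.signal_tracks.items():
    # 10 bp-mean bins, zero bins dropped, to keep the bedGraph compact
    rows = []
    for chrom, arr in arrays.items():
        n = len(arr) // 10 * 10
        means = arr[:n].reshape(-1, 10).mean(axis=1)
        for k in np.flatnonzero(means > 1e-9):
            rows.append((chrom, int(k) * 10, int(k) * 10 + 10, float(means[k])))
    smio.write_bedgraph(CORPUS / f"{assay}_{cfg.cells[0]}.bedgraph", rows)

print(f"corpus for seed {SEED} written to {CORPUS}")
print(f"  {len(ds.site_truth)} planted motif sites, "
      f"{len(ds.snp_table)} GWAS lead SNPs")
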