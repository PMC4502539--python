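"""Summit-centered aggregate profiles (DNase, H3K27ac, CG dinucleotide,
motif density) and a motif-density bedGraph track over one SE region."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, ensure_dirs

from stretchmotif import io as smio
from stretchmotif.intervals import GenomeInterval
from stretchmotif.profiles import (
    SignalTrack,
    aggregate_dinucleotide,
    aggregate_motif_density,
    aggregate_signal,
    motif_density_track,
)
from stretchmotif.simulate import SyntheticConfig, generate_dataset

ensure_dirs()
cfg = SyntheticConfig(seed=SEED)
ds = generate_dataset(cfg, with_gwas=False, with_signal=True)
cell = cfg.cells[0]
se_summits = ds.summits(cell, "SE")
te_summits = ds.summits(cell, "TE")
pwms = ds.pwms()

frames = {}
for assay in ("dnase", "h3k27ac"):
    track = SignalTrack.from_arrays(ds.signal_tracks[assay])
    for cls, summits in (("SE", se_summits), ("TE", te_summits)):
        prof = aggregate_signal(summits, track)
        frames[f"{assay}_{cls}"] = prof.values
        if cls == "SE":
            extreme = np.argmax(prof.values) if assay == "dnase" else np.argmin(prof.values)
            print(f"{assay} SE profile: {prof.n_bins} bins, "
                  f"extreme at bin {int(extreme)} (central bin {prof.central_bin})")
offsets = aggregate_signal(se_summits, SignalTrack.from_arrays(ds.signal_tracks["dnase"])).offsets

cg = aggregate_dinucleotide(se_summits, ds.genome, "CG")
frames["cg_SE"] = cg.values
dens = aggregate_motif_density(se_summits, list(pwms), pwms, ds.genome)
frames["motif_density_SE"] = dens.values
print(f"motif density SE profile: peak at bin {int(np.argmax(dens.values))}")

out = pd.DataFrame({"offset": offsets, **frames})
out.to_csv(RESULTS / "aggregate_profiles.tsv", sep="\t", index=False)

se_iv = next(
    GenomeInterval(r.chrom, int(r.start), int(r.end))
    for r in ds.enhancer_truth[
        (ds.enhancer_truth["cell"] == cell)
        & (ds.enhancer_truth["enhancer_class"] == "SE")
    ].itertuples(index=False)
)
track = motif_density_track(se_iv, list(pwms), pwms, ds.genome)
smio.write_bedgraph(RESULTS / "motif_density_track.bedgraph", track.to_bedgraph_rows())
print(f"density track over {se_iv.chrom}:{se_iv.start}-{se_iv.end}: "
      f"max {int(track.counts.max())} non-overlapping sites per 150 bp window")
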