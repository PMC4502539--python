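"""Classify SE/TE enhancers from the corpus files and partition them into
DHS / non-DHS compartments; write per-cell compartment statistics and the
SE-vs-TE descriptive comparisons (summit spacing, DHS lengths)."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CORPUS, RESULTS, ensure_dirs

from stretchmotif import io as smio
from stretchmotif.enhancers import (
    classify_enhancers,
    compare_distributions,
    dhs_lengths_by_class,
    partition_compartments,
    summit_spacing,
)

ensure_dirs()
genome = smio.read_fasta(CORPUS / "genome.fasta")
cells = sorted(
    p.stem.replace("segmentation_", "") for p in CORPUS.glob("segmentation_*.bed")
)

comp_rows, spacing_rows = [], []
for cell in cells:
    seg = smio.read_bed(CORPUS / f"segmentation_{cell}.bed")
    peaks = smio.read_narrowpeak(CORPUS / f"dhs_{cell}.narrowPeak")
    es = classify_enhancers(seg)
    comps = partition_compartments(es, peaks, genome)
    counts = es.counts()
    for name, comp in comps.items():
        comp_rows.append(
            {"cell": cell, "compartment": name,
             "n_intervals": len(comp.intervals),
             "total_bp": comp.total_nucleotides,
             "n_se": counts["SE"], "n_te": counts["TE"]}
        )
    se_sp = summit_spacing(es, peaks, "SE")
    te_sp = summit_spacing(es, peaks, "TE")
    lengths = dhs_lengths_by_class(es, peaks)
    _, p_spacing = compare_distributions(se_sp, te_sp, alternative="less")
    _, p_len = compare_distributions(
        lengths.get("SE", []), lengths.get("TE", []), alternative="greater"
    )
    spacing_rows.append(
        {"cell": cell,
         "median_se_spacing": float(np.median(se_sp)) if se_sp else np.nan,
         "median_te_spacing": float(np.median(te_sp)) if te_sp else np.nan,
         "p_spacing_se_less": p_spacing,
         "median_se_dhs_len": float(np.median(lengths.get("SE", [np.nan]))),
         "median_te_dhs_len": float(np.median(lengths.get("TE", [np.nan]))),
         "p_length_se_greater": p_len}
    )

pd.DataFrame(comp_rows).to_csv(RESULTS / "compartments.tsv", sep="\t", index=False)
df = pd.DataFrame(spacing_rows)
df.to_csv(RESULTS / "se_te_contrasts.tsv", sep="\t", index=False)
print(df.to_string(index=False))
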