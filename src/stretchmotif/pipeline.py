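"""High-level analysis steps chaining the library modules.

These are the operations the numbered ``analysis/`` drivers, the test suite,
and the acceptance script share: computing compartment enrichment tables
over a corpus, summit-centered central enrichment, the cell-identity
assignment cascade, and GWAS feature-set construction.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enhancers import COMPARTMENTS
from .expression import (
    CentralEnrichmentResult,
    assign_cell_motifs,
    central_enrichment,
    expression_enrichment_correlation,
)
from .gwas import motif_site_feature_set
from .intervals import GenomeInterval
from .motifs import PWM, scan
from .simulate import SyntheticDataset


def shuffled_copy(
    sequences: Sequence[tuple[str, str]], rng: np.random.Generator
) -> list[tuple[str, str]]:
    from .motifs import dinucleotide_shuffle

    return [(sid, dinucleotide_shuffle(s, rng)) for sid, s in sequences]


def compartment_enrichment_table(
    dataset: SyntheticDataset,
    compartments: Sequence[str] = COMPARTMENTS,
    cells: Sequence[str] | None = None,
    seed: int = 0,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Fold enrichment of every motif in every (cell, compartment).

    One dinucleotide-shuffled copy of each compartment's sequence set serves
    as the shared control for all motifs (the shuffle preserves dinucleotide
    counts, so one control set is a valid null for every motif).
    """
    rng = np.random.default_rng(seed)
    pwms = dataset.pwms()
    cells = list(cells or dataset.config.cells)
    rows = []
    for cell in cells:
        comp_seqs = dataset.compartment_sequences(cell)
        for comp in compartments:
            seqs = list(comp_seqs[comp].as_mapping().items())
            shuffled = shuffled_copy(seqs, rng)
            for name, pwm in pwms.items():
                real = len(scan(pwm, seqs, p_threshold))
                ctrl = len(scan(pwm, shuffled, p_threshold))
                fe = (real + 1.0) / (ctrl + 1.0)
                rows.append((name, cell, comp, fe))
    from .expression import build_enrichment_table

    return build_enrichment_table(rows)


def summit_centered_sequences(
    dataset: SyntheticDataset, cell: str, cls: str = "SE", length: int = 1000
) -> list[str]:
    """Fixed-length sequences centered on the cell's in-class DHS summits."""
    half = length // 2
    out = []
    for chrom, pos in dataset.summits(cell, cls):
        seq = dataset.genome[chrom]
        if pos - half < 0 or pos + half > len(seq):
            continue
        out.append(seq[pos - half : pos + half])
    return out


def central_enrichment_for_cell(
    dataset: SyntheticDataset,
    cell: str,
    cls: str = "SE",
    length: int = 1000,
    score_floor_bits: float = 5.0,
) -> dict[str, CentralEnrichmentResult]:
    seqs = summit_centered_sequences(dataset, cell, cls, length)
    pwms = dataset.pwms()
    return {
        name: central_enrichment(pwm, seqs, score_floor_bits)
        for name, pwm in pwms.items()
    }


def assignment_for_cell(
    dataset: SyntheticDataset,
    cell: str,
    enrichment: pd.DataFrame,
    central: Mapping[str, CentralEnrichmentResult] | None = None,
):
    """Run the full cell-identity assignment cascade for one cell."""
    central = central or central_enrichment_for_cell(dataset, cell)
    rho = expression_enrichment_correlation(
        enrichment, dataset.expression, dataset.motif_to_tf, "SE_DHS"
    )
    return assign_cell_motifs(
        enrichment,
        dataset.expression,
        dataset.motif_to_tf,
        rho,
        central,
        cell,
    )


def se_union_intervals(dataset: SyntheticDataset) -> list[GenomeInterval]:
    """Merged union of every cell's SE intervals (the high-coverage feature
    set used for permutation-null calibration)."""
    from .intervals import merge_intervals

    return merge_intervals(
        [
            iv
            for cell in dataset.config.cells
            for iv, cls in dataset.enhancer_set(cell).enhancers
            if cls == "SE"
        ]
    )


def gwas_feature_sets(
    dataset: SyntheticDataset,
    cell: str,
    motif_names: Sequence[str],
    p_threshold: float = 1e-4,
) -> dict[str, list[GenomeInterval]]:
    """GWAS feature sets for one cell: SE DHS / SE non-DHS intervals and the
    identity-motif sites within each."""
    comp_seqs = dataset.compartment_sequences(cell)
    pwms = dataset.pwms()
    out: dict[str, list[GenomeInterval]] = {
        "SE_DHS": comp_seqs["SE_DHS"].intervals,
        "SE_nonDHS": comp_seqs["SE_nonDHS"].intervals,
    }
    for comp in ("SE_DHS", "SE_nonDHS"):
        out[f"{comp}_motif_sites"] = motif_site_feature_set(
            motif_names, pwms, comp_seqs[comp], p_threshold
        )
    return out
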