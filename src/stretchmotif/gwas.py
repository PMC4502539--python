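"""GWAS SNP-locus enrichment in enhancer compartments and motif sites.

A SNP locus is a lead (index) SNP together with every proxy in strong LD
(r^2 >= 0.8). Enrichment of a trait's loci in a feature set (e.g. SE non-DHS
motif sites of one cell type) is tested by permutation: resample equal-sized
locus sets from the full multi-trait catalog pool and count, per draw, the
loci with at least one member SNP inside the features. The empirical p-value
is the standard maximal estimate ``(n_ge + 1) / (n_iter + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enhancers import CompartmentSequences
from .intervals import GenomeInterval, IntervalIndex, merge_intervals
from .motifs import PWM, scan

R2_THRESHOLD = 0.8
GENOMEWIDE_P = 5e-8
DEFAULT_N_ITER = 10_000


@dataclass(frozen=True)
class SNPRecord:
    rsid: str
    chrom: str
    pos: int  # 0-based
    trait: str
    pvalue: float
    is_lead: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: association p must be in (0, 1]")
        if self.pos < 0:
            raise ValueError(f"{self.rsid}: negative position")


@dataclass
class SNPLocus:
    """A lead SNP plus all proxies with r^2 >= the LD threshold."""

    lead: SNPRecord
    members: list[SNPRecord]
    trait: str

    def __post_init__(self) -> None:
        if self.lead not in self.members:
            raise ValueError(f"lead {self.lead.rsid} must be among locus members")

    def positions(self) -> list[tuple[str, int]]:
        return [(m.chrom, m.pos) for m in self.members]


@dataclass
class EnrichmentResult:
    trait: str
    cell: str
    feature_set: str
    observed: int
    n_iterations: int
    n_ge: int

    @property
    def p_empirical(self) -> float:
        return (self.n_ge + 1) / (self.n_iterations + 1)


def build_loci(
    snp_table: pd.DataFrame,
    ld_table: pd.DataFrame,
    r2_threshold: float = R2_THRESHOLD,
) -> list[SNPLocus]:
    """One locus per catalog row (lead SNP x trait), with r^2 >= threshold
    proxies attached. Proxy rows referencing unknown leads are skipped with a
    warning; leads without proxies form singleton loci.
    """
    known_leads = set(snp_table["rsid"])
    proxies_by_lead: dict[str, list[SNPRecord]] = {}
    for row in ld_table.itertuples(index=False):
        if row.lead_rsid not in known_leads:
            warnings.warn(
                f"LD row references unknown lead {row.lead_rsid}; skipped",
                stacklevel=2,
            )
            continue
        if row.r2 >= r2_threshold:
            proxies_by_lead.setdefault(row.lead_rsid, []).append(
                SNPRecord(
                    rsid=row.proxy_rsid,
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    trait="",
                    pvalue=1.0,
                    is_lead=False,
                )
            )
    loci: list[SNPLocus] = []
    for row in snp_table.itertuples(index=False):
        lead = SNPRecord(
            rsid=row.rsid,
            chrom=str(row.chrom),
            pos=int(row.pos),
            trait=row.trait,
            pvalue=float(row.pvalue),
            is_lead=True,
        )
        members = [lead] + [
            SNPRecord(
                rsid=p.rsid, chrom=p.chrom, pos=p.pos,
                trait=row.trait, pvalue=p.pvalue, is_lead=False,
            )
            for p in proxies_by_lead.get(row.rsid, [])
        ]
        loci.append(SNPLocus(lead=lead, members=members, trait=row.trait))
    return loci


def filter_genomewide(
    loci: Sequence[SNPLocus], threshold: float = GENOMEWIDE_P
) -> list[SNPLocus]:
    """Keep loci whose lead association p is strictly below the genome-wide
    significance threshold; proxies stay with their lead regardless of their
    own p-values."""
    return [loc for loc in loci if loc.lead.pvalue < threshold]


def locus_overlap_flags(
    loci: Sequence[SNPLocus], feature_intervals: Sequence[GenomeInterval]
) -> np.ndarray:
    """Boolean per locus: does any member SNP fall inside any feature?"""
    index = IntervalIndex(feature_intervals)
    flags = np.zeros(len(loci), dtype=bool)
    for i, loc in enumerate(loci):
        flags[i] = any(index.contains(chrom, pos) for chrom, pos in loc.positions())
    return flags


def count_locus_overlaps(
    loci: Sequence[SNPLocus], feature_intervals: Sequence[GenomeInterval]
) -> int:
    """Number of loci with >=1 member SNP inside the (merged) features; a
    locus counts at most once."""
    return int(locus_overlap_flags(loci, feature_intervals).sum())


def permutation_enrichment(
    trait_loci: Sequence[SNPLocus],
    catalog_loci_pool: Sequence[SNPLocus],
    feature_intervals: Sequence[GenomeInterval],
    n_iter: int = DEFAULT_N_ITER,
    seed: int | np.random.Generator = 0,
    trait: str = "",
    cell: str = "",
    feature_set: str = "",
    with_replacement: bool = False,
) -> EnrichmentResult:
    """Permutation test of locus-feature overlap against catalog resampling.

    Each iteration draws ``len(trait_loci)`` loci from the catalog pool
    (without replacement by default, preserving each locus's internal LD
    structure) and recounts overlaps. ``p = (n_ge + 1) / (n_iter + 1)`` where
    ``n_ge`` counts iterations whose overlap is >= the observed one.
    """
    n = len(trait_loci)
    pool_size = len(catalog_loci_pool)
    if not with_replacement and pool_size < n:
        raise ValueError(
            f"catalog pool ({pool_size}) smaller than trait locus set ({n})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = count_locus_overlaps(trait_loci, feature_intervals)
    # per-pool-locus overlap flags are fixed, so each iteration's count is the
    # number of sampled flagged loci
    flags = locus_overlap_flags(catalog_loci_pool, feature_intervals)
    if n == 0:
        counts = np.zeros(n_iter, dtype=np.int64)
    elif with_replacement:
        idx = rng.integers(0, pool_size, size=(n_iter, n))
        counts = flags[idx].sum(axis=1)
    else:
        counts = np.empty(n_iter, dtype=np.int64)
        # chunk the random-key matrix to bound memory
        chunk = max(1, int(5e7) // max(pool_size, 1))
        done = 0
        while done < n_iter:
            m = min(chunk, n_iter - done)
            keys = rng.random((m, pool_size))
            idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
            counts[done : done + m] = flags[idx].sum(axis=1)
            done += m
    n_ge = int((counts >= observed).sum())
    return EnrichmentResult(
        trait=trait or (trait_loci[0].trait if trait_loci else ""),
        cell=cell,
        feature_set=feature_set,
        observed=int(observed),
        n_iterations=int(n_iter),
        n_ge=n_ge,
    )


def motif_site_feature_set(
    motif_names: Sequence[str],
    pwms: Mapping[str, PWM],
    compartment: CompartmentSequences,
    p_threshold: float = 1e-4,
) -> list[GenomeInterval]:
    """Merged genomic intervals of a cell's identity-motif hits inside one
    enhancer compartment.

    Hits (both strands, scanner p <= threshold) are called on the
    compartment's sequences and projected back to genome coordinates.
    """
    if not motif_names:
        warnings.warn("empty motif set: feature set is empty", stacklevel=2)
        return []
    by_id = {
        f"{iv.chrom}:{iv.start}-{iv.end}": iv for iv in compartment.intervals
    }
    sequences = compartment.as_mapping()
    hits_ivs: list[GenomeInterval] = []
    for name in motif_names:
        for hit in scan(pwms[name], sequences, p_threshold):
            iv = by_id[hit.sequence_id]
            hits_ivs.append(
                GenomeInterval(iv.chrom, iv.start + hit.start, iv.start + hit.end)
            )
    return merge_intervals(hits_ivs)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "trait": r.trait,
                "cell": r.cell,
                "feature_set": r.feature_set,
                "observed": r.observed,
                "n_iterations": r.n_iterations,
                "n_ge": r.n_ge,
                "p_empirical": r.p_empirical,
            }
            for r in results
        ]
    )
    if not df.empty:
        # convenience only; the per-panel results are reported unadjusted
        df["p_bonferroni"] = np.minimum(df["p_empirical"] * len(df), 1.0)
    return df
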