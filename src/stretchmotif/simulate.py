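"""Synthetic data generator for the full pipeline.

Generates every input the analysis consumes — genome, per-cell chromatin
segmentations, DHS peaks with summits, a motif library, planted motif sites,
TF expression coupled to planting rates, GWAS SNP/LD tables, and signal
tracks — together with machine-readable truth tables for recovery tests.

What it emulates: cell-specific enhancer territories (stretch enhancers with
several long, closely spaced DHSs; typical enhancers with single shorter
DHSs), motif instances concentrated around DHS summits at cell-specific
rates, activator TFs whose expression tracks their motif's planting rate
across cells (repressors anti-track), and GWAS "disease" loci placed
preferentially inside stretch-enhancer non-DHS motif sites while control
loci fall uniformly.

All randomness flows from a single seed; identical config + seed gives a
byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enhancers import CompartmentSequences, EnhancerSet, classify_run
from .intervals import (
    GenomeInterval,
    NarrowPeak,
    intersect_intervals,
    subtract_intervals,
)
from .io import MemeMotifRecord
from .motifs import PWM, reverse_complement

BASES = "ACGT"
COMPARTMENTS = ("SE_DHS", "SE_nonDHS", "TE_DHS", "TE_nonDHS")
ROLES = ("activator", "repressor", "neutral")


@dataclass
class GwasDesign:
    """Shape of the synthetic GWAS catalog."""

    n_disease: int = 40
    n_control: int = 40
    n_background_traits: int = 8
    loci_per_background: int = 40
    disease_feature_fraction: float = 0.6  # fraction of disease leads in SE_nonDHS motif sites
    control_feature_fraction: float = 0.0
    max_proxies: int = 5
    proxy_window: int = 25_000
    r2_range: tuple[float, float] = (0.5, 1.0)
    frac_genomewide: float = 0.7


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic corpus; defaults are the study conditions
    all recovery tests run under (sized for a single CPU)."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    n_cells: int = 9
    n_se: int = 30
    n_te: int = 120
    se_length: tuple[int, int] = (3000, 5000)
    te_length: tuple[int, int] = (200, 800)
    dhs_per_se: int = 3
    dhs_per_te: int = 1
    se_dhs_length: tuple[int, int] = (150, 300)
    te_dhs_length: tuple[int, int] = (100, 200)
    summit_jitter: int = 10
    min_gap: int = 300
    # motif library
    n_motifs: int = 10
    n_activators: int = 6
    n_repressors: int = 2
    motif_width: tuple[int, int] = (8, 12)
    consensus_prob: float = 0.9
    # planting rates (sites per bp)
    lam_dhs_max: float = 1.0 / 150.0
    lam_nondhs_factor: float = 0.1
    lam_weight_range: tuple[float, float] = (0.1, 1.0)
    dhs_site_sd: float = 30.0  # site spread around the summit
    # expression coupling
    expression_scale: float = 10.0
    expression_noise_sd: float = 0.5
    # when False, TF expression is drawn independently of planting weights
    # (the decoupled null corpus used to calibrate the correlation test)
    expression_coupled: bool = True
    # signal tracks
    dnase_amplitude: float = 5.0
    dnase_sd: float = 100.0
    h3k27ac_amplitude: float = 3.0
    h3k27ac_se_te_ratio: float = 2.0
    # broad enhancer-wide bump minus a deep, narrow depression at the summit:
    # keeps flanking signal high across a +/-1500 bp window so the dip at the
    # summit is the profile's minimum, not the window edges
    h3k27ac_broad_sd: float = 800.0
    h3k27ac_dip_depth: float = 0.9
    h3k27ac_dip_sd: float = 100.0
    gwas: GwasDesign = field(default_factory=GwasDesign)
    seed: int = 0

    @property
    def cells(self) -> list[str]:
        return [f"cell{c + 1:02d}" for c in range(self.n_cells)]

    @property
    def n_neutral(self) -> int:
        return self.n_motifs - self.n_activators - self.n_repressors


@dataclass
class SyntheticDataset:
    """The generated corpus plus its truth tables."""

    config: SyntheticConfig
    genome: dict[str, str]
    segmentations: dict[str, list[tuple[GenomeInterval, tuple[str, ...]]]]
    peaks: dict[str, list[NarrowPeak]]
    enhancer_truth: pd.DataFrame  # cell, chrom, start, end, class
    motif_records: list[MemeMotifRecord] = field(default_factory=list)
    motif_roles: dict[str, str] = field(default_factory=dict)
    motif_to_tf: dict[str, str] = field(default_factory=dict)
    lam: pd.DataFrame | None = None  # motif, cell, compartment, rate
    site_truth: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    snp_table: pd.DataFrame | None = None
    ld_table: pd.DataFrame | None = None
    signal_tracks: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def pwms(self) -> dict[str, PWM]:
        return {r.name: PWM.from_record(r) for r in self.motif_records}

    def enhancer_set(self, cell: str) -> EnhancerSet:
        sub = self.enhancer_truth[self.enhancer_truth["cell"] == cell]
        return EnhancerSet(
            cell=cell,
            enhancers=[
                (GenomeInterval(r.chrom, int(r.start), int(r.end)), r.enhancer_class)
                for r in sub.itertuples(index=False)
            ],
        )

    def compartment_intervals(self, cell: str) -> dict[str, list[GenomeInterval]]:
        es = self.enhancer_set(cell)
        peak_ivs = [p.interval for p in self.peaks[cell]]
        out = {}
        for cls in ("SE", "TE"):
            ivs = es.intervals(cls)
            out[f"{cls}_DHS"] = intersect_intervals(ivs, peak_ivs)
            out[f"{cls}_nonDHS"] = subtract_intervals(ivs, peak_ivs)
        return out

    def compartment_sequences(self, cell: str) -> dict[str, CompartmentSequences]:
        out = {}
        for name, ivs in self.compartment_intervals(cell).items():
            out[name] = CompartmentSequences(
                cell=cell,
                compartment=name,
                intervals=ivs,
                sequences=[self.genome[iv.chrom][iv.start : iv.end] for iv in ivs],
            )
        return out

    def summits(self, cell: str, cls: str) -> list[tuple[str, int]]:
        """Summit positions of peaks whose summit lies in the given class."""
        es = self.enhancer_set(cell)
        ivs = es.intervals(cls)
        out = []
        for p in self.peaks[cell]:
            pos = p.summit
            if any(iv.chrom == p.interval.chrom and iv.contains(pos) for iv in ivs):
                out.append((p.interval.chrom, pos))
        return out


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_genome(config: SyntheticConfig, rng: np.random.Generator) -> dict[str, str]:
    return {
        chrom: bytes(_BASE_BYTES[rng.integers(0, 4, size=length)]).decode("ascii")
        for chrom, length in config.chrom_lengths.items()
    }


def generate_genome_and_annotation(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SyntheticDataset:
    """Generate the genome, per-cell segmentations, and DHS peaks.

    Enhancer runs of all cells are placed without overlap anywhere in the
    genome (cell-specific enhancer territories). Each run is emitted as two
    bookended enhancer-state segments ("EnhancerStrong" + "EnhancerWeak")
    when long enough, exercising the contiguity merge downstream; gaps are
    labeled "Quiescent". DHS peaks sit inside enhancers with summits near
    peak centers (+/- jitter).
    """
    rng = rng or np.random.default_rng(config.seed)
    genome = _random_genome(config, rng)
    chroms = list(config.chrom_lengths)
    units: list[tuple[str, str, int]] = []  # (cell, class, length)
    for cell in config.cells:
        for _ in range(config.n_se):
            units.append(
                (cell, "SE", int(rng.integers(config.se_length[0], config.se_length[1] + 1)))
            )
        for _ in range(config.n_te):
            units.append(
                (cell, "TE", int(rng.integers(config.te_length[0], config.te_length[1] + 1)))
            )
    need = sum(u[2] for u in units) + config.min_gap * (len(units) + len(chroms))
    capacity = sum(config.chrom_lengths.values())
    if need > capacity:
        raise ValueError(
            f"requested enhancers need ~{need} bp but genome has {capacity} bp"
        )
    order = rng.permutation(len(units))
    cursors = {c: 0 for c in chroms}
    extra = capacity - need
    # draw only a fraction of the slack as random gaps: exponential draws with
    # mean extra/len(units) would consume all of it on average, making
    # placement fail for about half the seeds
    mean_extra_gap = 0.6 * extra / max(len(units), 1)
    placements: list[tuple[str, str, GenomeInterval]] = []
    for k in order:
        cell, cls, length = units[k]
        placed = False
        start_chrom = int(rng.integers(len(chroms)))
        for j in range(len(chroms)):
            chrom = chroms[(start_chrom + j) % len(chroms)]
            gap = config.min_gap + int(rng.exponential(mean_extra_gap))
            pos = cursors[chrom] + gap
            if pos + length <= config.chrom_lengths[chrom] - config.min_gap:
                placements.append((cell, cls, GenomeInterval(chrom, pos, pos + length)))
                cursors[chrom] = pos + length
                placed = True
                break
            # retry with the minimal gap before falling through to next chrom
            pos = cursors[chrom] + config.min_gap
            if pos + length <= config.chrom_lengths[chrom] - config.min_gap:
                placements.append((cell, cls, GenomeInterval(chrom, pos, pos + length)))
                cursors[chrom] = pos + length
                placed = True
                break
        if not placed:
            raise ValueError("could not place all enhancers; genome too small")

    seg: dict[str, list[tuple[GenomeInterval, tuple[str, ...]]]] = {
        c: [] for c in config.cells
    }
    peaks: dict[str, list[NarrowPeak]] = {c: [] for c in config.cells}
    truth_rows = []
    for cell, cls, iv in placements:
        truth_rows.append(
            {"cell": cell, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "enhancer_class": cls}
        )
        if iv.length >= 200:
            split = iv.start + int(rng.integers(100, iv.length - 99))
            seg[cell].append((GenomeInterval(iv.chrom, iv.start, split), ("EnhancerStrong",)))
            seg[cell].append((GenomeInterval(iv.chrom, split, iv.end), ("EnhancerWeak",)))
        else:
            seg[cell].append((iv, ("EnhancerStrong",)))
        n_dhs = config.dhs_per_se if cls == "SE" else config.dhs_per_te
        lo, hi = config.se_dhs_length if cls == "SE" else config.te_dhs_length
        # spread peak centers evenly through the enhancer, then jitter
        centers = iv.start + (np.arange(n_dhs) + 0.5) / n_dhs * iv.length
        for c in centers:
            plen = int(rng.integers(lo, hi + 1))
            center = int(c) + int(rng.integers(-20, 21))
            start = max(iv.start, center - plen // 2)
            end = min(iv.end, start + plen)
            start = max(iv.start, end - plen)
            if end - start < 50:
                continue
            jitter = int(rng.integers(-config.summit_jitter, config.summit_jitter + 1))
            summit = int(np.clip((start + end) // 2 + jitter, start, end - 1))
            peaks[cell].append(
                NarrowPeak(
                    GenomeInterval(iv.chrom, start, end),
                    summit - start,
                    signal=float(rng.uniform(5, 50)),
                )
            )
    # fill gaps with a quiescent state so segmentations tile the genome
    for cell in config.cells:
        seg[cell].sort(key=lambda r: (r[0].chrom, r[0].start))
        filled: list[tuple[GenomeInterval, tuple[str, ...]]] = []
        cursors = {c: 0 for c in chroms}
        for iv, labels in seg[cell]:
            if iv.start > cursors[iv.chrom]:
                filled.append(
                    (GenomeInterval(iv.chrom, cursors[iv.chrom], iv.start), ("Quiescent",))
                )
            filled.append((iv, labels))
            cursors[iv.chrom] = iv.end
        for chrom in chroms:
            if cursors[chrom] < config.chrom_lengths[chrom]:
                filled.append(
                    (
                        GenomeInterval(chrom, cursors[chrom], config.chrom_lengths[chrom]),
                        ("Quiescent",),
                    )
                )
        seg[cell] = sorted(filled, key=lambda r: (r[0].chrom, r[0].start))
        peaks[cell].sort(key=lambda p: (p.interval.chrom, p.interval.start))

    return SyntheticDataset(
        config=config,
        genome=genome,
        segmentations=seg,
        peaks=peaks,
        enhancer_truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Motif library + planting
# ---------------------------------------------------------------------------

def generate_motif_library(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[MemeMotifRecord], dict[str, str], dict[str, str]]:
    """Random high-information PWMs with roles and TF gene names."""
    records = []
    roles = {}
    motif_to_tf = {}
    role_list = (
        ["activator"] * config.n_activators
        + ["repressor"] * config.n_repressors
        + ["neutral"] * config.n_neutral
    )
    for i, role in enumerate(role_list):
        width = int(rng.integers(config.motif_width[0], config.motif_width[1] + 1))
        consensus = rng.integers(0, 4, size=width)
        matrix = np.full((width, 4), (1 - config.consensus_prob) / 3)
        matrix[np.arange(width), consensus] = config.consensus_prob
        name = f"M{i + 1:02d}_{role[:3].upper()}"
        records.append(
            MemeMotifRecord(
                name=name, width=width, matrix=matrix, nsites=100,
                background=np.full(4, 0.25),
            )
        )
        roles[name] = role
        motif_to_tf[name] = f"TF{i + 1:02d}"
    return records, roles, motif_to_tf


def generate_planting_rates(
    config: SyntheticConfig,
    motif_roles: Mapping[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per (motif, cell, compartment) site rates.

    Each planted motif gets a cell profile: a random permutation of an evenly
    spaced weight ramp, so every motif has clearly distinct rates across
    cells. DHS compartments carry the full rate; non-DHS compartments a
    configurable fraction of it. Neutral motifs are never planted.
    """
    cells = config.cells
    lo, hi = config.lam_weight_range
    rows = []
    for motif, role in motif_roles.items():
        weights = np.linspace(lo, hi, len(cells))
        weights = weights[rng.permutation(len(cells))]
        for cell, wgt in zip(cells, weights):
            rate_dhs = 0.0 if role == "neutral" else config.lam_dhs_max * wgt
            rate_non = rate_dhs * config.lam_nondhs_factor
            for comp in COMPARTMENTS:
                rows.append(
                    {
                        "motif": motif,
                        "cell": cell,
                        "compartment": comp,
                        "rate": rate_dhs if comp.endswith("_DHS") else rate_non,
                        "weight": wgt if role != "neutral" else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def _sample_site(matrix: np.ndarray, rng: np.random.Generator) -> str:
    cum = np.cumsum(matrix, axis=1)
    idx = (rng.random(matrix.shape[0])[:, None] > cum).sum(axis=1)
    return "".join(BASES[i] for i in idx)


def plant_motifs(
    dataset: SyntheticDataset, rng: np.random.Generator | None = None
) -> None:
    """Mutate the genome in place, planting motif sites per compartment.

    Site counts per interval are Poisson(rate * length). In DHS compartments
    site positions concentrate around the containing peak's summit (truncated
    normal); in non-DHS compartments they are uniform. Sites never overlap
    each other within an interval: a rate above the packing limit (one site
    per motif width) is an error, and a small interval that saturates thins
    its Poisson draw to what fits. Fills ``dataset.site_truth``.
    """
    config = dataset.config
    rng = rng or np.random.default_rng(config.seed + 1)
    if dataset.lam is None:
        raise ValueError("generate planting rates before planting")
    editable = {c: bytearray(s, "ascii") for c, s in dataset.genome.items()}
    pwm_mat = {r.name: r.matrix for r in dataset.motif_records}
    widths = {r.name: r.width for r in dataset.motif_records}
    summit_by_peak: dict[str, list[tuple[GenomeInterval, int]]] = {}
    truth_rows = []
    for cell in config.cells:
        comp_ivs = dataset.compartment_intervals(cell)
        summits = {
            (p.interval.chrom, p.interval.start, p.interval.end): p.summit
            for p in dataset.peaks[cell]
        }
        lam_cell = dataset.lam[dataset.lam["cell"] == cell]
        for comp in COMPARTMENTS:
            ivs = comp_ivs[comp]
            lam_comp = lam_cell[lam_cell["compartment"] == comp]
            for iv in ivs:
                occupied: list[tuple[int, int]] = []
                # summit of the peak containing a DHS piece, for centering
                summit = None
                if comp.endswith("_DHS"):
                    for (chrom, ps, pe), s in summits.items():
                        if chrom == iv.chrom and ps < iv.end and pe > iv.start:
                            summit = s
                            break
                for row in lam_comp.itertuples(index=False):
                    w = widths[row.motif]
                    if iv.length < w or row.rate <= 0:
                        continue
                    if row.rate * w > 1.0:
                        raise ValueError(
                            f"rate {row.rate:.4g}/bp for {row.motif} (width {w}) "
                            "exceeds the non-overlapping packing limit 1/width"
                        )
                    n_sites = rng.poisson(row.rate * iv.length)
                    placed = 0
                    attempts = 0
                    # first pass concentrates near the summit; the fallback
                    # pass samples uniformly so a locally crowded summit
                    # neighborhood does not fail an interval with free space
                    max_attempts = 50 * max(n_sites, 1)
                    max_total = max_attempts + 200 * max(n_sites, 1)
                    while placed < n_sites and attempts < max_total:
                        attempts += 1
                        if summit is not None and attempts <= max_attempts:
                            pos = int(rng.normal(summit, config.dhs_site_sd)) - w // 2
                        else:
                            pos = iv.start + int(rng.integers(0, iv.length - w + 1))
                        if pos < iv.start or pos + w > iv.end:
                            continue
                        if any(pos < e and pos + w > s for s, e in occupied):
                            continue
                        site = _sample_site(pwm_mat[row.motif], rng)
                        strand = "+" if rng.random() < 0.5 else "-"
                        seq = site if strand == "+" else reverse_complement(site)
                        editable[iv.chrom][pos : pos + w] = seq.encode()
                        occupied.append((pos, pos + w))
                        truth_rows.append(
                            {
                                "cell": cell, "compartment": comp, "motif": row.motif,
                                "chrom": iv.chrom, "start": pos, "end": pos + w,
                                "strand": strand,
                            }
                        )
                        placed += 1
                    # a saturated small interval thins the Poisson draw; the
                    # packing-limit pre-check above rejects impossible rates
    dataset.genome = {c: b.decode("ascii") for c, b in editable.items()}
    dataset.site_truth = pd.DataFrame(
        truth_rows,
        columns=["cell", "compartment", "motif", "chrom", "start", "end", "strand"],
    )


def generate_expression(
    dataset: SyntheticDataset, rng: np.random.Generator | None = None
) -> None:
    """TF RPKM coupled to planting rates: activators track their motif's
    cell weight, repressors anti-track it, neutral TFs get low noise-only
    expression. RPKM floors at 0."""
    config = dataset.config
    rng = rng or np.random.default_rng(config.seed + 2)
    cells = config.cells
    lam = dataset.lam
    data = {}
    for motif, role in dataset.motif_roles.items():
        tf = dataset.motif_to_tf[motif]
        w = (
            lam[(lam["motif"] == motif) & (lam["compartment"] == "SE_DHS")]
            .set_index("cell")
            .loc[cells, "weight"]
            .to_numpy()
        )
        if not config.expression_coupled and role != "neutral":
            base = config.expression_scale * rng.uniform(0.0, 1.0, len(cells))
        elif role == "activator":
            base = config.expression_scale * w
        elif role == "repressor":
            base = config.expression_scale * (w.max() - w)
        else:
            base = np.full(len(cells), 0.5)
        vals = np.maximum(base + rng.normal(0, config.expression_noise_sd, len(cells)), 0.0)
        data[tf] = vals
    dataset.expression = pd.DataFrame(data, index=cells).T
    dataset.expression.columns = cells


# ---------------------------------------------------------------------------
# GWAS catalog
# ---------------------------------------------------------------------------

def generate_gwas(
    dataset: SyntheticDataset,
    disease_cell: str | None = None,
    rng: np.random.Generator | None = None,
) -> None:
    """Synthetic SNP and LD tables.

    Disease-trait leads fall inside planted SE non-DHS motif sites of the
    disease cell with the configured fraction (uniform otherwise); control
    and background traits are uniform. Leads get 0..max_proxies proxies
    within the proxy window with r^2 drawn across the 0.8 threshold, and
    association p-values such that ``frac_genomewide`` pass 5e-8.
    """
    config = dataset.config
    g = config.gwas
    rng = rng or np.random.default_rng(config.seed + 3)
    disease_cell = disease_cell or config.cells[0]
    if dataset.site_truth is None:
        raise ValueError("plant motifs before generating GWAS data")
    st = dataset.site_truth
    feature_sites = st[
        (st["cell"] == disease_cell) & (st["compartment"] == "SE_nonDHS")
    ]
    chroms = list(config.chrom_lengths)
    chrom_len = config.chrom_lengths

    def uniform_pos() -> tuple[str, int]:
        chrom = chroms[int(rng.integers(len(chroms)))]
        return chrom, int(rng.integers(0, chrom_len[chrom]))

    def feature_pos() -> tuple[str, int]:
        row = feature_sites.iloc[int(rng.integers(len(feature_sites)))]
        return str(row["chrom"]), int(rng.integers(row["start"], row["end"]))

    traits = (
        [("disease", g.n_disease, g.disease_feature_fraction)]
        + [("control", g.n_control, g.control_feature_fraction)]
        + [
            (f"background{k + 1:02d}", g.loci_per_background, 0.0)
            for k in range(g.n_background_traits)
        ]
    )
    snp_rows = []
    ld_rows = []
    counter = 0
    for trait, n_loci, fraction in traits:
        for _ in range(n_loci):
            counter += 1
            rsid = f"rs{counter:06d}"
            if rng.random() < fraction and len(feature_sites):
                chrom, pos = feature_pos()
            else:
                chrom, pos = uniform_pos()
            if rng.random() < g.frac_genomewide:
                pval = 10 ** rng.uniform(-12, -7.31)  # below 5e-8
            else:
                pval = 10 ** rng.uniform(-7, -5)
            snp_rows.append(
                {"rsid": rsid, "chrom": chrom, "pos": pos, "trait": trait,
                 "pvalue": pval}
            )
            for j in range(int(rng.integers(0, g.max_proxies + 1))):
                off = int(rng.integers(-g.proxy_window, g.proxy_window + 1))
                ppos = int(np.clip(pos + off, 0, chrom_len[chrom] - 1))
                ld_rows.append(
                    {
                        "lead_rsid": rsid,
                        "proxy_rsid": f"{rsid}_p{j + 1}",
                        "chrom": chrom,
                        "pos": ppos,
                        "r2": float(rng.uniform(*g.r2_range)),
                    }
                )
    dataset.snp_table = pd.DataFrame(snp_rows)
    dataset.ld_table = pd.DataFrame(
        ld_rows, columns=["lead_rsid", "proxy_rsid", "chrom", "pos", "r2"]
    )


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

def generate_signal_tracks(
    dataset: SyntheticDataset,
    cell: str | None = None,
    noise: bool = False,
    rng: np.random.Generator | None = None,
) -> None:
    """DNase and H3K27ac per-bp tracks for one cell.

    DNase: one Gaussian bump per summit. H3K27ac: a broad bump spanning the
    enhancer minus a deep narrow depression at the summit, so the profile dips
    at the summit while flanks stay high; SE peaks get
    ``h3k27ac_se_te_ratio`` times the TE amplitude. Optional Poisson noise
    discretizes the signal.
    """
    config = dataset.config
    rng = rng or np.random.default_rng(config.seed + 4)
    cell = cell or config.cells[0]
    tracks = {
        assay: {c: np.zeros(n) for c, n in config.chrom_lengths.items()}
        for assay in ("dnase", "h3k27ac")
    }
    es = dataset.enhancer_set(cell)
    se_idx = {(iv.chrom, iv.start, iv.end) for iv in es.intervals("SE")}
    half = 2400
    x = np.arange(-half, half + 1, dtype=float)
    dnase_shape = config.dnase_amplitude * np.exp(-(x**2) / (2 * config.dnase_sd**2))
    k27_shape = np.exp(-(x**2) / (2 * config.h3k27ac_broad_sd**2)) - (
        config.h3k27ac_dip_depth * np.exp(-(x**2) / (2 * config.h3k27ac_dip_sd**2))
    )
    for p in dataset.peaks[cell]:
        chrom = p.interval.chrom
        pos = p.summit
        in_se = any(
            c == chrom and s <= pos < e for c, s, e in se_idx
        )
        amp = config.h3k27ac_amplitude * (
            config.h3k27ac_se_te_ratio if in_se else 1.0
        )
        lo = max(pos - half, 0)
        hi = min(pos + half + 1, config.chrom_lengths[chrom])
        sl = slice(lo - (pos - half), len(x) - ((pos + half + 1) - hi))
        tracks["dnase"][chrom][lo:hi] += dnase_shape[sl]
        tracks["h3k27ac"][chrom][lo:hi] += amp * k27_shape[sl]
    if noise:
        for assay in tracks:
            for chrom in tracks[assay]:
                tracks[assay][chrom] = rng.poisson(tracks[assay][chrom]).astype(float)
    dataset.signal_tracks = tracks


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def generate_dataset(
    config: SyntheticConfig | None = None,
    with_gwas: bool = True,
    with_signal: bool = False,
) -> SyntheticDataset:
    """Run every generator stage with sub-seeds derived from ``config.seed``."""
    config = config or SyntheticConfig()
    ds = generate_genome_and_annotation(config)
    rng = np.random.default_rng(config.seed + 10)
    ds.motif_records, ds.motif_roles, ds.motif_to_tf = generate_motif_library(
        config, rng
    )
    ds.lam = generate_planting_rates(config, ds.motif_roles, rng)
    plant_motifs(ds)
    generate_expression(ds)
    if with_gwas:
        generate_gwas(ds)
    if with_signal:
        generate_signal_tracks(ds)
    return ds
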