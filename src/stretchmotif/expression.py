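"""Linking motif enrichment to TF expression and assigning cell-identity
motifs.

The connective tissue of the analysis: per-motif Spearman correlations of
across-cell enrichment with TF expression (with a shuffled-cell-label null),
a central-enrichment statistic for summit-centered sequences, the pruning
filters and exemplar-based agglomerative clustering used for enrichment
heatmaps, and the conjunctive filter cascade that assigns activator motifs
to cell types.

Default thresholds: expression > 2 RPKM, central-enrichment natural-log
adjusted p < -50, correlation rho > 0, heatmap filters log2 enrichment > 1.5
(max) and > 0.75 (range). All are strict inequalities and all are
configurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import PWM, encode_sequence, window_scores

ENRICHMENT_COLUMNS = ["motif", "cell", "compartment", "fold_enrichment"]

# printed filter defaults
MIN_RPKM = 2.0
MAX_LOG_ADJ_P = -50.0
MIN_RHO = 0.0
HEATMAP_MIN_LOG2 = 1.5
HEATMAP_MIN_RANGE = 0.75


def build_enrichment_table(
    records: Sequence[tuple[str, str, str, float]]
) -> pd.DataFrame:
    """Long-format enrichment table with a log2 column.

    ``records`` rows are (motif, cell, compartment, fold_enrichment).
    """
    df = pd.DataFrame(records, columns=ENRICHMENT_COLUMNS)
    if (df["fold_enrichment"] < 0).any():
        raise ValueError("fold enrichment must be >= 0")
    with np.errstate(divide="ignore"):
        df["log2_enrichment"] = np.log2(df["fold_enrichment"])
    return df


def pivot_enrichment(
    enrichment: pd.DataFrame, compartment: str, value: str = "fold_enrichment"
) -> pd.DataFrame:
    """Motif x cell matrix of one compartment's enrichment values."""
    sub = enrichment[enrichment["compartment"] == compartment]
    return sub.pivot(index="motif", columns="cell", values=value)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks; NaN for constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def expression_enrichment_correlation(
    enrichment: pd.DataFrame,
    expression: pd.DataFrame,
    motif_to_tf: Mapping[str, str],
    compartment: str,
) -> pd.Series:
    """Per-motif Spearman rho between across-cell enrichment in one
    compartment and the motif's TF expression across the same cells.

    Motifs without a TF mapping, without an expression row, or with a
    degenerate (constant) vector get NaN.
    """
    mat = pivot_enrichment(enrichment, compartment)
    cells = [c for c in mat.columns if c in expression.columns]
    if len(cells) < 3:
        raise ValueError("need >=3 cells with both enrichment and expression")
    out = {}
    for motif in mat.index:
        tf = motif_to_tf.get(motif)
        if tf is None or tf not in expression.index:
            out[motif] = float("nan")
            continue
        out[motif] = _spearman(
            mat.loc[motif, cells].to_numpy(), expression.loc[tf, cells].to_numpy()
        )
    return pd.Series(out, name=f"rho_{compartment}")


def shuffled_cell_null(
    enrichment: pd.DataFrame,
    expression: pd.DataFrame,
    motif_to_tf: Mapping[str, str],
    compartment: str,
    n_perm: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.Series, np.ndarray, float]:
    """Observed per-motif rho, a shuffled-cell-label null, and a rank-sum p.

    The null recomputes each motif's correlation after permuting the cell
    labels of its expression vector (``n_perm`` permutations per motif,
    pooled). Returns (observed, null_rhos, two_sided_ranksum_p).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = pivot_enrichment(enrichment, compartment)
    cells = [c for c in mat.columns if c in expression.columns]
    observed = expression_enrichment_correlation(
        enrichment, expression, motif_to_tf, compartment
    )
    null: list[float] = []
    for motif in mat.index:
        tf = motif_to_tf.get(motif)
        if tf is None or tf not in expression.index:
            continue
        e = mat.loc[motif, cells].to_numpy(dtype=float)
        x = expression.loc[tf, cells].to_numpy(dtype=float)
        for _ in range(n_perm):
            null.append(_spearman(e, x[rng.permutation(len(x))]))
    null_arr = np.asarray([v for v in null if np.isfinite(v)])
    obs_arr = observed.dropna().to_numpy()
    if len(obs_arr) == 0 or len(null_arr) == 0:
        return observed, null_arr, float("nan")
    p = float(stats.ranksums(obs_arr, null_arr).pvalue)
    return observed, null_arr, p


def cross_region_correlation(
    enrichment: pd.DataFrame,
    region_a: str,
    region_b: str,
    n_perm: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.Series, np.ndarray, float]:
    """Per-motif rho between across-cell enrichments in two compartments,
    with the same shuffled-cell null machinery.

    Returns (observed rho per motif, pooled null rhos, rank-sum p).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = pivot_enrichment(enrichment, region_a)
    b = pivot_enrichment(enrichment, region_b)
    cells = [c for c in a.columns if c in b.columns]
    if len(cells) < 3:
        raise ValueError("need >=3 cells present in both compartments")
    motifs = a.index.intersection(b.index)
    observed = pd.Series(
        {
            m: _spearman(a.loc[m, cells].to_numpy(), b.loc[m, cells].to_numpy())
            for m in motifs
        },
        name=f"rho_{region_a}_vs_{region_b}",
    )
    null: list[float] = []
    for m in motifs:
        va = a.loc[m, cells].to_numpy(dtype=float)
        vb = b.loc[m, cells].to_numpy(dtype=float)
        for _ in range(n_perm):
            null.append(_spearman(va, vb[rng.permutation(len(vb))]))
    null_arr = np.asarray([v for v in null if np.isfinite(v)])
    obs_arr = observed.dropna().to_numpy()
    if len(obs_arr) == 0 or len(null_arr) == 0:
        return observed, null_arr, float("nan")
    p = float(stats.ranksums(obs_arr, null_arr).pvalue)
    return observed, null_arr, p


# ---------------------------------------------------------------------------
# Central enrichment
# ---------------------------------------------------------------------------

@dataclass
class CentralEnrichmentResult:
    """Concentration of best motif sites near sequence centers.

    ``log_adjusted_p`` is the natural log of the best binomial upper-tail
    probability over candidate central windows, Bonferroni-multiplied by the
    number of windows tested. More negative = more centrally concentrated.
    """

    motif: str
    n_central: int
    n_total: int
    best_half_width: int
    log_adjusted_p: float


def central_enrichment(
    pwm: PWM,
    sequences: Sequence[str],
    score_floor_bits: float = 5.0,
) -> CentralEnrichmentResult:
    """Binomial central-enrichment of a motif in fixed-length sequences.

    For every sequence the best-scoring window at or above the score floor
    (both strands; ties resolved toward the center, then leftmost, then the
    plus strand) contributes one best site. For each candidate half-width h,
    the number of best-site starts within h of the central start position is
    compared to a Binomial(n_total, p0) with p0 = the fraction of possible
    start positions within the window; the minimum upper-tail probability is
    Bonferroni-corrected by the number of half-widths tested and reported as
    a natural log.
    """
    seqs = list(sequences)
    if not seqs:
        return CentralEnrichmentResult(pwm.name, 0, 0, 0, 0.0)
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("central_enrichment requires equal-length sequences")
    w = pwm.width
    n_positions = length - w + 1
    if n_positions <= 0:
        return CentralEnrichmentResult(pwm.name, 0, 0, 0, 0.0)
    center = (n_positions - 1) / 2.0
    best_starts: list[int] = []
    for s in seqs:
        enc = encode_sequence(s)
        fwd = window_scores(pwm, enc, "+")
        rev = window_scores(pwm, enc, "-")
        both = np.maximum(fwd, rev)
        top = both.max()
        if top < score_floor_bits:
            continue
        cand = np.nonzero(both == top)[0]
        # ties: closest to the center, then leftmost
        dist = np.abs(cand - center)
        best_starts.append(int(cand[np.lexsort((cand, dist))[0]]))
    n_total = len(best_starts)
    if n_total == 0:
        return CentralEnrichmentResult(pwm.name, 0, 0, 0, 0.0)
    starts = np.asarray(best_starts)
    dists = np.abs(starts - center)
    max_h = int(np.ceil(center))
    hs = np.arange(0, max_h + 1)
    # positions within half-width h of the center, and how many exist
    all_pos_dist = np.abs(np.arange(n_positions) - center)
    n_in_window = np.array([(all_pos_dist <= h).sum() for h in hs])
    p0 = n_in_window / n_positions
    n_central = np.array([(dists <= h).sum() for h in hs])
    with np.errstate(divide="ignore"):
        log_p = stats.binom.logsf(n_central - 1, n_total, p0)
    best = int(np.argmin(log_p))
    log_adj = float(log_p[best] + np.log(len(hs)))
    return CentralEnrichmentResult(
        motif=pwm.name,
        n_central=int(n_central[best]),
        n_total=n_total,
        best_half_width=int(hs[best]),
        log_adjusted_p=min(log_adj, 0.0),
    )


# ---------------------------------------------------------------------------
# Heatmap pruning and clustering
# ---------------------------------------------------------------------------

def prune_for_heatmap(
    enrichment: pd.DataFrame,
    expression: pd.DataFrame,
    motif_to_tf: Mapping[str, str],
    correlations: pd.Series,
    compartment: str = "SE_DHS",
    min_log2: float = HEATMAP_MIN_LOG2,
    min_range: float = HEATMAP_MIN_RANGE,
    min_rpkm: float = MIN_RPKM,
    min_rho: float = MIN_RHO,
) -> list[str]:
    """Motifs that are highly and differentially enriched, expressed, and
    positively correlated with their TF's expression.

    All comparisons are strict: max log2 enrichment > ``min_log2``, log2
    range > ``min_range``, max TF RPKM > ``min_rpkm``, rho > ``min_rho``.
    Motifs lacking a TF mapping or expression row are excluded.
    """
    import warnings

    log2 = pivot_enrichment(enrichment, compartment, value="log2_enrichment")
    kept: list[str] = []
    for motif in log2.index:
        tf = motif_to_tf.get(motif)
        if tf is None or tf not in expression.index:
            warnings.warn(f"motif {motif} has no TF mapping/expression; excluded",
                          stacklevel=2)
            continue
        row = log2.loc[motif].to_numpy(dtype=float)
        if not (row.max() > min_log2 and (row.max() - row.min()) > min_range):
            continue
        if not expression.loc[tf].max() > min_rpkm:
            continue
        rho = correlations.get(motif, float("nan"))
        if not (np.isfinite(rho) and rho > min_rho):
            continue
        kept.append(motif)
    return kept


@dataclass
class MotifClustering:
    """Result of exemplar-based agglomerative clustering."""

    order: list[str]
    merges: list[tuple[frozenset, frozenset]] = field(default_factory=list)

    def cut(self, k: int) -> dict[str, int]:
        """Cluster labels after stopping the merge sequence at k clusters."""
        current: list[set[str]] = [{m} for m in self.order]
        for a, b in self.merges:
            if len(current) <= k:
                break
            sa = next(c for c in current if set(a) <= c)
            sb = next(c for c in current if set(b) <= c)
            current.remove(sa)
            current.remove(sb)
            current.append(sa | sb)
        out: dict[str, int] = {}
        for i, c in enumerate(sorted(current, key=lambda c: min(c))):
            for m in c:
                out[m] = i
        return out


def cluster_motifs(log2_rows: pd.DataFrame) -> MotifClustering:
    """Exemplar-based agglomerative clustering of log2-enrichment vectors.

    Similarity between motifs is the negative squared Euclidean distance.
    At each step the pair of clusters whose merged cluster has the best
    exemplar (the member maximizing summed similarity to the merged members)
    is joined; ties break toward the lexicographically smallest motif-name
    pair. The returned leaf order is the heatmap row order.
    """
    names = list(log2_rows.index)
    if len(names) == 0:
        raise ValueError("no motifs to cluster")
    if len(names) == 1:
        return MotifClustering(order=names)
    X = log2_rows.to_numpy(dtype=float)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    sim = -d2
    idx = {m: i for i, m in enumerate(names)}

    def merged_score(members: tuple[str, ...]) -> float:
        rows = [idx[m] for m in members]
        sub = sim[np.ix_(rows, rows)]
        return float(sub.sum(axis=0).max())

    clusters: list[tuple[str, ...]] = [(m,) for m in sorted(names)]
    merges: list[tuple[frozenset, frozenset]] = []
    order_map: dict[tuple[str, ...], list[str]] = {c: list(c) for c in clusters}
    while len(clusters) > 1:
        best_pair = None
        best_score = -np.inf
        for a, b in itertools.combinations(sorted(clusters), 2):
            s = merged_score(a + b)
            if s > best_score:
                best_score = s
                best_pair = (a, b)
        a, b = best_pair
        merges.append((frozenset(a), frozenset(b)))
        clusters.remove(a)
        clusters.remove(b)
        merged = tuple(sorted(a + b))
        order_map[merged] = order_map.pop(a) + order_map.pop(b)
        clusters.append(merged)
    final_order = order_map[clusters[0]]
    return MotifClustering(order=final_order, merges=merges)


# ---------------------------------------------------------------------------
# Cell-identity motif assignment
# ---------------------------------------------------------------------------

@dataclass
class CellMotifSet:
    """Motifs assigned to one cell type, best central enrichment first."""

    cell: str
    motifs: list[str]


def assign_cell_motifs(
    enrichment: pd.DataFrame,
    expression: pd.DataFrame,
    motif_to_tf: Mapping[str, str],
    correlations: pd.Series,
    central_results: Mapping[str, CentralEnrichmentResult],
    cell: str,
    min_rpkm: float = MIN_RPKM,
    max_log_adjusted_p: float = MAX_LOG_ADJ_P,
    min_rho: float = MIN_RHO,
) -> CellMotifSet:
    """Conjunctive filter cascade assigning activator motifs to a cell type.

    A motif passes iff its TF is expressed in the cell (> min_rpkm RPKM), its
    central enrichment in the cell's summit-centered SE DHS sequences is
    strong (log adjusted p < max_log_adjusted_p), and its SE DHS enrichment
    correlates positively with TF expression across cells (rho > min_rho).
    Among motifs sharing a TF, only the one with the lowest log adjusted p is
    retained. Filters commute: any application order yields the same set.
    """
    mat = pivot_enrichment(enrichment, "SE_DHS")
    passed: list[tuple[str, str, float]] = []
    for motif in mat.index:
        tf = motif_to_tf.get(motif)
        if tf is None or tf not in expression.index or cell not in expression.columns:
            continue
        if not expression.loc[tf, cell] > min_rpkm:
            continue
        res = central_results.get(motif)
        if res is None or not res.log_adjusted_p < max_log_adjusted_p:
            continue
        rho = correlations.get(motif, float("nan"))
        if not (np.isfinite(rho) and rho > min_rho):
            continue
        passed.append((motif, tf, res.log_adjusted_p))
    best_by_tf: dict[str, tuple[str, float]] = {}
    for motif, tf, logp in passed:
        if tf not in best_by_tf or logp < best_by_tf[tf][1]:
            best_by_tf[tf] = (motif, logp)
    motifs = sorted(best_by_tf.values(), key=lambda t: t[1])
    return CellMotifSet(cell=cell, motifs=[m for m, _ in motifs])
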