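"""Co-occurrence network construction from an ASV table.

Edges connect taxa whose Spearman rank correlation across samples clears a
magnitude threshold (default |rho| > 0.8) with a Bonferroni-corrected p-value
below alpha (default 0.05).  The Bonferroni factor m counts only testable
pairs — pairs involving a zero-variance taxon are undefined and excluded.
Isolated taxa are dropped from the node list, so node counts reflect
connected taxa only.

Power note: with m in the thousands, the joint |rho| > 0.8 + Bonferroni gate
only admits pairs whose observed correlation is extreme for the sample size —
at n = 15 samples roughly |rho| ≳ 0.87.  Small-replicate designs (n = 4–6)
cannot produce any edge under this gate; choose replication accordingly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import AsvTable, ValidationError, logger


def filter_taxa(
    table: AsvTable,
    min_prevalence: float = 0.5,
    min_mean_relabund: float = 1e-4,
) -> AsvTable:
    """Keep taxa present in at least a fraction of samples and above a mean
    relative-abundance floor."""
    if not (0.0 <= min_prevalence <= 1.0):
        raise ValidationError("min_prevalence must be in [0, 1]")
    if min_mean_relabund < 0:
        raise ValidationError("min_mean_relabund must be >= 0")
    counts = table.counts
    prevalence = (counts > 0).mean(axis=1)
    mean_rel = table.relative_abundance().mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_rel >= min_mean_relabund)
    if not keep.any():
        raise ValidationError(
            f"filter removed all taxa ({table.n_taxa} in, 0 out; "
            f"min_prevalence={min_prevalence}, min_mean_relabund={min_mean_relabund})"
        )
    return AsvTable(counts.loc[keep].copy())


@dataclass
class CorrelationResult:
    """Pairwise Spearman correlations with raw and Bonferroni-adjusted p."""

    rho: pd.DataFrame
    p: pd.DataFrame
    p_adjusted: pd.DataFrame
    m: int  # number of testable pairs

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.rho.index)


def _spearman_p_t(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation with n-2 df."""
    r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def _spearman_p_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all permutations of one vector."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        return 0.0 if denom == 0 else float((a * b).sum() / denom)

    obs = abs(corr(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(ry))):
        total += 1
        if abs(corr(rx, ry[list(perm)])) >= obs - 1e-12:
            count += 1
    return count / total


def spearman_matrix(table: AsvTable, p_method: str = "auto") -> CorrelationResult:
    """All-pairs Spearman correlation on a taxa × samples table.

    ``p_method``: ``"t"`` (t approximation, n−2 df), ``"exact"`` (full
    permutation enumeration, only feasible for few samples) or ``"auto"``
    (exact for n ≤ 7, t otherwise).  Zero-variance taxa yield undefined
    correlations: their pairs get rho = NaN, p = 1 and are excluded from the
    Bonferroni factor m.
    """
    n = table.n_samples
    t_count = table.n_taxa
    if n < 4:
        raise ValidationError("spearman_matrix needs >= 4 samples")
    if t_count < 2:
        raise ValidationError("spearman_matrix needs >= 2 taxa")
    x = table.counts.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "spearman_matrix: %d constant taxa; their pairs are untestable", int(constant.sum())
        )
    z = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((z**2).sum(axis=1))
    denom[denom == 0] = 1.0
    zn = z / denom[:, None]
    rho = zn @ zn.T
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))

    if p_method not in ("auto", "t", "exact"):
        raise ValidationError(f"unknown p_method {p_method!r}")
    use_exact = p_method == "exact" or (p_method == "auto" and n <= 7)
    if use_exact and n > 9:
        raise ValidationError("exact Spearman p only supported for n <= 9 samples")

    p = np.ones((t_count, t_count))
    if use_exact:
        for i in range(t_count):
            for j in range(i + 1, t_count):
                if constant[i] or constant[j]:
                    continue
                p[i, j] = p[j, i] = _spearman_p_exact(x[i], x[j])
    else:
        p = _spearman_p_t(np.nan_to_num(rho, nan=0.0), n)
    np.fill_diagonal(p, 0.0)
    p[constant, :] = 1.0
    p[:, constant] = 1.0

    testable = ~constant
    k = int(testable.sum())
    m = k * (k - 1) // 2
    p_adj = np.minimum(1.0, p * m)
    np.fill_diagonal(p_adj, 0.0)

    ids = table.taxon_ids
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        p=pd.DataFrame(p, index=ids, columns=ids),
        p_adjusted=pd.DataFrame(p_adj, index=ids, columns=ids),
        m=m,
    )


@dataclass
class CoOccurrenceNetwork:
    """Undirected signed graph over taxa; edges carry ``rho`` and ``sign``."""

    graph: nx.Graph
    group: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "rho": a["rho"], "sign": a["sign"]}
            for u, v, a in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "sign"])


def build_network(
    corr: CorrelationResult,
    rho_threshold: float = 0.8,
    alpha: float = 0.05,
    group: str | None = None,
) -> CoOccurrenceNetwork:
    """Threshold a correlation matrix into a co-occurrence network.

    An edge requires |rho| > rho_threshold AND Bonferroni-adjusted p < alpha.
    Isolated taxa are dropped, so the node set is the connected taxa only.
    Output is invariant to the input taxon order (nodes added sorted).
    """
    if not (0.0 <= rho_threshold <= 1.0):
        raise ValidationError("rho_threshold must be in [0, 1]")
    if not (0.0 < alpha <= 1.0):
        raise ValidationError("alpha must be in (0, 1]")
    ids = corr.taxon_ids
    rho = corr.rho.to_numpy()
    p_adj = corr.p_adjusted.to_numpy()
    g = nx.Graph()
    order = np.argsort(np.array(ids, dtype=object))
    for ii in range(len(ids)):
        for jj in range(ii + 1, len(ids)):
            i, j = order[ii], order[jj]
            r = rho[i, j]
            if np.isnan(r):
                continue
            if abs(r) > rho_threshold and p_adj[i, j] < alpha:
                g.add_edge(ids[i], ids[j], rho=float(r), sign="+" if r > 0 else "-")
    return CoOccurrenceNetwork(graph=g, group=group)


def group_networks(
    table: AsvTable,
    metadata: pd.DataFrame,
    rho_threshold: float = 0.8,
    alpha: float = 0.05,
    min_prevalence: float = 0.5,
    min_mean_relabund: float = 1e-4,
    p_method: str = "t",
) -> dict[str, CoOccurrenceNetwork]:
    """Per-treatment networks: filter, correlate and threshold each group."""
    from .containers import groups_of, validate_metadata

    validate_metadata(metadata, table)
    nets = {}
    for gname, samples in groups_of(metadata).items():
        sub = filter_taxa(table.subset_samples(samples), min_prevalence, min_mean_relabund)
        corr = spearman_matrix(sub, p_method=p_method)
        nets[gname] = build_network(corr, rho_threshold, alpha, group=gname)
    return nets
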