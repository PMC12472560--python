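"""Community cohesion, the negative:positive cohesion ratio, and robustness
to node removal.

Cohesion quantifies, per sample, how strongly the community's taxa co-vary
with everything else.  Each taxon's *connectedness* is its average
null-corrected correlation with the other taxa, split into a positive and a
negative part; a sample's positive (negative) cohesion is the
abundance-weighted sum of positive (negative) connectedness.  The null
correction subtracts the expected correlation under independent per-taxon
shuffles of the abundance vectors, so purely compositional or
abundance-driven correlation is removed.  The per-sample stability (often
called complexity) ratio is |negative cohesion| / positive cohesion: values
above 1 indicate a competition-dominated community.

Robustness is measured by deleting nodes — uniformly at random or in
descending degree order ("targeted") — and recording the fraction of
surviving nodes in the largest connected component (or, optionally, the
natural connectivity of the pruned graph).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import AsvTable, ValidationError, groups_of, logger, validate_metadata
from .network import CoOccurrenceNetwork


@dataclass
class CohesionProfile:
    """Per-taxon connectedness and per-sample cohesion components."""

    connectedness_pos: pd.Series  # per taxon, >= 0
    connectedness_neg: pd.Series  # per taxon, <= 0
    cohesion_pos: pd.Series  # per sample, >= 0
    cohesion_neg: pd.Series  # per sample, <= 0
    stability_ratio: pd.Series  # per sample, |neg|/pos (NaN where pos == 0)
    null_iterations: int
    seed: int


def _corr_matrix(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns; zero-variance columns -> 0."""
    z = x - x.mean(axis=0, keepdims=True)
    sd = z.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    zn = z / sd_safe
    r = zn.T @ zn / x.shape[0]
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


def cohesion(
    table: AsvTable,
    null_iterations: int = 200,
    corr: str = "pearson",
    seed: int = 0,
) -> CohesionProfile:
    """Null-model-corrected cohesion of every sample in a table.

    The observed taxon–taxon correlation matrix (Pearson on relative
    abundances by default; ``corr="spearman"`` ranks first) is corrected by
    subtracting its expectation under ``null_iterations`` randomisations in
    which each taxon's abundance vector is independently permuted across
    samples.  Connectedness is the mean of the positive (resp. negative)
    corrected correlations per taxon; cohesion weights connectedness by
    relative abundance.
    """
    if table.n_samples < 4:
        raise ValidationError("cohesion needs >= 4 samples")
    if corr not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation {corr!r}")
    if null_iterations < 1:
        raise ValidationError("null_iterations must be >= 1")
    rel = table.relative_abundance().to_numpy().T  # samples x taxa
    n, t = rel.shape
    x = np.apply_along_axis(stats.rankdata, 0, rel) if corr == "spearman" else rel

    r_obs = _corr_matrix(x)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null_sum = np.zeros((t, t))
    for _ in range(null_iterations):
        perm = np.empty_like(x)
        for j in range(t):
            perm[:, j] = x[rng.permutation(n), j]
        null_sum += _corr_matrix(perm)
    r_null = null_sum / null_iterations
    r_corr = r_obs - r_null
    np.fill_diagonal(r_corr, 0.0)

    pos = np.where(r_corr > 0, r_corr, 0.0)
    neg = np.where(r_corr < 0, r_corr, 0.0)
    npos = (r_corr > 0).sum(axis=1)
    nneg = (r_corr < 0).sum(axis=1)
    conn_pos = np.where(npos > 0, pos.sum(axis=1) / np.maximum(npos, 1), 0.0)
    conn_neg = np.where(nneg > 0, neg.sum(axis=1) / np.maximum(nneg, 1), 0.0)

    coh_pos = rel @ conn_pos
    coh_neg = rel @ conn_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(coh_pos > 0, np.abs(coh_neg) / coh_pos, np.nan)
    if (coh_pos <= 0).any():
        logger.warning("cohesion: %d sample(s) with non-positive cohesion; ratio undefined",
                       int((coh_pos <= 0).sum()))

    taxa, samples = table.taxon_ids, table.sample_ids
    return CohesionProfile(
        connectedness_pos=pd.Series(conn_pos, index=taxa),
        connectedness_neg=pd.Series(conn_neg, index=taxa),
        cohesion_pos=pd.Series(coh_pos, index=samples),
        cohesion_neg=pd.Series(coh_neg, index=samples),
        stability_ratio=pd.Series(ratio, index=samples),
        null_iterations=null_iterations,
        seed=seed,
    )


def stability_ratio(profile: CohesionProfile) -> pd.Series:
    """|negative cohesion| / positive cohesion per sample (NaN where the
    positive part is non-positive)."""
    pos = profile.cohesion_pos.to_numpy()
    neg = profile.cohesion_neg.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pos > 0, np.abs(neg) / pos, np.nan)
    return pd.Series(ratio, index=profile.cohesion_pos.index)


@dataclass
class RobustnessResult:
    mode: str  # "random" | "targeted"
    removal_fraction: float
    replicates: int
    metric: str
    values: np.ndarray
    group: str | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def _giant_fraction(g: nx.Graph) -> float:
    if g.number_of_nodes() == 0:
        return 0.0
    giant = max((len(c) for c in nx.connected_components(g)), default=0)
    return giant / g.number_of_nodes()


def _natural_connectivity(g: nx.Graph) -> float:
    if g.number_of_nodes() == 0:
        return 0.0
    lam = np.linalg.eigvalsh(nx.to_numpy_array(g))
    # log-mean-exp for numerical safety
    m = lam.max()
    return float(m + np.log(np.exp(lam - m).mean()))


def robustness(
    net: CoOccurrenceNetwork,
    mode: str = "random",
    removal_fraction: float = 0.5,
    replicates: int = 100,
    metric: str = "giant_component_fraction",
    seed: int = 0,
) -> RobustnessResult:
    """Connectivity left after deleting a fraction of nodes.

    ``random`` mode removes ⌊fraction·N⌋ nodes uniformly without replacement,
    independently per replicate; ``targeted`` removes in descending degree
    order (ties broken by node id) and is deterministic (one replicate).
    """
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValidationError("robustness: empty network")
    if not (0.0 <= removal_fraction < 1.0):
        raise ValidationError("removal_fraction must be in [0, 1)")
    if metric == "giant_component_fraction":
        measure = _giant_fraction
    elif metric == "natural_connectivity":
        measure = _natural_connectivity
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    k = int(np.floor(removal_fraction * n))
    nodes = sorted(g.nodes())
    if mode == "targeted":
        order = sorted(nodes, key=lambda v: (-g.degree(v), v))
        pruned = g.copy()
        pruned.remove_nodes_from(order[:k])
        values = np.array([measure(pruned)])
        replicates = 1
    elif mode == "random":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        values = np.empty(replicates)
        for r in range(replicates):
            drop = rng.choice(len(nodes), size=k, replace=False)
            pruned = g.copy()
            pruned.remove_nodes_from([nodes[i] for i in drop])
            values[r] = measure(pruned)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return RobustnessResult(
        mode=mode,
        removal_fraction=removal_fraction,
        replicates=replicates,
        metric=metric,
        values=values,
        group=net.group,
    )


def compare_stability(
    values_by_group: dict[str, np.ndarray | pd.Series],
    control: str = "CK",
) -> pd.DataFrame:
    """Pairwise rank-sum tests of per-sample stability ratios (or robustness
    distributions) between each group and the control."""
    from .guilds import rank_sum_test
    from .pipeline import significance_stars

    if len(values_by_group) < 2:
        raise ValidationError("compare_stability needs >= 2 groups")
    if control not in values_by_group:
        raise ValidationError(f"control group {control!r} missing")
    clean = {}
    for g, v in values_by_group.items():
        arr = np.asarray(v, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 usable values")
        clean[g] = arr
    rows = []
    ctrl = clean[control]
    for g, arr in clean.items():
        if g == control:
            continue
        if np.array_equal(np.sort(arr), np.sort(ctrl)):
            stat, p = float(len(arr) * len(ctrl) / 2.0), 1.0
        else:
            stat, p = rank_sum_test(arr, ctrl)
        rows.append(
            {
                "group": g,
                "control": control,
                "mean": arr.mean(),
                "control_mean": ctrl.mean(),
                "statistic": stat,
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)
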