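"""Rarefaction, alpha diversity, Bray–Curtis ordination and PERMANOVA.

Alpha metrics use the bias-corrected Chao1 estimator and natural-log Shannon
entropy.  Beta diversity is Bray–Curtis; ordination is classical metric
scaling (PCoA) with a fixed sign convention so axes are reproducible;
group separation is tested with a permutation pseudo-F (PERMANOVA) whose
permutations are seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .containers import AsvTable, ValidationError, logger, validate_metadata


def rarefy(table: AsvTable, depth: int | str = "auto", seed: int = 0) -> AsvTable:
    """Subsample every sample without replacement to a common depth.

    ``depth="auto"`` uses the minimum column sum.  Samples shallower than
    *depth* are dropped with a logged warning rather than silently kept.
    """
    sums = table.sample_sums()
    if depth == "auto":
        depth = int(sums.min())
    depth = int(depth)
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    keep = sums[sums >= depth].index.tolist()
    dropped = [s for s in table.sample_ids if s not in keep]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) shallower than %d: %s", len(dropped), depth, dropped)
    if not keep:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = {}
    for sid in keep:
        col = table.counts[sid].to_numpy()
        if col.sum() == depth:
            out[sid] = col
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    return AsvTable(pd.DataFrame(out, index=table.taxon_ids))


def chao1(column) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1−1) / (2(F2+1)).

    F1 and F2 are singleton and doubleton counts.  An all-zero column has
    richness 0.
    """
    x = np.asarray(column)
    if (x < 0).any():
        raise ValidationError("chao1 requires non-negative counts")
    s_obs = int((x > 0).sum())
    if s_obs == 0:
        return 0.0
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(column) -> float:
    """Shannon entropy H = −Σ p ln p over non-zero proportions (nats)."""
    x = np.asarray(column, dtype=float)
    if (x < 0).any():
        raise ValidationError("shannon requires non-negative counts")
    total = x.sum()
    if total <= 0:
        raise ValidationError("shannon undefined for a zero-sum column")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: AsvTable) -> pd.DataFrame:
    """Per-sample observed richness, Chao1 and Shannon."""
    rows = []
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        rows.append(
            {
                "sample_id": sid,
                "observed": int((col > 0).sum()),
                "chao1": chao1(col),
                "shannon": shannon(col),
            }
        )
    return pd.DataFrame(rows)


def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between samples.

    A pair of all-zero samples gets distance 0 with a warning (the 0/0 case).
    """
    if table.n_samples < 2:
        raise ValidationError("bray_curtis needs at least 2 samples")
    x = table.counts.to_numpy(dtype=float).T  # samples x taxa
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        tot = (x[i] + x[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        if (tot == 0).any():
            logger.warning("bray_curtis: all-zero sample pair(s); distance set to 0")
        d[i, i + 1 :] = vals
        d[i + 1 :, i] = vals
    return DistanceMatrix(d, ids=table.sample_ids)


def pcoa(d: DistanceMatrix, k: int = 3):
    """Classical metric scaling of a distance matrix.

    Double-centres −½D², eigendecomposes, orders axes by descending
    eigenvalue, and keeps *k* axes.  Proportion explained is taken over the
    positive eigenvalues only.  Sign convention: the first non-zero loading
    of each axis is made positive, so coordinates are reproducible.

    Returns ``(coordinates, eigenvalues, proportion_explained)`` where
    coordinates is a samples × k DataFrame with columns ``PCo1..PCok``.
    """
    n = len(d.ids)
    if k > n - 1:
        raise ValidationError(f"k = {k} must be <= n-1 = {n - 1}")
    dm = d.data
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValidationError("distance matrix is not symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12
    prop = np.zeros_like(evals)
    if pos.any():
        prop[pos] = evals[pos] / evals[pos].sum()
    coords = np.zeros((n, k))
    for a in range(k):
        if evals[a] > 1e-12:
            axis = evecs[:, a] * np.sqrt(evals[a])
            nz = np.flatnonzero(np.abs(axis) > 1e-12)
            if nz.size and axis[nz[0]] < 0:
                axis = -axis
            coords[:, a] = axis
    frame = pd.DataFrame(coords, index=list(d.ids), columns=[f"PCo{a + 1}" for a in range(k)])
    return frame, evals[:k], prop[:k]


def permanova(
    d: DistanceMatrix,
    metadata: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation MANOVA on a distance matrix (one-way, unrestricted labels).

    The pseudo-F comes from the Gower-centred partition of squared distances
    into among- and within-group sums; the p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    validate_metadata(metadata)
    ids = list(d.ids)
    meta = metadata.set_index("sample_id").loc[ids]
    labels, inv = np.unique(meta["treatment"].to_numpy(), return_inverse=True)
    if len(labels) < 2:
        raise ValidationError("permanova needs >= 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        small = labels[sizes < 2].tolist()
        raise ValidationError(f"permanova groups with fewer than 2 samples: {small}")
    n = len(ids)
    a = len(labels)
    d2 = d.data**2
    ss_tot = d2.sum() / (2.0 * n)

    def f_stat(grouping: np.ndarray) -> float:
        ss_within = 0.0
        for k in range(a):
            idx = np.flatnonzero(grouping == k)
            block = d2[np.ix_(idx, idx)]
            ss_within += block.sum() / (2.0 * len(idx))
        ss_among = ss_tot - ss_within
        with np.errstate(divide="ignore"):  # zero within-group SS -> F = inf
            return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = f_stat(inv)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if f_stat(inv[perm]) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)
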