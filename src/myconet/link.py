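"""Correlation between guild relative abundance and per-sample network
stability (the |negative|:positive cohesion ratio).

Samples are aligned strictly by id — never by position — and pooled across
treatment groups, matching how such guild-versus-complexity panels are drawn:
one point per sample, one fitted line per guild.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError, logger


def correlate_guild_stability(
    guild_abundance: pd.DataFrame,
    stability: pd.Series,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-guild correlation between abundance and per-sample stability.

    Parameters
    ----------
    guild_abundance
        guild × sample relative abundances.
    stability
        per-sample stability ratio, indexed by sample id.  NaN entries
        (undefined ratios) are dropped pairwise.
    method
        ``"pearson"`` (R with a fitted line) or ``"spearman"``.

    Returns a DataFrame with columns guild, R, p, n, note.  A guild constant
    across samples has undefined R and is flagged rather than silently
    dropped.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method {method!r}")
    g_ids = set(guild_abundance.columns)
    s_ids = set(stability.index)
    if g_ids != s_ids:
        only_g = sorted(g_ids - s_ids)
        only_s = sorted(s_ids - g_ids)
        raise ValidationError(
            f"sample ids differ: only in guild table {only_g}, only in stability {only_s}"
        )
    stability = stability.loc[list(guild_abundance.columns)]
    keep = ~stability.isna()
    if keep.sum() < 3:
        raise ValidationError("correlate_guild_stability needs >= 3 usable samples")
    s = stability[keep].to_numpy(dtype=float)
    rows = []
    for guild in guild_abundance.index:
        x = guild_abundance.loc[guild, keep.index[keep]].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(s == s[0]):
            rows.append({"guild": guild, "R": np.nan, "p": np.nan, "n": len(x),
                         "note": "zero variance"})
            continue
        if method == "pearson":
            r, p = stats.pearsonr(x, s)
        else:
            r, p = stats.spearmanr(x, s)
        rows.append({"guild": guild, "R": float(r), "p": float(p), "n": len(x), "note": ""})
    return pd.DataFrame(rows)
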