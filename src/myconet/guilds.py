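"""Functional-guild assignment and per-sample guild abundance.

Taxa are mapped to trophic guilds (saprotroph / symbiotroph / pathotroph and
their mixtures) with a longest-match lookup against a reference of lineage
fragments: a genus-level entry beats a family-level one, which beats an
order/class/phylum entry.  This is a lookup-table stand-in for database-driven
guild prediction tools — the reference supplied decides the biology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    GUILD_LABELS,
    GUILDS,
    UNASSIGNED,
    AsvTable,
    ValidationError,
    groups_of,
    logger,
    validate_metadata,
)

#: Rank prefixes ordered most-specific first (species .. kingdom).
_RANK_SPECIFICITY = ("s__", "g__", "f__", "o__", "c__", "p__", "k__")

#: Small synthetic fixture reference for tests and examples: the dominant
#: rhizosphere genera mapped to plausible trophic guilds.  This is a test
#: fixture, not curated biology — real analyses should supply a proper
#: reference table.
FIXTURE_GUILD_REFERENCE = pd.DataFrame(
    [
        ("g__Penicillium", "Saprotroph"),
        ("g__Mortierella", "Saprotroph"),
        ("g__Saitozyma", "Saprotroph"),
        ("g__Trichoderma", "Saprotroph"),
        ("g__Humicola", "Saprotroph-Symbiotroph"),
        ("g__Fusarium", "Pathotroph-Saprotroph-Symbiotroph"),
    ],
    columns=["pattern", "guild"],
)


def _rank_of(pattern: str) -> int:
    """Specificity rank of a reference pattern; lower = more specific."""
    for i, prefix in enumerate(_RANK_SPECIFICITY):
        if pattern.startswith(prefix):
            return i
    return len(_RANK_SPECIFICITY)  # un-prefixed patterns match last


def assign_guilds(taxonomy: pd.DataFrame, ref: pd.DataFrame) -> pd.Series:
    """Map each taxon to a guild by its most specific matching lineage fragment.

    Parameters
    ----------
    taxonomy
        columns ``asv_id``, ``lineage`` (semicolon-delimited ranked string).
    ref
        columns ``pattern``, ``guild``; patterns are rank-prefixed fragments
        such as ``g__Mortierella`` or ``f__Nectriaceae``.

    Returns a Series indexed by asv_id with guild labels; taxa with no match
    or a malformed lineage become ``Unassigned`` (malformed ones are logged).
    """
    bad = set(ref["guild"]) - set(GUILD_LABELS)
    if bad:
        raise ValidationError(f"unknown guild labels in reference: {sorted(bad)}")
    # pattern -> (specificity, guild); duplicated patterns: first entry wins
    lookup: dict[str, tuple[int, str]] = {}
    for _, row in ref.iterrows():
        lookup.setdefault(row["pattern"], (_rank_of(row["pattern"]), row["guild"]))
    out = {}
    for _, row in taxonomy.iterrows():
        lineage = row["lineage"]
        if not isinstance(lineage, str) or not lineage.strip():
            logger.warning("assign_guilds: malformed lineage for %s; set to Unassigned", row["asv_id"])
            out[row["asv_id"]] = UNASSIGNED
            continue
        tokens = [t.strip() for t in lineage.split(";") if t.strip()]
        best: tuple[int, str] | None = None
        for tok in tokens:
            hit = lookup.get(tok)
            if hit is not None and (best is None or hit[0] < best[0]):
                best = hit
        out[row["asv_id"]] = best[1] if best else UNASSIGNED
    return pd.Series(out, name="guild")


def guild_relative_abundance(table: AsvTable, mapping: pd.Series) -> pd.DataFrame:
    """Guild × sample relative-abundance matrix (columns sum to 1, the
    Unassigned row carrying the remainder)."""
    totals = table.sample_sums()
    if (totals == 0).any():
        raise ValidationError("guild_relative_abundance: zero-total sample")
    guild_of = np.array([mapping.get(t, UNASSIGNED) for t in table.taxon_ids])
    rows = {}
    for g in GUILD_LABELS:
        mask = guild_of == g
        rows[g] = table.counts.loc[mask].sum(axis=0) / totals
    return pd.DataFrame(rows).T.loc[list(GUILD_LABELS)]


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum.

    Exact enumeration when both groups have ≤10 observations and no ties;
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_guilds(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    control: str = "CK",
) -> pd.DataFrame:
    """Per-guild pairwise rank-sum tests and percent change vs the control.

    Returns one row per (guild, group) for each non-control group: the
    rank-sum statistic, two-sided p, and the percent change of that group's
    mean relative abundance relative to the control mean.
    """
    validate_metadata(metadata)
    groups = groups_of(metadata)
    if control not in groups:
        raise ValidationError(f"control group {control!r} not in metadata")
    if len(groups) < 2:
        raise ValidationError("compare_guilds needs >= 2 groups")
    for g, samples in groups.items():
        if len(samples) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
    from .pipeline import significance_stars

    rows = []
    for guild in abundance.index:
        ctrl_vals = abundance.loc[guild, groups[control]].to_numpy(dtype=float)
        for gname, samples in groups.items():
            if gname == control:
                continue
            vals = abundance.loc[guild, samples].to_numpy(dtype=float)
            if np.array_equal(np.sort(vals), np.sort(ctrl_vals)) and np.allclose(vals.mean(), ctrl_vals.mean()):
                stat, p = float(len(vals) * len(ctrl_vals) / 2.0), 1.0
            else:
                stat, p = rank_sum_test(vals, ctrl_vals)
            ctrl_mean = ctrl_vals.mean()
            pct = np.nan if ctrl_mean == 0 else 100.0 * (vals.mean() - ctrl_mean) / ctrl_mean
            rows.append(
                {
                    "guild": guild,
                    "group": gname,
                    "control": control,
                    "statistic": stat,
                    "p_value": p,
                    "percent_change": pct,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)
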