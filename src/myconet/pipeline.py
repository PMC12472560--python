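"""End-to-end orchestration: from count table (real or synthetic) to the full
result bundle, plus the shared reporting statistics (significance stars,
Kruskal–Wallis with Dunn post hoc and a compact letter display).

``run_all`` executes every stage in method order — rarefaction, alpha
diversity, Bray–Curtis/PCoA/PERMANOVA, guild assignment and tests, per-group
networks and topology, cohesion/stability/robustness, and the
guild–stability correlation — writing each artifact as TSV/GraphML/JSON
under an output directory together with a manifest that suffices to
reproduce the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from . import io as mio
from .containers import AsvTable, ValidationError, groups_of, logger, validate_metadata
from .diversity import alpha_diversity, bray_curtis, pcoa, permanova, rarefy
from .guilds import assign_guilds, compare_guilds, guild_relative_abundance
from .link import correlate_guild_stability
from .network import group_networks
from .stability import cohesion, compare_stability, robustness
from .topology import compare_topology, summarize


def significance_stars(p: float) -> str:
    """Conventional star labels: * p<0.05, ** p<0.01, *** p<0.001,
    **** p<0.0001; "ns" otherwise (strict inequalities: p = 0.05 is ns)."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn post hoc with compact letter display
# ---------------------------------------------------------------------------

def _dunn_pairwise(values: list[np.ndarray], names: list[str], h: float) -> pd.DataFrame:
    """Pairwise rank comparisons after a Kruskal–Wallis test.

    Two families of p-values are reported per pair: Dunn z-tests on pooled
    ranks (tie-corrected, Holm-adjusted, columns ``z``/``p_value``/
    ``p_adjusted``) and the rank-scale Fisher-LSD t-tests the agricolae-style
    letter display is built from (``p_lsd``).  The LSD tests are unadjusted
    and only meaningful when protected by a significant omnibus test — the
    Dunn z family is so conservative at the n = 4–6 replication typical of
    field studies that it cannot separate any pair after Holm adjustment.
    """
    pooled = np.concatenate(values)
    ranks = sstats.rankdata(pooled)
    n = len(pooled)
    k = len(values)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks = []
    sizes = []
    start = 0
    for v in values:
        mean_ranks.append(ranks[start : start + len(v)].mean())
        sizes.append(len(v))
        start += len(v)
    s2 = ranks.var(ddof=1)  # variance of pooled ranks (= n(n+1)/12 untied)
    lsd_scale = s2 * (n - 1 - h) / (n - k) if n > k else np.inf
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sstats.norm.sf(abs(z))
            se_lsd = np.sqrt(lsd_scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se_lsd == 0 or not np.isfinite(se_lsd):
                p_lsd = 1.0 if mean_ranks[i] == mean_ranks[j] else 0.0
            else:
                t = (mean_ranks[i] - mean_ranks[j]) / se_lsd
                p_lsd = 2.0 * sstats.t.sf(abs(t), df=n - k)
            rows.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "z": z,
                    "p_value": p,
                    "p_lsd": p_lsd,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="holm")[1] if len(out) else []
    return out


def _letter_display(names: list[str], pairwise: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Greedy insert-and-absorb compact letter display at the given alpha.

    Groups sharing a letter are not significantly different.  Ties are broken
    by the order groups appear in *names*.
    """
    sig = {
        frozenset((r["group_1"], r["group_2"]))
        for _, r in pairwise.iterrows()
        if r["letter_p"] < alpha
    }

    def compatible(group: str, members: set[str]) -> bool:
        return all(frozenset((group, m)) not in sig for m in members)

    cliques: list[set[str]] = []
    for g in names:
        placed = False
        for c in cliques:
            if compatible(g, c):
                c.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    # absorb cliques fully contained in another
    cliques = [c for i, c in enumerate(cliques)
               if not any(i != j and c < other for j, other in enumerate(cliques))]
    letters = {g: "" for g in names}
    for c, letter in zip(cliques, "abcdefghijklmnopqrstuvwxyz"):
        for g in names:
            if g in c:
                letters[g] += letter
    return letters


def kruskal_dunn(values_by_group: dict[str, np.ndarray]) -> tuple[float, float, dict[str, str], pd.DataFrame]:
    """Kruskal–Wallis H (tie-corrected) with post hoc comparisons and a
    compact letter display at alpha = 0.05.

    Letters come from the protected rank-scale LSD comparisons (only applied
    when the omnibus test is significant; otherwise every group shares one
    letter); the pairwise table additionally carries Holm-adjusted Dunn
    z-tests.  Requires ≥3 groups of ≥2 values each; for two groups use the
    rank-sum test instead.  Returns ``(H, p, letters, pairwise_table)``.
    """
    names = list(values_by_group)
    if len(names) < 3:
        raise ValidationError("kruskal_dunn needs >= 3 groups; use the two-group rank-sum test")
    values = [np.asarray(values_by_group[g], dtype=float) for g in names]
    for g, v in zip(names, values):
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 values")
    try:
        h, p = sstats.kruskal(*values)
    except ValueError:  # all pooled values identical
        h, p = 0.0, 1.0
    pairwise = _dunn_pairwise(values, names, float(h))
    # protected LSD: without a significant omnibus test, nothing separates
    pairwise["letter_p"] = pairwise["p_lsd"] if p < 0.05 else 1.0
    letters = _letter_display(names, pairwise)
    return float(h), float(p), letters, pairwise


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything `run_all` needs.  Either the three input paths are set, or
    ``synthetic`` holds keyword arguments for
    :class:`myconet.simulate.SimulationDesign` and inputs are generated."""

    table_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    guild_reference_path: str | None = None
    synthetic: dict | None = None
    rarefaction_depth: int | str = "auto"
    rho_threshold: float = 0.8
    alpha: float = 0.05
    min_prevalence: float = 0.5
    min_mean_relabund: float = 1e-4
    null_iterations: int = 200
    removal_fraction: float = 0.5
    replicates: int = 100
    control: str = "CK"
    guilds_on_rarefied: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_threshold <= 1.0):
            raise ValidationError("rho_threshold must be in [0, 1]")
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError("alpha must be in (0, 1]")
        if not (0.0 <= self.removal_fraction < 1.0):
            raise ValidationError("removal_fraction must be in [0, 1)")
        if self.null_iterations < 1 or self.replicates < 1:
            raise ValidationError("null_iterations and replicates must be >= 1")
        have_paths = self.table_path is not None and self.metadata_path is not None
        if not have_paths and self.synthetic is None:
            raise ValidationError("either input paths or a synthetic design must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        from .simulate import SimulationDesign, generate_dataset

        design = SimulationDesign(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        return generate_dataset(design)
    table = mio.read_asv_table(config.table_path)
    metadata = mio.read_metadata(config.metadata_path)
    taxonomy = (
        mio.read_taxonomy(config.taxonomy_path) if config.taxonomy_path else
        pd.DataFrame({"asv_id": table.taxon_ids, "lineage": [""] * table.n_taxa})
    )
    if config.guild_reference_path:
        guild_ref = mio.read_guild_reference(config.guild_reference_path)
    else:
        from .guilds import FIXTURE_GUILD_REFERENCE

        guild_ref = FIXTURE_GUILD_REFERENCE
    return table, taxonomy, metadata, guild_ref


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run the whole analysis and write the result bundle under *out_dir*.

    Returns a dict of in-memory results keyed by artifact name.  Any stage
    failure is re-raised annotated with the stage name; artifacts written
    before the failure are left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    t0 = time.time()
    try:
        stage = "inputs"
        table, taxonomy, metadata, guild_ref = _load_inputs(config)
        validate_metadata(metadata, table)

        stage = "rarefaction"
        rare = rarefy(table, config.rarefaction_depth, seed=config.seed)
        metadata = metadata[metadata["sample_id"].isin(rare.sample_ids)].reset_index(drop=True)
        mio.write_asv_table(rare, out / "rarefied_table.tsv")

        stage = "alpha_diversity"
        alpha = alpha_diversity(rare)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
        results["alpha"] = alpha

        stage = "beta_diversity"
        dm = bray_curtis(rare)
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            out / "bray_curtis.tsv", sep="\t"
        )
        k = min(3, len(dm.ids) - 1)
        coords, evals, prop = pcoa(dm, k=k)
        coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        f_stat, p_val = permanova(dm, metadata, n_perm=999, seed=config.seed)
        pd.DataFrame(
            [{"pseudo_F": f_stat, "p_value": p_val, "stars": significance_stars(p_val)}]
        ).to_csv(out / "permanova.tsv", sep="\t", index=False)
        results.update({"distance": dm, "pcoa": (coords, evals, prop), "permanova": (f_stat, p_val)})

        stage = "guilds"
        mapping = assign_guilds(taxonomy, guild_ref)
        guild_table = guild_relative_abundance(rare if config.guilds_on_rarefied else table, mapping)
        guild_table.to_csv(out / "guild_abundance.tsv", sep="\t")
        guild_tests = compare_guilds(guild_table, metadata, control=config.control)
        guild_tests.to_csv(out / "guild_tests.tsv", sep="\t", index=False)
        results.update({"guilds": guild_table, "guild_tests": guild_tests})

        stage = "networks"
        nets = group_networks(
            rare,
            metadata,
            rho_threshold=config.rho_threshold,
            alpha=config.alpha,
            min_prevalence=config.min_prevalence,
            min_mean_relabund=config.min_mean_relabund,
        )
        for gname, net in nets.items():
            mio.write_network(net, out / f"network_{gname}.graphml", format="graphml")
            mio.write_network(net, out / f"network_{gname}_edges.csv", format="edge_csv")
        results["networks"] = nets

        stage = "topology"
        summaries = [summarize(net) for net in nets.values()]
        topo = compare_topology(summaries, control=config.control)
        topo.to_csv(out / "topology.tsv", sep="\t")
        results["topology"] = topo

        stage = "cohesion"
        coh_rows = []
        ratios_by_group: dict[str, pd.Series] = {}
        for gname, samples in groups_of(metadata).items():
            prof = cohesion(
                rare.subset_samples(samples),
                null_iterations=config.null_iterations,
                seed=config.seed,
            )
            ratios_by_group[gname] = prof.stability_ratio
            for sid in samples:
                coh_rows.append(
                    {
                        "sample_id": sid,
                        "treatment": gname,
                        "cohesion_pos": prof.cohesion_pos[sid],
                        "cohesion_neg": prof.cohesion_neg[sid],
                        "stability_ratio": prof.stability_ratio[sid],
                    }
                )
        coh_table = pd.DataFrame(coh_rows)
        coh_table.to_csv(out / "cohesion.tsv", sep="\t", index=False)
        results["cohesion"] = coh_table

        stage = "robustness"
        rob_rows = []
        rob_by_group: dict[str, np.ndarray] = {}
        for gname, net in nets.items():
            if net.n_nodes == 0:
                logger.warning("robustness: empty network for group %s; skipped", gname)
                continue
            rnd = robustness(
                net, "random", config.removal_fraction, config.replicates, seed=config.seed
            )
            tgt = robustness(net, "targeted", config.removal_fraction)
            rob_by_group[gname] = rnd.values
            rob_rows.append(
                {
                    "group": gname,
                    "random_mean": rnd.mean,
                    "random_sd": rnd.sd,
                    "targeted": float(tgt.values[0]),
                }
            )
        rob_table = pd.DataFrame(rob_rows)
        rob_table.to_csv(out / "robustness.tsv", sep="\t", index=False)
        results["robustness"] = rob_table
        results["robustness_values"] = rob_by_group

        stage = "stability_tests"
        usable = {g: v.dropna() for g, v in ratios_by_group.items() if v.dropna().size >= 2}
        if len(usable) >= 2 and config.control in usable:
            stab_tests = compare_stability(usable, control=config.control)
        else:
            stab_tests = pd.DataFrame()
            logger.warning("stability_tests: not enough usable groups; table empty")
        stab_tests.to_csv(out / "stability_tests.tsv", sep="\t", index=False)
        results["stability_tests"] = stab_tests

        stage = "guild_stability_link"
        ratios = pd.concat(ratios_by_group.values())
        link = correlate_guild_stability(guild_table, ratios)
        link.to_csv(out / "guild_stability_link.tsv", sep="\t", index=False)
        results["link"] = link

        stage = "manifest"
        manifest = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "python": platform.python_version(),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "elapsed_seconds": round(time.time() - t0, 2),
            "artifacts": sorted(p.name for p in out.iterdir()),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        results["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
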