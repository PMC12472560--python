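# myconet

Co-occurrence network stability analysis for soil fungal communities.

`myconet` takes an ASV (amplicon sequence variant) count table — taxa ×
samples, as produced by any ITS amplicon workflow — together with sample
metadata, a taxonomy table and a guild reference, and computes the full
analysis chain used to ask *"did a treatment change the structure and
stability of the fungal interaction network?"*:

1. **Diversity** — rarefaction to even depth, Chao1 and Shannon alpha
   diversity, Bray–Curtis distances, PCoA ordination, and PERMANOVA for
   group separation.
2. **Functional guilds** — lookup-table assignment of taxa to trophic guilds
   (Saprotroph, Symbiotroph, Pathotroph and their mixtures), per-sample guild
   relative abundances, and rank-sum group comparisons.
3. **Co-occurrence networks** — per-treatment Spearman correlation networks:
   an edge joins two taxa when |ρ| > 0.8 with a Bonferroni-corrected
   p < 0.05; topology panel (nodes, edges, average degree 2E/N, density
   2E/(N(N−1)), clustering, path length, diameter, greedy modularity Q).
4. **Stability** — per-sample community *cohesion* under a taxon-shuffle
   null model: each taxon's connectedness is its mean null-corrected
   correlation with all other taxa, split into positive and negative parts;
   a sample's cohesion is the abundance-weighted sum, and its stability
   (complexity) ratio is |C⁻| / C⁺. Network *robustness* is the connectivity
   left after removing 50% of nodes at random or in descending-degree order.
5. **Guild–stability link** — Pearson correlation between each guild's
   relative abundance and the per-sample stability ratio.

A first-class synthetic-data module generates ASV tables with planted
co-abundance modules (latent Gaussian factors), anti-correlated
(competition-like) taxa, treatment-specific guild mixes and multinomial
sampling at fixed depth, so the whole pipeline is testable without raw
sequence data.

## Worked example

```python
import numpy as np, pandas as pd
import myconet as mc

# standard fixture: a control (CK), a conventional-film treatment (CF) with
# dense, competition-rich planted structure, and a biodegradable-film
# treatment (BF) with sparse, cooperation-dominated structure
design = mc.treatment_effect_design(seed=0)
table, taxonomy, metadata, guild_ref = mc.generate_dataset(design)

nets = mc.group_networks(table, metadata)
for g in ("CK", "CF", "BF"):
    s = mc.summarize(nets[g])
    print(f"{g}: nodes={s.nodes} edges={s.edges} "
          f"avg_degree={s.average_degree:.2f} density={s.density:.3f}")
```

prints

```
CK: nodes=27 edges=66 avg_degree=4.89 density=0.188
CF: nodes=40 edges=116 avg_degree=5.80 density=0.149
BF: nodes=22 edges=18 avg_degree=1.64 density=0.078
```

— the conventional-film group has the most connected network and the
biodegradable-film group the sparsest, as planted. Cohesion shows the same
story on the stability side:

```python
for g in ("CK", "CF", "BF"):
    sub = table.subset_samples([s for s in table.sample_ids if s.startswith(g)])
    prof = mc.cohesion(sub, null_iterations=200, seed=0)
    print(g, round(float(np.nanmean(prof.stability_ratio)), 3))
```

```
CK 0.833
CF 0.865
BF 0.635
```

The BF group's |negative|:positive cohesion ratio is lowest: its planted
community lacks competitive (anti-correlated) pairs, the configuration
ecological theory flags as fragile. Correlating guild abundance with the
per-sample ratio across all 45 samples recovers the planted coupling —
saprotrophs and symbiotrophs, which the BF mix depletes, associate
positively with stability (Sap R = 0.51, p = 3.8e-4; Sym R = 0.58,
p = 3.6e-5).

The same pipeline runs from the shell:

```bash
myconet generate --out data/ --seed 0
myconet network --table data/asv_table.tsv --metadata data/metadata.tsv \
    --group CK --out ck.graphml
myconet runall --config config.yaml --out results/
```

`runall` writes the full bundle: alpha-diversity, Bray–Curtis and PCoA
tables, PERMANOVA, guild abundances and tests, per-group GraphML networks
(Gephi-ready) with topology summaries, cohesion/stability/robustness tables,
guild–stability correlations, and a manifest that reproduces the run.

## Layout

| module | contents |
| --- | --- |
| `myconet.simulate` | `SimulationDesign`, `generate_dataset`, `plant_group_effect`, fixtures |
| `myconet.io` | TSV/GraphML readers and writers with line-level validation |
| `myconet.diversity` | `rarefy`, `chao1`, `shannon`, `bray_curtis`, `pcoa`, `permanova` |
| `myconet.guilds` | `assign_guilds`, `guild_relative_abundance`, `compare_guilds` |
| `myconet.network` | `filter_taxa`, `spearman_matrix`, `build_network`, `group_networks` |
| `myconet.topology` | `summarize`, `compare_topology`, closed-form helpers |
| `myconet.stability` | `cohesion`, `stability_ratio`, `robustness`, `compare_stability` |
| `myconet.link` | `correlate_guild_stability` |
| `myconet.pipeline` | `PipelineConfig`, `run_all`, `significance_stars`, `kruskal_dunn` |

See `docs/methods.md` for the models, defaults and their rationale.
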