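# micasa

**Mi**crobial **c**ommunity **as**sembly **a**nalysis for enrichment-reactor
microbiomes.

Mixed-culture enrichment reactors (for example, feast–famine reactors
selecting polyhydroxyalkanoate-storing bacteria across a temperature
gradient) pose a recurring set of questions: how diverse is the community
and what drives its structure, which organisms form the persistent core,
which taxa deviate from neutral assembly, and which taxa track an
environmental driver such as temperature. `micasa` implements that
analysis chain as a tested, reusable library and CLI operating on an
ASV-by-sample count table with taxonomy, sample metadata, and an optional
rooted phylogeny:

* **Preprocessing** — contaminant (mitochondria/chloroplast) and
  fully-unassigned ASV removal, rank aggregation, closure, top-N selection.
* **Diversity** — analytic rarefied richness
  `E[S] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n))`, Shannon entropy, Bray–Curtis and
  (un)weighted UniFrac distances, PCoA, and one-factor PERMANOVA
  (McArdle–Anderson pseudo-F, categorical or numeric covariates, seeded
  permutations).
* **Core microbiome** — occupancy ranking by
  `(mean time-specific occupancy + replication consistency)/2`, an
  explanatory-value curve `E_k = BC(top-k)/BC(all)` over mean pairwise
  Bray–Curtis similarity, and the "last 2%" stopping rule on relative
  gains `C = 1 − BC(subset)/BC(all)`.
* **Neutral model** — Sloan's single-parameter model: predicted occupancy
  `1 − I_{d/N}(Nmp, Nm(1−p))`, least-squares fit of the migration rate
  `m`, Wilson 95% band, and per-taxon classification into neutral /
  above (selected) / below (dispersal-limited).
* **CODA-LASSO** — zero-sum-constrained L1 log-contrast regression
  `yᵢ = β₀ + Σⱼ βⱼ log xⱼᵢ + εᵢ` with `Σβⱼ = 0`, solved by exact pairwise
  coordinate descent with cross-validated penalty, yielding disjoint
  positively/negatively associated taxon signatures.
* **Synthetic data** — a generator emulating the 3-temperature ×
  4-timepoint × triplicate design with known ground truth (source
  community, true `m`, planted core/selected/dispersal-limited taxa, true
  zero-sum β), so every stage is verifiable by parameter recovery.

## Worked example

Simulate a study-scale dataset with planted structure, then recover it:

```python
from micasa import (SimulationConfig, simulate_dataset, fit_neutral_model,
                    temperature_signature, bray_curtis_matrix, permanova)
from micasa.core import core_microbiome

cfg = SimulationConfig(
    n_taxa=300, n_planted_core=10, n_planted_above=5, n_planted_below=5,
    n_signal_taxa=5, seed=42,
)
ds, truth = simulate_dataset(cfg)
dna = ds.filter_samples(ds.metadata.df["phase"] == "DNA-enrichment")

fit = fit_neutral_model(dna.table)
print(f"migration rate m = {fit.m:.3f} (true {truth.m_true}), R^2 = {fit.r_squared:.2f}")
print("assembly classes:", fit.class_counts.to_dict())

res = core_microbiome(dna, threshold=0.02, max_rank=60)
print(f"core size = {len(res.core)}; planted core recovered: "
      f"{len(set(res.core) & set(truth.planted_core_ids))}/10")

dm = bray_curtis_matrix(dna.table)
pr = permanova(dm, dna.metadata.df["temperature"], n_permutations=999, seed=0)
print(f"PERMANOVA temperature: R^2 = {pr.r_squared:.3f}, p = {pr.p_value:.3f}")

sig = temperature_signature(dna, seed=0)
print("temperature-associated genera:",
      {t: round(b, 2) for t, b in sig.beta.items() if b != 0})
```

Output:

```
migration rate m = 0.244 (true 0.15), R^2 = 0.56
assembly classes: {'neutral': 251, 'above': 38, 'below': 11}
core size = 15; planted core recovered: 10/10
PERMANOVA temperature: R^2 = 0.021, p = 0.445
temperature-associated genera: {'Genus_0066': -8.94, 'Genus_0012': -8.93, 'Genus_0239': 6.31, 'Genus_0158': 6.24, 'Genus_0149': 5.31, 'Genus_0026': 0.02}
```

Reading this: the fitted migration rate lands above the true 0.15 — the
expected upward bias of the standard occupancy-threshold fit on sampled
counts (see `docs/methods.md`); the 20 planted non-neutral taxa are among
those flagged above/below the band. All 10 planted persistent taxa are
recovered in the 15-member core. Whole-community PERMANOVA barely sees
temperature because only 5 of 300 taxa respond to it — while the
compositional log-contrast regression pinpoints exactly those five (three
positive, two negative, one tiny false positive), illustrating why the
two analyses complement each other.

The same pipeline runs from the shell:

```bash
micasa simulate --out-dir fixture --seed 42
micasa run-all --config config.toml        # preprocess → diversity →
                                           # core → neutral → codalasso
micasa neutral --abundance fixture/abundance.tsv --taxonomy fixture/taxonomy.tsv \
       --metadata fixture/metadata.tsv --group Low --out-dir out
```

Input formats: abundance TSV (`feature_id` + sample columns; transposed
tables are auto-detected), taxonomy TSV (seven rank columns or a
QIIME-style semicolon `Taxon` column), metadata TSV keyed by `sample_id`,
newick tree with branch lengths.

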