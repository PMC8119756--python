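# lowbiom

Decontamination and absolute quantification for **low-biomass 16S rRNA
amplicon studies** — fetal/neonatal samples, amniotic fluid, biopsies,
built environments: any setting where genuine microbial DNA is comparable
in amount to the reagent and environmental DNA that enters every tube.

In such studies, empty sampling instruments ("negative field controls")
are exposed to the sampling environment and processed exactly like
specimens. They measure the contamination background, and this package
implements the analysis built on them:

* **Field-control contaminant filtering.** For each amplicon sequence
  variant (ASV), compute its prevalence and mean relative abundance in
  specimens and in field controls, per sample type. An ASV is removed when

  > prev_specimen ≤ 2 × prev_control **and** mra_specimen ≤ 10 × mra_control

  (both thresholds configurable). Specimens left with fewer than 500 reads
  after filtering are dropped. An ASV absent from every control can never
  be removed — its control-side bounds are zero.
* **Absolute qPCR quantification.** Per-run standard curves
  (Cq = slope·log₁₀ copies + intercept, efficiency = 10^(−1/slope) − 1),
  inversion to copies per reporting unit, and an **exact** two-tailed
  Mann–Whitney U test (full enumeration of all C(n₁+n₂, n₁) group
  assignments for pooled n ≤ 20) to compare specimens to controls.
* **Community statistics.** Relative abundance, genus aggregation with
  "unclassified *parent*" pooling, Shannon diversity (natural log, no
  rarefaction), Bray–Curtis distances on proportions, classical PCoA,
  one-way PERMANOVA and betadisper-style dispersion tests with seeded
  permutations, and paired Spearman correlations (Bonferroni-corrected)
  between sample types of the same subject over features with total count
  > 100.
* **A ground-truthed simulator.** Synthetic studies with lognormal
  absolute loads, Dirichlet-multinomial counts, and qPCR readings, in which
  every feature is labelled contaminant or signal — so filter sensitivity
  and specificity are measurable exactly. Defaults emulate a paired
  bovine meconium / amniotic-fluid cesarean-section design (23 couples,
  11 + 8 field controls, ~92k–128k reads/sample, specimen qPCR means
  4,350 and 3,170 copies against backgrounds of 980 and 1,610).

## Worked example

```python
from lowbiom import SimulationConfig, simulate_study, apply_decontamination

study = simulate_study(SimulationConfig(seed=42))
reports = apply_decontamination(study.table, study.metadata)
```

Running `python examples/02_decontaminate.py` (which does the above and
compares against the simulator's ground truth) prints:

```
amnion: removed 40 of 65 features present in specimens (40 true contaminants), dropped 0 specimens
  mean reads/specimen: 123,842 -> 69,721
meconium: removed 40 of 65 features present in specimens (40 true contaminants), dropped 0 specimens
  mean reads/specimen: 89,380 -> 64,208
```

All 40 ground-truth contaminants are removed and no genuine signal taxon
is lost: the filter recovers the simulated contamination structure
exactly. `examples/03_qpcr_quantify.py` continues with quantification:

```
standard curve: slope=-3.3219, efficiency=1.000, r^2=1.0000
meconium: specimens 4,532 copies (n=23) vs controls 1,442 (n=11), U=217, p=0.0009226 [normal_approximation]
```

i.e. a perfect-efficiency curve and significantly more bacterial DNA in
specimens than in the field-control background. The other scripts under
`examples/` walk through simulation, community comparison (PERMANOVA,
PCoA, paired correlations) and the end-to-end pipeline.

## Command line

```bash
lowbiom simulate --seed 42 --out-dir study/
lowbiom run-all --table study/feature_table.tsv --metadata study/metadata.tsv \
    --taxonomy study/taxonomy.tsv --qpcr study/qpcr.csv --out-dir results/
```

Subcommands `decontam`, `qpcr`, `diversity` and `compare` run individual
stages. All inputs and outputs are plain TSV/CSV/JSON; `manifest.json`
records input hashes, parameters, seed and library versions.

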