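# silaf — heavy-lysine labeling quantification for fly proteomics

`silaf` is a self-contained Python implementation of the downstream
quantification used in stable-isotope labeling of amino acids in flies
(SILAF) and related two-channel SILAC experiments: animals are raised on a
chemically defined diet in which lysine is replaced by ¹³C₆-lysine, heavy
and light proteomes are mixed, digested with Lys-C, and every peptide is
quantified as a heavy/light (H/L) intensity pair.  The package takes
search-engine result tables (evidence, protein groups, phospho-sites in the
MaxQuant-style tab-separated dialect) and computes:

- **Label incorporation** from raw intensities, `H / (H + L)`, per peptide,
  protein, timepoint and functional category — the quantity used to verify
  that labeling is complete (≥ 95%) before quantitative work.
- **Protein turnover** from pulse-labeling time courses by least-squares
  fits of the single-pool first-order model `f(t) = 1 − exp(−k t)`, with
  half-life `ln 2 / k`.
- **Fold changes** from normalized H/L ratios: per-run median centering on
  the log2 scale, protein ratio = median of peptide log2 ratios, technical
  replicates averaged before biological statistics.
- **Phosphosite occupancy changes**: sites filtered at localization
  probability > 0.75; the occupancy change is the site's log2 H/L minus the
  matched protein's log2 H/L in the same replicate, so pure abundance
  changes cancel.  Sites on strongly changed proteins (> 4-fold by default)
  are flagged as potentially confounded.
- **Moderated statistics**: a one-sample empirical-Bayes moderated t-test
  (prior variance and prior degrees of freedom estimated across features by
  closed-form moments of `log s²`) with Benjamini–Hochberg FDR — both
  implemented here, and verified in the test suite against Bioconductor
  limma and statsmodels as independent oracles.
- **Enrichment**: hypergeometric overrepresentation analysis and
  permutation-based gene-set enrichment (weighted running-sum score,
  gene-label permutations) over GMT gene sets, plus per-category box-plot
  summaries with rank-sum tests.

Because real LC-MS/MS studies of this kind live in external repositories,
the package ships a first-class synthetic-experiment generator
(`silaf.synthetic_data`): a random proteome with in-silico Lys-C/P
digestion, first-order labeling kinetics with fast (ribosome-like) and slow
(OXPHOS-like) categories, a designated down-regulated category, phosphosites
with localization probabilities, biological/technical replicates,
missingness-not-at-random, and contaminant/decoy rows — together with a
persisted ground truth so every stage can be scored by parameter recovery.

## Worked example

```python
from pathlib import Path
from silaf import (RunConfig, make_ground_truth, run_pipeline,
                   score_recovery, simulate_experiment)

gt = make_ground_truth(n_proteins=1000, seed=42)     # OXPHOS category down ~2-fold
paths = simulate_experiment(gt, Path("sim"))
config = RunConfig(
    evidence=str(paths["evidence"]),
    protein_groups=str(paths["protein_groups"]),
    sites=str(paths["sites"]),
    annotation=str(paths["annotation"]),
    gene_sets=str(paths["gene_sets"]),
    rng_seed=42,
)
summary = run_pipeline(config, Path("run"))
report = score_recovery(Path("run"), gt)
```

This prints/produces (exact numbers for seed 42):

```
proteins quantified: 1000
proteome significant: {'up': 1, 'down': 50, 'n_tested': 1000, 'threshold': 0.01}
sites: 1999 detected / 1578 localized
phospho significant: {'up': 164, 'down': 164, 'n_tested': 1578, 'threshold': 0.05}
GSEA: ['OXPHOS'] | ORA: ['OXPHOS']
log2fc_mae = 0.0494
sensitivity = 1.0
empirical_fdr = 0.0196
occupancy_bias = -0.0154
```

Reading: all 1000 simulated proteins were quantified; at the adjusted-p
threshold of 0.01 the moderated test calls 50 proteins down-regulated —
exactly the 50-member OXPHOS-like category carrying a true ~2-fold loss —
with one false positive; 1578 of 1999 simulated phosphosites pass the
localization filter (the generator draws 80% confident sites); both GSEA
and ORA flag the OXPHOS category and nothing else; and the recovered
log2 fold changes sit within 0.05 of truth on average.

The same stages are available from the shell:

```sh
silaf simulate --n-proteins 1000 --seed 42 --out sim/
silaf run --config config.yaml --out run/
silaf score --run-dir run/ --ground-truth sim/ground_truth.json
```

## Layout

```
src/silaf/
  tables_io.py        # dialect-configurable TSV/GMT readers and writers
  synthetic_data.py   # Lys-C digestion, labeling kinetics, experiment simulator
  quant_core.py       # filtering, normalization, incorporation, fold changes
  turnover.py         # first-order turnover fits, labeling quartiles
  phospho.py          # localization filter, occupancy changes, confound flags
  stats_inference.py  # moderated t-test, BH adjustment, significance calls
  enrichment.py       # hypergeometric ORA, permutation GSEA, category tests
  pipeline.py         # run orchestration, config, recovery scoring
  cli.py              # `silaf` command-line entry points
```

See `docs/methods.md` for the statistical models, default parameters, and
known limitations.
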