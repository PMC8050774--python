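# Methods

This note documents the models and procedures implemented in `silaf`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Quantification model

**Input contract.** The pipeline consumes search-engine output tables and
treats identification as settled upstream: peptide-spectrum matching, FDR
control of identifications, and protein inference are properties of the
input, not steps of this package.  Flag columns follow the `"+"` convention
(`Reverse`, `Potential contaminant`, `Only identified by site`); all column
names are configurable (`TableDialect`), since different search-engine
versions name columns differently.  An empty intensity cell is parsed as
*absent*, never as zero — zero signal and unmeasured signal are different
facts, and the distinction propagates through every stage.

**Filtering.** Protein groups with any of the three quality flags are
excluded before quantification.  The removal counts per flag are written to
the structured run log so reported numbers can be audited.

**Incorporation.** Label incorporation is computed from raw (not
normalized) intensities as `H / (H + L)`.  Protein-level incorporation sums
the heavy and light intensities of the protein's peptides within a
timepoint before taking the quotient (intensity-weighted), which makes the
estimate robust to individual low-intensity peptides.  When an observation
has signal in neither channel the quantity is undefined and reported
missing.  Per-replicate fractions are kept separate by default
(`pool_replicates="after"`); pooling intensities across replicates before
the quotient is available as a config switch since either convention is
defensible.

**Normalization.** H/L ratios are median-centered on the log2 scale within
each run (raw file).  This reproduces the default behavior of the upstream
tools whose "normalized ratio" columns these pipelines usually inherit.  It
is idempotent and equivariant under global rescaling of either channel.
Caveat: median centering assumes most peptides are unchanged; when a large
fraction of the proteome truly shifts in one direction, the median absorbs
part of the shift and all fold changes acquire a small common bias.  With
the default study design (5% of proteins regulated) this bias is ≈ 0.02
log2 units, well inside the recovery tolerance; designs where most of the
proteome changes need a different normalization anchor.

**Protein fold changes.** Per replicate, the protein log2 ratio is the
*median* of its peptides' normalized log2 ratios (robust to single outlier
peptides; the peptide count is reported so stricter thresholds can be
applied).  Technical replicates are averaged on the log2 scale before any
biological statistics — technical re-injections are not independent
biological evidence, and treating them as such would be pseudo-replication.
Peptides observed in only one channel are excluded from ratio statistics
but retained for incorporation and presence counts: a 0 or infinite ratio
carries real information about presence, none about relative abundance.

## Turnover

Pulse labeling is modeled as a single-pool first-order process,
`f(t) = 1 − exp(−k t)` with `f(0) = 0` and asymptote 1: animals arrive
unlabeled when transferred to heavy food, and the fully labeled state is
complete replacement.  The rate is fitted per protein by unweighted least
squares on the fraction scale (fractions are bounded and roughly
homoscedastic) over `k ∈ (1e-6, 10]` per day using bounded scalar
minimization; fits at the bounds are reported non-converged rather than
raised, since an all-zero time course is data, not a usage error.  The
model deliberately omits precursor-pool enrichment, label recycling, and
growth dilution; in growing larvae the apparent `k` therefore conflates
synthesis and dilution.  A sub-unity plateau (for non-dividing adult tissue
pools) is left to the caller: the two-parameter extension is easy to
mis-identify with few timepoints, so the default stays one-parameter.

Labeling-quartile bins of the final timepoint (`[0–25] (25–50] (50–75]
(75–100]`, closed at zero, right-closed elsewhere) partition proteins for
overrepresentation input; per-category medians and quartiles summarize the
kinetic structure (ribosome-like fast, OXPHOS-like slow).

## Phosphosite occupancy

Sites require localization probability **strictly** greater than 0.75; a
site at exactly 0.75 is removed.  The occupancy change is defined as the
difference of log2 site and protein H/L ratios within the same replicate.
This is the protein-normalized site ratio, not an absolute stoichiometry:
computing absolute occupancies per channel would require the unmodified
counterpart peptide's ratio as a third input, which standard site tables do
not reliably provide.  The config exposes `occupancy_method` semantics
through this single default; the three-ratio stoichiometry method is a
known alternative and deliberately not silently substituted.  Technical
replicates are averaged after the within-replicate subtraction, consistent
with the protein-level convention.  Sites on proteins whose own level
changes more than fourfold (|log2FC| > 2, configurable) are flagged
`confounded` — a strong protein change can masquerade as an occupancy
change through imperfect matching — but flagged rows are never dropped.

## Moderated statistics

The design is one-sample on per-biological-replicate log2 values: in a
mixing design each replicate is self-paired, so the null is mean log2 ratio
= 0.  Per-feature variances `s²` with `d = n − 1` degrees of freedom are
shrunk toward a prior `s₀²` with prior degrees of freedom `d₀`:

    s²_post = (d₀ s₀² + d s²) / (d₀ + d),
    t = mean / sqrt(s²_post / n),   df = d₀ + d.

`(d₀, s₀²)` are estimated by method of moments on `log s²`: with
`e = log s² − ψ(d/2) + log(d/2)`, the excess of `var(e)` over the expected
sampling variance `ψ′(d/2)` equals `ψ′(d₀/2)`, inverted by Newton
iteration on the trigamma function; `s₀²` follows from the mean of `e`.
The test suite verifies exact agreement (1e-10) with Bioconductor limma's
`eBayes` on the same matrices.  When the moment equation has no positive
root (observed variances less dispersed than pure sampling noise) the
implementation falls back to `d₀ = 0` — the ordinary t-test — with a
warning; an explicit `prior_df` argument overrides estimation, giving the
ordinary t at 0 and complete shrinkage at infinity.  Features with fewer
than two finite replicates are reported untested.  Proteome and
phosphoproteome tables are moderated separately: their variance structures
differ, and pooling them would let the larger table dominate the prior.

Multiple testing uses Benjamini–Hochberg step-up with enforced
monotonicity, implemented once and shared by every correcting module.
Significance conventions: adjusted p < 0.01 for proteome fold changes,
< 0.05 for occupancy changes, with direction by the sign of the mean log2
fold change.

## Enrichment

ORA uses the one-sided hypergeometric upper tail of the foreground/set
overlap within a user-supplied background (sets intersected with the
background first; fewer than 3 foreground hits → untested).  GSEA ranks
features by decreasing log2 fold change and computes the weighted
running-sum score with weight `|log2fc|^w`, `w = 1`; the extrema of the
running sum occur only adjacent to hits, so scores are computed from hit
positions in O(m log m).  Significance is by gene-label permutation
(random same-size sets; phenotype permutation is impossible with a single
ranked list), p floored at `1/(n_perm+1)`, and the normalized score divides
by the mean |score| of same-sign permutations.  With all-equal fold changes
and `w = 0` the statistic reduces to the classic unweighted
Kolmogorov–Smirnov form (verified against an independent O(N) running-sum
implementation).  Identifier mapping between namespaces is out of scope:
gene sets must share the ID space of the results.  Category box-plot
summaries use Tukey conventions (box = quartiles, whiskers = most extreme
data within 1.5×IQR) with a two-sided Wilcoxon rank-sum test of each
category against all other proteins, BH-adjusted across categories.

## Synthetic experiments

The generator emulates the *quantitative structure* of a two-channel
labeled experiment, not mass spectra.  Defaults describe a realistic study:

| parameter | default | rationale |
|---|---|---|
| proteins | 1000 | desk-scale proteome slice |
| replicates | 4 biological × 2 technical | phospho-study design |
| peptide ratio noise | 0.25 (log2 sd) | typical H/L replicate scatter |
| biological variation | 0.05 (log2 sd, shared per protein×replicate) | condition-level noise |
| detected peptides/protein | 1 + Poisson(4), max 10 | dispersed counts; many low-evidence proteins |
| regulated category | 50-protein OXPHOS-like, log2FC ~ N(−1, 0.2) | concentrated ~2-fold loss |
| phosphosites | Poisson(2) per protein on S/T/Y; 20% with ±1 occupancy shift | site-level truth |
| localization mixture | 80% confident (> 0.75), 20% ambiguous | exercises the strict filter |
| contaminants / decoys | 2% / 1% of rows | exercises flag filtering |
| missingness | logistic in log2 intensity, max 30%, midpoint 16 | missing-not-at-random at low intensity |
| turnover regimes | adult medians: bulk 0.043/d, ribosome 0.052/d, OXPHOS 0.014/d; larval ×20 | ~45% bulk labeling at day 14; ribosome fast, OXPHOS slow; larvae ≳97% by day 4 |
| time course | days 0–14 in 2-day steps, n = 2, channel noise 0.02 (log2 sd) | pulse design |

Sequences are random over the 20 standard residues with lysine at 7%
(Lys-C peptides average ~14 residues); digestion uses Lys-C/P (cleaves
after K, including before proline) with up to two missed cleavages, and a
7–40 residue observability window.  Per-peptide yields are fixed log-normal
factors; per-site noise scales are drawn log-normally because site-level
measurement error is heterogeneous in real data — a structureless constant
variance would make empirical-Bayes moderation degenerate, which real
tables never are.

Not emulated: spectra, retention time, fractionation chemistry, ionization
competition, ratio compression, arginine labeling or proline conversion
(the Lys-only design avoids it), and shared peptides between protein
groups.  Passing recovery tests therefore demonstrates correctness of the
downstream arithmetic and statistics under a faithful noise model — not
robustness to search-engine artifacts.

Determinism: one `numpy` generator seeded from the ground truth drives all
draws in fixed order, and floats are serialized as shortest round-tripping
decimals, so identical ground truth yields byte-identical tables on any
platform with IEEE-754 doubles.

## Pipeline and recovery scoring

Each run writes one directory per stage, a machine-readable
`summary.json`, a JSON-lines log of every filtering/normalization decision
(no timestamps — reruns are byte-identical), and a copy of the config.
Stages communicate only through documented files, so the pipeline restarts
at any stage.  With a ground truth supplied, `score_recovery` reports:
fold-change MAE (< 0.1), turnover median relative error (< 5%), occupancy
bias (< 0.05), realized FDR (≤ 0.1) and sensitivity (≥ 0.8) at the default
thresholds.  Noise-free simulations recover every fold change,
incorporation fraction, and occupancy change to machine precision, which
pins the arithmetic; the noisy tolerances pin the statistics.

Problem sizes in the test and acceptance runs (200–1000 proteins, 2000
features for calibration, 20×1000-permutation enrichment runs) were chosen
as the smallest sizes at which the binomial/KS checks have meaningful
resolution.

## Known limitations

- Median-ratio normalization biases fold changes when a majority of the
  proteome shifts in one direction (see above).
- One protein group = one protein in the simulator; razor/shared-peptide
  ambiguity is untested.
- The occupancy definition is relative, not absolute stoichiometry.
- GSEA on degenerate rankings (many exactly tied fold changes, e.g.
  noise-free simulations) is meaningless: ties are broken
  deterministically by identifier and zero weights collapse the statistic
  to its unweighted form.
- The turnover model ignores precursor-pool kinetics; fitted rates are
  apparent rates.
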