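# Methods

## Coordinate system and data model

All positional computations run on **gene ordinals** — the 1-based rank of
a gene along its chromosome — not base pairs. The landscape statistics
(100-gene windows, contiguous-gene region calls) are defined in gene
units, so ordinals are the native coordinate; BED export maps a closed
ordinal interval [s, e] to the 0-based half-open interval [s−1, e), and
the convention is stated in a header comment of every BED file. Within a
chromosome, ordinals must form 1..n with no gaps; readers enforce this.

Small-secreted-protein (SSP) status is derived, never stored:
`is_secreted AND protein_length < 250` aa, with the 250-aa cutoff a single
configuration constant. Category labels (Pfam accessions, GO ids, class
tags, secondary-metabolite cluster ids) are treated as flat strings; GO
terms are **not** propagated up the ontology graph — enrichment operates
on the annotations exactly as provided.

## Versatility assignment

Versatility is proxied by the number of genus-level homolog hits *h*
(self-hit included, so *h* ≥ 1). Classification:

- **core** — gene has an ortholog in a distantly related ascomycete
  (membership list is an input). Core status takes precedence over the hit
  count: orthology is the stronger, direct criterion, so a core gene with
  *h* = 1 is still core.
- **orphan** — non-core gene with *h* = 1.
- **remaining** — everything else, ranked by ascending *h* into `n_bins`
  (default 10) bins.

Bin occupancies are ⌊n/b⌋ or ⌈n/b⌉ with the larger bins first, which for
6,698 genes in 10 bins gives eight bins of 670 and two of 669 (modal
occupancy 670). Hit-count ties at a bin boundary are split
deterministically by lexicographic gene id; a `keep_ties_together` flag
instead assigns a whole tie-run to the bin owning its midpoint, at the
price of unequal occupancy. The versatility index is 0 (orphan), the bin
number, or `n_bins`+1 (core). The hit-count table is assumed to be already
collapsed to one count per genus; the package does not re-collapse.

## Response sets

An up (down) set at threshold *t* and significance α is
{log₂FC > +*t* and p < α} ({log₂FC < −*t* and p < α}) with **strict**
inequalities on both sides; a gene at exactly log₂FC = *t* is excluded.
Thresholds are taken on the log₂ scale throughout the library; because
fold-change cutoffs are quoted on both linear and log scales in this
field, the CLI exposes `--min-log2fc` and `--min-fc` (converted as log₂)
as mutually exclusive flags, defaulting to log₂FC > 2, p < 0.01. Time
points are pooled by set union with provenance recorded in the label.

Overlap statistics:

- `venn` — exhaustive mutually exclusive region counts for 2 or 3
  same-direction sets; counts sum to the union size and reconstruct each
  input size.
- `specific_fraction(A, B)` = 100·|A∖B|/|A|; undefined (NaN, logged) for
  empty A. The identity `specific + 100·|A∩B|/|A| = 100` holds exactly.
- `overlap_test` — 2×2 [both, A only, B only, neither] over an **explicit
  universe size**. The universe is always a parameter because enrichment
  denominators are analysis-specific and no single constant is correct for
  every table; fold = observed / (|A|·|B|/universe). Two-tailed Fisher
  exact by default; χ² (with continuity correction) available.
- `magnitude_bias` — per shared gene, compare |log₂FC| between two
  conditions; ties counted separately and excluded from the test. Default
  test: two-sided binomial sign test of greater-in-A against 1/2. A
  Fisher-on-counts variant (observed split vs an even split) is provided
  behind a flag because such comparisons are sometimes quoted as Fisher
  tests without the table being specified.
- `fc_concordance` — Spearman by default (rank-based, robust to the heavy
  tails of fold-change distributions); Pearson available.
- `threshold_profile_overlap` — rebuilds each condition's set at every
  threshold of an ascending list and reports the percentage also present
  in a fixed reference set (e.g. the VI response at base thresholds), with
  a Fisher p per row; empty sets are flagged (`is_empty`), not dropped.

p-values of 0 are never reported as 0 in formatted output; anything below
the smallest representable positive double prints as `<1e-300`.

## Chromosomal landscapes

Windows of `window` genes (default 100) advance by `step` (default 1; the
original analysis does not state a step, and step 1 is the maximal
resolution). Per window: arithmetic mean versatility index and, per
condition, the fraction of window genes in the up set. Window means are
computed by cumulative sums and satisfy the rolling-update identity to
1e-9.

Region calling is per chromosome: threshold = mean − SD (troughs, on the
mean-index track) or mean + SD (hotspots, on the up-fraction track) of
that chromosome's window values. Qualifying windows are expanded to their
gene spans, overlapping/adjacent spans merged, regions spanning fewer than
`min_run` genes (default 5, chosen to suppress single-window noise)
dropped, and survivors labelled alphabetically genome-wide by position.
The default mode applies the threshold to window means (matching how the
tracks are plotted); a `gene` mode applies it to raw per-gene indices with
runs of consecutive genes, which is sharper for block-shaped implants and
is what the permutation tests use to demonstrate that the statistic
detects spatial clustering rather than composition. A zero-variance
chromosome yields no regions, with a warning.

Because the threshold is relative (mean ∓ SD), *some* windows qualify on
any non-degenerate chromosome; calls are therefore meaningful as the
locations of the most extreme runs, and window-mode boundaries are blurred
by up to one window length on each side. Trough–hotspot coincidence
requires ≥ `min_overlap` shared genes (default 1) with a hotspot of at
least one condition. A region is flagged sub/telomeric when it lies
within `telomere_margin` genes (default 100) of a chromosome end; no
positional annotation beyond gene rank is used.

## Enrichment

Fold = (observed/|set|)/(category/universe); two-tailed Fisher exact on
the corresponding 2×2. Depletions (fold < 1) are reported with the same
two-tailed p, not suppressed. Every multi-row table carries a
Benjamini–Hochberg adjusted p column alongside the raw p, as standard
practice even where original analyses quote raw thresholds only.
Threshold sweeps rebuild the response set per threshold, so observed
counts are non-increasing by set nesting. Secondary-metabolite summaries
report per-cluster up counts, the number of clusters with ≥1 and ≥3
up-regulated genes, and Fisher enrichment of the pooled cluster gene set.
The up-vs-down bias test is a two-sided binomial test of the up count
against 1/2 of the regulated category genes (genes in both pooled sets
are excluded); binomial was chosen because the corresponding published
test construction is not identifiable, and the Fisher machinery remains
available through `overlap_test` for users who prefer a 2×2 formulation.

## Orthology

Best hits are chosen by highest bitscore, then lowest e-value, then
lexicographically smallest subject id — a fully deterministic rule,
because similarity-search output order is not reproducible; resolved ties
are logged. RBH pairs require mutual best hits; the output is symmetric
under swapping the input tables and no gene occurs in two pairs.
Cross-species overlap counts ortholog pairs regulated in both species;
the expected count under independence is |A∩pairs|·|B∩pairs|/n_orthologs
over the ortholog-pair universe (the natural choice; other denominators
are not reconstructable in general, so per-cell folds from other sources
are not comparison targets). The down/up ratio is
(down_overlap/down_total)/(up_overlap/up_total), reported to one decimal,
with a two-tailed Fisher test on the corresponding 2×2 (shared with the
generic overlap machinery).

## Synthetic-data generator

The generator is first-class, tested code; its defaults **are** the study
conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes / n_chrom | 10,635 / 7 | genome size and chromosome count |
| n_core / n_orphan | 3,297 / 640 | core and orphan genes (remaining: 6,698) |
| regions | 19 × 60 genes | implanted lineage-specific clusters, 8 telomeric |
| hotspot regions | 13 of 19 (+4 condition-specific) | clusters with implanted up-regulation density |
| pooled set sizes | 1,847/1,882 (VsSf), 1,668/1,615 (VsSm), 1,913/1,923 (VI) | up/down genes per condition |
| specific fractions | 211/1,668 up, 153/1,615 down | VsSm genes absent from VsSf |
| magnitude_ratio | 1.2 | VsSf over VsSm \|log₂FC\| on shared genes (direction is documented, the value is not; 1.2 is a moderate, clearly detectable bias) |
| vi_overlap_odds | 3 | VI sampling odds multiplier for bacterial-response genes |
| hotspot_boost | 6 | up-sampling weight multiplier inside hotspot regions |
| up/down index slopes | 0.8 / 1.6 | up weight rising as versatility falls; down weight rising with it |
| max \|log₂FC\| | 11.5 | cap, the largest value the emulated design reports |
| cond_correlation | unset | optional override: specific fractions = 1 − correlation (no published coefficient exists to match) |

Mechanics: regulated pools are weighted samples without replacement
(Gumbel top-k, equivalent to successive weighted draws); the VsSm pools
share genes with VsSf except for the configured specific fractions; VI
pools resample the bacterial pools at configurable odds; pooled sets are
split over the 2 h/6 h time points at the per-time-point sizes.
Magnitudes are floor-shifted folded Gaussians (floor 2.05, so every
regulated gene passes the strict default threshold), capped at 11.5;
bacterial magnitudes of genes shared with the VI pool are drawn from a
low range, producing the documented decay of the bacteria–VI overlap as
the fold-change threshold rises. SSP genes receive boosted up-weights and
scaled magnitudes in the bacterial conditions only; secondary-metabolite
cluster genes receive a milder up-weight boost in all conditions.
Unregulated genes draw log₂FC ~ N(0, 0.7) and uniform p, with one
deliberate coupling: a null gene that draws p < 0.012 keeps |log₂FC| ≤
1.9 (the common low-count case of significant-but-weak changes), so at
the default cutoffs the thresholded sets recover the truth pools exactly
and recovery tests measure the pipeline rather than generator noise.

Determinism: every output table uses its own RNG stream derived from the
master seed and a fixed label (CRC32), so adding a table never perturbs
existing ones and identical seeds give byte-identical files. The truth
object (JSON) records parameters, implanted regions, category gene lists,
regulated pools and the ortholog map — sufficient to recompute every
expected summary without re-reading the generated tables.

What the generator does **not** emulate: read-level noise and dispersion
(log₂FC and p are drawn directly, not estimated from counts), realistic
sequence content, annotation errors, correlated category memberships, or
inter-replicate variability. Passing tests therefore demonstrate that the
statistics and region calls are implemented correctly and are calibrated
under their stated nulls — not that they would be robust to the full
error structure of real RNA-seq.

## Numerical and design choices

- Exact tests via `scipy.stats` (`fisher_exact`, `binomtest`,
  `chi2_contingency`); BH adjustment via `statsmodels`. The test suite
  cross-checks Fisher p against an independent hypergeometric enumeration
  oracle on all 2×2 tables with total ≤ 60.
- Undefined quantities (empty reference set, empty category, zero
  variance, zero expected count) return NaN with a logged warning rather
  than raising, so batch reports can render them; genuine contract
  violations (p ∉ [0,1], duplicate ordinals, inconsistent counts) raise.
- Test problem sizes: the full-size synthetic genome (10,635 genes) for
  landscape and recovery checks, 1,200–2,000-gene genomes elsewhere;
  the null-calibration check uses 1,000-gene sets in a 10,000-gene
  universe over 50 seeds, where the fold's Monte-Carlo error is small
  enough to resolve a ±0.1 band around 1.
- CLI exit codes: 0 success, 1 user/configuration error, 2 internal
  error; every run writes a manifest with config echo, input checksums
  and stage timings, and `report` is a pure function of the output files.

## Known limitations

- Window-mode region boundaries carry up to one window of edge blur;
  sub-window features are invisible at the default resolution.
- The relative (mean ∓ SD) calling rule adapts to each chromosome, which
  is the point, but means region *counts* are not comparable across
  datasets with very different variance structure.
- Enrichment treats annotations as flat labels; ontology-aware
  propagation and annotation uncertainty are out of scope.
- RBH is similarity-only; paralog confusion and synteny are not modelled.
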