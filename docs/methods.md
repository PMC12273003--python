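# Methods

This note documents the models, parameters and numerical choices behind
psiquant, and what the synthetic experiments do and do not establish.

## 1. The BID-seq signal model and site calling

BID-seq converts pseudouridine (Ψ) into a reverse-transcription deletion.
For a site modified on a fraction *f* of transcript copies, the observed
deletion ("gap") ratio is a monotone function of *f*; spike-in calibration
inverts it. The calling procedure:

1. **Replicate combination.** Total and deletion read counts are summed per
   (reference, position, strand) across replicates of one tissue; positions
   absent from a replicate contribute zero.
2. **Background estimation.** The background deletion rate is the median gap
   ratio over non-uridine reference positions with depth ≥ `min_depth`,
   floored at 10⁻⁴ so the test stays defined on deletion-free data. A global
   per-dataset background is used; sequence-context-specific backgrounds are
   out of scope.
3. **Testing.** Every uridine position with depth ≥ `min_depth` gets a
   one-sided upper-tail binomial p-value against the background rate;
   Benjamini–Hochberg adjustment runs across all tested candidates of the
   dataset.
4. **Filtering.** Sites are kept when q ≤ `q_cutoff` (0.05), deletion reads
   ≥ `min_deletion_reads` (5) and gap ratio ≥ `min_gap_ratio` (0.02).
   Comparisons at thresholds are inclusive (a site exactly at a threshold
   passes). Defaults are deliberately permissive and configurable.
5. **Calibration.** The gap ratio is mapped to stoichiometry through a
   monotone piecewise-linear curve through user-supplied control points
   (first point (0, 0), last fraction 1.0; inputs beyond the last control
   point clamp to 1.0). No parametric functional form is fitted. With the
   identity curve the reported fraction equals the gap ratio exactly, which
   the tests exploit as a limit case. The calibration does not subtract the
   background rate, so reported fractions carry an additive bias of roughly
   the background (1% at defaults) — small against the binomial noise at
   the depths targeted, and documented rather than corrected to keep the
   inverse map monotone.

Coordinates are 1-based inclusive in every TSV (rRNA site nomenclature such
as 23S:Ψ2702 is 1-based); BED6/bedGraph exports are 0-based half-open with
score = round(1000 × fraction). Deletions longer than 1 nt are counted as
one gapped read upstream of this package (pileups are its input).

## 2. Conservation

Orthologous gene pairs are aligned with a hand-written Smith–Waterman local
aligner (linear gaps; defaults match +2, mismatch −1, gap −2 — the scoring
is configurable since only the algorithm, not its parameters, is canonical).
Cell-level ties prefer diagonal, then up, then left, and the optimum is the
first maximal cell in row-major order; this makes tracebacks deterministic
and testable. Each queried Ψ (uridine) position in species A maps through
the alignment columns to its partner base in species B:

* no partner aligns a base (outside the local window, or a gap) → **Class 1**;
* bases align but none is U → **Class 2**;
* exactly one partner carries an aligned U → **Class 3**;
* two or more partners (one-to-many orthology) carry aligned U → **Class 4**.

Classes 3–4 count as conserved. Matching is exact-column: no flanking-window
tolerance is allowed around the aligned position.

MSA conservation scores are per-column mean pairwise identity among non-gap
pairs (columns with fewer than two bases score 0), smoothed with a centred
moving average (default width 50 columns — the display smoothing width is
not canonical, so it is exposed) and min–max scaled; a constant track scales
to all zeros with a warning. Ψ density and conservation are compared per
non-overlapping window (Pearson, two-sided t-transform p). MSAs are inputs
(aligned FASTA); the bundled centre-star aligner exists only to build small
synthetic fixtures and is not a production MSA method.

## 3. Translation efficiency

Footprint reads are filtered to 29–35 nt (inclusive) and assigned to a
P-site by a fixed offset from the 5′ end (default 12 nt, configurable —
different protocols imply different offsets, and ORF/phase inference is out
of scope; annotated CDS coordinates are trusted instead). TPM is the
abundance unit throughout; `E_transcript = TPM_ribo / TPM_RNA` restricted to
transcripts with both values ≥ `min_tpm` (default 1).

Codon dwell: per gene, P-site counts are summed over each codon's three
nucleotides and divided by the gene's mean codon coverage, so per-gene
relative coverages average 1 by construction and the statistic is invariant
to global count rescaling. Five codons at each CDS end (always covering
start and stop) are trimmed to avoid initiation/termination occupancy
artefacts; genes below a mean codon coverage of 0.5 are excluded. Across
genes, each codon occurrence is weighted by the gene's RNA TPM (an
unweighted mean is available). `E_codon = 1 / dwell`.

## 4. Statistics layer

* **Site–TE correlations.** One Pearson r per (site, transcript) over the
  tissues where both are measured (≥ 3 required; zero-variance series are
  skipped and logged). The per-site summary is the **median r over
  transcripts**, and the headline tally is the share of sites with
  positive vs negative median.
* **tRNA regions.** Each tRNA site carries a cloverleaf region label from an
  input model table (folding is not inferred from sequence); its fraction is
  correlated with `E_codon` of every codon its tRNA decodes. Records pool by
  region; the sign odds ratio is n_pos/n_neg (exact zeros excluded, infinite
  when n_neg = 0) with a one-tailed binomial p against 0.5.
* **Group analyses.** Transcripts are split into quantile groups of equal
  size ±1 on the summed Ψ fraction (ties broken by a stable sort on
  (value, transcript id), so group membership is reproducible). Lifetime
  uses 4 groups and tests one-tailed whether higher-Ψ groups live *shorter*;
  TE uses tertiles and tests one-tailed whether higher-Ψ groups translate
  *better*; a strata argument re-runs the TE analysis per site-location
  stratum (e.g. 5′-UTR vs non-5′-UTR). Raw one-tailed p-values are reported
  with BH-adjusted q alongside.
* **Rank-sum test.** Exact by full enumeration of rank assignments
  (midranks under ties) for combined n ≤ 12; otherwise the normal
  approximation with tie correction and continuity correction. The exact
  path is property-tested against an independent exact implementation.
* **Gene features.** Relative 5′-UTR length is UTR5/CDS length;
  transcripts with zero-length CDS are excluded.

Where an analysis admits two readings (per-gene correlations pooled into
groups vs per-group correlation), the per-gene-then-pool form is the default
and the other is reachable by composing the primitives.

## 5. The synthetic-data generator

The generator emulates the statistical structure of a multi-tissue BID-seq +
polysome-profiling survey. Default study conditions (all in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 60 | transcripts (5′-UTR 30–150 nt, CDS 300–900 nt, 3′-UTR 60–240 nt) |
| `n_tissues`, `n_replicates` | 9, 2 | a nine-organ survey, two BID-seq replicates |
| `psi_site_rate` | 0.017 | per-uridine planting probability → ~200 sites |
| fraction mixture | 0.78·Beta(1.2, 12) + 0.22·Beta(5, 2) | >2/3 of planted stoichiometries below 0.2, a minority above 0.5 |
| `share_all_tissues` / `share_unique` | 0.30 / 0.30 | tissue-shared vs tissue-unique sites; the rest partial |
| `background_deletion_rate` | 0.01 | position-independent |
| depth | NB(mean 1000, dispersion 10) | per-position read depth |
| `dwell_range` | [0.5, 2] | planted per-codon dwell times (log-uniform) |
| `footprint_reads_per_codon` | 20 | mean footprint depth |
| `dwell_noise_sd` | 0.15 | lognormal per-codon-occurrence noise |
| `lifetime_effect` / `te_effect` | −0.5 / +0.5 | slopes of log-lifetime / log-TE on summed Ψ fraction |
| `trna_loop_coupling` | 1.0 | T-arm-loop→codon coupling (anticodon/D loops at half strength, stems 0) |

Deletion counts are Binomial(depth, g(f) + bg) at planted sites (g the
inverse calibration) and Binomial(depth, bg) elsewhere. One global seed
feeds hierarchical per-(tissue, replicate) streams, so adding a replicate
never perturbs existing ones, and every output is bit-reproducible from
seed + config.

The tRNA complement is a 45-member set over the 61 sense codons (G34
anticodons wobble-decode the third-base C and U codons, everything else
one-to-one), each 76 nt with canonical cloverleaf region labels; linker
positions 8, 9 and 26 are folded into the adjacent stems so the eight
region labels cover every position. One Ψ site is planted per structural
region per tRNA; loop-site stoichiometry deviations lower the decoded
codons' dwell times (T-arm loop at full strength, anticodon-arm and D-arm
loops at half), stems are uncoupled by construction and serve as negative
controls.

Group analyses of lifetime and TE are exercised at 1,800 transcripts — the
scale of a genome-wide lifetime survey — by raising `n_genes` for those
runs only; sequence-level stages keep the 60-gene default, which already
yields ~200 planted sites.

**What the generator does not model:** read-level artefacts (adapters, UMIs,
alignment errors), sequence-context-dependent backgrounds, isoform
structure and splicing (transcripts are intron-free; exon/intron labelling
is supported for annotations that provide it), rRNA depletion, ribosome
phasing and fraction-specific polysome structure. Passing tests therefore
show that the estimators recover their own generative model at realistic
depths and effect sizes — not that real libraries are free of the artefacts
listed.

## 6. Null calibration

Two checks guard the correlation layer against optimistic bias. With all
planted couplings at zero, (a) the share of sites with positive median r
must sit in the central 99% binomial band around 0.5, and (b) the sign-odds
ratio's one-tailed binomial p must be super-uniform at level 0.05. For (b),
with 21 continuous correlation records the positive count is exactly
Binomial(21, ½) under the null and the level-0.05 rejection region is
n_pos ≥ 15, an event of probability 0.0392 — super-uniformity holds
analytically, and a 200-replicate simulation is checked against the
one-sided 99.5% binomial acceptance bound for a 5% rate (a raw Monte-Carlo
estimate fluctuates ±0.014 around the true rate and is not itself the
quantity the property constrains).

## 7. Known limitations

* The Smith–Waterman implementation is a clarity-first O(nm) Python loop;
  it is exact and deterministic but not suited to chromosome-scale inputs
  (gene-scale sequences take well under a second).
* Calibration curves are interpolated, not fitted; users must supply
  spike-in control points when gap ratios saturate below 1.
* The background deletion rate is global; per-motif backgrounds would
  sharpen calling near the detection limit.
* `E_transcript` from protein/RNA abundance ratios is supported only as
  precomputed input tables; no mass-spectrometry processing is included.
* Tissue-unique sites are defined by strict presence/absence at full
  calling thresholds; a site absent for lack of coverage is not
  distinguished statistically (coverage gating happens upstream at
  `min_depth`), and no differential-modification test is invented.
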