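# Methods

This note records the models, conventions and numerical choices behind the
package, in the spirit of a statistical methods appendix.

## Contig curation

**Pipeline order.** Size selection (drop < 1 kb), circularity detection,
keep-longer dereplication, then the four-criterion admission rule. The size
floor is re-applied after the circular terminal repeat is trimmed, so a
contig whose trimmed genome falls below 1 kb never enters the database;
this makes `curate()` idempotent (re-running on its own output is the
identity).

**Circularity.** An assembler walking a circular genome ends where it
began, so the linearized contig carries an exact terminal direct repeat. We
call a contig circular iff its longest exact prefix-equals-suffix overlap
(the longest border, computed with the KMP prefix function in O(L)) has
length k with `min_terminal_repeat ≤ k < L/2`, and then trim the duplicated
suffix. The default floor of 20 bp makes chance calls vanishingly rare: a
random linear contig of length L has probability ≈ L·4⁻²⁰ < 10⁻⁷ of a
spurious ≥ 20 bp terminal repeat. Borders ≥ L/2 indicate tandem-repeat
artefacts, not circles, and are left uncalled. Real circularity tests vary
between assemblers; the exact-repeat criterion is the package's own,
chosen because it is fully specified and testable against planted truth.

**Pairwise identity.** For pairs where both contigs are ≤ 20 kb we use
exact local dynamic programming (match +1, mismatch −1, gap open −2, gap
extend −1; Biopython's PairwiseAligner) and report matches / alignment
columns plus the aligned span as a fraction of the shorter contig. Above
20 kb we switch to an infix (containment) alignment of the shorter contig
into the longer via edlib, which finds the exact minimum-edit-distance
placement in near-linear time; the two modes agree within 0.01 identity on
contained pairs. "90 % of their length" in the dereplication rule is read
as 90 % of the *shorter* contig: the longer contig survives, so containment
of the shorter is the operative condition.

**Dereplication.** A single greedy pass over contigs sorted by length
descending (ties broken lexicographically by id); a contig is dropped iff
it matches an already retained contig at ≥ 90 % identity over ≥ 90 %
coverage. Sorting internally makes the result invariant to input order,
and on small instances the greedy pass provably equals brute-force
longest-first elimination. A cheap edlib edit-distance screen (a pair
meeting identity i over coverage c has infix edit distance ≤ ((1−i)+(1−c))
of the shorter's length; we use twice that bound as a safety margin) skips
the exact alignment for obviously unrelated pairs.

**Admission.** The four criteria are evaluated independently and any one
admits a contig: (A) external viral-prediction flag; (B) reference-virus
hit at ≥ 50 % identity over ≥ 90 % of the contig; (C) circular; (D) rescue
for novel sequence — length > 3 kb, coverage ≥ 10× and *no*
nucleotide-screen alignment > 100 nt with e-value below threshold. The
e-value threshold defaults to 1e-10; a 1e-5 variant of the same rule is in
circulation and is available via `CurationThresholds(nt_hit_evalue=1e-5)`.
Coverage comes from the contig record (assembler-reported); it is not
recomputed, since read mapping is outside this package's scope.

## Contamination estimation

A marker locus occupies the fraction `copies × L_marker / L_genome` of a
bacterial genome, so if a fraction r of all reads aligns to the marker, the
implied fraction of bacterial chromosomal DNA is `r / (copies × L_marker /
L_genome)` — linear in r, capped at 1 with a flag (heavily contaminated
samples routinely exceed unity because the conversion's assumptions are
coarse). Defaults: rRNA operon 5 kb × 4 copies, genome 4 Mb (so a 0.04 %
read fraction implies 8 % bacterial DNA); cpn60 universal target 558 bp
(midpoint of the 549–567 bp segment range) × 1 copy (0.00077 % implies
~5.5 %). Read fractions are taken at face value; reverse-transcribed rRNA
from co-purified ribosomes can inflate the rRNA-based estimate, which is
precisely why the single-copy cpn60 marker is carried alongside. Cohort
reports use medians and IQRs with linear interpolation between order
statistics, and flag any sample whose rRNA read fraction exceeds 0.02 %.

## Spike-in quantification

Under shotgun sequencing, a feature's expected read share is proportional
to its total nucleic acid, `N_i × L_i`. With a spike of known titre S and
genome length L_s, the expected spike read fraction is
`f = S·L_s / (S·L_s + Σ N_i·L_i)`. Two estimators invert this:

* equal-size: `N_total = S(1−f)/f`, exact when all genomes equal L_s. We
  use S(1−f)/f rather than S/f because the spike's own reads are not part
  of the endogenous pool; the difference is negligible for f ≤ 1 %.
* length-aware: `N_total = Σ_i S (c_i/c_s)(L_s/L_i)` with per-feature read
  counts c and lengths L; unbiased for heterogeneous genomes and reducing
  exactly to the equal-size form when all L_i = L_s. On communities with
  5–100 kb genomes the equal-size formula instead estimates the
  length-weighted total `Σ N_i L_i / L_s` — a bias the tests demonstrate.

Calibration regresses spike read *percentage* on titre in natural units
(ordinary least squares, unadjusted R²), matching how linearity of recovery
is assessed across a titre series; single-titre use at 10⁶ pfu/g is the
recommended operating point. A spike recovering zero reads raises
`SpikeDropoutError` — the load is inestimable, never numeric (the fate of
an RNA phage spike under a DNA-virome protocol). Load summaries report mean
± sample SD of log10 loads across calibration points or replicates; a
single point is flagged `sd_undefined`.

At low titre the spike read count is small (10⁵ pfu/g against a 10¹⁰/g
community at 10⁶ reads yields ~10 spike reads), so per-sample estimates
carry ~±0.14 log10 of Poisson noise. The spike-recovery check therefore
simulates 10 replicate samples per titre and estimates each level's load
from the pooled spike fraction, which brings the error within ±0.1 log10.

## Ecology statistics

**Spearman distance.** d = 1 − ρ on per-sample relative abundances, with
average ranks for ties (essential for sparse counts); range [0, 2].
Rank-based, hence invariant to per-sample scaling and any strictly
monotone transform; computing on relative abundances rather than raw
counts only affects tie structure. Constant profiles have undefined rank
correlation and are reported as errors naming the sample.

**PCoA.** Classical Torgerson scaling: eigendecomposition of the
double-centred −½D². 1 − ρ is not guaranteed Euclidean, so negative
eigenvalues can occur; they are retained in the eigenvalue report but
excluded from coordinates, and proportion explained is relative to the
positive eigenvalue sum. On genuinely Euclidean inputs the coordinates
reproduce the distances to 1e-9.

**PERMANOVA.** McArdle–Anderson formulation on the Gower-centred matrix
G = −½ C D² C: factors are added in the user-given order as dummy-coded
columns, sequential (Type I) SS per factor is the increment in tr(H G)
across nested hat matrices, and pseudo-F_k = (SS_k/df_k)/(SS_res/df_res).
Sequential R² values plus residual R² sum to 1 by construction, so factor
order is part of the declared analysis; a marginal mode (each factor fitted
alone) is available for comparison but forfeits additivity. p-values
permute whole rows/columns of D with the (count + 1)/(n_perm + 1)
estimator — p = 0.001 is the smallest attainable value at 1000
permutations — or enumerate all n! permutations exactly on small designs
(`n_permutations="exact"`, no +1 correction). With strongly non-Euclidean
distances and near noise-free clustering the residual mean square can reach
zero or below; the pseudo-F is then off-scale and reported as `inf`, while
R² and permutation p remain well defined.

**Alpha diversity.** Shannon entropy with natural log (base configurable);
Chao1 in its classic form S_obs + F1²/(2F2), switching to the
bias-corrected S_obs + F1(F1−1)/2 when no doubletons exist.

**Group comparisons.** Within- vs between-subject distance sets are
compared with a two-sided Mann-Whitney U (exact enumeration when both sets
have ≤ 8 untied values, tie-corrected normal approximation otherwise);
multi-group comparisons use Kruskal-Wallis with tie correction, delegating
to Mann-Whitney at two groups. All-equal observations are flagged
degenerate (H = 0, p = 1) rather than erroring.

## Synthetic data generator

The generator produces the statistical structure the analyses assume, not
sequencing reads. Per-feature community log-abundances are standard normal;
each donor draws a per-feature offset (sd `donor_effect_sd`), each
treatment level and operator a per-feature offset (sds
`treatment_effect_sd`, `operator_effect_sd`), and each sample adds
independent noise (sd `noise_sd`), all on the natural-log scale. Reads are
multinomial with probabilities ∝ abundance × genome length — the assumption
under which the equal-size load formula is exact. Genome lengths are
log-uniform on 3–100 kb. Defaults (4 donors × 6 samples, 150 features,
donor 1.0 / treatment 0.3 / noise 0.2, 10⁵ reads) encode a donor-dominant
storage-style design: under them the donor R² exceeds the treatment R² in
essentially every replicate, the qualitative pattern such experiments
report. Effect sizes for storage/operator perturbations are calibration
knobs, not estimates from any real dataset.

Contig fixtures plant circular genomes by rotating a random sequence to a
random cut position and appending the first k bases (k uniform on
[min_repeat, 2·min_repeat], exercising the detector threshold); linear
fixtures are plain random sequence. Size classes default to those seen in
gut phageome assemblies (1–3 kb plasmid-like, ~5 kb Gokushovirinae,
~6.3 kb other Microviridae, 38–46 kb temperate Caudovirales, 94–101 kb
crAssphage-like). MDA's over-amplification of small circular ssDNA genomes
is not simulated by default — no quantitative model of it is established —
but a per-class multiplicative coverage bias hook (`class_bias`) is
exposed.

What the generator does **not** emulate: sequence-level read errors,
chimeras, uneven coverage along genomes, compositional zero-inflation
beyond multinomial sampling, or MDA bias by default. Tests passing on this
generator therefore validate the estimators' mathematics and determinism,
not robustness to those real-data artefacts.

## Problem sizes and reproducibility

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical outputs.
The test suite runs at desk scale: curation correctness uses 200 planted
contigs across the five size classes and 100 random dereplication
instances of ≤ 10 contigs; PERMANOVA exactness enumerates all 8! label
permutations and calibrates the null over 500 replicates at n = 10;
spike recovery uses 10 replicate samples of 10⁶ reads at each of three
titres. Experiment-scale quantities from real sequencing runs (donor-level
R² values, contig counts, read recruitment rates, per-donor absolute
loads) depend on the underlying data and are covered qualitatively by the
parameter-recovery properties rather than numerically.

## Known limitations

* The circularity detector requires an *exact* terminal repeat; assembler
  mismatches at contig ends would need a relaxed matching mode.
* The contamination conversion assumes a single genome size and copy
  number for the whole community; it is a first-order screening statistic,
  not a per-taxon decomposition.
* PERMANOVA permutes raw labels (no restricted/strata permutation), so
  nested designs are tested against the fully exchangeable null.
* The length-aware load estimator propagates no uncertainty from the
  per-feature counts; only the spike count's sampling noise is reflected
  in the replicate SD.
* Differential-abundance analysis is intentionally not re-implemented; an
  externally produced results table can be joined to the report outputs.
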