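# phageome

Computational pipeline for shotgun metagenomic profiling of human faecal
phageomes (the bacteriophage fraction of the gut virome). It implements the
analysis stages that follow read QC, assembly and mapping — which are
delegated to external tools whose outputs (contig FASTA, evidence tables,
count tables) this package consumes:

* **Viral contig curation** — size selection, circular-contig detection via
  exact terminal direct repeats, keep-longer dereplication (≥ 90 % identity
  over ≥ 90 % of the shorter contig), and a four-criterion admission rule
  (external viral prediction ∨ reference-virus similarity ∨ circularity ∨ a
  rescue rule for novel contigs: > 3 kb, ≥ 10× coverage, no long significant
  nucleotide-database hit), with a per-contig audit trail.
* **Bacterial contamination estimation** — converts the fraction of reads
  aligning to a marker locus into the implied fraction of bacterial
  chromosomal DNA: `bacterial_fraction = read_fraction / (copies × L_marker / L_genome)`.
  Bundled models: the rRNA operon (~5 kb × 4 copies per ~4 Mb genome) and the
  single-copy 549–567 bp cpn60 universal-target segment. Samples above the
  0.02 % rRNA read-fraction screening threshold are flagged.
* **Spike-in absolute quantification** — an exogenous phage (lactococcal
  phage Q33, 31.1 kb genome) added at known titre *S* (pfu/g) calibrates
  total viral load from its read fraction *f*: `N_total = S(1 − f)/f` under
  equal genome sizes, with a length-aware variant
  `N_total = Σᵢ S (cᵢ/c_s)(L_s/Lᵢ)` when per-feature genome lengths are known.
* **Ecology statistics** — Spearman-rank β-diversity (d = 1 − ρ), classical
  PCoA, PERMANOVA with sequential (Type I) sums of squares and
  label-permutation p-values, Shannon/Chao1 α-diversity,
  within/between-subject distance comparisons (Mann-Whitney U) and
  Kruskal-Wallis group tests — the toolkit used to quantify donor
  individuality against storage, freeze-thaw and operator effects.
* **Synthetic data** — generators for donor-structured communities
  (log-normal donor baselines, multinomial read sampling weighted by
  abundance × genome length), size-classed circular/linear contig sets and
  spiked communities, each returning the full latent truth so every
  estimator can be scored against known ground truth.

## Worked example

```python
import numpy as np
from phageome import (CommunitySpec, generate_community, spearman_distance,
                      permanova, within_between_distances,
                      estimate_bacterial_fraction, RRNA_MODEL,
                      ParticleCommunity, spike_community, spike_fraction,
                      estimate_total_load, load_summary)

# a storage-style experiment: 4 donors x 6 samples, donor effects dominant
spec = CommunitySpec(noise_sd=0.5, seed=1)
matrix, metadata, truth = generate_community(spec)
d = spearman_distance(matrix)
res = permanova(d, {"donor": truth.donor_of_sample,
                    "treatment": truth.treatment_of_sample},
                n_permutations=999, seed=1)
print(res.to_frame().to_string(index=False))
```

```
   factor  df  sum_squares  r_squared   pseudo_f  p_value
    donor   3     1.820725   0.916898 198.972260    0.001
treatment   2     0.110115   0.055453  18.050404    0.001
 residual  18     0.054904   0.027649        NaN      NaN
```

Donor identity explains ~92 % of the β-diversity variance while the planted
treatment effect explains ~6 % — the donor-dominant clustering the
statistics are designed to resolve. Within-subject distances are much
smaller than between-subject ones:

```python
wb = within_between_distances(d, {m.sample_id: m.donor for m in metadata})
# within median 0.124, between median 0.466, p = 2.24e-32
```

Contamination and absolute load, on the same bundled models:

```python
estimate_bacterial_fraction(4e-4, RRNA_MODEL).fraction   # 0.08
# a 0.04% rRNA read fraction implies 8% bacterial chromosomal DNA

loads = []
for level, titre in enumerate((1e5, 1e6, 1e7)):
    comm = ParticleCommunity(np.full(100, 1e8), np.full(100, 31_100),
                             spike_titre=titre)            # true load 1e10/g
    row = spike_community(comm, 1_000_000, seed=level)
    loads.append(estimate_total_load(titre, spike_fraction(row, "sample0")))
est = load_summary(loads)
# total load: 10.09 +/- 0.12 log10 particles/g  (truth: 10.0)
```

## Command line

```bash
phageome --seed 1 simulate --out sim/
phageome curate --contigs contigs.fasta --evidence evidence.tsv --out curated/
phageome contam --fractions fractions.tsv --out report.tsv
phageome spike  --counts counts.tsv --lengths lengths.tsv --meta meta.tsv \
                --spike-id Q33 --out loads.tsv
phageome stats  --counts counts.tsv --lengths lengths.tsv --meta meta.tsv \
                --factors donor,treatment --permutations 999 --out stats/
```

Every subcommand writes a JSON run manifest (parameters, seed, input
checksums) alongside its outputs.

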