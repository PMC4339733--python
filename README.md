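# kmerbin

Taxonomy-independent binning of metagenomic shotgun reads.

Environmental sequencing mixes reads from many unknown microbial species.
`kmerbin` partitions such reads into species-level bins — and estimates how
many species are present, their relative abundances, sequencing coverages
and genome sizes — using only the reads themselves, with no reference
database. It is aimed at microbiome researchers working with simple
communities (a handful of dominant species) of either short Illumina-style
reads (75 bp paired-end) or long Sanger-style reads.

## The model

Two compositional signals separate reads from different species:

1. **k-mer frequency.** Count every canonical 16-mer across all reads.
   A k-mer from a species sequenced at k-mer coverage λ occurs
   approximately Poisson(λ) times, so the counts x₁…xₙ of the n distinct
   k-mers follow a mixture of m Poisson distributions with parameters
   θ = {α₁…α_m; λ₁…λ_m}, where α_j is the relative abundance and λ_j the
   k-mer coverage of species j. θ is fitted by EM on the count histogram:

   - E-step: Z_ij = α_j p(x_i; λ_j) / Σ_r α_r p(x_i; λ_r)
   - M-step: α_j = (1/n) Σ_i Z_ij,  λ_j = Σ_i Z_ij x_i / Σ_i Z_ij

   Counts of k-mers occurring 0–3 times are unobserved or inflated by
   sequencing errors, so they are iteratively replaced by truncated-Poisson
   estimates N_x = Σ_j p(x; λ_j)·T_j / (1 − Σ_{s≤3} p(s; λ_j)), where T_j is
   component j's responsibility mass over the reliable tail (x ≥ 4), and
   the EM is re-run until the estimates stabilise.

   m starts deliberately large (default 10). Each component's implied
   genome size Σ_i Z_ij x_i / λ_j is computed, components below 400 kb —
   smaller than the smallest sequenced free-living genome — are pruned,
   and the survivors are the predicted species.

2. **Markov (oligonucleotide) structure.** Reads are first assigned by the
   Poisson probabilities of their median k-mer frequency (with an adaptive
   probability-gap cutoff and paired-end consistency). Then a 5th-order
   Markov chain is trained on each bin's pooled 6-mer counts, every read is
   rescored under every chain, and reads are reassigned to their
   best-scoring bin when the score clears that bin's β-percentile cutoff
   (β = 10 %, halved each round) — iterated to a fixed point. This step is
   what separates species with *similar coverage* but different genome
   composition.

A built-in simulator generates multi-species shotgun datasets (genomes
sampled from distinct order-5 chains, uniform shotgun reads, optional 1 %
substitution errors) with per-read ground-truth labels.

## Worked example

```python
import kmerbin as kb

# simulate two 500 kb genomes at 5x and 10x genome coverage, 75 bp pairs
specs = [kb.SimulationSpec(genome_length=500_000, coverage=5,  chain_seed=11),
         kb.SimulationSpec(genome_length=500_000, coverage=10, chain_seed=22)]
sim = kb.simulate_metagenome(specs, seed=7)

results = kb.ReadBinner(sim.reads, m_init=10).fit()
print(results.summary())
print("accuracy:", kb.binning_accuracy(results.binning, sim.truth))
```

```
Taxonomy-independent read binning results
=========================================================
reads: 100000 (paired)    k: 16    initial m: 10
distinct 16-mers: 980668    occurrences: 6000000
predicted species number: 2
unassigned reads: 0 (0.0%)

 species  alpha kmer_coverage genome_size_em genome_size_final  n_reads
       0 0.5070          4.09        497,144           488,782    33332
       1 0.4930          8.07        490,171           495,681    66668

accuracy: 1.0
```

Reading the table: the binner started from m = 10 candidate components,
pruned eight sub-400 kb groups, and reports 2 species. The k-mer coverages
4.09 and 8.07 match the expected values (genome coverage × 60/75 = 4 and
8), the genome sizes are within ~2 % of the true 500 kb, and after Markov
refinement every read sits in the bin of its true species (accuracy 1.0).
`results.labels_frame()` gives the per-read labels; `results.save(dir)`
writes the report, a TSV per-species table, and one read-id list per bin.

The same pipeline is available from the shell:

```bash
kmerbin simulate --species 500000:5 --species 500000:10 --out-dir sim/
kmerbin bin -i sim/reads.fasta -r paired --interleaved -m 10 --out-dir out/
```

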