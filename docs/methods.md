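# Methods

This note documents the statistical model, the algorithmic and numerical
choices, and the limits of what the simulation-based tests demonstrate.

## Model

### Poisson mixture on the k-mer spectrum

All reads are decomposed into canonical k-mers (k = 16 by default; at that
length a random k-mer is very unlikely to recur by chance in a microbial
genome, so each distinct k-mer effectively tags one genomic locus).
Canonicalisation — counting a k-mer and its reverse complement as one key —
is essential because shotgun reads sample both strands; counting strands
separately would split each locus's coverage across two keys and break the
count model.

Under uniform shotgun sampling, the occurrence count of a genomic k-mer
from a species with k-mer coverage λ is approximately Poisson(λ), where
λ = genome coverage × (L − k + 1)/L for read length L. The counts of the
n distinct k-mers are therefore modelled as an m-component Poisson mixture
with abundances α and coverages λ, fitted by EM. Because the
responsibility of k-mer i depends only on its count x_i, the fit runs on
the weighted count histogram — algebraically identical to the per-k-mer
fit (a property verified against a brute-force per-k-mer implementation to
1e-12 per parameter per iteration) but O(#distinct counts × m) per
iteration instead of O(n × m).

EM details: initialisation α_j = 1/m, λ_j = 10j + 10; convergence when the
maximum absolute change over all 2m parameters falls below 1e-5 (the
criterion is stated only as a "small difference" in the method's source;
max-change is the strictest common reading); hard iteration cap 10,000.
All pmf arithmetic is in log space (x·lnλ − λ − lnΓ(x+1), log-sum-exp for
mixture densities), inlined rather than routed through scipy.stats because
it sits in the hot loop; equivalence with scipy's logpmf is tested.

### Correction of counts 0–3

Observed tallies at 1–3 occurrences are inflated by sequencing errors and
low-abundance species, and count 0 is unobservable. The correction
replaces the histogram weights at x = 0..3 with the truncated-Poisson
completion

    N_x = Σ_j p(x; λ_j) · T_j / (1 − Σ_{s=0..3} p(s; λ_j)),

where T_j = Σ_{x_i ≥ 4} Z_ij is component j's responsibility mass over the
reliably observed tail, recomputed from the current model. Estimation and
refitting alternate — each refit warm-starts from the previous model —
until the four estimates change by less than 0.5 k-mers (`tol_counts`;
"do not change" is the stated criterion, and sub-unit stability is the
natural resolution for counts), with an outer cap of 100 rounds. Raw
weights at x ≥ 4 are never altered; the x = 0 estimate enters the EM as a
histogram entry with pmf p(0; λ_j) and no sequence identity. On
zero-truncated single-component data this demonstrably reduces the upward
bias of λ̂ (tested at λ = 5 and 8).

Components whose truncation denominator 1 − P(X ≤ 3) falls below 1e-12
are skipped in the estimate (their extrapolation is pure noise); if every
component is degenerate the fit aborts with an error.

### Species number by genome-size pruning

A component's implied genome size is Σ_x w_x Z(x,j)·x / λ_j — the k-mer
occurrences it explains divided by its per-k-mer coverage, i.e. its count
of distinct genomic k-mers, reported as base pairs without the −k+1
correction. Starting from a deliberately generous m (default 10),
components implying less than 400,000 bp are discarded (strictly below:
exactly 400 kb survives), surviving α are renormalised, one extra E-step
redistributes the pruned components' k-mers, and the α-update is applied
once more with λ frozen. The survivor count is the predicted species
number. If nothing was pruned, a warning recommends retrying with a
slightly larger m.

### Initial read assignment

Each read is summarised by the median occurrence count x of its k-mers
(lower-middle convention on even counts, keeping the statistic an integer
so the pmf needs no interpolation). The evidence for species j is the raw
pmf p(x; λ_j) — deliberately not weighted by α and not normalised, which
makes the fixed gap cutoff C meaningful. The read is assigned to the
best species iff best − second-best > C, starting at C = 0.5 and lowering
by 0.01 (from scratch) while half or more of the reads remain unassigned;
at C = 0 the strictly-positive-gap assignment is accepted as is. Paired
mates must agree: a single assigned mate pulls in the other, and mates
confidently assigned to different bins are both unassigned. Reads shorter
than k, or with no N-free window, are unassigned, never errors.

### Markov-chain refinement

Each bin's reads (pooled with their reverse complements, so the model is
strand-neutral) yield 6-mer counts, giving a 5th-order transition matrix
with add-one pseudocounts and a stationary 5-mer context distribution.
A read's score under a chain is its average per-base log-likelihood —
log π(first context) counts for `order` bases, each transition for one —
maximised over the two strands. Length normalisation matters because the
percentile cutoff pools reads whose usable lengths may differ.

Per iteration: train a chain per non-empty bin; set each bin's cutoff to
the nearest-rank β-percentile of its own members' scores under its own
chain (β starts at 0.10 and halves every iteration); rescore every read —
including currently unassigned ones — under all chains; assign each read
to its best-scoring bin when the best score reaches that bin's cutoff;
reconcile mates; stop when the label map repeats or after `max_iter`
(default 25) rounds. Bins that empty out are dropped with a warning.

Two tie-break choices here are deliberate:

- **Ties at the cutoff stay assigned.** The nearest-rank percentile is
  exactly one member's score; rejecting ties would eject that member
  every round, so the labelling could never reach the fixed point the
  stopping rule looks for. Keeping ties preserves the ~β rejection rate
  and makes exact convergence attainable.
- **Mate conflicts follow the stronger mate.** In the refinement phase,
  mates assigned to different bins both move to the bin of the mate with
  the higher score (ties to the lower index) rather than both dropping to
  unassigned. When coverage heterogeneity or error k-mers split one
  genome across two bins — a documented behaviour of this family of
  methods — the two bins carry nearly identical chains and mates fall on
  either side at random; unassigning every such pair would discard a
  large fraction of that species' reads for no information gain. The
  initial phase keeps the strict both-unassigned rule, where the gap
  statistic carries no comparable strength signal. Pair consistency (both
  mates share one label) holds for every output either way.

Score ties between bins break toward the lower bin index, making reruns
byte-identical.

After convergence, each species' final genome size is the total number of
k-mer windows in its bin's reads divided by λ_j.

Model divergence between two trained chains is measured by the
symmetrised, stationary-weighted Kullback–Leibler divergence
½ Σ_c π_a(c) KL(t_a(c)‖t_b(c)) + ½ (a↔b), finite because pseudocounts keep
all probabilities positive.

## Synthetic data

The simulator stands in for read simulation from real genome assemblies,
which this package deliberately does not download. Each species' genome is
sampled from its own random order-5 Markov chain (Dirichlet(1) rows;
stationary distribution by power iteration), emulating the
genus/species-specific oligonucleotide composition that the refinement
step exploits. Reads are 75 bp paired-end by default (insert 300 bp, a
typical short-insert library), drawn uniformly from both strands at a
prescribed genome coverage, with optional i.i.d. per-base substitution
errors (1 % emulates a short-read error profile). Binning accuracy uses
the majority rule: each predicted bin maps to the species contributing
most of its reads (ties to the lower species index); unassigned reads
count as incorrect — the conservative convention.

What the simulator does *not* emulate: repeated sequence within and
between genomes (real genomes share k-mers; here collisions are
negligible), GC- and position-dependent coverage bias, indel errors,
quality-score structure, and position-dependent error rates (real
short-read errors concentrate at the 3′ end, which corrupts *fewer* k-mer
windows per error than the uniform model — the simulated 1 % setting is,
if anything, harsher). Passing tests therefore demonstrate correctness of
the method's machinery and its behaviour under its own model assumptions,
not performance on real libraries, where accuracy is genus-dependent and
lower.

Benchmark problem sizes were chosen at realistic bacterial scale while
keeping simulations quick: 0.9–1.5 Mb genomes at 4/8/16× coverage for
species-number recovery (~0.5 M reads), and two 500 kb genomes at 5×/10×
(100 k reads) for the refinement comparisons.

## Known limitations

- One genome sequenced at two very different depths (e.g. strain mixtures
  or coverage steps) can legitimately appear as two mixture components;
  if both halves exceed 400 kb they are reported as two species. The
  chain divergence of the resulting bins (`relative_entropy`) is the
  diagnostic.
- Heavy error load at low coverage can leave an error-k-mer component
  whose implied size exceeds 400 kb; it then typically converges into a
  duplicate bin of an existing species rather than a spurious one, but
  inflates the species count.
- The species number is bounded above by `m_init`; the tool warns, but
  does not automatically escalate, when no component could be pruned.
- Abundances α are fractions of *distinct k-mers*, which track genome
  size × presence, not cell counts.
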