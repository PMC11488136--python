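# Methods

## Model

### Reference database

Input is a pre-aligned FASTA of mitogenomes and a rooted Newick tree with
branch lengths in expected substitutions/site whose leaves match the
alignment records. Computing the alignment itself is out of scope; the
builder is deterministic given its inputs.

**Ancestral paths.** Every internal tree node receives an aligned sequence:
per column, the marginal maximum-likelihood base under the same HKY model
used downstream (conditional likelihoods by Felsenstein pruning, outside
probabilities by a pre-order pass, exact ties broken alphabetically), with
the gap/non-gap indicator reconstructed separately by Fitch parsimony (ties
resolved toward non-gap, so ancestors prefer to carry sequence). This is a
deliberately simple, testable reconstruction — production pipelines use
heavier tools — and its fidelity degrades with divergence; see
Limitations.

**Graph construction.** Maximal runs of alignment columns that induce the
same partition of records (grouping by residue, gap as its own group)
collapse into one graph node per distinct non-gap allele; each record
becomes one path, and edges follow adjacency of consecutive non-gap
characters. The only property the likelihood needs is the path-spelling
identity — every path spells its degapped record exactly — which is
enforced by construction and property-tested; any construction rule with
that property would be admissible. Node offsets are 0-based, intervals
half-open, sequences treated as linear (users with fragments spanning the
circular junction should rotate their references).

**Signature index.** A signature node is traversed by exactly one path; the
per-path signature sets are pairwise disjoint by construction. The fraction
of aligned fragments touching each set estimates that source's visibility
and seeds both the source count k₀ (sets with >1% of aligned fragments;
floor 1) and the chain initialisation.

### Alignment

Each fragment is aligned in both orientations against every path with
affine-gap local alignment (match +1, mismatch −1, first gap position −2,
each further −1; all configurable). Best-per-path alignment is exact for
path-realizable alignments, which is what a mitogenome-sized graph
produces; there is no seed-and-extend heuristic. Scores come from a
compiled Smith–Waterman–Gotoh scan over all path/strand pairs; the single
winner is retraced with Biopython's PairwiseAligner under identical scoring
(on a window bounded by the scan's end position, with a full-path fallback
guarded by a score-equality assertion). Ties break by tree pre-order of the
path's node, then forward strand. Fragments scoring below 0.8 × read length
(configurable) are unmapped. Only the single best alignment is kept;
multi-mapping across graph locations is not modelled.

Events are recorded per base (match, mismatch, insertion, deletion,
softclip, unresolved-N) with the graph node/offset and the base's distances
from the fragment's own 5′ and 3′ ends — the frame deamination is indexed
in. For reverse-complement alignments the events are stored in
original-fragment orientation; at likelihood time the mutation channel runs
on the reference strand and the damage/error channels on the fragment
strand (the post-mutation base is complemented between them). This is exact
for the damage model; the HKY channel on the complementary strand is exact
only under strand-symmetric base frequencies, a second-order effect at the
divergences involved.

### Likelihood

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| κ | 2.0 | HKY transition/transversion parameter (mitochondrial transition bias); configurable, logged |
| π | MSA base counts (+1 pseudocount) | stationary frequencies; rate matrix normalised so t is in substitutions/site |
| δ profiles | zero damage | per-position C→T (5′-anchored) and G→A (3′-anchored) rates, flat residual beyond the table; TSV input, bam2prof-style 12-column tables accepted |
| indel probability | 0.02 | per inserted/deleted base (empirical mitogenome rate); applied per base because the source resolution (per event vs per base) is not documented |
| probability floor | 1e−12 | clamp before log; zero-ε quality strings occur in simulated data |

The full 16-term marginalisation over (post-mutation, post-damage) base
pairs is always computed — no shortcut formulas — so a damage event
reverting a mutation is handled correctly. Unsupported-path bases use
(6/7)(ε/3) + (1/7)(1−ε), which *increases* from 1/7 to 2/7 with ε (the
error-weighted term dominates). A deletion on a node the evaluated path
does not traverse contributes nothing (the unsupported model is defined for
read bases). θ enters as an ordinary mixture weight, Σᵢ θᵢ P(r|βᵢ): a flat
prior makes the posterior proportional to this likelihood but cannot remove
θ from it, otherwise the weights would be unidentifiable.

HKY transition matrices come from the spectral decomposition of the
symmetrised rate matrix (exact for a reversible chain, cheap to re-evaluate
per proposal) and are unit-tested against `scipy.linalg.expm` at 1e−10.

The scalar functions in `likelihood.py` define the semantics. The sampler
uses `engine.PlacementEngine`, which precomputes, per aligned base, the
placement-independent damage×error 4-vector, pools identical
(graph-base, vector) pairs (qualities repeat and damage rates flatten to
the residual away from fragment ends, so a few hundred pools cover
everything), folds placement-independent events into per-fragment
constants, and reduces with numba kernels. Engine and reference are
asserted equal in the tests.

### Inference

Metropolis–Hastings with target ∝ mixture likelihood (flat priors over
branches × [0,1] × simplex):

- **branch hop** (probability 0.2): one source moves to a uniformly chosen
  adjacent branch (parent/sibling/child), β resampled U(0,1); Hastings term
  log|nbrs(cur)| − log|nbrs(new)|;
- **β walk**: reflected Gaussian (σ = 0.1), symmetric;
- **θ walk** (k > 1): θ′ ∝ θᵢ·exp(zᵢ), z ~ N(0, 0.3²); Hastings term
  Σlog θ′ − Σlog θ (the logistic-normal Jacobian).

Defaults: 10⁵ iterations, 10% burn-in, 4 chains available (`run_chains`)
with one chain per k used in the experiments below, initialisation from the
signature ranking (β = 0.5, θ uniform; random fill if fewer ranked sets
than k). Random initialisation is available and is known to converge poorly
once several sources are present. The sampler is run for every k in 1..k₀
(k = 0 is meaningless for a likelihood over reads; `--force-k` extends the
scan, mirroring forced-k analyses on real data). Model selection picks the
smallest k whose successor improves the best log-likelihood by less than
τ = 2·ln(n)/2 (two parameters per added source, BIC-style); the full
k-curve is always reported so users can override.

Diagnostics: post-burn-in 5/50/95% quantiles for every θᵢ and βᵢ,
per-branch visit frequencies, the MAP state (argmax of recorded
log-likelihood), and per-parameter effective sample sizes
N/(1 + 2Σρ̂) with Geyer's initial-positive-sequence truncation (constant
series count as fully independent, with the k=1 θ series the prime
example). Any ESS below 200 raises a warning flag. Label switching is
handled by sorting sources by posterior mean θ at summary time.

## Synthetic data

`make_reference_set` draws a coalescent topology (msprime), rescales branch
lengths by bisection on the analytic expected HKY identity to hit a target
mean pairwise identity (realized identity asserted within ±1%), and evolves
sequences from a π-distributed root (AT-rich, mitochondrial-like) down the
tree, returning the leaf alignment, the calibrated tree and the true
sequence of every node. Gap-free references make the "alignment" trivial;
gap handling is exercised by hand-built alignments in the tests.

`simulate_fragments` draws, per read: source ~ θ, start uniform, strand
uniform, length log-normal(μ=3.7344, σ=0.35) truncated to [20, reference
length] — the canonical aDNA fragment-length distribution, mean ≈ 44.5 bp —
then applies position-dependent deamination (C→T by 5′ distance, G→A by 3′
distance on the fragment strand) and quality-derived errors at constant
Phred 30. The default damage profile is a double-stranded-library pattern:
0.3·0.45^p + 0.01 for p < 15, residual 0.01. A truth table records source,
coordinates, strand and damage/error counts per read.

What the generator does *not* emulate: contaminating reads from other taxa
(the method assumes a pre-filtered input), quality-score variation,
indel-generating library artifacts, circular genomes, and real
reconstruction noise in the reference ancestors (simulation truth is exact,
database ancestors are reconstructed — the small gap between them is the
realistic part). Passing recovery tests therefore demonstrate the
estimator's behaviour under its own model assumptions at realistic
divergences, not robustness to classifier leakage or library chemistry.

## Desk-scale experiments

The experiment drivers (`single_source_downsampling`, `two_source_mixture`,
`three_source_mixture`) use 5 kb references (vs ~16.5 kb real mitogenomes)
with 7–8 taxa at 93% mean pairwise identity, chosen so the full study runs
in minutes on one CPU; fragment counts — the quantities the experiments are
about — are kept at full scale (grid 500→10; 1,000; 1,500). Per-fragment
placement information is genome-length invariant (it depends on fragment
length × per-site branch lengths), so shrinking the reference mainly
raises the nominal coverage numbers, which are reported from the actual
reference length.

The single-source experiment samples from the *typical* ancestral node
(median minimum-incident-branch-length among internal non-root nodes): the
extremes are degenerate (a coalescent draw can make an ancestor coincide
with a leaf, which no method can place) or trivially separable (deep splits
flanked by long branches). Recovery readouts: the MAP placement's nearest
tree node (derived end for β ≥ 0.5, else ancestral end), the posterior
nearest-node mass, and the fraction of accepted states on branches adjacent
to the truth. In mixtures, recovery means the per-source modal nearest
nodes match the true source multiset.

A known divergence from the original study: at these conditions the
single-source breakpoint extends below 50 fragments — the majority of
replicates still recover the node at 10 fragments (with visibly diffuse
posteriors: adjacent-branch acceptance 0.76–1.0) — because coalescent
interior branches at family-level divergence carry more distinguishing
sites per fragment than a rapid-radiation ancestral node does. The
downsampling grid is reported as measured.

## Numerical choices and edge cases

- Probabilities are clamped at 1e−12 before logs; mixture and fragment
  combinations use log-sum-exp.
- β = 0 and β = 1 short-circuit to a single node product (the other term
  has weight zero even if its product underflows).
- θ simplex validated to 1e−12 at construction; proposals renormalise
  exactly.
- Exact likelihood ties in reconstruction fall to the alphabetically first
  base; alignment ties to the earliest pre-order path, forward strand.
- A non-finite initial likelihood re-initialises randomly up to 20 times,
  then errors.
- One integer seed drives everything (reference simulation, reads, MCMC);
  manifests record it together with input checksums.

## Known limitations

Single best alignment only (no multi-mapping model); no contamination
class in the mixture; no rate heterogeneity across sites; no
single-/double-stranded library distinction in the damage model; ancestral
reconstruction quality, and hence internal-node placement, degrades for
highly divergent or low-entropy taxa; linear-sequence treatment of circular
genomes.
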