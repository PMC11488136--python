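# branchmix

Branch placement and mixture deconvolution of ancient mitochondrial DNA
fragments on a fixed phylogeny.

Ancient environmental DNA (aeDNA) from sediments mixes short, damaged
fragments from many organisms. After a first-pass classifier has pulled out
the reads belonging to one taxon (say, bears), the interesting questions
are finer: *how many* distinct sources from that family are in the sample,
*where* do they sit on the family's mitochondrial phylogeny (a known
species? an ancestral/extinct lineage partway along a branch?), and *in
what proportions*? branchmix answers these with a damage-aware likelihood
and MCMC over a pangenome-graph reference.

## The model

The reference is a multiple sequence alignment of mitogenomes plus a rooted
tree. Every tree node — leaves *and* internal nodes, whose sequences are
reconstructed by marginal maximum likelihood — owns one **reference path**
through a pangenome graph built by collapsing alignment columns. A sample
is modelled as a mixture of k sources; source i is a **placement**
β<sub>i</sub> ∈ [0,1] on a tree branch between an ancestral node N_A and a
derived node N_D (distances t_A = β·t, t_D = (1−β)·t), with mixture weight
θ<sub>i</sub> on the simplex.

For a fragment *r* with aligned bases *b*:

- a base on a graph node traversed by the evaluated path chains three
  channels, marginalising over all 16 intermediate states:
  P(b|b_g,t) = Σ<sub>b_s</sub> Σ<sub>b_d</sub>
  P<sub>HKY</sub>(b_s|b_g,t) · P<sub>damage</sub>(b_d|b_s; pos5, pos3) ·
  P<sub>err</sub>(b|b_d, ε), where the deamination rate δ is
  position-dependent (C→T indexed from the 5′ end, G→A from the 3′ end) and
  ε comes from the base quality;
- a base on a node the path does not traverse costs
  (6/7)·(ε/3) + (1/7)·(1−ε);
- insertions/deletions cost 0.02 per base; N bases and softclips cost ε/3.

Then P(r|β<sub>i</sub>) = (1−β<sub>i</sub>)·∏P(b|N_A,t_A) +
β<sub>i</sub>·∏P(b|N_D,t_D), fragments combine as
P(D|θ,β) = ∏<sub>r</sub> Σ<sub>i</sub> θ<sub>i</sub> P(r|β<sub>i</sub>),
and with flat priors the posterior is proportional to this likelihood.
A Metropolis–Hastings sampler (branch hops with degree-corrected Hastings
ratios, reflected Gaussian steps on β, logistic-normal steps on θ) explores
it for every k from 1 to the signature-node estimate k₀ — the number of
**signature node sets** (nodes private to one path) hit by more than 1% of
aligned fragments. A BIC-style rule then picks the smallest supported k,
and the full k-curve is always reported.

## Worked example

`examples/04_two_source_mixture.py` simulates two references at ~93%
identity, mixes 600 damaged fragments at 55:45 and runs the full k-scan:

```
true mixture: T0 55% + T6 45%
signature-node estimate: k0 = 2
k-curve (best log-likelihood): {1: -2873.8, 2: -2414.9}
selected k = 2
source 1: branch  T0  theta = 0.546 [0.504, 0.587]  beta median = 1.00
source 2: branch  T6  theta = 0.454 [0.413, 0.496]  beta median = 0.99
```

The k-curve jumps by ~460 log-likelihood units from one source to two and
the selected model places both sources at the correct leaves (β ≈ 1 means
"at the derived node") with 90% credible intervals bracketing the true
proportions. The other scripts in `examples/` walk through database
construction, the per-base damage model, single-source placement and the
file-based pipeline; each prints what its numbers mean.

A thin CLI wraps the same library calls:

```bash
branchmix simulate --refs 7 --identity 0.93 --sources N4:1.0 --n-frags 250 --seed 5 --out sim
branchmix run --msa sim.refs.fasta --tree sim.nwk --fastq sim.fastq.gz --out results/
```

`run` writes the graph (GFA), alignment table, per-k traces, k-curve,
diagnostics (posterior quantiles, per-parameter effective sample sizes with
a warning below ESS 200) and a manifest with input checksums and the seed.

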