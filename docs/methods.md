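# Methods

## Scope and model

`aprkit` implements the computational core of an ancestral-protein-
reconstruction (APR) study of a protein family: maximum-likelihood
phylogenetics under empirical amino-acid substitution models,
empirical-Bayes marginal reconstruction of ancestral sequences,
family-level conservation and divergence statistics, and
structure-based contact / protein-structure-network (PSN) analysis.
Everything is driven either by user data (FASTA/PHYLIP alignments,
Newick trees, PAML-style `.dat` rate matrices, PDB structures) or by
the package's own synthetic-data generator, which provides ground
truth for testing.

### Substitution model

A reversible 20-state Markov model is built from a symmetric
exchangeability matrix S and equilibrium frequencies π:

    q_ij = S_ij π_j  (i ≠ j),  q_ii = −Σ_{j≠i} q_ij,

rescaled so −Σ_i π_i q_ii = 1; branch lengths are expected
substitutions per site. Detailed balance π_i q_ij = π_j q_ji holds by
construction. Transition matrices P(t) = exp(Qt) are obtained from the
symmetrised eigendecomposition (similarity transform with diag(√π)),
which is numerically exact for reversible Q; the symmetric factor is
re-symmetrised after reconstruction so P's detailed-balance symmetry
is exact in floating point (this is what makes ML pairwise distances
exactly symmetric in their arguments).

Among-site rate variation uses the discrete-gamma approximation with
k equal-probability categories (default k = 4), each category carrying
the conditional mean of the unit-mean gamma within its inter-quantile
slab (the mean, not the median, so the category mean is 1 without
ad-hoc rescaling; a final renormalisation enforces it to machine
precision). An invariant-sites class (+I) adds a rate-0 category of
weight p_inv, with the remaining rates rescaled by 1/(1−p_inv).

Bundled matrices: LG, WAG, JTT, Dayhoff, exported to PAML layout from
the matrices shipped with the R package phangorn (which reproduces the
published values; the LG file is spot-checked against the published LG
exchangeabilities and frequencies in the test suite). Any other
PAML-style `.dat` file can be supplied by path, so models distributed
with other programs (e.g. the Qmaker matrices) plug in without code
changes. The default model-selection panel is {LG, WAG, JTT, Dayhoff}.

### Likelihood

Felsenstein pruning over alignment site patterns (unique columns with
multiplicities). Gaps and `X` are missing data: a tip contributes an
all-ones conditional vector, so an all-gap column contributes exactly
zero log-likelihood. Underflow is controlled by per-node,
per-(category, pattern) rescaling of conditional-likelihood vectors;
the accumulated log scale factors re-enter through a log-sum-exp over
rate categories, so mixing across categories is exact. A zero-rate
category uses P = I, whose likelihood correctly vanishes on variable
site patterns.

The model is reversible, so the stored rooting is arbitrary:
log-likelihood and marginal posteriors are invariant to rerooting
(verified to 1e−9 in the tests).

### Tree search

* **Start tree**: neighbor joining on ML pairwise distances (per-pair
  1-D likelihood maximisation over t ∈ [1e−6, 10], Brent, tolerance
  1e−8, gap/X sites skipped). NJ follows Saitou–Nei with negative
  branch estimates clamped to 0 and Q-criterion ties broken by the
  lowest (row, col) pair; the result is rooted at the final three-way
  join. NJ was chosen over BioNJ for determinism and simplicity; on
  additive inputs both are exact, which is the property the tests pin.
* **Branch lengths**: round-robin single-branch Brent optimisation
  (bounds [1e−8, 10], per-branch tolerance 1e−8), sweeping until the
  log-likelihood improves by < 1e−6 or 50 sweeps. Each branch is
  optimised against fresh inside/outside vectors, so the
  log-likelihood is non-decreasing by construction.
* **Topology**: NNI hill climbing. Every internal edge (scanned in
  canonical bipartition order) contributes its two rearrangements;
  each candidate is scored after full branch-length re-optimisation;
  the single best improving move is accepted per round, iterating to a
  local optimum. SPR/TBR are out of scope — at the family sizes this
  package targets, NNI from an NJ start recovers simulated topologies
  reliably (exercised in the acceptance tests).
* **Supports**: nonparametric bootstrap. Replicate r resamples
  columns with a dedicated substream `default_rng([seed, r])`, reruns
  distances + NJ + branch-length optimisation (NNI optional), and
  counts bipartitions; supports are reported on the input tree's
  internal edges. Substitution-model parameters (α, p_inv) are reused
  from the full-data fit rather than re-estimated per replicate —
  standard practice and a large speed-up. Bootstrap runs are
  bit-reproducible given the seed.

### Model selection

For each candidate matrix and each +G/+I/+F option combination,
branch lengths and (α, p_inv) are optimised on the fixed topology by
coordinate ascent (α ∈ [0.02, 100], p_inv ∈ [0, 0.99], Brent,
tolerance 1e−6, up to 4 outer rounds). Free parameters: (2n−3) branch
lengths, +1 per +G, +1 per +I, +19 per +F (observed frequencies are
counted from non-gap residues with no pseudocount; +F is refused when
some residue never occurs, rather than silently flooring). Ranking is
by AIC = 2k − 2 lnL.

### Ancestral reconstruction

Marginal (empirical-Bayes) reconstruction: for internal node v and
site s, p_v(a) ∝ Σ_c w_c · up_v(c, a) · out_v(c, a), the standard
inside–outside decomposition, where the outside recursion places π at
the stored root. Because the per-site category weighting enters
through the same sum, categories are mixed by their posterior mass for
that site, which is the exact empirical-Bayes answer under the rate
mixture. MAP residues break probability ties alphabetically (for
determinism); meanPP is the average MAP posterior over columns
reconstructed as present.

Gap placement is deliberately outside the probabilistic model (which
treats gaps as missing data): a Fitch small-parsimony pass on the
binary presence/absence character per column, root ties resolved to
presence, gives each ancestor a defined sequence length. Joint
reconstruction and posterior sampling are out of scope.

Nodes are addressed by deterministic integer ids in the PAML style —
tips 1..n in Newick order of appearance, internal nodes n+1..2n−1 in
preorder from the stored root — and, because integer ids are fragile
under re-ordering or re-rooting of a tree file, also by MRCA tip
lists. Note that an unrooted tree stored with a trifurcating root has
n−2 internal nodes (ids n+1..2n−2); a rooted binary input has n−1.

### Conservation and divergence statistics

Percent identity uses the co-non-gap denominator: 100 × (identical
non-gap pairs) / (columns where both sequences have a residue), with
`X` never counting as identical. Published identity figures for a
protein pair can differ by a few points depending on the denominator
convention; this package's convention is fixed and documented rather
than tuned to match any particular published number. Column
conservation reports non-gap residue frequencies, the consensus and
its fraction, and information content IC = log2(20) − H in bits with
no small-sample correction (all-gap columns: IC 0, consensus '-').
Clade conservation restricts the count to a named clade at the column
of a reference sequence's ungapped position (gapped clade members are
excluded from the denominator by default; a flag counts them as
mismatches). Divergent-position reports list all co-non-gap differing
columns between two sequences with each sequence's own residue
numbering, plus an optional third sequence's numbering for statements
like "ancestral position X corresponds to orthologue position Y".

### Structure analysis

PDB parsing (via gemmi) keeps heavy atoms only, drops waters and
altlocs other than blank/'A', flags HETATM groups as ligands keyed by
residue name, and keys residues by author number + insertion code.

* **Ligand contacts**: protein residues with any heavy atom within the
  cutoff (default 4.0 Å) of any ligand heavy atom; backbone atoms
  included, since backbone-mediated contacts (e.g. glycine) are real.
* **Residue contact pairs**: minimum heavy-atom distance between two
  selections against a cutoff (default 6.0 Å).
* **PSN**: nodes are residues represented by side-chain heavy atoms
  (Cα for glycine); edge strength I_ij = 100 · n_ij / √(N_i N_j) with
  n_ij the number of inter-residue atom pairs within the atom cutoff
  (default 3.0 Å) and N_i the node's own atom count. A per-residue-type
  normalisation table can be supplied where tabulated factors are
  preferred; the self-contained default keeps the package free of
  external constants. Sequence neighbours (|i−j| ≤ 1) are excluded;
  edges are kept when I_ij > i_min.
* **Communication paths**: shortest = minimum hop count, ties broken
  by maximum cumulative strength, then lexicographically. Constrained
  paths must pass through a given via residue and remain simple; the
  search is exact (iterative-deepening enumeration from the
  unconstrained lower bound), verified against exhaustive simple-path
  enumeration on random networks.

## Synthetic data

The generator emulates the inputs the analyses consume, with recorded
ground truth:

* `simulate_alignment` evolves sites down a tree: per-site rate
  category draws, root states from π, then child states branch by
  branch in preorder (within a branch, draws grouped by category and
  parent state). Same seed ⇒ bit-identical output. It does **not**
  simulate indels (gaps are missing data in every downstream analysis,
  so a gap process would add no tested behaviour), heterotachy, or
  site-specific profiles — so passing recovery tests demonstrates
  correctness of the inference machinery under the model, not
  robustness to model violation in real families.
* `random_tree` draws a uniform random binary topology by sequential
  random edge attachment with uniform branch lengths.
* `synthetic_structure` places residues far apart on a circle and
  plants exact minimum heavy-atom distances (± 0.01 Å) for requested
  residue pairs and ligand-residue pairs, verifying the realised
  geometry and rejecting infeasible requests. These toys validate
  distance bookkeeping and network logic, not protein physics.

## Study conditions used by `scripts/acceptance.py`

A 12-taxon family, 300 columns, LG+G (α = 1, k = 4), branch lengths
uniform in [0.05, 0.3]; bootstrap at the fixture scale of 50
replicates; model-selection accuracy over 10 replicates of 500 columns
(LG vs JTT on a 5-taxon tree); a 20-residue toy structure with nine
residues planted in ligand contact (3.5 Å against the 4.0 Å criterion,
decoys at 5.5 Å) and a planted two-step communication path. These
sizes are chosen so the whole script reruns in minutes on one CPU
while every quantity is measured, not assumed.

## Numerical choices and degenerate inputs

* Likelihood tolerance chain: branch Brent 1e−8, sweep stop 1e−6,
  α/p_inv 1e−6, NNI acceptance 1e−6.
* Distances capped at 10 substitutions/site; branch lengths bounded to
  [1e−8, 10].
* Transition-matrix entries are clipped to [0, 1] after the spectral
  reconstruction (stray negatives are at round-off scale).
* MAP ties, NJ Q-ties, NNI scan order, bootstrap substreams and output
  orderings are all deterministic; reruns are byte-identical.
* Alignments must have ≥ 2 sequences; all-gap columns are removed by a
  cleaning step before analysis; 2-tip trees are allowed for
  likelihood but not for NJ (≥ 3) or NNI (≥ 4 with an internal edge).

## Known limitations

* NNI-only topology search can in principle stall in local optima that
  SPR would escape; at the tested scales it recovers simulated
  topologies from NJ starts.
* The PSN normalisation differs from servers that use tabulated
  per-residue-type factors; network strengths are therefore comparable
  within a run, and an override table is the escape hatch when
  server-compatible numbers are needed.
* Family-scale claims (tens of thousands of homologs) are exercised in
  kind on synthetic fixtures; the statistics are the same, the data
  size is not.
* Codon/nucleotide models, free-rate models, partitioned models, joint
  ancestral reconstruction and alignment inference are out of scope.
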