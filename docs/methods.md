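# Methods

## Scope and model of the analysis

`c4evo` asks where on a phylogeny the coordinated changes of three feature
classes — gene expression, protein sequence and morphology — concentrate.
Internal nodes are labelled N1..Nm from the root in preorder, the first
("A") clade numbered before the second ("B"); each node's *preceding node*
is its nearest ancestral internal node.  Because the numbering runs through
clade A first, the preceding relation is N(i−1) except at clade boundaries;
for the packaged 16-species *Flaveria* tree the exceptions are N11→N5 and
N10→N8, stored as data rather than re-derived.  The packaged topology is
reconstructed from the published node semantics (N1 the genus ancestor, N3
the ancestor of all intermediate + C4 species with *F. sonorensis* branching
first, N7 the ancestor of the clade-A C4-like + C4 species) and has one
trifurcation (at N8), giving 16 tips and 14 internal nodes.  Branch lengths
in the fixture default to 1.0 and are meant to be overridden with real
estimates (`flaveria_tree(branch_lengths=...)`) — the published lengths are
not machine-readable, and inventing numbers would silently alter change
rates.

## Ancestral reconstruction

**Continuous traits.**  Under Brownian motion the joint density of all node
states is a Gaussian Markov random field whose precision matrix is the tree's
graph Laplacian weighted by inverse branch lengths.  The ML internal states
therefore solve one linear system (conditional mean given the tips); the
root estimate is the GLS phylogenetic mean, every estimate obeys the discrete
maximum principle (it lies within the tip range), and the reconstruction is
exactly affine-equivariant.  The Brownian rate σ² is profiled analytically
from the tip likelihood (ML, denominator n), and reported variances are the
conditional variances σ²·diag(L_II⁻¹).  No iterative optimizer is involved,
which keeps the estimator deterministic and directly testable against a
grid-search likelihood oracle (agreement < 1e-4 in the tests).

**C4-specific quantities** use the descendant-assignment shortcut instead:
each internal node inherits the value of its most recent derived species.
"Most recent derived species" is operationalized as the nearest tip (edge
count, name order on ties) reachable through a child branch off the backbone,
where the backbone child is the internal child with the lowest N-number.
This reproduces the canonical exemplars (N3 ← *F. sonorensis*,
N6 ← *F. ramosissima*, N7 ← *F. palmeri* for the CO2 compensation point).

**Protein sequences.**  Marginal ancestral residues come from the pruning
(sum-product) algorithm under an equal-rates 21-state model: the 20 amino
acids plus gap as an explicit state, uniform stationary frequencies, branch
lengths in expected substitutions per site.  `X` and species missing from an
alignment contribute flat partial likelihoods (an incomplete assembly is not
evidence).  Columns gapped in every present species are fixed to gap with
posterior 1 by convention.  The equal-rates choice (rather than an empirical
exchange matrix) keeps the reconstruction exactly checkable against direct
summation over all internal-state assignments — the tests verify agreement
to 1e-10 — and is pluggable should an empirical matrix be wanted; stage
assignments of the headline changes are robust to the model because they
depend on where a derived residue first becomes the posterior argmax.

## Change calling and node assignment

A column is called a C3→C4 change iff all present C3 reference sequences
carry one identical non-gap residue and at least two C4 sequences share an
identical state different from it; a shared C4 gap scores as a deletion, a
shared C4 residue where the C3 references are gapped as an insertion, and
contiguous indel columns merge into one event with a length.  Gaps and `X`
in C4 sequences neither count toward nor veto the two-species quorum.
A called change is assigned to the earliest internal node (N-number order)
whose reconstructed residue equals the derived state while its preceding
node retains the ancestral state; if the derived state never appears at an
internal node the change sits on a terminal branch and is labelled
"after N<parent>".  Assignments with posterior < 0.5 are flagged
low-confidence but kept.  Stage summaries bucket events into before-N5 /
N5 / N6 / N7 / after-N7; the "path" convention leaves clade-B assignments in
an explicit `other` bucket (so the stages always partition the events), and
a "broad" convention folds them into before-N5.

## Expression normalization

Pipeline order is fixed: (1) contig FPKM summed onto best-hit gene ids
(E ≤ 0.001); (2) genes kept iff the maximum species-level FPKM ≥ 1 (boundary
kept); (3) rank-conserved reference scaling; (4) quantile normalization
where Euclidean divergences are computed.  The reference genes are those
whose fractional rank falls inside the 20–80% band in *every* sample
(strictest reading; configurable) ranked by the variance of that fractional
rank across samples — smallest variance wins, ties broken by gene id — and
the 1000 best form the internal reference, as in cross-species RNA-seq
scaling.  Each sample is divided by its reference mean and the grand
reference mean multiplied back, so identical samples are a fixed point and a
global per-sample factor is removed exactly.  A provenance flag refuses
double scaling.  Quantile normalization maps ranks onto the row-wise mean of
the sorted columns, ties receiving the mean of the quantile values they span.

## Divergence and significance

Protein divergence is Nei–Gojobori counting dN: per-codon nonsynonymous
sites as the fraction of the three possible changes at each position that
alter the amino acid (changes to stops count as nonsynonymous), observed
differences averaged over all mutational pathways between codons with
stop-traversing paths excluded, and Jukes–Cantor correction
dN = −(3/4)ln(1 − (4/3)pN); pN ≥ 3/4 raises a saturation error.  Counting
agrees closely with codon-model ML for congeneric comparisons, and the
divergence table accepts externally computed dN vectors where exact
reproduction of an ML value is needed.  The implementation is cross-checked
in the tests against Biopython's independent NG86 routine.

Expression and morphology divergences are Euclidean distances to a reference
species (*F. cronquistii* in the study design) on quantile-normalized
matrices, missing genes excluded pairwise.  Divergence–divergence relations
are ordinary least squares with R² = squared Pearson r.  Change rates divide
|relative change| by the branch length into the node.

Per-node significance uses one-way ANOVA followed by all-pairs Tukey HSD
(studentized-range p with pooled within-group variance, Tukey–Kramer for
unbalanced groups) and BH adjustment applied *on top of* the Tukey p-values
across pairs.  The double adjustment is deliberately conservative; the
type-I rate measured over 1000 identical-group simulations is well below
the nominal 5%.  Stars follow 0.05 / 0.01 / 0.001.

## Hybrid screening

A site is evaluable at coverage ≥ 10 and mixed when the second-most-frequent
base reaches 20% frequency and 3 reads (defaults; all configurable, as the
original read-level criteria are not fully specified).  The positive
background merges counts site-wise for every unordered sample pair — an
in-silico F1 — and collects the C(n,2) mixed-site ratios.  The binomial null
rate p0 is the 5th percentile of the background for the "higher than
background" test and the 95th percentile for the "lower" test, making both
one-sided claims conservative (the background mean is available as an
option).  Verdicts at P < 0.001: hybrid-like, non-hybrid, else inconclusive.
Heterozygosity and hybridity are indistinguishable at a single locus; the
verdict is genome-wide by design.

## Synthetic data: what it emulates, and what it does not

All generators draw from one seeded PCG64 stream per operation, so a
scenario's seed fixes every output byte across platforms.  Defaults encode
the study conditions: the 16-species tree; 30 continuous traits (the coded
morphology table); a 5-SD burst into N7; 6000 genes with a ≈7% DE fraction
(the share of expressed genes called differentially expressed in genus-wide
C3-vs-C4 leaf comparisons) at 50-fold lineage-specific up-regulation
(C4-pathway transcripts are reported at roughly 8- to 120-fold between C4
and C3 leaves), negative-binomial dispersion 0.1, 2
leaf samples per species and log-normal(0, 0.3) per-sample factors; protein
alignments of 300 columns with 10 injected changes inherited from N7 over a
0.01/site/branch background; and for the hybrid screen 2% parental
divergence at 30× Poisson coverage over 50,000 sites with 0.1% sequencing
error, the F1 crossing a basal C3 with a clade-A C3-C4 species (the known
real hybrid is such a cross) and haplotypes evolved along the tree so the
mixing background spans a realistic range of pairwise divergences.
Expression matrices are desk-scaled (6000 genes vs the ~12,000 expressed
genes of a full cross-species leaf dataset; the gene count is a scenario
field).

The generators do *not* emulate read-level artifacts (mapping bias, PCR
duplicates), assembly fragmentation, indel evolution beyond single-column
injection, rate variation across sites or lineages, or correlated trait
evolution.  Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated models, not robustness to upstream
artifacts in real data.

## Numerical choices and degenerate inputs

Inside/outside sequence likelihoods are max-rescaled per column against
underflow.  Branch lengths must be strictly positive for reconstruction;
the relative-change formula refuses negative trait values (shift or recode
first) and flags a zero predecessor as missing rather than dividing.  The
expression filter keeps the boundary value exactly.  Tukey pairs with zero
pooled variance degenerate to p ∈ {0, 1} by the sign of the difference.
Quantile normalization of a single column is the identity.  dN of identical
or synonymously differing sequences is exactly 0; ambiguous or gapped codons
are skipped with a logged count.

## Known limitations

- The equal-rates substitution model shifts stage counts slightly relative
  to empirical matrices for deep, saturated alignments; the interface is
  model-pluggable but ships only the equal-rates kernel.
- NG86 counting underestimates dN at high divergence relative to codon-model
  ML; for congeners the difference is small, and external dN tables can be
  substituted.
- The BM variance uses the plug-in ML σ², so interval coverage is very
  slightly anti-conservative on small trees (measured ≈93–96% in the tests).
- Fixture branch lengths are unit-valued placeholders; change *rates* on the
  fixture are only meaningful once real lengths are supplied.
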