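# c4evo

Coordinated-evolution analysis of C4 photosynthesis in the genus *Flaveria*.

C4 photosynthesis evolved from the ancestral C3 pathway repeatedly, and
*Flaveria* — with extant C3, C3-C4 intermediate, C4-like and C4 species —
is the classic system for asking *how*: do gene expression, protein sequence
and morphology change gradually along the phylogeny, or in coordinated bursts
at particular ancestral nodes?  `c4evo` implements that analysis as a tested,
reusable pipeline:

- **Phylogeny handling** (`c4evo.tree`) — newick I/O, the root-to-tip node
  numbering N1..Nm (clade A before clade B), the nearest-preceding-node
  relation N[pre], and the packaged 16-species *Flaveria* topology in which
  N3 is the ancestor of all intermediate + C4 species and N7 the ancestor of
  the clade-A C4-like + C4 species.
- **Ancestral traits** (`c4evo.traits`) — maximum-likelihood ancestral states
  of continuous traits under Brownian motion (exact Gaussian Markov random
  field solution, no iterative optimizer), the descendant-assignment shortcut
  for C4-specific traits, and per-node relative change `(N − N_pre)/N_pre`.
- **Ancestral sequences** (`c4evo.sequences`) — the C3-vs-C4 amino-acid
  change caller (both C3 references identical, ≥2 C4 species sharing a
  different residue), marginal ancestral-sequence reconstruction by the
  pruning algorithm under a 21-state equal-rates model, node assignment of
  each change, and per-node relative protein difference.
- **Expression pipeline** (`c4evo.expression`) — contig→gene FPKM
  aggregation, the max-FPKM ≥ 1 expression filter, cross-sample scaling on a
  rank-conserved 1000-gene internal reference, quantile normalization,
  modified-gene intersection, Fisher-exact pathway enrichment (BH-adjusted)
  and orthogroup annotation-consistency scoring.
- **Divergence statistics** (`c4evo.divergence`) — Nei–Gojobori dN with
  Jukes–Cantor correction, Euclidean expression/morphology divergence to a
  reference species, OLS divergence–divergence regression with R², per-node
  change rates normalized by branch length, and one-way ANOVA → Tukey HSD →
  Benjamini–Hochberg significance calls.
- **Hybrid screening** (`c4evo.hybrid`) — genome-wide mixed-site ratios from
  RNA-seq allele counts, a positive background from pairwise in-silico sample
  mixing, and one-sided binomial verdicts (hybrid-like / non-hybrid /
  inconclusive).
- **Synthetic data** (`c4evo.simulate`) — seed-deterministic generators for
  every input class with known ground truth: Brownian traits with an optional
  burst at a chosen node, protein alignments with clade-restricted injected
  changes, negative-binomial expression with lineage fold changes and
  per-sample factors, and allele counts for pure vs F1 samples evolved along
  the tree.
- **Orchestration** (`c4evo.pipeline`, `c4evo` CLI) — stage-wise runs with
  provenance headers, resumable outputs, and a machine-readable summary.

## The statistic at the core

For every feature class (expression, protein, morphology) the value of each
internal node N is reconstructed and compared with its nearest preceding node
N\[pre\]:

    relative change(N) = (N − N[pre]) / N[pre]          (traits, expression)
    relative difference(N) = #differing columns / aligned length   (protein)

A "major event" is a node whose relative changes are jointly, significantly
larger than at other nodes (one-way ANOVA, Tukey HSD, BH).  On data shaped
like the real genus-wide datasets the major event lands at N7 — the transition between
C3-C4 and C4-like species — for all three feature classes.

## Worked example

```sh
c4evo run-all --seed 7 --outdir run7
```

runs every stage on the default synthetic scenario (16-species tree, 30
morphology traits, 6000 genes, burst at N7) and prints, among other fields:

```json
{
  "argmax_change_node": {
    "expression": "N7",
    "morphology": "N7",
    "protein": "N7"
  }
}
```

i.e. all three feature classes locate the largest coordinated change at N7,
the C3-C4 → C4-like transition.  `run7/` contains per-stage TSVs (node
change profiles, ANOVA/Tukey/BH tables, divergence regressions, change
rates, hybrid verdicts), each stamped with the config hash and seed.
The same library calls work on real inputs: newick trees, trait CSVs,
aligned FASTA orthogroups, FPKM TSVs and allele-count TSVs.

A library-level example:

```python
from c4evo.tree import flaveria_tree
from c4evo.traits import assign_descendant_values, relative_change_continuous

tree = flaveria_tree()
gamma = {"F_robusta": 62.1, "F_sonorensis": 29.6, "F_angustifolia": 24.1,
         "F_ramosissima": 9.0, "F_palmeri": 4.7, ...}
nodes = assign_descendant_values(tree, gamma)      # N3 -> 29.6, N7 -> 4.7
profile = relative_change_continuous(nodes, tree.preceding_overrides())
```

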