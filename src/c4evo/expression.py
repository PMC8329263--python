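"""Cross-species expression-matrix plumbing.

Pipeline order is fixed: contig→gene FPKM aggregation, expressed-gene
filtering (max species-level FPKM ≥ 1), rank-conserved reference scaling,
then quantile normalization where Euclidean divergences are computed.

The rank-conserved scaling follows the internal-reference strategy used for
cross-species RNA-seq comparisons: among genes whose FPKM rank falls in the
20–80% band of every sample, the 1000 genes with the most stable fractional
ranks across samples act as an internal reference; each sample is divided by
its reference-gene mean and the grand reference mean is multiplied back so
values stay on the FPKM scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "aggregate_fpkm_by_gene",
    "filter_expressed",
    "rank_conserved_scaling",
    "quantile_normalize",
    "intersect_modified_genes",
    "pathway_enrichment",
    "annotation_consistency",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """gene × sample FPKM matrix with per-sample metadata.

    ``metadata`` is indexed by sample id with at least a ``species`` column;
    ``organ``, ``lab`` and ``photosynthetic_type`` columns are carried when
    available.  ``scaled`` guards against re-applying reference scaling.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def species_max(self) -> pd.DataFrame:
        """Per-gene maximum FPKM within each species (max over its samples)."""
        species = self.metadata.loc[self.values.columns, "species"]
        return self.values.T.groupby(species.values).max().T

    def copy_with(self, values: pd.DataFrame, scaled: bool | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values, self.metadata, self.scaled if scaled is None else scaled
        )


def aggregate_fpkm_by_gene(
    contig_fpkm: pd.DataFrame,
    annotation: pd.DataFrame,
    metadata: pd.DataFrame,
    evalue_max: float = 1e-3,
) -> ExpressionMatrix:
    """Sum contig FPKM onto their best-hit gene ids.

    ``annotation`` has columns ``contig``, ``gene`` and optionally
    ``evalue``; hits above ``evalue_max`` and unannotated contigs are
    dropped (counts logged).
    """
    ann = annotation.copy()
    if "evalue" in ann.columns:
        n_before = len(ann)
        ann = ann[ann["evalue"] <= evalue_max]
        if len(ann) < n_before:
            log.info("dropped %d annotations with E-value > %g", n_before - len(ann), evalue_max)
    mapping = ann.set_index("contig")["gene"]
    annotated = contig_fpkm.index.intersection(mapping.index)
    n_dropped = len(contig_fpkm.index) - len(annotated)
    if n_dropped:
        log.info("dropped %d unannotated contigs", n_dropped)
    if len(annotated) == 0:
        warnings.warn("no annotated contigs; result is empty", stacklevel=2)
        empty = contig_fpkm.iloc[0:0]
        empty.index.name = "gene"
        return ExpressionMatrix(empty, metadata)
    sub = contig_fpkm.loc[annotated]
    gene_fpkm = sub.groupby(mapping.loc[annotated].values).sum()
    gene_fpkm.index.name = "gene"
    return ExpressionMatrix(gene_fpkm.sort_index(), metadata)


def filter_expressed(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose maximum species-level FPKM is ≥ ``threshold``.

    The boundary value itself is kept (the filter is "max ≥ 1 FPKM").
    """
    keep = m.species_max().max(axis=1) >= threshold
    log.info("expression filter kept %d of %d genes", int(keep.sum()), len(keep))
    return m.copy_with(m.values.loc[keep])


def rank_conserved_reference(
    values: pd.DataFrame,
    n_ref: int = 1000,
    window: tuple[float, float] = (0.20, 0.80),
) -> pd.Index:
    """The ``n_ref`` genes with the most conserved FPKM ranks across samples.

    Eligible genes sit inside the ``window`` fractional-rank band in every
    sample; the conservation score is the variance of the fractional rank
    across samples (smaller = more conserved), ties broken by gene id.
    """
    frac_rank = values.rank(axis=0, method="average") / len(values)
    lo, hi = window
    eligible = ((frac_rank >= lo) & (frac_rank <= hi)).all(axis=1)
    n_eligible = int(eligible.sum())
    if n_eligible < n_ref:
        raise ValueError(
            f"only {n_eligible} genes fall inside the {lo:.0%}–{hi:.0%} rank "
            f"window in every sample; lower n_ref (requested {n_ref})"
        )
    score = frac_rank[eligible].var(axis=1, ddof=1)
    order = score.sort_values(kind="stable").index
    # deterministic tie handling at the cutoff boundary
    ranked = sorted(zip(score.loc[order], order))
    return pd.Index([g for _, g in ranked[:n_ref]])


def rank_conserved_scaling(
    m: ExpressionMatrix,
    n_ref: int = 1000,
    window: tuple[float, float] = (0.20, 0.80),
) -> ExpressionMatrix:
    """Remove per-sample scale factors using a rank-conserved gene reference.

    Each sample is divided by the mean FPKM of the reference genes in that
    sample, then all values are multiplied by the grand mean of the
    reference genes so the output stays on the FPKM scale.  Identical
    samples are a fixed point; a global per-sample factor is removed
    exactly.  Refuses to re-scale an already scaled matrix.
    """
    if m.scaled:
        raise ValueError("matrix is already reference-scaled; refusing to re-scale")
    ref = rank_conserved_reference(m.values, n_ref=n_ref, window=window)
    sample_means = m.values.loc[ref].mean(axis=0)
    grand_mean = float(sample_means.mean())
    scaled = m.values.div(sample_means, axis=1) * grand_mean
    return m.copy_with(scaled, scaled=True)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the row-wise mean of the sorted columns.

    Ties within a column receive the mean of the quantile values they span
    (average-rank convention), so the output columns are permutations of one
    common sorted vector whenever there are no ties.
    """
    if (values.values < 0).any():
        raise ValueError("quantile normalization expects non-negative values")
    arr = values.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    ranks = values.rank(axis=0, method="average").to_numpy()
    out = np.interp(ranks, np.arange(1, len(values) + 1), mean_sorted)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def intersect_modified_genes(
    de_genes: Sequence[str], changed_genes: Sequence[str]
) -> list[str]:
    """Genes both differentially expressed and protein-changed ("modified")."""
    return sorted(set(de_genes) & set(changed_genes))


def pathway_enrichment(
    modified: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of each gene set among ``modified``.

    Rows: set name; columns: overlap, set size, odds ratio, raw and
    BH-adjusted p, significance at ``alpha``.  The universe defaults to the
    filtered expressed gene set of the analysis.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    mod = set(modified) & uni
    rows = []
    for name, members in gene_sets.items():
        mem = set(members) & uni
        a = len(mem & mod)
        b = len(mem - mod)
        c = len(mod - mem)
        d = len(uni) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, len(mem), odds, p))
    df = pd.DataFrame(
        rows, columns=["gene_set", "overlap", "set_size", "odds_ratio", "p_value"]
    ).set_index("gene_set")
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] < alpha
    return df


def annotation_consistency(
    member_annotations: Sequence[str],
    ath_members: Sequence[str] = (),
) -> float:
    """Annotation-consistency percentage of one orthogroup.

    With Arabidopsis members present: % of members annotated to any of the
    Arabidopsis gene ids in the group.  Without: the frequency of the most
    common annotation label.
    """
    annotations = list(member_annotations)
    if not annotations:
        raise ValueError("empty orthogroup")
    if ath_members:
        ath = set(ath_members)
        frac = sum(1 for a in annotations if a in ath) / len(annotations)
    else:
        counts: dict[str, int] = {}
        for a in annotations:
            counts[a] = counts.get(a, 0) + 1
        frac = max(counts.values()) / len(annotations)
    return 100.0 * frac
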