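"""Divergence matrices and per-node significance machinery.

Protein divergence between two coding sequences is the nonsynonymous rate dN
estimated by Nei–Gojobori (1986) counting: nonsynonymous sites are counted
per codon as the fraction of the three possible changes at each position
that alter the amino acid, observed differences are averaged over all
mutational pathways between the two codons (paths through stop codons
excluded), and the proportion pN = Nd/N is corrected for multiple hits with
the Jukes–Cantor formula dN = −(3/4)·ln(1 − (4/3)·pN).  Counting dN agrees
closely with codon-model ML for closely related congeners; externally
computed dN tables can be substituted wherever a dN vector is consumed.

Expression and morphology divergence are Euclidean distances on
quantile-normalized matrices relative to a reference species.  Per-node
significance of relative changes uses one-way ANOVA followed by all-pairs
Tukey HSD, with Benjamini–Hochberg adjustment applied on top of the Tukey
p-values across pairs (a deliberately conservative double adjustment).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats
from statsmodels.stats.multitest import multipletests

from c4evo.traits import NodeChangeProfile

__all__ = [
    "SaturationError",
    "dn_counting",
    "euclidean_divergence",
    "divergence_table",
    "fit_divergence_regression",
    "correlation_matrix",
    "change_rate",
    "anova_tukey_bh",
    "significance_stars",
]

log = logging.getLogger(__name__)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODON_TABLE.stop_codons)
_BASES = "ACGT"


class SaturationError(ValueError):
    """pN ≥ 3/4: the Jukes–Cantor correction is undefined (saturated)."""


def _translate(codon: str) -> str | None:
    if codon in _STOPS:
        return None
    return _CODON_TABLE.forward_table.get(codon)


def _nonsyn_sites(codon: str) -> float:
    """Nonsynonymous site count of one codon (changes to stops count as nonsyn)."""
    aa = _translate(codon)
    n = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _translate(mutant) != aa:
                n += 1.0 / 3.0
    return n


def _path_counts(a: str, b: str) -> tuple[float, float] | None:
    """(syn, nonsyn) differences between codons, averaged over mutation paths.

    Paths that traverse a stop codon are excluded; returns None when every
    path does (the codon pair is then uninformative).
    """
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        cur = a
        syn = nonsyn = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != b:
                ok = False
                break
            if _translate(cur) == _translate(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            totals.append((syn, nonsyn))
    if not totals:
        return None
    syn = float(np.mean([t[0] for t in totals]))
    nonsyn = float(np.mean([t[1] for t in totals]))
    return syn, nonsyn


def dn_counting(cds_a: str, cds_b: str) -> float:
    """Nei–Gojobori dN between two aligned, in-frame coding sequences.

    Sequences must be equal length and a multiple of 3; internal stop codons
    are rejected.  Codons containing gaps or ambiguous bases are skipped
    (count logged).  Raises :class:`SaturationError` when pN ≥ 3/4.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("coding sequences must be aligned to equal length")
    if len(a) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    sites_a = sites_b = 0.0
    nd = 0.0
    skipped = 0
    n_codons = len(a) // 3
    for i in range(n_codons):
        ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
        if any(ch not in _BASES for ch in ca + cb):
            skipped += 1
            continue
        internal = i < n_codons - 1
        if internal and (ca in _STOPS or cb in _STOPS):
            raise ValueError(f"internal stop codon at codon {i + 1}")
        if ca in _STOPS or cb in _STOPS:
            continue  # aligned terminal stop carries no information
        counts = _path_counts(ca, cb)
        if counts is None:
            skipped += 1
            continue
        sites_a += _nonsyn_sites(ca)
        sites_b += _nonsyn_sites(cb)
        nd += counts[1]
    if skipped:
        log.info("dn_counting skipped %d ambiguous/gapped codons", skipped)
    n_sites = (sites_a + sites_b) / 2.0
    if n_sites == 0:
        return 0.0
    p_n = nd / n_sites
    if p_n >= 0.75:
        raise SaturationError(f"pN = {p_n:.3f} ≥ 3/4; dN is saturated")
    return -0.75 * math.log(1.0 - 4.0 * p_n / 3.0) + 0.0


# -- Euclidean divergence ----------------------------------------------------------


def euclidean_divergence(values: pd.DataFrame, reference: str) -> pd.Series:
    """Euclidean distance of every column (species/sample) to ``reference``.

    Genes with a missing value in either member of a pair are excluded from
    that pair (exclusion counts logged).  The reference's distance to itself
    is exactly 0.
    """
    if reference not in values.columns:
        raise KeyError(f"reference {reference!r} not in matrix")
    ref = values[reference]
    out = {}
    for col in values.columns:
        pair = pd.concat([ref, values[col]], axis=1).dropna()
        n_excluded = len(values) - len(pair)
        if n_excluded:
            log.info("%s vs %s: excluded %d genes with missing values", reference, col, n_excluded)
        diff = pair.iloc[:, 0] - pair.iloc[:, 1]
        out[col] = float(np.sqrt((diff**2).sum()))
    series = pd.Series(out, name=f"distance_to_{reference}")
    series[reference] = 0.0
    return series


def divergence_table(
    reference: str,
    protein_dn: Mapping[str, float] | None = None,
    expression: pd.DataFrame | None = None,
    morphology: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-species divergence set relative to ``reference``.

    Columns among protein_dN / expression_distance / morphology_distance,
    depending on the inputs supplied.  Expression and morphology matrices
    are expected quantile-normalized.
    """
    parts = {}
    if protein_dn is not None:
        parts["protein_dN"] = pd.Series(dict(protein_dn))
    if expression is not None:
        parts["expression_distance"] = euclidean_divergence(expression, reference)
    if morphology is not None:
        parts["morphology_distance"] = euclidean_divergence(morphology, reference)
    if not parts:
        raise ValueError("no divergence component supplied")
    df = pd.DataFrame(parts)
    df.index.name = "species"
    return df


# -- regression and correlation ----------------------------------------------------


def fit_divergence_regression(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS fit of y on x: (slope, intercept, R², p).  R² = squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with ≥3 points")
    if np.var(x) == 0:
        raise ValueError("zero variance in x; regression undefined")
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2, res.pvalue


def correlation_matrix(profiles: Sequence[NodeChangeProfile]) -> pd.DataFrame:
    """Pearson correlations between per-node change profiles of feature classes."""
    df = pd.DataFrame({p.feature_class: p.changes for p in profiles}).dropna()
    return df.corr(method="pearson")


# -- change rates ------------------------------------------------------------------


def change_rate(
    profile: NodeChangeProfile, branch_lengths: Mapping[str, float]
) -> dict[str, float]:
    """|relative change| per unit branch length into each node."""
    rates = {}
    for node, change in profile.changes.items():
        length = branch_lengths.get(node)
        if length is None or length <= 0:
            warnings.warn(f"node {node}: zero/missing branch length, skipped", stacklevel=2)
            continue
        rates[node] = abs(change) / length
    return rates


# -- ANOVA / Tukey HSD / BH --------------------------------------------------------


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AnovaResult:
    f_statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame  # group1, group2, diff, p_tukey, p_adjusted, stars


def anova_tukey_bh(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA, all-pairs Tukey HSD, then BH across the pairs.

    Groups with fewer than 2 replicates are excluded with a warning.  Tukey
    p-values come from the studentized-range distribution with the pooled
    within-group variance (Tukey–Kramer for unbalanced groups); BH is
    applied on top across all pairs.
    """
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if len(arr) < 2:
            warnings.warn(f"group {name!r} has <2 replicates; excluded", stacklevel=2)
            continue
        clean[name] = arr
    if len(clean) < 2:
        raise ValueError("need at least two groups with ≥2 replicates")

    names = sorted(clean)
    arrays = [clean[n] for n in names]
    f_stat, p_omnibus = stats.f_oneway(*arrays)

    k = len(names)
    n_total = sum(len(a) for a in arrays)
    df_within = n_total - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_within

    rows = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(names), 2):
        a, b = arrays[i], arrays[j]
        diff = b.mean() - a.mean()
        se = math.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
        if se == 0:
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_within))
        rows.append((gi, gj, diff, min(max(p, 0.0), 1.0)))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "diff", "p_tukey"])
    pairwise["p_adjusted"] = multipletests(pairwise["p_tukey"], method="fdr_bh")[1]
    pairwise["stars"] = pairwise["p_adjusted"].map(significance_stars)
    return AnovaResult(float(f_stat), float(p_omnibus), pairwise)
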