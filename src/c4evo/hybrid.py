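"""Hybrid-origin screening from RNA-seq allele counts.

A hybrid between two species expresses both parental alleles, so the
genome-wide fraction of transcribed sites showing two different alleles
("mixed sites") is elevated.  Each sample's mixed-site ratio is compared
against a positive background built by pairwise in-silico mixing of all
samples — merged read counts mimic a true F1 — with one-sided binomial
tests: a sample is called hybrid-like when its mixed-site count is
significantly above the background reference rate, non-hybrid when
significantly below, inconclusive otherwise.

Allele counts are stored per sample as a site × (A, C, G, T) count table.
A site is evaluable when total coverage reaches ``min_cov``; it is mixed
when the second-most frequent base reaches both a minor-allele fraction and
an absolute minor count.  Single-locus heterozygosity cannot be separated
from hybridity; the verdict is genome-wide by design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlleleCountTable",
    "MixedSiteResult",
    "call_mixed_sites",
    "merge_counts",
    "mixing_background",
    "binomial_hybrid_test",
]

BASES = ("A", "C", "G", "T")


@dataclass
class AlleleCountTable:
    """Per-site base counts for one sample.

    ``counts`` is indexed by site id with columns A, C, G, T (non-negative
    integers).
    """

    sample_id: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [b for b in BASES if b not in self.counts.columns]
        if missing:
            raise ValueError(f"{self.sample_id}: missing base columns {missing}")
        self.counts = self.counts[list(BASES)]
        if (self.counts.values < 0).any():
            raise ValueError(f"{self.sample_id}: negative counts")
        if self.counts.index.duplicated().any():
            raise ValueError(f"{self.sample_id}: duplicate site ids")

    @classmethod
    def from_tsv(cls, path, sample_id: str | None = None) -> "AlleleCountTable":
        df = pd.read_csv(path, sep="\t")
        sid = sample_id or str(df["sample"].iloc[0])
        if "sample" in df.columns:
            df = df[df["sample"] == sid]
        return cls(sid, df.set_index("site")[list(BASES)])


@dataclass
class MixedSiteResult:
    """Mixed-site counts and (after testing) verdict for one sample."""

    sample_id: str
    n_evaluable: int
    n_mixed: int
    p_higher: float | None = None
    p_lower: float | None = None
    verdict: str | None = None  # hybrid-like | non-hybrid | inconclusive
    background: np.ndarray | None = field(default=None, repr=False)

    @property
    def ratio(self) -> float:
        return self.n_mixed / self.n_evaluable if self.n_evaluable else float("nan")


def _mixed_mask(
    counts: np.ndarray,
    min_cov: int,
    min_minor_frac: float,
    min_minor_count: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(evaluable mask, mixed mask) over sites for an (n_sites, 4) count array."""
    total = counts.sum(axis=1)
    evaluable = total >= min_cov
    part = np.sort(counts, axis=1)
    minor = part[:, -2]  # second-most-frequent base
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, minor / total, 0.0)
    mixed = evaluable & (frac >= min_minor_frac) & (minor >= min_minor_count)
    return evaluable, mixed


def call_mixed_sites(
    table: AlleleCountTable,
    min_cov: int = 10,
    min_minor_frac: float = 0.2,
    min_minor_count: int = 3,
) -> MixedSiteResult:
    """Count evaluable and mixed sites for one sample.

    A site is evaluable iff total coverage ≥ ``min_cov`` and mixed iff the
    second-most frequent base has frequency ≥ ``min_minor_frac`` and count
    ≥ ``min_minor_count``.
    """
    arr = table.counts.to_numpy(dtype=float)
    evaluable, mixed = _mixed_mask(arr, min_cov, min_minor_frac, min_minor_count)
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise ValueError(f"{table.sample_id}: no site reaches coverage {min_cov}")
    return MixedSiteResult(table.sample_id, n_eval, int(mixed.sum()))


def merge_counts(a: AlleleCountTable, b: AlleleCountTable) -> AlleleCountTable:
    """Site-wise sum of two samples' counts (union of sites).

    Commutative and associative; merging a sample with itself doubles
    coverage but cannot create new mixed sites.
    """
    merged = a.counts.add(b.counts, fill_value=0)
    return AlleleCountTable(f"{a.sample_id}+{b.sample_id}", merged)


def mixing_background(
    samples: Sequence[AlleleCountTable],
    min_cov: int = 10,
    min_minor_frac: float = 0.2,
    min_minor_count: int = 3,
) -> np.ndarray:
    """Mixed-site ratios of all C(n,2) pairwise in-silico sample mixtures."""
    if len(samples) < 2:
        raise ValueError("need at least two samples to build a mixing background")
    ratios = []
    for a, b in itertools.combinations(samples, 2):
        shared = a.counts.index.intersection(b.counts.index)
        if len(shared) == 0:
            import warnings

            warnings.warn(
                f"{a.sample_id}/{b.sample_id} share no sites; pair skipped", stacklevel=2
            )
            continue
        merged = merge_counts(a, b)
        try:
            res = call_mixed_sites(merged, min_cov, min_minor_frac, min_minor_count)
        except ValueError:
            continue
        ratios.append(res.ratio)
    return np.asarray(ratios)


def binomial_hybrid_test(
    result: MixedSiteResult,
    background: np.ndarray,
    alpha: float = 0.001,
    reference: str = "quantile",
) -> MixedSiteResult:
    """Complete a mixed-site result with binomial tests against the background.

    With ``reference="quantile"`` the null rate p0 for the "higher than
    background" test is the 5th percentile of the background ratios and the
    95th percentile for the "lower" test (conservative for both one-sided
    claims); ``reference="mean"`` uses the background mean for both.  The
    verdict is hybrid-like iff P(X ≥ n_mixed) < alpha, non-hybrid iff
    P(X ≤ n_mixed) < alpha, else inconclusive.
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("empty background")
    if result.n_evaluable == 0:
        raise ValueError("no evaluable sites")
    if reference == "quantile":
        p_hi = float(np.quantile(background, 0.05))
        p_lo = float(np.quantile(background, 0.95))
    elif reference == "mean":
        p_hi = p_lo = float(background.mean())
    else:
        raise ValueError(f"unknown reference rule {reference!r}")
    n, k = result.n_evaluable, result.n_mixed
    result.p_higher = float(stats.binom.sf(k - 1, n, p_hi))  # P(X >= k) at p0_low
    result.p_lower = float(stats.binom.cdf(k, n, p_lo))  # P(X <= k) at p0_high
    if result.p_higher < alpha:
        result.verdict = "hybrid-like"
    elif result.p_lower < alpha:
        result.verdict = "non-hybrid"
    else:
        result.verdict = "inconclusive"
    result.background = background
    return result
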