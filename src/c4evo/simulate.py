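"""Synthetic data generators with known ground truth for every pipeline stage.

The generators emulate the structure of the real analysis inputs — a 16-species
Flaveria-like phylogeny with C3 / C3-C4 / C4-like / C4 tips, Brownian trait
evolution with an optional burst at a chosen internal node, protein
alignments with clade-restricted substitutions inherited from a chosen node,
negative-binomial expression counts with lineage-specific fold changes, and
binomial allele counts for hybrid vs pure samples — so that recovery and
calibration experiments have exact truth available.

All randomness flows through one seeded numpy PCG64 generator per operation
(seed plus a fixed per-operation stream offset), so a scenario's seed fully
determines every output byte on every platform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from c4evo.hybrid import AlleleCountTable, BASES
from c4evo.sequences import AA_ALPHABET, ChangeEvent, ProteinAlignment
from c4evo.tree import FLAVERIA_TIP_TYPES, Node, PhyloTree, flaveria_tree, number_nodes

__all__ = [
    "SyntheticScenario",
    "scenario_tree",
    "random_yule_tree",
    "simulate_bm_traits",
    "simulate_protein_alignment",
    "simulate_expression",
    "simulate_allele_counts",
]

# fixed stream offsets so the per-operation generators are independent
_STREAM = {"tree": 1, "traits": 2, "sequences": 3, "expression": 4, "alleles": 5}


@dataclass
class SyntheticScenario:
    """Study-shaped simulation settings; the seed determines everything.

    Defaults mirror the study conditions: the 16-species tree, a burst at N7
    of 5 branch-SD units, ~50-fold expression changes in C4/C4-like lineages
    (C4-pathway transcripts in this genus are reported at roughly 8- to
    120-fold between C4 and C3 leaves), 2% parental
    divergence at 30× coverage over 50,000 sites for the hybrid screen, and
    0.1% sequencing error.
    """

    seed: int = 0
    # tree
    tree_kind: str = "flaveria"  # flaveria | yule
    n_tips: int = 16
    # continuous traits (BM); 30 mirrors the coded-morphology table
    n_traits: int = 30
    sigma2: float = 1.0
    root_value: float = 10.0
    burst_node: str | None = "N7"
    burst_sd: float = 5.0
    # protein alignments
    n_genes_protein: int = 5
    aligned_length: int = 300
    background_rate: float = 0.01  # substitutions per site per unit branch length
    n_injected_changes: int = 10
    change_node: str = "N7"
    # expression
    n_genes_expression: int = 6000
    n_de_genes: int = 440  # ≈7.3% of genes, the DE fraction seen in real C3/C4 leaf data
    fold_change: float = 50.0
    samples_per_species: int = 2
    nb_dispersion: float = 0.1
    lib_factor_sigma: float = 0.3
    mean_log_sigma: float = 2.0
    n_ref_genes: int = 1000
    # hybrid screen
    divergence: float = 0.02
    coverage: float = 30.0
    n_sites: int = 50_000
    error_rate: float = 0.001
    hybrid_parents: tuple[str, str] = ("F_cronquistii", "F_angustifolia")

    def __post_init__(self) -> None:
        self.hybrid_parents = tuple(self.hybrid_parents)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticScenario":
        return cls(**json.loads(text))


def scenario_tree(scenario: SyntheticScenario) -> PhyloTree:
    if scenario.tree_kind == "flaveria":
        return flaveria_tree()
    if scenario.tree_kind == "yule":
        return random_yule_tree(scenario.n_tips, scenario.rng("tree"))
    raise ValueError(f"unknown tree kind {scenario.tree_kind!r}")


def random_yule_tree(n_tips: int, rng: np.random.Generator) -> PhyloTree:
    """Random Yule (pure-birth) tree with exponential branch lengths."""
    if n_tips < 2:
        raise ValueError("need ≥2 tips")
    root = Node(length=0.0)
    leaves = [root.add_child(Node()), root.add_child(Node())]
    while len(leaves) < n_tips:
        idx = int(rng.integers(len(leaves)))
        leaf = leaves.pop(idx)
        leaves.append(leaf.add_child(Node()))
        leaves.append(leaf.add_child(Node()))
    for i, leaf in enumerate(leaves):
        leaf.label = f"t{i + 1}"
    for node in root.preorder():
        if node is not root:
            node.length = float(rng.exponential(1.0))
    return number_nodes(PhyloTree(root))


# -- Brownian traits ---------------------------------------------------------------


def simulate_bm_traits(
    scenario: SyntheticScenario, tree: PhyloTree | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Brownian trait evolution with an optional jump ("burst") at one node.

    Returns (tip table: species × traits, true node values: nodes × traits).
    The jump is ``burst_sd`` multiples of the branch increment's SD, added on
    the branch leading into ``burst_node``.  With ``sigma2 = 0`` all values
    equal the root value (plus any burst downstream).
    """
    tree = tree or scenario_tree(scenario)
    rng = scenario.rng("traits")
    sigma = float(np.sqrt(scenario.sigma2))
    tip_rows: dict[str, dict[str, float]] = {}
    node_rows: dict[str, dict[str, float]] = {}
    for k in range(scenario.n_traits):
        name = f"trait_{k + 1}"
        values: dict[int, float] = {}
        for node in tree.preorder():
            if node is tree.root:
                val = scenario.root_value
            else:
                step_sd = sigma * float(np.sqrt(node.length))
                val = values[id(node.parent)] + float(rng.normal(0.0, step_sd))
                if scenario.burst_node and node.label == scenario.burst_node:
                    burst_scale = step_sd if step_sd > 0 else float(np.sqrt(node.length))
                    val += scenario.burst_sd * burst_scale
            values[id(node)] = val
            target = tip_rows if node.is_tip else node_rows
            target.setdefault(node.label, {})[name] = val
    tips = pd.DataFrame(tip_rows).T.sort_index()
    nodes = pd.DataFrame(node_rows).T
    nodes = nodes.loc[sorted(nodes.index, key=lambda s: int(s[1:]) if s[1:].isdigit() else 0)]
    tips.index.name = nodes.index.name = "species"
    return tips, nodes


# -- protein alignments ------------------------------------------------------------


def _descendant_tips(node: Node) -> set[str]:
    return {n.label for n in node.preorder() if n.is_tip}


def simulate_protein_alignment(
    scenario: SyntheticScenario, tree: PhyloTree | None = None
) -> tuple[list[ProteinAlignment], list[ChangeEvent]]:
    """Alignments evolved on the tree plus the list of injected true changes.

    Each gene starts from a random root sequence; Poisson substitutions occur
    along branches at ``background_rate`` per site per unit branch length;
    ``n_injected_changes`` columns per gene additionally switch to a new
    residue on the branch into ``change_node`` and are inherited by all its
    descendants.  At zero background rate the caller recovers the injected
    events exactly.
    """
    tree = tree or scenario_tree(scenario)
    rng = scenario.rng("sequences")
    aa = np.frombuffer(AA_ALPHABET.encode(), dtype="S1").astype("U1")
    length = scenario.aligned_length
    alignments: list[ProteinAlignment] = []
    truth: list[ChangeEvent] = []
    change_tips = _descendant_tips(tree.find(scenario.change_node))
    for g in range(scenario.n_genes_protein):
        og = f"OG{g + 1:04d}"
        root_seq = rng.choice(len(aa), size=length)
        inject_cols = rng.choice(length, size=scenario.n_injected_changes, replace=False)
        inject_cols.sort()
        derived = {}
        for col in inject_cols:
            old = root_seq[col]
            new = int(rng.integers(len(aa) - 1))
            if new >= old:
                new += 1
            derived[int(col)] = new
            truth.append(
                ChangeEvent(
                    og,
                    int(col) + 1,
                    str(aa[old]),
                    str(aa[new]),
                    "substitution",
                    assigned_node=scenario.change_node,
                )
            )
        seqs: dict[int, np.ndarray] = {id(tree.root): root_seq}
        for node in tree.preorder():
            if node is tree.root:
                continue
            seq = seqs[id(node.parent)].copy()
            n_subs = int(rng.poisson(scenario.background_rate * node.length * length))
            if n_subs:
                pos = rng.integers(length, size=n_subs)
                shift = rng.integers(1, len(aa), size=n_subs)
                seq[pos] = (seq[pos] + shift) % len(aa)
            if node.label == scenario.change_node:
                for col, new in derived.items():
                    seq[col] = new
            seqs[id(node)] = seq
        tip_seqs = {
            tip.label: "".join(aa[seqs[id(tip)]]) for tip in tree.tips()
        }
        alignments.append(ProteinAlignment(og, tip_seqs))
    # truth is defined for tips below the change node; keep for reference
    assert change_tips  # the change node always has descendant tips
    return alignments, truth


_CODONS_BY_AA: dict[str, list[str]] | None = None


def _codons_by_aa() -> dict[str, list[str]]:
    global _CODONS_BY_AA
    if _CODONS_BY_AA is None:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        out: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            out.setdefault(aa, []).append(codon)
        _CODONS_BY_AA = {aa: sorted(cs) for aa, cs in out.items()}
    return _CODONS_BY_AA


def proteins_to_cds(
    alignments: list[ProteinAlignment], rng: np.random.Generator
) -> dict[str, dict[str, str]]:
    """Back-translate aligned proteins to in-frame CDS with random synonymous codons.

    Gaps become ``---``; codon choice is random among synonyms, so the CDS
    pairs carry synonymous noise on top of the protein differences (as real
    coding sequences do).  Returns {orthogroup: {species: cds}}.
    """
    table = _codons_by_aa()
    out: dict[str, dict[str, str]] = {}
    for aln in alignments:
        per_sp: dict[str, str] = {}
        for sp, seq in aln.sequences.items():
            codons = []
            for ch in seq:
                if ch == "-":
                    codons.append("---")
                else:
                    options = table[ch]
                    codons.append(options[int(rng.integers(len(options)))])
            per_sp[sp] = "".join(codons)
        out[aln.orthogroup_id] = per_sp
    return out


# -- expression --------------------------------------------------------------------


def simulate_expression(
    scenario: SyntheticScenario, tree: PhyloTree | None = None
) -> tuple["pd.DataFrame", pd.DataFrame, dict]:
    """Gene × sample FPKM matrix with NB noise, lineage folds and sample factors.

    Returns (fpkm, sample metadata, truth) where truth holds the DE gene
    ids, the per-sample residual factors and the per-gene base means.  DE
    genes are multiplied by ``fold_change`` in samples of every species
    descended from ``change_node`` (the C4/C4-like lineage of the default
    tree), making the expression effect lineage-specific.
    Counts are negative-binomial around the gene mean; the reported FPKM
    surrogate retains a log-normal per-sample factor (the cross-lab
    distortion that reference scaling is meant to remove), so
    ``rank_conserved_scaling`` should recover the factors.
    """
    tree = tree or scenario_tree(scenario)
    rng = scenario.rng("expression")
    genes = [f"AT{i + 1:07d}" for i in range(scenario.n_genes_expression)]
    species = tree.tip_labels()
    tip_types = {
        t.label: (t.tip_type or FLAVERIA_TIP_TYPES.get(t.label, "C3")) for t in tree.tips()
    }
    samples, meta_rows = [], []
    for sp in species:
        for r in range(scenario.samples_per_species):
            sid = f"{sp}_leaf_{r + 1}"
            samples.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "species": sp,
                    "organ": "leaf",
                    "lab": "lab1" if r % 2 == 0 else "lab2",
                    "photosynthetic_type": tip_types[sp],
                }
            )
    metadata = pd.DataFrame(meta_rows).set_index("sample")

    base_mean = rng.lognormal(mean=3.0, sigma=scenario.mean_log_sigma, size=len(genes))
    de_idx = rng.choice(len(genes), size=scenario.n_de_genes, replace=False)
    de_genes = sorted(genes[i] for i in de_idx)
    is_de = np.zeros(len(genes), dtype=bool)
    is_de[de_idx] = True
    lib_factors = rng.lognormal(mean=0.0, sigma=scenario.lib_factor_sigma, size=len(samples))

    upregulated = _descendant_tips(tree.find(scenario.change_node))
    fpkm = np.empty((len(genes), len(samples)))
    r_nb = 1.0 / scenario.nb_dispersion  # NB size parameter
    for j, sid in enumerate(samples):
        mu = base_mean.copy()
        if metadata.loc[sid, "species"] in upregulated:
            mu = np.where(is_de, mu * scenario.fold_change, mu)
        p = r_nb / (r_nb + mu)
        counts = rng.negative_binomial(r_nb, p)
        fpkm[:, j] = counts * lib_factors[j]
    values = pd.DataFrame(fpkm, index=pd.Index(genes, name="gene"), columns=samples)
    truth = {
        "de_genes": de_genes,
        "lib_factors": pd.Series(lib_factors, index=samples),
        "base_mean": pd.Series(base_mean, index=genes),
    }
    return values, metadata, truth


# -- allele counts -----------------------------------------------------------------


def _apply_errors(
    counts: np.ndarray, rng: np.random.Generator, error_rate: float
) -> np.ndarray:
    """Move a Binomial(error_rate) share of each base's reads to the other bases."""
    out = counts.astype(np.int64).copy()
    for b in range(4):
        n_err = rng.binomial(out[:, b], error_rate)
        out[:, b] -= n_err
        others = [x for x in range(4) if x != b]
        spread = rng.multinomial(n_err, [1 / 3] * 3)
        for k, o in enumerate(others):
            out[:, o] += spread[:, k]
    return out


def simulate_allele_counts(
    scenario: SyntheticScenario, tree: PhyloTree | None = None
) -> tuple[dict[str, AlleleCountTable], dict[str, bool]]:
    """Allele-count tables: one pure sample per species plus one F1 hybrid.

    Species haplotypes evolve along the tree (per-site substitution
    probability per branch calibrated so the two ``hybrid_parents`` end up
    ``divergence`` apart), giving the pairwise-mixing background the spread
    of divergences the test relies on.  Pure samples draw every read from
    their own haplotype; the F1 draws each read from either parental
    haplotype with probability 1/2.  Coverage is Poisson(``coverage``) per
    site and reads carry ``error_rate`` errors (uniform over other bases).
    Returns the tables plus truth flags {sample: is_hybrid}.
    """
    if not 0 <= scenario.divergence < 1:
        raise ValueError("divergence must be in (0, 1)")
    tree = tree or scenario_tree(scenario)
    rng = scenario.rng("alleles")
    n = scenario.n_sites

    pa, pb = scenario.hybrid_parents
    path_len = _path_length(tree, pa, pb)
    per_unit = scenario.divergence / path_len  # substitution prob per unit branch

    haplotypes: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            haplotypes[id(node)] = rng.integers(4, size=n)
            continue
        hap = haplotypes[id(node.parent)].copy()
        mut = rng.random(n) < per_unit * node.length
        shift = rng.integers(1, 4, size=int(mut.sum()))
        hap[mut] = (hap[mut] + shift) % 4
        haplotypes[id(node)] = hap
    tip_haps = {t.label: haplotypes[id(t)] for t in tree.tips()}

    sites = pd.Index([f"s{i + 1}" for i in range(n)], name="site")

    def reads_to_table(name: str, h1: np.ndarray, h2: np.ndarray | None) -> AlleleCountTable:
        cov = rng.poisson(scenario.coverage, size=n)
        counts = np.zeros((n, 4), dtype=np.int64)
        if h2 is None:
            np.add.at(counts, (np.arange(n), h1), cov)
        else:
            k1 = rng.binomial(cov, 0.5)
            np.add.at(counts, (np.arange(n), h1), k1)
            np.add.at(counts, (np.arange(n), h2), cov - k1)
        counts = _apply_errors(counts, rng, scenario.error_rate)
        return AlleleCountTable(name, pd.DataFrame(counts, index=sites, columns=list(BASES)))

    tables: dict[str, AlleleCountTable] = {}
    flags: dict[str, bool] = {}
    for sp in tree.tip_labels():
        tables[sp] = reads_to_table(sp, tip_haps[sp], None)
        flags[sp] = False
    f1_name = f"F1_{pa}x{pb}"
    tables[f1_name] = reads_to_table(f1_name, tip_haps[pa], tip_haps[pb])
    flags[f1_name] = True
    return tables, flags


def _path_length(tree: PhyloTree, a: str, b: str) -> float:
    anc = tree.mrca([a, b])
    total = 0.0
    for lab in (a, b):
        node = tree.find(lab)
        while node is not anc:
            total += node.length
            node = node.parent
    if total <= 0:
        raise ValueError(f"zero path length between {a} and {b}")
    return total
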