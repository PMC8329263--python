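"""Ancestral protein sequences and C3→C4 amino-acid change calling.

The change caller scans an aligned orthogroup for columns at which both C3
reference species carry one identical residue while at least two C4 species
share a different residue (or a shared gap, scored as an indel).  Called
changes are then placed on the phylogeny by marginal ancestral-sequence
reconstruction: a change is assigned to the earliest internal node whose
reconstructed residue is the derived (C4) state while its preceding node
still carries the ancestral (C3) state.

Reconstruction uses the pruning (sum-product) algorithm under an equal-rates
amino-acid model: all exchanges equally likely, uniform stationary
frequencies, with the gap character treated as a 21st state.  Branch lengths
are in expected substitutions per site.  The model is deliberately simple —
exact, deterministic and directly checkable against exhaustive enumeration —
and is pluggable through the ``n_states``/transition machinery below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from c4evo.tree import PhyloTree, preceding_node, _n_index
from c4evo.traits import NodeChangeProfile

__all__ = [
    "ProteinAlignment",
    "ChangeEvent",
    "AncestralSequenceSet",
    "call_c3c4_changes",
    "reconstruct_marginal_sequences",
    "assign_change_node",
    "per_node_change_counts",
    "stage_summary",
    "protein_relative_difference",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
STATES = AA_ALPHABET + GAP  # gap as 21st state
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)
UNKNOWN = "X"


@dataclass
class ProteinAlignment:
    """One orthogroup's aligned amino-acid sequences, one per species."""

    orthogroup_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.orthogroup_id}: aligned sequences differ in length {lengths}"
            )
        allowed = set(STATES + UNKNOWN)
        for sp, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - allowed
            if bad:
                raise ValueError(f"{self.orthogroup_id}/{sp}: invalid characters {bad}")
            self.sequences[sp] = seq

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def column(self, col: int) -> dict[str, str]:
        """1-based alignment column."""
        return {sp: seq[col - 1] for sp, seq in self.sequences.items()}

    @classmethod
    def from_fasta(cls, source, orthogroup_id: str) -> "ProteinAlignment":
        records = SeqIO.parse(source, "fasta")
        return cls(orthogroup_id, {r.id: str(r.seq) for r in records})

    def to_fasta(self) -> str:
        buf = StringIO()
        records = [
            SeqRecord(Seq(seq), id=sp, description="") for sp, seq in self.sequences.items()
        ]
        SeqIO.write(records, buf, "fasta")
        return buf.getvalue()


@dataclass
class ChangeEvent:
    """One called C3→C4 change: a substitution or a merged indel run."""

    orthogroup_id: str
    column: int  # 1-based start column
    c3_residue: str
    c4_residue: str
    kind: str  # substitution | insertion | deletion
    length: int = 1
    assigned_node: str | None = None
    posterior: float | None = None
    low_confidence: bool = False


@dataclass
class AncestralSequenceSet:
    """Reconstructed sequences at internal nodes with per-column max posteriors."""

    orthogroup_id: str
    sequences: dict[str, str]
    posterior: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def to_fasta(self) -> str:
        buf = StringIO()
        records = [
            SeqRecord(Seq(seq), id=label, description="")
            for label, seq in self.sequences.items()
        ]
        SeqIO.write(records, buf, "fasta")
        return buf.getvalue()


# -- change calling ----------------------------------------------------------------


def call_c3c4_changes(
    aln: ProteinAlignment,
    c3_ids: Sequence[str],
    c4_ids: Sequence[str],
    quorum: int = 2,
) -> list[ChangeEvent]:
    """Call columns differing between the C3 references and ≥``quorum`` C4 species.

    A column is called iff all present C3 sequences carry one identical
    non-gap residue (or, for insertions, all carry a gap) and at least
    ``quorum`` C4 sequences share an identical state different from it.
    Gaps and ``X`` in C4 sequences neither count toward nor veto the quorum;
    species absent from the alignment are simply excluded (incomplete
    assemblies are not evidence of disagreement).  Contiguous runs of
    gap-vs-residue columns are merged into single indel events.
    """
    present_c3 = [s for s in c3_ids if s in aln.sequences]
    present_c4 = [s for s in c4_ids if s in aln.sequences]
    if len(present_c3) < 2 or len(present_c4) < 2:
        raise ValueError(
            f"{aln.orthogroup_id}: need ≥2 C3 and ≥2 C4 sequences present "
            f"(have {len(present_c3)} C3, {len(present_c4)} C4)"
        )

    raw: list[ChangeEvent] = []
    for col in range(1, aln.aligned_length + 1):
        states = aln.column(col)
        c3_states = {states[s] for s in present_c3}
        if len(c3_states) != 1:
            continue  # C3 agreement required; includes any X
        c3_res = c3_states.pop()
        if c3_res == UNKNOWN:
            continue
        c4_informative = [
            states[s] for s in present_c4 if states[s] != UNKNOWN
        ]
        if c3_res == GAP:
            # candidate insertion: C4 residue where C3 has none
            counts = _state_counts(r for r in c4_informative if r != GAP)
            res, n = _argmax_count(counts)
            if res is not None and n >= quorum:
                raw.append(
                    ChangeEvent(aln.orthogroup_id, col, GAP, res, "insertion")
                )
            continue
        counts = _state_counts(r for r in c4_informative if r != c3_res)
        res, n = _argmax_count(counts)
        if res is None or n < quorum:
            continue
        kind = "deletion" if res == GAP else "substitution"
        raw.append(ChangeEvent(aln.orthogroup_id, col, c3_res, res, kind))
    return _merge_indel_runs(raw)


def _state_counts(residues: Iterable[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    return counts


def _argmax_count(counts: dict[str, int]) -> tuple[str | None, int]:
    if not counts:
        return None, 0
    res = max(sorted(counts), key=counts.get)
    return res, counts[res]


def _merge_indel_runs(events: list[ChangeEvent]) -> list[ChangeEvent]:
    """Merge runs of adjacent same-kind indel columns into single events."""
    out: list[ChangeEvent] = []
    for ev in events:
        if (
            out
            and ev.kind in ("insertion", "deletion")
            and out[-1].kind == ev.kind
            and out[-1].column + out[-1].length == ev.column
        ):
            out[-1].length += 1
            continue
        out.append(ev)
    return out


# -- marginal ancestral reconstruction ---------------------------------------------


def _transition_matrix(t: float, k: int = N_STATES) -> np.ndarray:
    """Equal-rates k-state transition matrix, t in substitutions/site."""
    e = np.exp(-k * t / (k - 1))
    p_same = 1.0 / k + (k - 1.0) / k * e
    p_diff = 1.0 / k - e / k
    mat = np.full((k, k), p_diff)
    np.fill_diagonal(mat, p_same)
    return mat


def _tip_likelihood(seq: str | None, length: int) -> np.ndarray:
    """(length, k) partial likelihoods; missing species and X are uninformative."""
    lik = np.ones((length, N_STATES))
    if seq is None:
        return lik
    for i, ch in enumerate(seq):
        if ch == UNKNOWN:
            continue
        lik[i] = 0.0
        lik[i, STATE_INDEX[ch]] = 1.0
    return lik


def reconstruct_marginal_sequences(
    tree: PhyloTree, aln: ProteinAlignment
) -> AncestralSequenceSet:
    """Marginal ancestral sequences at every internal node by sum-product.

    Per column the exact marginal posterior over the 21 states is computed
    with an inside (postorder) and outside (preorder) pass; the reported
    state is the argmax.  Species missing from the alignment contribute flat
    likelihoods.  Columns gapped in every present species are fixed to the
    gap state with posterior 1 by convention.
    """
    for node in tree.preorder():
        if node is not tree.root and node.length <= 0:
            raise ValueError("reconstruction requires strictly positive branch lengths")
    length = aln.aligned_length
    tips = tree.tips()

    all_gap = np.ones(length, dtype=bool)
    any_present = False
    for sp in aln.sequences:
        any_present = True
        arr = np.frombuffer(aln.sequences[sp].encode(), dtype="S1")
        all_gap &= arr == GAP.encode()
    if not any_present:
        raise ValueError("empty alignment")

    inside: dict[int, np.ndarray] = {}
    trans: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node is not tree.root:
            trans[id(node)] = _transition_matrix(node.length)
        if node.is_tip:
            inside[id(node)] = _tip_likelihood(aln.sequences.get(node.label), length)
        else:
            lik = np.ones((length, N_STATES))
            for child in node.children:
                lik *= inside[id(child)] @ trans[id(child)].T
            # rescale per column to avoid underflow on deep trees
            scale = lik.max(axis=1, keepdims=True)
            scale[scale == 0] = 1.0
            inside[id(node)] = lik / scale

    prior = np.full(N_STATES, 1.0 / N_STATES)
    outside: dict[int, np.ndarray] = {id(tree.root): np.tile(prior, (length, 1))}
    for node in tree.preorder():
        if node.is_tip:
            continue
        for child in node.children:
            msg = outside[id(node)].copy()
            for sib in node.children:
                if sib is not child:
                    msg *= inside[id(sib)] @ trans[id(sib)].T
            out = msg @ trans[id(child)]
            scale = out.max(axis=1, keepdims=True)
            scale[scale == 0] = 1.0
            outside[id(child)] = out / scale

    gap_idx = STATE_INDEX[GAP]
    sequences: dict[str, str] = {}
    posteriors: dict[str, np.ndarray] = {}
    for node in tree.internal_nodes():
        post = inside[id(node)] * outside[id(node)]
        norm = post.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        post = post / norm
        post[all_gap] = 0.0
        post[all_gap, gap_idx] = 1.0
        best = post.argmax(axis=1)
        sequences[node.label] = "".join(STATES[i] for i in best)
        posteriors[node.label] = post[np.arange(length), best]
    return AncestralSequenceSet(aln.orthogroup_id, sequences, posteriors)


# -- node assignment and summaries -------------------------------------------------


def assign_change_node(
    event: ChangeEvent,
    anc: AncestralSequenceSet,
    overrides: Mapping[str, str] | None = None,
    tree: PhyloTree | None = None,
    aln: ProteinAlignment | None = None,
    posterior_threshold: float = 0.5,
) -> str:
    """Place a called change on the tree.

    The assigned node is the earliest internal node (in N-number order) whose
    reconstructed state at the event column equals the derived C4 state while
    its preceding node still carries the ancestral C3 state.  If the derived
    state never appears at an internal node, the change happened on a
    terminal branch and the assignment is ``"after <parent label>"`` (requires
    ``tree`` and ``aln``).  Assignments with posterior below
    ``posterior_threshold`` are kept but flagged low-confidence.
    """
    col = event.column - 1
    ov = dict(overrides) if overrides else None
    labels = sorted(
        (lab for lab in anc.sequences if _n_index(lab) is not None),
        key=lambda lab: _n_index(lab),
    )
    for lab in labels:
        if _n_index(lab) == 1:
            continue
        pre = preceding_node(lab, ov)
        if pre not in anc.sequences:
            continue
        if (
            anc.sequences[lab][col] == event.c4_residue
            and anc.sequences[pre][col] == event.c3_residue
        ):
            event.assigned_node = lab
            event.posterior = float(anc.posterior[lab][col])
            event.low_confidence = event.posterior < posterior_threshold
            return lab
    # derived state first appears on a terminal branch
    if tree is not None and aln is not None:
        candidates = []
        for tip in tree.tips():
            seq = aln.sequences.get(tip.label)
            if seq is not None and seq[col] == event.c4_residue:
                parent = tip.parent.label if tip.parent is not None else "root"
                candidates.append((_n_index(parent) or 0, parent))
        if candidates:
            _, parent = min(candidates)
            label = f"after {parent}"
            event.assigned_node = label
            event.low_confidence = True
            return label
    event.assigned_node = "unassigned"
    event.low_confidence = True
    return "unassigned"


STAGES = ("before N5", "at N5", "at N6", "at N7", "after N7", "other")


def per_node_change_counts(
    events: Iterable[ChangeEvent],
) -> tuple[dict[str, int], dict[str, int]]:
    """Counts per assigned node plus the stage summary partition.

    Stage buckets: before N5 (N2–N4), at N5/N6/N7, after N7 (N8+ and
    terminal branches below N7), other (clade-B or unassigned).  Buckets
    always partition the events, so the stage counts sum to the total.
    """
    per_node: dict[str, int] = {}
    events = list(events)
    for ev in events:
        key = ev.assigned_node or "unassigned"
        per_node[key] = per_node.get(key, 0) + 1
    return per_node, stage_summary(events)


def stage_summary(
    events: Iterable[ChangeEvent], convention: str = "path"
) -> dict[str, int]:
    """Partition events into the N5/N6/N7 stage buckets.

    ``convention="path"`` counts only N2–N4 as "before N5", leaving clade-B
    assignments in "other"; ``convention="broad"`` folds everything outside
    the clade-A path (including clade B) into "before N5".
    """
    summary = {s: 0 for s in STAGES}
    for ev in events:
        node = ev.assigned_node or "unassigned"
        if node.startswith("after "):
            base = _n_index(node.split()[-1])
            summary["after N7" if base is not None and base >= 7 else "other"] += 1
            continue
        idx = _n_index(node)
        if idx is None:
            summary["other"] += 1
        elif idx < 5:
            summary["before N5"] += 1
        elif idx == 5:
            summary["at N5"] += 1
        elif idx == 6:
            summary["at N6"] += 1
        elif idx == 7:
            summary["at N7"] += 1
        elif idx <= 10:
            summary["after N7"] += 1
        else:
            summary["other"] += 1
    if convention == "broad":
        summary["before N5"] += summary.pop("other")
        summary["other"] = 0
    return summary


def protein_relative_difference(
    anc: AncestralSequenceSet | Sequence[AncestralSequenceSet],
    overrides: Mapping[str, str] | None = None,
) -> NodeChangeProfile:
    """Per-node relative protein difference vs the preceding node.

    For one gene: (number of columns differing between the node's and its
    predecessor's reconstructed sequences) / aligned length.  For a list of
    genes the transcriptome-wide value is the mean over genes.
    """
    sets = [anc] if isinstance(anc, AncestralSequenceSet) else list(anc)
    ov = dict(overrides) if overrides else None
    per_node: dict[str, list[float]] = {}
    for aset in sets:
        labels = [lab for lab in aset.sequences if _n_index(lab) is not None]
        for lab in labels:
            if _n_index(lab) == 1:
                continue
            pre = preceding_node(lab, ov)
            if pre not in aset.sequences:
                continue
            a, b = aset.sequences[lab], aset.sequences[pre]
            if len(a) != len(b):
                raise ValueError("reconstructed sequence length mismatch")
            diff = sum(1 for x, y in zip(a, b) if x != y)
            per_node.setdefault(lab, []).append(diff / len(a))
    profile = NodeChangeProfile(feature_class="protein")
    for lab, vals in per_node.items():
        profile.changes[lab] = float(np.mean(vals))
    return profile
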