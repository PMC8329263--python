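"""Change calling, marginal ancestral sequences and node assignment."""

import itertools

import numpy as np
import pytest

from c4evo.sequences import (
    AA_ALPHABET,
    N_STATES,
    STATES,
    ProteinAlignment,
    assign_change_node,
    call_c3c4_changes,
    per_node_change_counts,
    protein_relative_difference,
    reconstruct_marginal_sequences,
    stage_summary,
    _transition_matrix,
)
from c4evo.simulate import SyntheticScenario, random_yule_tree, simulate_protein_alignment
from c4evo.tree import flaveria_tree, number_nodes, parse_newick


def enumeration_posteriors(tree, aln):
    """Independent oracle: direct summation over all internal-state assignments.

    Builds the joint probability tensor with one axis per internal node via
    numpy broadcasting and marginalizes by summation — no message passing.
    Feasible for ≤6 tips (≤5 internal nodes, 21⁵ states).
    """
    internals = tree.internal_nodes()
    tips = tree.tips()
    axis = {id(n): i for i, n in enumerate(internals)}
    k = N_STATES
    length = aln.aligned_length
    out = {}
    for col in range(length):
        tensor = np.full([k] * len(internals), 1.0 / k)
        for node in tree.preorder():
            if node.parent is None:
                continue
            P = _transition_matrix(node.length)
            if node.is_tip:
                ch = aln.sequences.get(node.label, "X" * length)[col]
                if ch == "X":
                    continue
                vec = P[:, STATES.index(ch)]
                shape = [1] * len(internals)
                shape[axis[id(node.parent)]] = k
                tensor = tensor * vec.reshape(shape)
            else:
                sa, sb = axis[id(node.parent)], axis[id(node)]
                shape = [1] * len(internals)
                shape[sa] = k
                shape[sb] = k
                # orient P onto the (parent, child) axes
                mat = P if sa < sb else P.T
                tensor = tensor * mat.reshape(shape)
        for node in internals:
            other = tuple(i for i in range(len(internals)) if i != axis[id(node)])
            marg = tensor.sum(axis=other)
            out.setdefault(node.label, []).append(marg / marg.sum())
    return {lab: np.array(v) for lab, v in out.items()}


class TestCallChanges:
    def make(self, c3, c4):
        seqs = {f"c3_{i}": s for i, s in enumerate(c3)}
        seqs.update({f"c4_{i}": s for i, s in enumerate(c4)})
        return (
            ProteinAlignment("og", seqs),
            [f"c3_{i}" for i in range(len(c3))],
            [f"c4_{i}" for i in range(len(c4))],
        )

    def test_basic_substitution_with_quorum(self):
        aln, c3, c4 = self.make(["D", "D"], ["G", "G", "D", "-"])
        events = call_c3c4_changes(aln, c3, c4)
        assert len(events) == 1
        ev = events[0]
        assert (ev.c3_residue, ev.c4_residue, ev.kind) == ("D", "G", "substitution")
        assert ev.column == 1

    def test_c3_disagreement_blocks_call(self):
        aln, c3, c4 = self.make(["D", "E"], ["G", "G", "G", "G"])
        assert call_c3c4_changes(aln, c3, c4) == []

    def test_quorum_of_one_insufficient(self):
        aln, c3, c4 = self.make(["D", "D"], ["G", "A", "S", "T"])
        assert call_c3c4_changes(aln, c3, c4) == []

    def test_x_neither_counts_nor_vetoes(self):
        aln, c3, c4 = self.make(["D", "D"], ["G", "G", "X", "X"])
        assert len(call_c3c4_changes(aln, c3, c4)) == 1

    def test_shared_c4_gap_is_deletion(self):
        aln, c3, c4 = self.make(["D", "D"], ["-", "-", "D", "D"])
        events = call_c3c4_changes(aln, c3, c4)
        assert len(events) == 1
        assert events[0].kind == "deletion"

    def test_c3_gap_c4_residue_is_insertion(self):
        aln, c3, c4 = self.make(["-", "-"], ["G", "G", "G", "-"])
        events = call_c3c4_changes(aln, c3, c4)
        assert len(events) == 1
        assert events[0].kind == "insertion"

    def test_indel_run_merged(self):
        aln, c3, c4 = self.make(["DAAAD", "DAAAD"], ["D---D", "D---D", "D---D", "DAAAD"])
        events = call_c3c4_changes(aln, c3, c4)
        assert len(events) == 1
        assert events[0].kind == "deletion"
        assert events[0].length == 3
        assert events[0].column == 2

    def test_invariant_to_c4_order_and_gap_columns(self):
        aln, c3, c4 = self.make(["DK-", "DK-"], ["GK-", "GR-", "GX-", "DK-"])
        base = call_c3c4_changes(aln, c3, c4)
        for perm in itertools.permutations(c4):
            again = call_c3c4_changes(aln, c3, list(perm))
            assert [(e.column, e.c3_residue, e.c4_residue) for e in again] == [
                (e.column, e.c3_residue, e.c4_residue) for e in base
            ]

    def test_missing_species_excluded_not_disagreement(self):
        # two C4 assemblies absent: quorum met by the two present sequences
        seqs = {"c3_0": "D", "c3_1": "D", "c4_0": "G", "c4_1": "G"}
        aln = ProteinAlignment("og", seqs)
        events = call_c3c4_changes(aln, ["c3_0", "c3_1"], ["c4_0", "c4_1", "c4_2", "c4_3"])
        assert len(events) == 1

    def test_fewer_than_two_present_errors(self):
        aln = ProteinAlignment("og", {"c3_0": "D", "c4_0": "G", "c4_1": "G"})
        with pytest.raises(ValueError):
            call_c3c4_changes(aln, ["c3_0", "c3_1"], ["c4_0", "c4_1"])


class TestMarginalReconstruction:
    def test_uniform_column_high_posterior(self):
        tree = number_nodes(parse_newick("((A:.05,B:.05):.05,(C:.05,D:.05):.05);"))
        aln = ProteinAlignment("og", {sp: "A" for sp in "ABCD"})
        anc = reconstruct_marginal_sequences(tree, aln)
        for lab, seq in anc.sequences.items():
            assert seq == "A"
            assert anc.posterior[lab][0] >= 0.99

    def test_matches_enumeration_small_trees(self, rng):
        """Pruning equals direct-summation enumeration on ≤6-tip trees."""
        newicks = [
            "(A:1,B:0.5);",
            "((A:1,B:1):0.5,C:2);",
            "((A:.3,B:.8):.4,(C:.6,D:.2):.9);",
            "(((A:.5,B:.5):.5,C:1):.5,(D:.7,E:.7):.4);",
            "(((A:.5,B:.4):.3,(C:.2,D:.6):.7):.2,(E:.8,F:.3):.5);",
        ]
        aas = list(AA_ALPHABET[:8]) + ["-"]
        for nwk in newicks:
            tree = number_nodes(parse_newick(nwk))
            tips = tree.tip_labels()
            seqs = {t: "".join(rng.choice(aas, size=3)) for t in tips}
            seqs[tips[0]] = seqs[tips[0]][:2] + "X"  # exercise the unknown state
            aln = ProteinAlignment("og", seqs)
            anc = reconstruct_marginal_sequences(tree, aln)
            oracle = enumeration_posteriors(tree, aln)
            for lab in anc.sequences:
                for col in range(3):
                    mine = anc.posterior[lab][col]
                    state = anc.sequences[lab][col]
                    want = oracle[lab][col][STATES.index(state)]
                    assert abs(mine - want) < 1e-10
                    # reported state attains the oracle maximum
                    assert mine >= oracle[lab][col].max() - 1e-10

    def test_all_gap_column_convention(self, quartet):
        aln = ProteinAlignment("og", {sp: "-" for sp in "ABCD"})
        anc = reconstruct_marginal_sequences(quartet, aln)
        for lab in anc.sequences:
            assert anc.sequences[lab] == "-"
            assert anc.posterior[lab][0] == pytest.approx(1.0)

    def test_missing_species_uniform(self, quartet):
        aln = ProteinAlignment("og", {"A": "K", "B": "K", "C": "K"})  # D missing
        anc = reconstruct_marginal_sequences(quartet, aln)
        assert all(s == "K" for s in anc.sequences.values())


class TestNodeAssignment:
    def test_injected_changes_assigned_to_true_node(self, ftree, overrides, c3_ids, c4_ids):
        sc = SyntheticScenario(seed=5, background_rate=0.0, n_genes_protein=3)
        alignments, truth = simulate_protein_alignment(sc, ftree)
        for aln in alignments:
            events = call_c3c4_changes(aln, c3_ids, c4_ids)
            assert len(events) == sc.n_injected_changes
            anc = reconstruct_marginal_sequences(ftree, aln)
            for ev in events:
                assert assign_change_node(ev, anc, overrides, ftree, aln) == "N7"
                assert not ev.low_confidence

    def test_terminal_branch_changes_get_after_label(self, ftree, overrides, c3_ids, c4_ids):
        # derived residue in two C4 tips independently, never at an internal node
        seqs = {t.label: "A" for t in ftree.tips()}
        seqs["F_trinervia"] = "W"
        seqs["F_kochiana"] = "W"
        aln = ProteinAlignment("og", seqs)
        events = call_c3c4_changes(aln, c3_ids, c4_ids)
        assert len(events) == 1
        anc = reconstruct_marginal_sequences(ftree, aln)
        label = assign_change_node(events[0], anc, overrides, ftree, aln)
        assert label.startswith("after N")

    def test_stage_counts_partition(self, ftree, overrides, c3_ids, c4_ids):
        sc = SyntheticScenario(seed=8, background_rate=0.02, n_genes_protein=2)
        alignments, _ = simulate_protein_alignment(sc, ftree)
        all_events = []
        for aln in alignments:
            events = call_c3c4_changes(aln, c3_ids, c4_ids)
            anc = reconstruct_marginal_sequences(ftree, aln)
            for ev in events:
                assign_change_node(ev, anc, overrides, ftree, aln)
            all_events.extend(events)
        per_node, stages = per_node_change_counts(all_events)
        assert sum(per_node.values()) == len(all_events)
        assert sum(stages.values()) == len(all_events)
        broad = stage_summary(all_events, convention="broad")
        assert sum(broad.values()) == len(all_events)
        assert broad["other"] == 0

    def test_empty_event_list_all_zero(self):
        per_node, stages = per_node_change_counts([])
        assert per_node == {}
        assert all(v == 0 for v in stages.values())


class TestProteinRelativeDifference:
    def test_identical_sequences_zero(self, ftree, overrides):
        from c4evo.sequences import AncestralSequenceSet

        anc = AncestralSequenceSet("og", {f"N{i}": "AAAA" for i in range(1, 15)})
        prof = protein_relative_difference(anc, overrides)
        assert all(v == 0.0 for v in prof.changes.values())

    def test_direct_formula(self, overrides):
        from c4evo.sequences import AncestralSequenceSet

        seq1 = "A" * 100
        seq2 = "C" * 5 + "A" * 95
        anc = AncestralSequenceSet("og", {"N1": seq1, "N2": seq2})
        prof = protein_relative_difference(anc, overrides)
        assert prof.changes["N2"] == pytest.approx(0.05)

    def test_profile_maximal_at_injection_node(self, ftree, overrides):
        sc = SyntheticScenario(seed=21, background_rate=0.001, n_genes_protein=5)
        alignments, _ = simulate_protein_alignment(sc, ftree)
        anc_sets = [reconstruct_marginal_sequences(ftree, a) for a in alignments]
        prof = protein_relative_difference(anc_sets, overrides)
        assert prof.argmax_abs() == "N7"

    def test_pooled_is_mean_over_genes(self, overrides):
        from c4evo.sequences import AncestralSequenceSet

        a = AncestralSequenceSet("og1", {"N1": "AAAA", "N2": "CAAA"})
        b = AncestralSequenceSet("og2", {"N1": "AAAA", "N2": "CCAA"})
        prof = protein_relative_difference([a, b], overrides)
        assert prof.changes["N2"] == pytest.approx((0.25 + 0.5) / 2)
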