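"""Folding process: exact small aggregates, invariants, determinism."""

import numpy as np
import pytest

from geofold import (
    ContactNetwork,
    FoldingParams,
    attempt_link,
    graph_diameter,
    make_straight_chain,
    pairwise_distances,
    radius_of_gyration,
    run_ensemble,
    run_folding,
    trace_to_csv,
    violates_exclusion,
)


class TestAttemptLink:
    def test_triangle_closure(self):
        chain = make_straight_chain(3)
        net = ContactNetwork.backbone(3)
        outcome, folded = attempt_link(chain, net, (0, 2), FoldingParams(seed=0))
        assert outcome == "success"
        assert net.has_edge(0, 2)
        d = pairwise_distances(folded)
        off = d[~np.eye(3, dtype=bool)]
        # three mutually tangent unit spheres: all pair distances 1
        assert np.allclose(off, 1.0, atol=2e-2)

    def test_already_linked_rejected(self):
        chain = make_straight_chain(4)
        net = ContactNetwork.backbone(4)
        net.add_edge(0, 2)
        with pytest.raises(ValueError):
            attempt_link(chain, net, (0, 2))

    def test_backbone_adjacent_rejected(self):
        chain = make_straight_chain(4)
        with pytest.raises(ValueError):
            attempt_link(chain, ContactNetwork.backbone(4), (1, 2))

    def test_failure_leaves_chain_unchanged(self):
        # fold N=5 to completion, then any remaining pair must fail
        chain, net, _ = run_folding(5, FoldingParams(seed=0))
        open_pairs = [
            (i, j)
            for i in range(5)
            for j in range(i + 2, 5)
            if not net.has_edge(i, j)
        ]
        assert open_pairs, "five equal spheres cannot be mutually tangent"
        outcome, after = attempt_link(chain, net.copy(), open_pairs[0])
        assert outcome == "fail"
        assert np.allclose(after.positions, chain.positions)


class TestRunFolding:
    def test_two_beads_trivial(self):
        _, net, trace = run_folding(2, FoldingParams(seed=5))
        assert net.n_edges == 1
        assert trace.l == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_three_beads_always_triangle(self, seed):
        _, net, _ = run_folding(3, FoldingParams(seed=seed))
        assert net.n_edges == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_four_beads_always_tetrahedron(self, seed):
        chain, net, _ = run_folding(4, FoldingParams(seed=seed))
        assert net.n_edges == 6
        d = pairwise_distances(chain)
        off = d[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0, atol=2e-2)

    @pytest.mark.parametrize("seed", range(5))
    def test_five_beads_never_complete(self, seed):
        _, net, _ = run_folding(5, FoldingParams(seed=seed))
        assert net.n_edges < 10  # K5 needs five mutually tangent spheres

    def test_final_network_connected_with_backbone(self):
        _, net, _ = run_folding(24, FoldingParams(seed=3))
        for i in range(23):
            assert net.has_edge(i, i + 1)
        graph_diameter(net)  # raises if disconnected

    def test_compaction_shrinks_radius_of_gyration(self):
        chain, net, _ = run_folding(60, FoldingParams(seed=7), record_attempts=False)
        straight = make_straight_chain(60)
        assert radius_of_gyration(chain) < radius_of_gyration(straight)
        assert graph_diameter(net) < 59

    def test_max_degree_within_kissing_number(self):
        _, net, _ = run_folding(60, FoldingParams(seed=11), record_attempts=False)
        assert net.degrees().max() <= 12

    def test_edge_count_monotone_and_l_consistent(self):
        _, net, trace = run_folding(20, FoldingParams(seed=2))
        successes = [a for a in trace.attempts if a[1] == "success"]
        assert trace.l == len(successes)
        assert net.n_edges == 19 + trace.l

    def test_deterministic_given_seed(self):
        a = run_folding(15, FoldingParams(seed=42))
        b = run_folding(15, FoldingParams(seed=42))
        assert a[1].edges == b[1].edges
        assert np.array_equal(a[0].positions, b[0].positions)
        assert a[2].attempts == b[2].attempts

    def test_snapshots_at_requested_success_counts(self):
        _, _, trace = run_folding(20, FoldingParams(seed=9), snapshot_at=(0, 2, 5))
        ls = [l for l, _ in trace.snapshots]
        assert ls[0] == 0 and set(ls) <= {0, 2, 5}

    def test_heterogeneous_chain_folds_cleanly(self):
        params = FoldingParams(a=0.4, seed=13)
        chain, net, _ = run_folding(20, params, record_attempts=False)
        violated, _ = violates_exclusion(chain, params.tol_overlap)
        assert not violated
        assert net.n_edges > 19  # some non-backbone links formed

    def test_step_invariants_on_logged_run(self):
        """Excluded volume and bond conservation hold at every accepted
        dynamics step of a full N=60 folding (measured in-kernel)."""
        params = FoldingParams(seed=7)
        chain, net, trace = run_folding(60, params, validate=True,
                                        record_attempts=False)
        min_contact = 2 * chain.radii.min()
        assert trace.max_bond_violation <= params.tol_bond * min_contact + 1e-9
        assert trace.max_overlap_violation <= params.tol_overlap * min_contact + 1e-9
        # and the final state satisfies both invariants exactly as specified
        violated, _ = violates_exclusion(chain, params.tol_overlap)
        assert not violated
        d = pairwise_distances(chain)
        contact = chain.contact_distances()
        for i, j in net.edges:
            assert abs(d[i, j] - contact[i, j]) <= params.tol_bond * contact[i, j]

    def test_trace_csv_export(self, tmp_path):
        _, _, trace = run_folding(10, FoldingParams(seed=1))
        path = tmp_path / "trace.csv"
        trace_to_csv(trace, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "attempt_index,i,j,outcome,l"
        assert len(lines) == len(trace.attempts) + 1


class TestRunEnsemble:
    def test_n3_always_three_edges(self):
        table = run_ensemble([3], reps=5, params=FoldingParams(seed=0))
        assert len(table) == 5
        assert (table["edges"] == 3).all()

    def test_row_count_and_columns(self):
        table = run_ensemble([2, 3], reps=1, params=FoldingParams(seed=1))
        assert len(table) == 2
        assert {"N", "seed", "edges", "mean_degree", "diameter", "Rg",
                "lambda_second_largest"} <= set(table.columns)

    def test_seeds_deterministic(self):
        t1 = run_ensemble([3, 4], reps=2, params=FoldingParams(seed=5))
        t2 = run_ensemble([3, 4], reps=2, params=FoldingParams(seed=5))
        assert t1.equals(t2)
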