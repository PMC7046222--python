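"""PRN construction from Cα coordinates and its brute-force oracle."""

import numpy as np
import pytest

from geofold import (
    ResidueTrace,
    build_prn,
    generate_toy_pdb,
    mean_link_length,
    read_calpha,
)

COLLINEAR_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3      10.000   0.000   0.000  1.00  0.00           C
END
"""


def brute_force_prn(coords, d_c):
    """Independent O(N^2) oracle for the threshold network."""
    edges = set()
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            if 0 < np.linalg.norm(coords[i] - coords[j]) <= d_c:
                edges.add((i, j))
    return edges


class TestReadCalpha:
    def test_collinear_three_residues(self):
        trace = read_calpha(COLLINEAR_PDB)
        assert len(trace) == 3
        assert np.allclose(trace.coordinates[:, 0], [0, 5, 10])

    def test_non_ca_atoms_ignored(self):
        text = COLLINEAR_PDB.replace(
            "END",
            "ATOM      4  CB  ALA A   3      11.000   0.000   0.000"
            "  1.00  0.00           C\nEND",
        )
        assert len(read_calpha(text)) == 3

    def test_first_model_only(self):
        two_models = (
            "MODEL        1\n" + COLLINEAR_PDB.replace("END", "ENDMDL\n")
            + "MODEL        2\n"
            + COLLINEAR_PDB.replace("0.000   0.000   0.000", "9.000   9.000   9.000")
            .replace("END", "ENDMDL\nEND\n")
        )
        trace = read_calpha(two_models)
        assert len(trace) == 3
        assert np.allclose(trace.coordinates[0], [0, 0, 0])

    def test_no_ca_raises(self):
        with pytest.raises(ValueError):
            read_calpha("ATOM      1  CB  ALA A   1       0.000   0.000   0.000"
                        "  1.00  0.00           C\nEND\n")

    def test_highest_occupancy_altloc(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       3.000   0.000   0.000  0.70  0.00           C\n"
            "ATOM      3  CA  ALA A   2       5.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        trace = read_calpha(text)
        assert len(trace) == 2
        assert trace.coordinates[0, 0] == pytest.approx(3.0)


class TestBuildPrn:
    def test_collinear_default_cutoff(self):
        net = build_prn(read_calpha(COLLINEAR_PDB), d_c=6.5)
        assert net.edges == {(0, 1), (1, 2)}  # 10 A > 6.5 A

    def test_larger_cutoff_adds_long_edge(self):
        net = build_prn(read_calpha(COLLINEAR_PDB), d_c=12.0)
        assert net.edges == {(0, 1), (1, 2), (0, 2)}

    def test_square_excludes_diagonal(self):
        trace = read_calpha(generate_toy_pdb("square", 4, spacing=6.0))
        net = build_prn(trace, d_c=6.5)
        assert net.n_edges == 4  # diagonal 6*sqrt(2) ~ 8.49 A excluded
        assert not net.has_edge(0, 2) and not net.has_edge(1, 3)

    def test_boundary_distance_counts_as_connected(self):
        trace = ResidueTrace(np.array([[0.0, 0, 0], [6.5, 0, 0]]))
        assert build_prn(trace, d_c=6.5).has_edge(0, 1)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        trace = ResidueTrace(rng.uniform(0, 25, size=(40, 3)))
        prev = set()
        for d_c in (4.0, 5.0, 6.5, 8.0):
            edges = build_prn(trace, d_c).edges
            assert prev <= edges
            prev = edges

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        coords = rng.uniform(0, 20, size=(n, 3))
        trace = ResidueTrace(coords)
        assert build_prn(trace, 6.5).edges == brute_force_prn(coords, 6.5)

    def test_straight_trace_is_path_graph(self):
        # spacing s with s < d_c < 2s gives exactly the path graph
        s = 5.0
        trace = read_calpha(generate_toy_pdb("collinear", 12, spacing=s))
        net = build_prn(trace, d_c=6.5)
        assert net.edges == {(i, i + 1) for i in range(11)}

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            build_prn(read_calpha(COLLINEAR_PDB), d_c=-1.0)


class TestMeanLinkLength:
    def test_single_edge(self):
        trace = ResidueTrace(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        net = build_prn(trace, 6.5)
        assert mean_link_length(trace, net) == pytest.approx(5.0)

    def test_two_edges_average(self):
        trace = ResidueTrace(np.array([[0.0, 0, 0], [4.0, 0, 0], [10.0, 0, 0]]))
        net = build_prn(trace, 6.5)  # edges at 4 and 6
        assert mean_link_length(trace, net) == pytest.approx(5.0)

    def test_collinear_trace(self):
        trace = read_calpha(COLLINEAR_PDB)
        net = build_prn(trace, 6.5)
        assert mean_link_length(trace, net) == pytest.approx(5.0)

    def test_empty_network_raises(self):
        trace = ResidueTrace(np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        net = build_prn(trace, 6.5)
        with pytest.raises(ValueError):
            mean_link_length(trace, net)
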