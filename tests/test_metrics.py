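"""Network observables: degrees, diameter, R_g, Laplacian spectra."""

import numpy as np
import pytest

from geofold import (
    BeadChain,
    ContactNetwork,
    average_degree,
    degree_distribution,
    graph_diameter,
    laplacian_spectrum,
    make_straight_chain,
    radius_of_gyration,
    spectrum_histogram,
)


class TestDegrees:
    def test_path_distribution(self, path4):
        assert degree_distribution(path4) == {1: 0.5, 2: 0.5}

    def test_complete_distribution(self, complete4):
        assert degree_distribution(complete4) == {3: 1.0}

    def test_empty_graph(self):
        assert degree_distribution(ContactNetwork(3)) == {0: 1.0}

    def test_probabilities_sum_to_one(self, path4, complete4):
        for net in (path4, complete4):
            assert sum(degree_distribution(net).values()) == pytest.approx(1.0)

    def test_average_degree_path10(self):
        net = ContactNetwork.backbone(10)
        assert average_degree(net) == pytest.approx(1.8)

    def test_average_degree_triangle(self):
        net = ContactNetwork(3, {(0, 1), (1, 2), (0, 2)})
        assert average_degree(net) == pytest.approx(2.0)


class TestDiameter:
    def test_path(self):
        assert graph_diameter(ContactNetwork.backbone(17)) == 16

    def test_complete(self, complete4):
        assert graph_diameter(complete4) == 1

    def test_six_cycle(self):
        net = ContactNetwork(6, {(i, (i + 1) % 6) for i in range(6)})
        assert graph_diameter(net) == 3

    def test_disconnected_reports_components(self):
        net = ContactNetwork(4, {(0, 1), (2, 3)})
        with pytest.raises(ValueError, match="component sizes"):
            graph_diameter(net)

    def test_agrees_with_brute_force_bfs(self):
        import networkx as nx

        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g):
                continue
            net = ContactNetwork(n, set(map(tuple, g.edges())))
            # brute force: max over all-pairs BFS eccentricities
            brute = max(
                max(nx.single_source_shortest_path_length(g, s).values())
                for s in g
            )
            assert graph_diameter(net) == brute


class TestRadiusOfGyration:
    def test_single_point(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_collinear_three(self):
        assert radius_of_gyration(make_straight_chain(3)) == pytest.approx(
            np.sqrt(2 / 3)
        )

    def test_unit_square_corners(self, unit_square_chain):
        assert radius_of_gyration(unit_square_chain) == pytest.approx(np.sqrt(0.5))

    @pytest.mark.parametrize("n", range(2, 51))
    def test_closed_form_for_unit_spaced_chain(self, n):
        chain = make_straight_chain(n)
        expected = np.sqrt((n**2 - 1) / 12)
        assert radius_of_gyration(chain) == pytest.approx(expected, abs=1e-9)


class TestLaplacianSpectrum:
    def test_path2(self):
        spec = laplacian_spectrum(ContactNetwork.backbone(2))
        assert np.allclose(spec.eigenvalues, [0, 2], atol=1e-9)
        assert spec.second_largest == pytest.approx(0.0, abs=1e-9)

    def test_path3_closed_form(self):
        spec = laplacian_spectrum(ContactNetwork.backbone(3))
        assert np.allclose(spec.eigenvalues, [0, 1, 3], atol=1e-9)

    def test_complete4(self, complete4):
        spec = laplacian_spectrum(complete4)
        assert np.allclose(spec.eigenvalues, [0, 4, 4, 4], atol=1e-9)
        assert spec.second_largest == pytest.approx(4.0)
        assert spec.fiedler == pytest.approx(4.0)

    def test_trace_identity_and_zero_multiplicity(self):
        rng = np.random.default_rng(3)
        import networkx as nx

        for _ in range(8):
            n = int(rng.integers(4, 40))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(1 << 30)))
            net = ContactNetwork(n, set(map(tuple, g.edges())))
            spec = laplacian_spectrum(net)
            assert spec.eigenvalues.sum() == pytest.approx(2 * net.n_edges, abs=1e-6)
            assert spec.eigenvalues.min() >= -1e-9
            n_zero = int(np.sum(spec.eigenvalues < 1e-9))
            assert n_zero == nx.number_connected_components(g)

    def test_largest_bounded_by_twice_max_degree(self):
        net = ContactNetwork(6, {(0, i) for i in range(1, 6)})
        spec = laplacian_spectrum(net)
        assert spec.eigenvalues[-1] <= 2 * net.degrees().max() + 1e-9


class TestSpectrumHistogram:
    def test_two_value_spectrum(self):
        spec = laplacian_spectrum(ContactNetwork.backbone(2))  # {0, 2}
        centers, probs, peak = spectrum_histogram([spec], bin_width=1.0)
        assert probs[0] == pytest.approx(0.5)  # bin [0,1)
        assert probs[2] == pytest.approx(0.5)  # bin [2,3)
        assert peak == pytest.approx(0.5)  # tie broken toward smaller

    def test_duplication_invariance(self, complete4):
        spec = laplacian_spectrum(complete4)
        _, p1, peak1 = spectrum_histogram([spec], 0.5)
        _, p2, peak2 = spectrum_histogram([spec, spec, spec], 0.5)
        assert np.allclose(p1, p2)
        assert peak1 == peak2

    def test_normalized(self, path4, complete4):
        specs = [laplacian_spectrum(path4), laplacian_spectrum(complete4)]
        _, probs, _ = spectrum_histogram(specs, 0.5)
        assert probs.sum() == pytest.approx(1.0)

    def test_bad_bin_width(self, path4):
        with pytest.raises(ValueError):
            spectrum_histogram([laplacian_spectrum(path4)], 0.0)


def test_spectrum_requires_two_nodes():
    with pytest.raises(ValueError):
        laplacian_spectrum(ContactNetwork(1))
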