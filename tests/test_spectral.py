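import math

import numpy as np
import networkx as nx
import pytest

import latspec as ls
from latspec.graph import GraphError

from conftest import random_molecular_graph
from oracles import energy_from_charpoly, estrada_from_charpoly

E = math.e


class TestSpectrum:
    def test_p2(self, p2):
        s = ls.spectrum_of(p2)
        np.testing.assert_allclose(s.values, [1, -1], atol=1e-12)

    def test_star_spectrum(self, star5):
        """K_{1,k-1} has eigenvalues +-sqrt(k-1) and k-2 zeros."""
        s = ls.spectrum_of(star5)
        np.testing.assert_allclose(s.values, [2, 0, 0, 0, -2], atol=1e-12)

    def test_cycle_spectrum(self, c6):
        """C_k eigenvalues are 2 cos(2 pi j / k)."""
        s = ls.spectrum_of(c6)
        np.testing.assert_allclose(s.values, [2, 1, 1, -1, -1, -2], atol=1e-12)

    def test_sorted_descending_and_order_recorded(self):
        rng = np.random.default_rng(7)
        g = random_molecular_graph(rng, max_vertices=20)
        s = ls.spectrum_of(g)
        assert s.source_order == g.n_vertices
        assert (np.diff(s.values) <= 1e-12).all()

    def test_asymmetric_rejected(self):
        with pytest.raises(GraphError, match="symmetric"):
            ls.spectrum_of(np.array([[0, 1], [0, 0]]))


class TestDescriptors:
    @pytest.mark.parametrize("family, k, expected", [
        ("path", 2, 2.0),
        ("cycle", 6, 8.0),
        ("path", 3, 2 * math.sqrt(2)),
    ])
    def test_energy_closed_forms(self, family, k, expected):
        s = ls.spectrum_of(ls.reference_graph(family, k))
        assert ls.graph_energy(s) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("family, k, expected", [
        ("empty", 4, 4.0),
        ("path", 2, E + 1 / E),
        ("cycle", 6, E**2 + 2 * E + 2 / E + E**-2),
    ])
    def test_estrada_closed_forms(self, family, k, expected):
        s = ls.spectrum_of(ls.reference_graph(family, k))
        assert ls.estrada_index(s) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("family, k, inertia", [
        ("star", 5, (1, 3, 1)),
        ("cycle", 6, (3, 0, 3)),
        ("path", 3, (1, 1, 1)),
    ])
    def test_inertia(self, family, k, inertia):
        s = ls.spectrum_of(ls.reference_graph(family, k))
        assert ls.inertia_of(s) == inertia

    @pytest.mark.parametrize("family, k, sig_rank", [
        ("star", 5, (0, 2)),
        ("path", 3, (0, 2)),
        ("cycle", 6, (0, 6)),
    ])
    def test_signature_rank(self, family, k, sig_rank):
        s = ls.spectrum_of(ls.reference_graph(family, k))
        assert ls.signature_rank(s) == sig_rank

    def test_energy_zero_iff_edgeless(self):
        assert ls.graph_energy(ls.spectrum_of(ls.reference_graph("empty", 5))) == 0
        assert ls.graph_energy(ls.spectrum_of(ls.reference_graph("path", 5))) > 0


class TestOracleEquivalence:
    """Eigensolver route vs exact characteristic-polynomial roots."""

    @pytest.mark.parametrize("builder", [
        lambda: ls.reference_graph("path", 5),
        lambda: ls.reference_graph("cycle", 7),
        lambda: ls.reference_graph("star", 9),
        lambda: ls.reference_graph("complete", 5),
        lambda: ls.make_graph(
            [(v, "X") for v in range(10)],
            list(nx.gnp_random_graph(10, 0.4, seed=11).edges)),
        lambda: ls.make_graph(
            [(v, "X") for v in range(12)],
            list(nx.gnp_random_graph(12, 0.3, seed=5).edges)),
    ])
    def test_energy_and_estrada_match_charpoly_roots(self, builder):
        g = builder()
        a = ls.adjacency_of(g).entries
        s = ls.spectrum_of(g)
        assert ls.graph_energy(s) == pytest.approx(energy_from_charpoly(a), abs=1e-8)
        assert ls.estrada_index(s) == pytest.approx(estrada_from_charpoly(a), abs=1e-8)


class TestSpectralInvariants:
    def test_trace_identities_on_random_graphs(self):
        """Sum of eigenvalues is 0 (trace) and sum of squares is 2|E|."""
        rng = np.random.default_rng(123)
        for _ in range(30):
            g = random_molecular_graph(rng, max_vertices=40)
            v = ls.spectrum_of(g).values
            scale = max(1.0, float(np.abs(v).max()))
            assert abs(v.sum()) / (scale * len(v)) < 1e-8
            assert (v @ v) == pytest.approx(2 * g.n_edges, rel=1e-8)

    def test_estrada_matches_walk_series(self):
        """EE equals sum over k of trace(A^k)/k! (truncated at 30)."""
        for g in [ls.reference_graph("path", 5), ls.reference_graph("cycle", 6),
                  ls.reference_graph("star", 6), ls.bii3_sheet((1, 1))]:
            a = ls.adjacency_of(g).entries.astype(float)
            radius = float(np.abs(ls.spectrum_of(g).values).max())
            assert radius <= 6
            total, power = 0.0, np.eye(a.shape[0])
            for k in range(31):
                total += np.trace(power) / math.factorial(k)
                power = power @ a
            assert ls.estrada_index(ls.spectrum_of(g)) == pytest.approx(total, abs=1e-6)

    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("n", [1, 3])
    def test_bipartite_spectrum_symmetry(self, m, n):
        """Bipartite spectra are symmetric about zero, so s = 0, p = n-."""
        for g in (ls.bii3_sheet((m, n)), ls.benzene_ptype((m, n))):
            v = ls.spectrum_of(g).values
            np.testing.assert_allclose(v, -v[::-1], atol=1e-8)
            p, eta, n_minus = ls.inertia_of(ls.spectrum_of(g))
            assert p == n_minus
            assert ls.signature_rank(ls.spectrum_of(g))[0] == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(99)
        g = random_molecular_graph(rng, max_vertices=25)
        perm = rng.permutation(g.vertex_ids)
        mapping = dict(zip(g.vertex_ids, (int(x) for x in perm)))
        relabeled = ls.make_graph(
            [(mapping[v], g.elements[v]) for v in g.vertex_ids],
            [(mapping[u], mapping[v]) for u, v in g.edges])
        r1 = ls.descriptors_of(g, 1, 1)
        r2 = ls.descriptors_of(relabeled, 1, 1)
        assert r1.energy == pytest.approx(r2.energy, abs=1e-10)
        assert r1.estrada == pytest.approx(r2.estrada, abs=1e-10)
        assert (r1.p_plus, r1.eta, r1.n_minus) == (r2.p_plus, r2.eta, r2.n_minus)


class TestDescriptorSweep:
    def test_energy_grows_with_lattice_size(self):
        records = ls.descriptor_sweep("bii3", 3, range(1, 4))
        energies = [r.energy for r in records]
        assert energies == sorted(energies)
        assert len(set(energies)) == 3
        assert [(r.m, r.n) for r in records] == [(3, 1), (3, 2), (3, 3)]

    def test_reference_family_sweep(self):
        (rec,) = ls.descriptor_sweep("cycle", 1, [6])
        assert rec.energy == pytest.approx(8.0, abs=1e-10)

    def test_empty_range_rejected(self):
        with pytest.raises(GraphError, match="empty"):
            ls.descriptor_sweep("bii3", 3, [])

    def test_frame_layout(self):
        frame = ls.sweep_to_frame(ls.descriptor_sweep("bre", 1, range(1, 3)))
        assert list(frame.columns) == ["m", "n", "energy", "estrada", "p",
                                       "n_minus", "eta", "signature", "rank"]
        assert (frame["p"] + frame["n_minus"] + frame["eta"]).tolist() == [
            ls.benzene_ptype((1, n)).n_vertices for n in (1, 2)]
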