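"""Community quality metrics, classification, connectivity, boundaries."""

import numpy as np
import pandas as pd
import pytest

import larvanet as ln
from larvanet.mapeq import Partition
from larvanet.structmetrics import ClassifierConfig, boundary_bins
from larvanet.transportnet import FlowMap


def _fm(pairs):
    return FlowMap(
        pairs=pd.DataFrame(
            {
                "particle_id": range(len(pairs)),
                "spawn_cell": [p[0] for p in pairs],
                "settle_cell": [p[1] for p in pairs],
            }
        )
    )


def _part(assignment):
    nodes = np.array(sorted(assignment))
    return Partition(nodes=nodes, labels=np.array([assignment[n] for n in nodes]))


class TestClassify:
    @pytest.mark.parametrize(
        "rho,F,label",
        [
            (1.00, 0.17, "sink"),
            (0.93, 0.98, "source"),  # difference exactly at the 0.05 threshold
            (0.91, 0.90, "permeable"),
            (0.97, 0.95, "impermeable"),  # high cutoff is inclusive
            (1.00, 1.00, "impermeable"),
            (0.97, 0.94, "unclassified"),  # straddles the high cutoff
        ],
    )
    def test_decision_rule(self, rho, F, label):
        assert ln.classify(rho, F) == label

    def test_source_sink_takes_precedence(self):
        # both ratios high but far apart: sink, not impermeable
        assert ln.classify(1.00, 0.95, ClassifierConfig(delta=0.05, h=0.9)) == "sink"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ln.classify(1.2, 0.5)


class TestCoherenceFortress:
    def test_coherence_direct_count(self):
        # community 1 = {1}: spawns 10, retains 4
        pairs = [(1, 1)] * 4 + [(1, 2)] * 6 + [(2, 2)] * 5
        fm = _fm(pairs)
        part = _part({1: 1, 2: 2})
        assert ln.coherence(fm, part, 1) == pytest.approx(0.4)

    def test_full_retention_and_full_export(self):
        fm = _fm([(1, 1), (1, 1), (2, 1)])
        part = _part({1: 1, 2: 2})
        assert ln.coherence(fm, part, 1) == 1.0
        assert ln.coherence(fm, part, 2) == 0.0

    def test_fortress_direct_count(self):
        # community 1 receives 20 settlers, 5 spawned inside
        pairs = [(1, 1)] * 5 + [(2, 1)] * 15 + [(1, 2)] * 5 + [(2, 2)] * 10
        fm = _fm(pairs)
        part = _part({1: 1, 2: 2})
        assert ln.fortress(fm, part, 1) == pytest.approx(0.25)

    def test_fortress_complement_is_external_settlers(self):
        pairs = [(1, 1)] * 3 + [(2, 1)] * 7 + [(2, 2)] * 4
        fm = _fm(pairs)
        part = _part({1: 1, 2: 2})
        F = ln.fortress(fm, part, 1)
        external = 7 / 10
        assert 1 - F == pytest.approx(external)

    def test_no_settlers_reported_missing_with_warning(self):
        fm = _fm([(1, 2), (2, 2)])
        part = _part({1: 1, 2: 2})
        with pytest.warns(UserWarning, match="fortress"):
            assert np.isnan(ln.fortress(fm, part, 1))

    def test_invariant_to_relabeling_and_order(self, pd_flow_map, pd_partition):
        best, _ = pd_partition
        flipped = Partition(
            nodes=best.nodes,
            labels=best.n_communities + 1 - best.labels,  # reverse ids
        )
        for m in range(1, best.n_communities + 1):
            assert ln.coherence(pd_flow_map, best, m) == pytest.approx(
                ln.coherence(pd_flow_map, flipped, best.n_communities + 1 - m)
            )


class TestMixing:
    def _uniform_net(self):
        pairs = [(i, j) for i in range(4) for j in range(4)]
        return ln.to_network(_fm(pairs))

    def test_uniform_spreading_gives_unity(self):
        net = self._uniform_net()
        part = _part({i: 1 for i in range(4)})
        assert ln.mixing(net, part, 1) == pytest.approx(1.0)

    def test_deterministic_routing_gives_zero(self):
        pairs = [(0, 1), (1, 2), (2, 3), (3, 0)]
        net = ln.to_network(_fm(pairs))
        part = _part({i: 1 for i in range(4)})
        assert ln.mixing(net, part, 1) == 0.0

    def test_two_node_eighty_twenty_split(self):
        pairs = [(0, 0)] * 8 + [(0, 1)] * 2 + [(1, 1)] * 8 + [(1, 0)] * 2
        net = ln.to_network(_fm(pairs))
        part = _part({0: 1, 1: 1})
        h = -(0.8 * np.log2(0.8) + 0.2 * np.log2(0.2))
        assert ln.mixing(net, part, 1) == pytest.approx(h, abs=1e-9)

    def test_singleton_community_is_unity_by_convention(self):
        pairs = [(0, 0), (1, 1)]
        net = ln.to_network(_fm(pairs))
        part = _part({0: 1, 1: 2})
        assert ln.mixing(net, part, 1) == 1.0


class TestGlobalQuality:
    def test_equal_sized_communities_reduce_to_plain_mean(self):
        q = pd.DataFrame(
            {"community": [1, 2], "n_bins": [5, 5], "mixing": [0.2, 0.6],
             "coherence": [0.8, 1.0], "fortress": [0.9, 0.7]}
        )
        M, r, F = ln.global_quality(q)
        assert (M, r, F) == (pytest.approx(0.4), pytest.approx(0.9), pytest.approx(0.8))

    def test_single_community_passes_through(self):
        q = pd.DataFrame(
            {"community": [1], "n_bins": [7], "mixing": [0.45],
             "coherence": [0.93], "fortress": [0.94]}
        )
        assert ln.global_quality(q) == (
            pytest.approx(0.45), pytest.approx(0.93), pytest.approx(0.94)
        )

    def test_particle_weighted_coherence_equals_fortress(self, pd_flow_map, pd_partition):
        """Every retained particle spawns once and settles once, so the
        spawn-weighted coherence and settle-weighted fortress both equal
        (internally settled) / (total retained)."""
        best, _ = pd_partition
        from larvanet.structmetrics import _counts

        spawn, settle = _counts(pd_flow_map, best)
        total = len(spawn)
        internal = (spawn == settle).sum()
        comms = np.unique(best.labels)
        wc = sum(
            (spawn == m).sum() * ln.coherence(pd_flow_map, best, m) for m in comms
        ) / total
        wf = 0.0
        for m in comms:
            n_set = (settle == m).sum()
            if n_set:
                wf += n_set * ln.fortress(pd_flow_map, best, m)
        wf /= total
        assert wc == pytest.approx(wf, abs=1e-12)
        assert wc == pytest.approx(internal / total, abs=1e-12)


class TestConnectivityMatrix:
    def test_no_exchange_gives_identity(self):
        fm = _fm([(1, 1), (2, 2), (1, 1)])
        part = _part({1: 1, 2: 2})
        mat = ln.connectivity_matrix(fm, part)
        np.testing.assert_array_equal(mat.to_numpy(), np.eye(2))

    def test_seven_percent_transfer(self):
        pairs = [(1, 1)] * 93 + [(1, 2)] * 7 + [(2, 2)] * 10
        mat = ln.connectivity_matrix(_fm(pairs), _part({1: 1, 2: 2}))
        assert mat.loc[1, 2] == pytest.approx(0.07)

    def test_rows_sum_to_one(self, pd_flow_map, pd_partition):
        best, _ = pd_partition
        mat = ln.connectivity_matrix(pd_flow_map, best)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_diagonal_equals_coherence_exactly(self, pd_flow_map, pd_partition):
        best, _ = pd_partition
        mat = ln.connectivity_matrix(pd_flow_map, best)
        for m in np.unique(best.labels):
            assert mat.loc[m, m] == ln.coherence(pd_flow_map, best, m)


class TestBoundaryPersistence:
    def _line_partitions(self, grid):
        """Three adjacent cells A-B-C (a straight axial line)."""
        a = grid.cell(-63.0, 45.0)
        b = int(grid.neighbors(a)[0])
        c = int(grid.neighbors(b)[0])
        return a, b, c

    def test_identical_ensemble_gives_zero_or_one(self, grid):
        a, b, c = self._line_partitions(grid)
        part = _part({a: 1, b: 1, c: 2})
        df = ln.boundary_persistence(grid, [part] * 4)
        vals = dict(zip(df["cell_id"], df["persistence"]))
        assert vals[a] == 0.0 and vals[b] == 1.0 and vals[c] == 1.0

    def test_fraction_counts_boundary_solutions(self, grid):
        a, b, c = self._line_partitions(grid)
        split = _part({a: 1, b: 1, c: 2})
        merged = _part({a: 1, b: 1, c: 1})
        ensemble = [split] * 7 + [merged] * 3
        df = ln.boundary_persistence(grid, ensemble)
        vals = dict(zip(df["cell_id"], df["persistence"]))
        assert vals[b] == pytest.approx(0.7) and vals[c] == pytest.approx(0.7)
        assert vals[a] == 0.0

    def test_surrounded_by_own_community_is_never_boundary(self, grid):
        a = grid.cell(-63.0, 45.0)
        cells = {a: 1}
        for nb in grid.neighbors(a):
            cells[int(nb)] = 1
        mask = boundary_bins(grid, _part(cells))
        part = _part(cells)
        assert not mask[list(part.nodes).index(a)]

    def test_mismatched_cell_sets_rejected(self, grid):
        a, b, c = self._line_partitions(grid)
        with pytest.raises(ValueError, match="cell sets"):
            ln.boundary_persistence(grid, [_part({a: 1, b: 1}), _part({a: 1, c: 1})])


def test_community_quality_table_is_consistent(pd_flow_map, pd_network, pd_partition):
    best, _ = pd_partition
    q = ln.community_quality(pd_flow_map, pd_network, best)
    assert set(q["community"]) == set(np.unique(best.labels))
    assert q["n_bins"].sum() == len(best.nodes)
    finite = q[np.isfinite(q["fortress"])]
    assert ((finite["coherence"] >= 0) & (finite["coherence"] <= 1)).all()
    assert ((finite["mixing"] >= 0) & (finite["mixing"] <= 1)).all()
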