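"""Chromosome construction, state propagation, phenotype, and operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netherit import genotype as gt
from netherit.genotype import (
    IncompatibleParentsError,
    InvalidParameterError,
    LinearChromosome,
    NetworkChromosome,
)


def _random_network(n, rng):
    return gt.build_network(n, "random", rng)


class TestConstruction:
    def test_too_small_network_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            gt.build_network(1, "random", rng)

    def test_unknown_topology_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            gt.build_network(8, "ring", rng)

    def test_two_gene_network_is_forced(self, rng):
        for topo in gt.TOPOLOGIES:
            c = gt.build_network(2, topo, rng)
            assert c.heads.tolist() == [0]

    @pytest.mark.parametrize("topo", gt.TOPOLOGIES)
    @pytest.mark.parametrize("n", [2, 16, 64])
    def test_tree_edge_count(self, topo, n, rng):
        c = gt.build_network(n, topo, rng)
        outdeg = np.bincount(c.heads, minlength=n)
        assert outdeg.sum() == n - 1

    def test_head_indices_guarantee_acyclicity(self, rng):
        c = gt.build_network(128, "scale_free", rng)
        assert np.all(c.heads < np.arange(1, 128))

    def test_mutational_target_size(self, rng):
        for n in (2, 16, 256):
            c = gt.build_network(n, "random", rng)
            assert c.n_mutable == 2 * n - 1
        assert LinearChromosome(np.zeros(16, dtype=np.int8)).n_mutable == 16

    def test_invalid_head_rejected(self):
        with pytest.raises(InvalidParameterError):
            NetworkChromosome(np.array([0, 2]), np.array([1, 1]), 0)

    def test_scale_free_outdegree_more_dispersed(self, rng):
        """Preferential attachment concentrates edges on hubs."""
        reps, n = 1000, 256
        var = {}
        mx = {}
        for topo in gt.TOPOLOGIES:
            heads, _, _ = gt.build_networks_batch(n, topo, reps, rng)
            flat = heads + n * np.arange(reps)[:, None]
            deg = np.bincount(flat.ravel(), minlength=reps * n).reshape(reps, n)
            var[topo] = deg.var(axis=1).mean()
            mx[topo] = deg.max(axis=1).mean()
        assert var["scale_free"] > var["random"]
        assert mx["scale_free"] > mx["random"]


class TestPropagation:
    @pytest.mark.parametrize(
        "head_state,function,expected",
        [
            (0, 1, 0),  # off activator -> off
            (1, 1, 1),  # on activator -> on
            (1, 0, 0),  # on repressor -> off
            (0, 0, 1),  # off repressor -> on
        ],
    )
    def test_truth_table(self, head_state, function, expected):
        c = NetworkChromosome(np.array([0]), np.array([function]), head_state)
        assert gt.propagate_states(c)[1] == expected

    def test_all_activators_propagate_root(self, chain_network):
        assert gt.propagate_states(chain_network).tolist() == [1] * 6

    def test_scalar_and_batch_routes_agree(self, rng):
        for topo in gt.TOPOLOGIES:
            heads, funcs, roots = gt.build_networks_batch(40, topo, 25, rng)
            batch = gt.propagate_states_batch(heads, funcs, roots)
            for i in range(25):
                c = NetworkChromosome(heads[i], funcs[i], int(roots[i]))
                assert np.array_equal(gt.propagate_states(c), batch[i])
            ph = gt.phenotype_network_batch(heads, funcs, roots)
            for i in range(25):
                c = NetworkChromosome(heads[i], funcs[i], int(roots[i]))
                assert gt.phenotype_network(c) == pytest.approx(ph[i])


class TestPhenotype:
    def test_worked_example_eight_terminals_four_on(self, star_network):
        assert gt.phenotype_network(star_network) == pytest.approx(70.0)

    def test_full_and_empty_scale(self, star_network):
        allon = NetworkChromosome(star_network.heads, np.ones(8, dtype=np.int8), 1)
        alloff = NetworkChromosome(star_network.heads, np.ones(8, dtype=np.int8), 0)
        assert gt.phenotype_network(allon) == pytest.approx(140.0)
        assert gt.phenotype_network(alloff) == pytest.approx(0.0)

    def test_phenotype_bounded_and_proportional(self, rng):
        for _ in range(50):
            c = _random_network(int(rng.integers(2, 64)), rng)
            ph = gt.phenotype_network(c)
            term = gt.terminal_mask(c)
            on = gt.propagate_states(c)[term].sum()
            assert 0.0 <= ph <= 140.0
            assert ph == pytest.approx(140.0 * on / term.sum())

    def test_linear_phenotype(self):
        bits = np.zeros(16, dtype=np.int8)
        bits[:8] = 1
        assert gt.phenotype_linear(LinearChromosome(bits)) == pytest.approx(70.0)
        assert gt.phenotype_linear(LinearChromosome(np.ones(10))) == 140.0
        assert gt.phenotype_linear(LinearChromosome(np.zeros(10))) == 0.0


class TestMutation:
    def test_zero_rate_is_identity(self, rng):
        c = _random_network(32, rng)
        assert gt.mutate(c, 0.0, rng) == c
        l = LinearChromosome(rng.integers(0, 2, 20))
        assert gt.mutate(l, 0.0, rng) == l

    def test_rate_one_hits_every_element(self, rng):
        c = _random_network(16, rng)
        m = gt.mutate(c, 1.0, rng)
        assert m.root_state == c.root_state ^ 1
        assert np.array_equal(m.functions, c.functions ^ 1)
        # every head with an alternative regulator must change
        assert np.all(m.heads[1:] != c.heads[1:])
        assert m.heads[0] == 0  # gene 1 has no alternative
        assert np.all(m.heads < np.arange(1, 16))

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            gt.mutate(_random_network(4, rng), 1.5, rng)

    def test_linear_flip_fraction(self, rng):
        bits = np.zeros(1000, dtype=np.int8)
        m = gt.mutate(LinearChromosome(bits), 0.5, rng)
        assert abs(m.bits.mean() - 0.5) < 0.06

    def test_batch_route_matches_reference_semantics(self, rng):
        heads, funcs, roots = gt.build_networks_batch(16, "random", 200, rng)
        mh, mf, mr = gt.mutate_network_batch(heads, funcs, roots, 1.0, rng)
        assert np.array_equal(mf, funcs ^ 1)
        assert np.array_equal(mr, roots ^ 1)
        assert np.all(mh[:, 1:] != heads[:, 1:])
        assert np.all(mh[:, 0] == 0)
        assert np.all(mh < np.arange(1, 16))


class TestRecombination:
    def test_zero_rate_returns_one_parent(self, rng):
        a = _random_network(20, rng)
        b = _random_network(20, rng)
        child = gt.recombine(a, b, 0.0, rng)
        assert child == a or child == b

    def test_identical_parents_any_rate(self, rng):
        a = _random_network(20, rng)
        assert gt.recombine(a, a.copy(), 0.7, rng) == a

    def test_incompatible_parents_rejected(self, rng):
        with pytest.raises(IncompatibleParentsError):
            gt.recombine(_random_network(8, rng), _random_network(9, rng), 0.5, rng)
        with pytest.raises(IncompatibleParentsError):
            gt.recombine(
                _random_network(8, rng),
                LinearChromosome(np.zeros(8, dtype=np.int8)),
                0.5,
                rng,
            )

    def test_switch_count_matches_binomial_mean(self, rng):
        """r=0.5 over 101 loci: about (n-1)*r = 50 parent switches."""
        n, reps = 101, 400
        a = LinearChromosome(np.zeros(n, dtype=np.int8))
        b = LinearChromosome(np.ones(n, dtype=np.int8))
        switches = [
            int(np.abs(np.diff(gt.recombine(a, b, 0.5, rng).bits)).sum())
            for _ in range(reps)
        ]
        assert abs(np.mean(switches) - 50.0) < 1.5

    def test_batch_switch_count(self, rng):
        n, reps = 101, 2000
        bits = np.vstack([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
        mom = np.zeros(reps, dtype=np.int64)
        dad = np.ones(reps, dtype=np.int64)
        off = gt.recombine_linear_batch(bits, mom, dad, 0.5, rng)
        switches = np.abs(np.diff(off, axis=1)).sum(axis=1)
        assert abs(switches.mean() - 50.0) < 1.0

    def test_network_blocks_move_jointly(self, rng):
        """Head and function of a gene always come from the same parent."""
        n = 30
        a = _random_network(n, rng)
        b = _random_network(n, rng)
        # make parent B recognisable on both fields of every block
        b.functions = a.functions ^ 1
        child = gt.recombine(a, b, 0.5, rng)
        from_b = child.functions != a.functions
        same_head_where_a = child.heads[~from_b] == a.heads[~from_b]
        same_head_where_b = child.heads[from_b] == b.heads[from_b]
        assert same_head_where_a.all() and same_head_where_b.all()


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_acyclicity_closed_under_operators(seed):
    """Random walks of mutation/recombination never break head(i) < i."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 24))
    pool = [gt.build_network(n, "random", rng) for _ in range(4)]
    bound = np.arange(1, n)
    for _ in range(50):
        if rng.random() < 0.5:
            i = int(rng.integers(len(pool)))
            pool[i] = gt.mutate(pool[i], 0.3, rng)
        else:
            i, j = rng.integers(len(pool), size=2)
            pool[int(i)] = gt.recombine(pool[int(i)], pool[int(j)], 0.5, rng)
        for c in pool:
            assert np.all(c.heads < bound)
            assert np.all(c.heads >= 0)


class TestSerialization:
    def test_json_roundtrip(self, rng):
        c = _random_network(12, rng)
        assert gt.chromosome_from_json(gt.chromosome_to_json(c)) == c
        l = LinearChromosome(rng.integers(0, 2, 12))
        assert gt.chromosome_from_json(gt.chromosome_to_json(l)) == l

    def test_graph_exports(self, rng, tmp_path):
        c = _random_network(10, rng)
        g = gt.to_networkx(c)
        assert g.number_of_nodes() == 10 and g.number_of_edges() == 9
        gt.write_graphml(c, str(tmp_path / "net.graphml"))
        gt.write_dot(c, str(tmp_path / "net.dot"))
        text = (tmp_path / "net.dot").read_text()
        assert text.startswith("digraph") and "->" in text
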