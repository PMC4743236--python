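"""Random generation and augmentation: exact counts, parameter recovery,
core preservation and ensemble reproducibility."""

import numpy as np
import pytest
from scipy import stats as sps

from nrbnkit.generate import (
    AugmentationSpec,
    ConfigError,
    GenerationSpec,
    REGIME_PRESETS,
    augment,
    augment_ensemble,
    canalyzing_inhibitor,
    generate_ensemble,
    generate_functions,
    generate_network,
    generate_topology,
)
from nrbnkit.fixtures import synthetic_core
from nrbnkit.netio import network_to_text


class TestTopology:
    def test_erdos_renyi_exact_node_and_edge_counts(self):
        net = generate_topology(
            GenerationSpec(n_nodes=200, topology="erdos-renyi", m_edges=400, seed=1)
        )
        assert net.n_nodes == 200 and net.n_edges == 400

    def test_fixed_indegree_every_node_has_k_regulators(self):
        net = generate_topology(
            GenerationSpec(n_nodes=10, topology="fixed-indegree", k=2, seed=2)
        )
        assert all(d == 2 for d in net.in_degrees().values())

    def test_er_at_maximum_density_is_complete(self):
        net = generate_topology(
            GenerationSpec(n_nodes=5, topology="erdos-renyi", m_edges=20, seed=3)
        )
        assert net.n_edges == 20
        assert all(len(net.regulators_of(n)) == 4 for n in net.nodes)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ConfigError):
            generate_topology(
                GenerationSpec(n_nodes=5, topology="fixed-indegree", k=5, seed=0)
            )
        with pytest.raises(ConfigError):
            generate_topology(
                GenerationSpec(n_nodes=5, topology="erdos-renyi", m_edges=21, seed=0)
            )

    def test_er_indegree_distribution_is_binomial(self):
        """In-degree of a large sparse ER digraph follows Bin(n-1, p);
        chi-square goodness of fit at alpha=0.01 against the Poisson
        limit with the same mean."""
        n, m = 10_000, 20_000
        net = generate_topology(
            GenerationSpec(n_nodes=n, topology="erdos-renyi", m_edges=m, seed=4)
        )
        degs = np.array(list(net.in_degrees().values()))
        lam = m / n
        kmax = 8
        observed = np.array(
            [np.sum(degs == k) for k in range(kmax)] + [np.sum(degs >= kmax)]
        )
        pmf = sps.poisson.pmf(np.arange(kmax), lam)
        expected = np.append(pmf, 1 - pmf.sum()) * n
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < sps.chi2.ppf(0.99, df=kmax)

    def test_preferential_attachment_has_heavier_indegree_tail_than_er(self):
        n = 2000
        ba = generate_topology(
            GenerationSpec(n_nodes=n, topology="barabasi-preferential", k=2, seed=5)
        )
        er = generate_topology(
            GenerationSpec(n_nodes=n, topology="erdos-renyi", m_edges=ba.n_edges, seed=5)
        )
        # total degree tail (in+out), orientation is random
        def p99(net):
            tot = {v: 0 for v in net.nodes}
            for u, v in net.edges():
                tot[u] += 1
                tot[v] += 1
            return np.percentile(list(tot.values()), 99)

        assert p99(ba) > p99(er)

    def test_watts_strogatz_zero_rewiring_is_exact_ring_lattice(self):
        n, k = 12, 4
        net = generate_topology(
            GenerationSpec(n_nodes=n, topology="watts-strogatz", ws_k=k, ws_p=0.0, seed=6)
        )
        expected = set()
        for i in range(n):
            for d in range(1, k // 2 + 1):
                expected.add((net.nodes[i], net.nodes[(i + d) % n]))
                expected.add((net.nodes[(i + d) % n], net.nodes[i]))
        assert set(net.edges()) == expected

    def test_power_law_indegrees_within_bounds(self):
        net = generate_topology(
            GenerationSpec(n_nodes=100, topology="power-law", exponent=2.5, seed=7)
        )
        degs = list(net.in_degrees().values())
        assert min(degs) >= 1 and max(degs) <= 99


class TestFunctions:
    def test_degenerate_bias_one_gives_all_ones(self):
        topo = generate_topology(
            GenerationSpec(n_nodes=20, topology="erdos-renyi", m_edges=40, seed=8)
        )
        net = generate_functions(topo, "bias-random", bias=1.0, seed=8)
        assert all(all(b == 1 for b in f.table) for f in net.functions.values())

    def test_bias_recovered_within_binomial_ci(self):
        """At 10^4 sampled table bits the empirical fraction of ones lies
        within 3 sigma of the requested bias."""
        topo = generate_topology(
            GenerationSpec(n_nodes=400, topology="fixed-indegree", k=5, seed=9)
        )
        net = generate_functions(topo, "bias-random", bias=0.5, seed=9)
        bits = [b for f in net.functions.values() for b in f.table]
        n = len(bits)
        assert n >= 10_000
        phat = np.mean(bits)
        sigma = np.sqrt(0.5 * 0.5 / n)
        assert abs(phat - 0.5) < 3 * sigma

    def test_canalyzing_functions_have_forcing_input(self):
        topo = generate_topology(
            GenerationSpec(n_nodes=30, topology="fixed-indegree", k=3, seed=10)
        )
        net = generate_functions(topo, "canalyzing", bias=0.5, seed=10)
        for f in net.functions.values():
            k = f.arity
            forced = False
            for pos in range(k):
                for val in (0, 1):
                    outs = {
                        f.table[row]
                        for row in range(1 << k)
                        if (row >> (k - 1 - pos)) & 1 == val
                    }
                    if len(outs) == 1:
                        forced = True
            assert forced

    def test_canalyzing_inhibitor_silences_target_when_active(self):
        f = canalyzing_inhibitor(("miR", "tf"), "miR", rng=0)
        for row in range(4):
            if row >> 1 == 1:  # miR active
                assert f.table[row] == 0

    def test_logic_scheme_compiles_expressions_over_all_regulators(self):
        topo = generate_topology(
            GenerationSpec(n_nodes=20, topology="fixed-indegree", k=3, seed=11)
        )
        net = generate_functions(topo, "logic", seed=11)
        for name, f in net.functions.items():
            assert f.expression is not None
            assert set(f.inputs) == set(topo.regulators_of(name))

    def test_regime_presets_expose_both_chaotic_variants(self):
        assert REGIME_PRESETS["ordered"] == {"k": 2, "bias": 0.3}
        assert REGIME_PRESETS["critical"] == {"k": 2, "bias": 0.5}
        assert REGIME_PRESETS["chaotic"]["k"] == 3
        assert "chaotic-low-bias" in REGIME_PRESETS


class TestAugmentation:
    def test_fig_scale_augmentation_counts(self):
        """40 genes / 51 edges grown by 160 nodes and 349 edges gives
        exactly 200 nodes and 400 edges."""
        core = synthetic_core()
        out = augment(core, AugmentationSpec(n_nodes=200, m_edges=400, seed=12))
        assert out.n_nodes == 200 and out.n_edges == 400
        assert sum(out.core_flags.values()) == 40

    def test_empty_augmentation_is_identity(self):
        core = synthetic_core()
        out = augment(core, AugmentationSpec(n_nodes=40, m_edges=51, seed=13))
        assert network_to_text(out) == network_to_text(core)

    def test_core_edges_preserved_exactly(self):
        core = synthetic_core()
        out = augment(core, AugmentationSpec(n_nodes=120, m_edges=260, seed=14))
        core_set = set(core.nodes)
        restricted = {
            (u, v) for u, v in out.edges() if u in core_set and v in core_set
        }
        # deleting added edges within the core view recovers the core exactly
        assert set(core.edges()) <= restricted
        added_into_core = restricted - set(core.edges())
        for u, v in added_into_core:
            assert u not in core_set or v not in core_set  # never core->core

    def test_conservation_of_added_counts(self):
        core = synthetic_core()
        for n, m, s in [(50, 80, 1), (90, 200, 2), (200, 400, 3)]:
            out = augment(core, AugmentationSpec(n_nodes=n, m_edges=m, seed=s))
            assert out.n_nodes - core.n_nodes == n - 40
            assert out.n_edges - core.n_edges == m - 51

    def test_duplicate_then_bias_preserves_all_new_inputs_off_rows(self):
        core = synthetic_core()
        out = augment(
            core,
            AugmentationSpec(
                n_nodes=80, m_edges=200, seed=15,
                core_extension_policy="duplicate-then-bias",
            ),
        )
        for name in core.nodes:
            f0 = core.functions[name]
            f1 = out.functions[name]
            j = f1.arity - f0.arity
            assert f1.inputs[: f0.arity] == f0.inputs
            for row in range(1 << f0.arity):
                assert f1.table[row << j] == f0.table[row]

    def test_silent_policy_makes_new_inputs_nonfunctional(self):
        core = synthetic_core()
        out = augment(
            core,
            AugmentationSpec(
                n_nodes=80, m_edges=200, seed=16, core_extension_policy="silent"
            ),
        )
        for name in core.nodes:
            f0, f1 = core.functions[name], out.functions[name]
            j = f1.arity - f0.arity
            for row in range(1 << f1.arity):
                assert f1.table[row] == f0.table[row >> j]

    def test_protect_core_inputs_flag(self):
        core = synthetic_core()
        out = augment(
            core,
            AugmentationSpec(
                n_nodes=100, m_edges=250, seed=17, protect_core_inputs=True
            ),
        )
        for name in core.nodes:
            assert out.functions[name].inputs == core.functions[name].inputs

    def test_target_smaller_than_core_rejected(self):
        with pytest.raises(ConfigError):
            augment(synthetic_core(), AugmentationSpec(n_nodes=30, m_edges=60))


class TestEnsembles:
    def test_ensemble_shares_core_but_differs_elsewhere(self):
        core = synthetic_core()
        nets = augment_ensemble(
            core, AugmentationSpec(n_nodes=60, m_edges=120), count=5, seed=18
        )
        texts = {network_to_text(n) for n in nets}
        assert len(texts) == 5  # all distinct
        for net in nets:
            assert sum(net.core_flags.values()) == 40

    def test_same_master_seed_gives_byte_identical_ensembles(self):
        spec = GenerationSpec(n_nodes=30, topology="erdos-renyi", m_edges=60)
        a = generate_ensemble(spec, 4, seed=19)
        b = generate_ensemble(spec, 4, seed=19)
        assert [network_to_text(x) for x in a] == [network_to_text(x) for x in b]

    def test_singleton_ensemble(self):
        nets = generate_ensemble(
            GenerationSpec(n_nodes=10, topology="erdos-renyi", m_edges=20), 1, seed=20
        )
        assert len(nets) == 1
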