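"""Branch placement, species filtering and projection normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import REF_NEWICK_5_UNIFORM
from ercnet.errors import (EmptyResultError, FormatError, LabelError,
                           TopologyConflictError)
from ercnet.phylo_rates import (AverageRateVector, BranchRateMatrix,
                                compute_average_vector, filter_min_species,
                                load_gene_trees, normalize_relative_rates,
                                read_rate_matrix, transform_rates,
                                write_rate_matrix)
from ercnet.synthetic import SimulationConfig, simulate_phylogeny, \
    simulate_rate_matrix
from ercnet.topology import SpeciesTopology


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def _flat_topo(n_branches, n_species=3):
    """Artificial branch system for pure-arithmetic tests (no tree ops)."""
    species = tuple(chr(ord("a") + i) for i in range(n_species))
    return SpeciesTopology(species=species,
                           branch_ids=tuple((f"b{i}",) for i in range(n_branches)))


def _matrix(values, topo=None, species_sets=None):
    values = np.asarray(values, dtype=float)
    topo = topo or _flat_topo(values.shape[1])
    g = values.shape[0]
    sets = species_sets or (frozenset(topo.species),) * g
    return BranchRateMatrix(topology=topo, genes=tuple(f"g{i}" for i in range(g)),
                            values=values, species_sets=sets)


class TestLoading:
    def test_identity_tree_fills_every_branch(self, tmp_path, topo5):
        _write(tmp_path, "gene1.nwk", REF_NEWICK_5_UNIFORM)
        m = load_gene_trees(tmp_path, topo5)
        assert m.genes == ("gene1",)
        assert m.mask.all()
        np.testing.assert_allclose(m.values[0], 0.1)

    def test_pruned_leaf_absents_merged_branches(self, tmp_path, topo5):
        # drop e: pendant e vanishes, and the (d,e) branch merges with the
        # pendant of d, so both are absent; everything else still maps
        _write(tmp_path, "gene1.nwk",
               "((a:0.1,b:0.1):0.05,(c:0.1,d:0.2):0.05);")
        m = load_gene_trees(tmp_path, topo5)
        present = {b for b, ok in zip(topo5.branch_ids, m.mask[0]) if ok}
        # canonical ids name the side away from the anchor species 'a':
        # pendant a = (b,c,d,e); the ab|cde split = (c,d,e)
        assert present == {("b", "c", "d", "e"), ("b",), ("c",),
                           ("c", "d", "e")}
        idx = topo5.branch_index[("c", "d", "e")]
        assert m.values[0, idx] == 0.1  # root-flank lengths sum to one branch

    def test_file_order_is_irrelevant(self, tmp_path, topo5):
        rng = np.random.default_rng(5)
        trees = {}
        for k in range(6):
            L = rng.uniform(0.01, 0.5, 7).round(6)
            trees[f"g{k}"] = (f"((a:{L[0]},b:{L[1]}):{L[2]},"
                              f"(c:{L[3]},(d:{L[4]},e:{L[5]}):{L[6]}):0.0);")
        d1 = tmp_path / "fwd"
        d2 = tmp_path / "rev"
        d1.mkdir(), d2.mkdir()
        for name, nwk in trees.items():
            (d1 / f"{name}.nwk").write_text(nwk)
        for name in reversed(list(trees)):
            (d2 / f"{name}.nwk").write_text(trees[name])
        m1 = load_gene_trees(d1, topo5)
        m2 = load_gene_trees(sorted(d2.iterdir(), reverse=True), topo5)
        assert m1.genes == m2.genes
        assert np.array_equal(m1.values, m2.values, equal_nan=True)

    def test_unparseable_newick_names_the_file(self, tmp_path, topo5):
        bad = _write(tmp_path, "broken.nwk", "((a:0.1,b:0.2;;;")
        with pytest.raises(FormatError, match="broken.nwk"):
            load_gene_trees(tmp_path, topo5)

    def test_alien_leaf_rejected(self, tmp_path, topo5):
        _write(tmp_path, "gene1.nwk", "((a:1,zz:1):1,(c:1,d:1):1);")
        with pytest.raises(LabelError, match="zz"):
            load_gene_trees(tmp_path, topo5)

    def test_conflicting_topology_rejected(self, tmp_path, topo5):
        # (a,c) is not a split of the reference ((a,b),(c,(d,e)))
        _write(tmp_path, "gene1.nwk", "((a:1,c:1):1,(b:1,(d:1,e:1):1):1);")
        with pytest.raises(TopologyConflictError):
            load_gene_trees(tmp_path, topo5)

    def test_missing_branch_length_rejected(self, tmp_path, topo5):
        _write(tmp_path, "gene1.nwk", "((a:1,b),(c:1,(d:1,e:1):1):1);")
        with pytest.raises(FormatError, match="length"):
            load_gene_trees(tmp_path, topo5)


class TestFiltering:
    def _matrix_with_counts(self, counts):
        rng = np.random.default_rng(0)
        phylo = simulate_phylogeny(max(counts) + 1, rng=rng)
        species = list(phylo.topology.species)
        B = phylo.topology.n_branches
        sets = tuple(frozenset(species[:c]) for c in counts)
        vals = np.abs(rng.standard_normal((len(counts), B)))
        return BranchRateMatrix(topology=phylo.topology,
                                genes=tuple(f"g{i}" for i in range(len(counts))),
                                values=vals, species_sets=sets)

    def test_sixteen_of_thirtythree_dropped_at_seventeen(self):
        m = self._matrix_with_counts([16, 33, 17])
        out, dropped = filter_min_species(m, 17)
        assert out.genes == ("g1", "g2")
        assert dropped == [("g0", 16)]

    def test_threshold_two_keeps_everything(self):
        m = self._matrix_with_counts([5, 9, 12])
        out, dropped = filter_min_species(m, 2)
        assert out.n_genes == 3 and dropped == []

    def test_counting_over_a_range_of_coverages(self):
        m = self._matrix_with_counts(list(range(10, 20)))
        out, dropped = filter_min_species(m, 17)
        assert out.n_genes == 3
        assert len(dropped) == 7

    def test_all_dropped_is_an_error(self):
        m = self._matrix_with_counts([5, 6])
        with pytest.raises(EmptyResultError):
            filter_min_species(m, 30)


class TestAverageAndProjection:
    def test_average_is_the_columnwise_mean(self):
        m = _matrix([[1.0, 2.0], [3.0, 4.0]])
        avg = compute_average_vector(m)
        np.testing.assert_allclose(avg.values, [2.0, 3.0])
        assert list(avg.counts) == [2, 2]

    def test_single_contributor_branch(self):
        m = _matrix([[1.0, np.nan], [3.0, 4.0]])
        avg = compute_average_vector(m)
        np.testing.assert_allclose(avg.values, [2.0, 4.0])
        assert list(avg.counts) == [2, 1]

    def test_average_tracks_generator_truth(self):
        # a ~= t_i * E[mu * exp(sigma d)] for many background genes
        rng = np.random.default_rng(11)
        phylo = simulate_phylogeny(16, rng=rng)
        cfg = SimulationConfig(n_species=16, n_genes=3000, p_missing=0.0, seed=0)
        m, truth = simulate_rate_matrix(phylo, cfg, rng=rng)
        avg = compute_average_vector(m)
        expected = phylo.branch_times * np.exp(
            cfg.mu_meanlog + cfg.mu_sdlog ** 2 / 2) * np.exp(cfg.sigma ** 2 / 2)
        se = m.values.std(axis=0) / np.sqrt(cfg.n_genes)
        assert (np.abs(avg.values - expected) < 3 * se + 1e-12).mean() > 0.9

    def test_projection_formula_worked_example(self):
        # a=(1,2,2), b=(2,2,5): <b,a>=16, <a,a>=9 -> r = b - (16/9) a
        m = _matrix([[2.0, 2.0, 5.0]])
        avg = AverageRateVector(values=np.array([1.0, 2.0, 2.0]),
                                counts=np.array([1, 1, 1]))
        rel, bad = normalize_relative_rates(m, avg)
        assert bad == []
        np.testing.assert_allclose(rel.values[0],
                                   [2 - 16 / 9, 2 - 32 / 9, 5 - 32 / 9],
                                   atol=1e-12)

    def test_gene_proportional_to_average_projects_to_zero(self):
        avg = AverageRateVector(values=np.array([1.0, 2.0, 2.0]),
                                counts=np.array([3, 3, 3]))
        m = _matrix([[3.0, 6.0, 6.0]])
        rel, _ = normalize_relative_rates(m, avg)
        np.testing.assert_allclose(rel.values[0], 0.0, atol=1e-12)

    def test_restricted_orthogonality_with_missing_branch(self):
        avg = AverageRateVector(values=np.array([1.0, 2.0, 2.0]),
                                counts=np.array([2, 2, 2]))
        m = _matrix([[2.0, 3.0, np.nan]])
        rel, _ = normalize_relative_rates(m, avg)
        assert np.isnan(rel.values[0, 2])
        inner = rel.values[0, 0] * 1.0 + rel.values[0, 1] * 2.0
        assert abs(inner) < 1e-9

    def test_orthogonality_and_mask_conservation_on_simulated_data(self):
        rng = np.random.default_rng(3)
        phylo = simulate_phylogeny(20, rng=rng)
        cfg = SimulationConfig(n_species=20, n_genes=60, seed=0)
        m, _ = simulate_rate_matrix(phylo, cfg, rng=rng)
        avg = compute_average_vector(m)
        rel, bad = normalize_relative_rates(m, avg)
        assert bad == []
        assert np.array_equal(rel.mask, m.mask)
        a = np.where(avg.usable, avg.values, 0.0)
        r = np.where(rel.mask, rel.values, 0.0)
        np.testing.assert_allclose(r @ a, 0.0, atol=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=-8, max_value=8))
    def test_scale_equivariance_power_of_two(self, log2c):
        # multiplying a gene's lengths by c multiplies its residual by c;
        # powers of two make the float identity exact
        c = 2.0 ** log2c
        avg = AverageRateVector(values=np.array([0.5, 1.5, 2.5, 1.0]),
                                counts=np.array([2, 2, 2, 2]))
        base = np.array([[0.3, 0.9, 2.2, 0.7]])
        r1, _ = normalize_relative_rates(_matrix(base), avg)
        r2, _ = normalize_relative_rates(_matrix(c * base), avg)
        assert np.array_equal(r2.values, c * r1.values)

    def test_unusable_average_flags_gene_non_normalizable(self):
        avg = AverageRateVector(values=np.array([np.nan, np.nan, 2.0]),
                                counts=np.array([0, 0, 1]))
        m = _matrix([[1.0, 2.0, np.nan]])
        rel, bad = normalize_relative_rates(m, avg)
        assert bad == ["g0"]
        assert np.isnan(rel.values[0]).all()


class TestTransformsAndIO:
    def test_transforms(self):
        m = _matrix([[0.0, 1.0, 4.0]])
        np.testing.assert_allclose(transform_rates(m, "sqrt").values,
                                   [[0.0, 1.0, 2.0]])
        np.testing.assert_allclose(transform_rates(m, "log1p").values,
                                   np.log1p([[0.0, 1.0, 4.0]]))
        assert transform_rates(m, "none") is m
        with pytest.raises(ValueError):
            transform_rates(m, "boxcox")

    def test_tsv_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(8)
        phylo = simulate_phylogeny(12, rng=rng)
        cfg = SimulationConfig(n_species=12, n_genes=15, seed=0)
        m, _ = simulate_rate_matrix(phylo, cfg, rng=rng)
        path = tmp_path / "rates.tsv"
        write_rate_matrix(m, path, meta={"note": "fixture"})
        back = read_rate_matrix(path, topology=phylo.topology)
        assert back.genes == m.genes
        assert np.array_equal(back.values, m.values, equal_nan=True)
        assert back.species_sets == m.species_sets
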