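"""Random projections, encoders, ensemble runs and consensus partitions."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from scstab import (
    EnsembleConfig,
    NormalizedMatrix,
    Partition,
    SubspaceEnsembleClustering,
    consensus_partition,
    encode,
    random_projection,
    run_ensemble,
)
from scstab.ensemble import EnsembleResult, coassociation_matrix, member_seeds


def make_nm(n_genes=60, n_cells=30, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    return NormalizedMatrix(
        values=rng.normal(size=(n_genes, n_cells)),
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        labels=labels,
    )


class TestRandomProjection:
    def test_full_fraction_is_identity(self):
        nm = make_nm()
        proj = random_projection(nm, 1.0, member_seed=1)
        assert proj.gene_ids == nm.gene_ids
        assert np.array_equal(proj.values, nm.values)

    def test_half_fraction_subsets_genes(self):
        nm = make_nm(n_genes=500)
        proj = random_projection(nm, 0.5, member_seed=1)
        assert proj.n_genes == 250
        assert set(proj.gene_ids) <= set(nm.gene_ids)
        assert len(set(proj.gene_ids)) == 250

    def test_different_seeds_differ(self):
        nm = make_nm(n_genes=200)
        a = random_projection(nm, 0.2, member_seed=7)
        b = random_projection(nm, 0.2, member_seed=8)
        assert a.gene_ids != b.gene_ids

    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="fraction"):
            random_projection(make_nm(), 0.0, member_seed=1)

    def test_floor_exceeding_genes_rejected(self):
        with pytest.raises(ValueError, match="genes"):
            random_projection(make_nm(n_genes=10), 0.1, member_seed=1, min_genes=20)


class TestEncode:
    @pytest.mark.parametrize("encoder", ["autoencoder", "pca_fallback"])
    def test_shape_and_determinism(self, encoder):
        nm = make_nm(n_genes=40, n_cells=25)
        a = encode(nm, 5, epochs=3, member_seed=2, encoder=encoder)
        b = encode(nm, 5, epochs=3, member_seed=2, encoder=encoder)
        assert a.shape == (25, 5)
        assert np.array_equal(a, b)

    def test_pca_recovers_low_rank_structure(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 40))
        coords = rng.normal(size=(30, 2))
        X = coords @ basis  # exactly rank 2, cells x genes
        nm = NormalizedMatrix(values=X.T, gene_ids=[f"g{i}" for i in range(40)],
                              cell_ids=[f"c{i}" for i in range(30)])
        enc = encode(nm, 2, epochs=1, member_seed=0, encoder="pca_fallback")
        # reconstruction from the 2-dim encoding is exact for a rank-2 matrix
        recon, *_ = np.linalg.lstsq(enc - enc.mean(0), X - X.mean(0), rcond=None)
        err = np.linalg.norm((enc - enc.mean(0)) @ recon - (X - X.mean(0)))
        assert err / np.linalg.norm(X - X.mean(0)) < 1e-6

    def test_encode_dim_must_be_smaller_than_genes(self):
        with pytest.raises(ValueError, match="encode_dim"):
            encode(make_nm(n_genes=5), 5, epochs=1, member_seed=0)

    def test_nonfinite_input_rejected(self):
        nm = make_nm(n_genes=20)
        nm.values[0, 0] = np.nan
        with pytest.raises(ValueError):
            encode(nm, 4, epochs=1, member_seed=0)


class TestEnsembleConfig:
    def test_b_must_allow_pairs(self):
        with pytest.raises(ValueError, match="B"):
            EnsembleConfig(B=1)

    def test_k_one_rejected(self):
        with pytest.raises(ValueError, match="k"):
            EnsembleConfig(k=1)

    def test_plugin_requires_function(self):
        with pytest.raises(ValueError, match="plugin"):
            EnsembleConfig(base_clusterer="plugin")


class TestRunEnsemble:
    def _cfg(self, **kw):
        base = dict(B=4, projection_fraction=0.5, encode_dim=5,
                    encoder="pca_fallback", k=3, seed=0)
        base.update(kw)
        return EnsembleConfig(**base)

    def test_member_count_and_coassociation_range(self):
        er = run_ensemble(make_nm(), self._cfg())
        assert len(er.members) == 4
        assert np.all((0.0 <= er.coassociation) & (er.coassociation <= 1.0))
        assert np.allclose(np.diag(er.coassociation), 1.0)
        assert np.allclose(er.coassociation, er.coassociation.T)

    def test_coassociation_conservation(self):
        """Sum of co-association equals the mean member same-pair count."""
        er = run_ensemble(make_nm(n_cells=20), self._cfg())
        n = 20
        iu = np.triu_indices(n, k=1)
        co_sum = er.coassociation[iu].sum()
        member_pairs = []
        for m in er.members:
            lab = m.as_array()
            member_pairs.append(
                sum(lab[i] == lab[j] for i, j in zip(*iu))
            )
        assert co_sum == pytest.approx(np.mean(member_pairs))

    def test_k_exceeding_cells_rejected(self):
        with pytest.raises(ValueError, match="cells"):
            run_ensemble(make_nm(n_cells=4), self._cfg(k=5))

    def test_end_to_end_determinism(self):
        a = run_ensemble(make_nm(), self._cfg(seed=3))
        b = run_ensemble(make_nm(), self._cfg(seed=3))
        assert all(x.assignment == y.assignment for x, y in zip(a.members, b.members))
        assert np.array_equal(a.coassociation, b.coassociation)

    def test_cell_permutation_metamorphic(self, three_type_norm):
        # k-means initialisation sees cells in order, so exact member equality
        # is only guaranteed up to the clustering's own stability; on clearly
        # structured data the recovered partitions must agree.
        cfg = self._cfg(B=4, projection_fraction=0.1, encode_dim=8, k=3)
        n = three_type_norm.n_cells
        perm = np.random.default_rng(1).permutation(n)
        nm_perm = NormalizedMatrix(values=three_type_norm.values[:, perm],
                                   gene_ids=three_type_norm.gene_ids,
                                   cell_ids=[three_type_norm.cell_ids[i] for i in perm])
        er = run_ensemble(three_type_norm, cfg)
        er_perm = run_ensemble(nm_perm, cfg)
        for m, mp in zip(er.members, er_perm.members):
            assert adjusted_rand_score(np.asarray(m.assignment)[perm],
                                       mp.assignment) >= 0.95

    def test_plugin_clusterer(self):
        calls = []

        def fake(X, k, seed):
            calls.append((X.shape, k))
            return np.arange(X.shape[0]) % k

        cfg = self._cfg(base_clusterer="plugin", clusterer_fn=fake)
        er = run_ensemble(make_nm(), cfg)
        assert len(calls) == 4
        assert all(m.n_clusters == 3 for m in er.members)

    def test_failing_member_identified(self):
        def broken(X, k, seed):
            raise RuntimeError("boom")

        cfg = self._cfg(base_clusterer="plugin", clusterer_fn=broken)
        with pytest.raises(RuntimeError, match="member 0"):
            run_ensemble(make_nm(), cfg)

    def test_well_separated_members_recover_labels(self, three_type_norm):
        cfg = self._cfg(B=5, projection_fraction=0.1, encode_dim=8, k=3)
        er = run_ensemble(three_type_norm, cfg)
        for m in er.members:
            assert adjusted_rand_score(three_type_norm.labels, m.assignment) >= 0.9


class TestConsensus:
    def test_identical_members_reproduced(self):
        members = [Partition([1, 1, 2, 2, 3, 3])] * 4
        er = EnsembleResult(members=members,
                            coassociation=coassociation_matrix(members),
                            config=EnsembleConfig(B=4, k=3, encode_dim=1))
        cons = consensus_partition(er, 3)
        assert adjusted_rand_score([1, 1, 2, 2, 3, 3], cons.assignment) == 1.0

    def test_identity_coassociation_yields_singletons(self):
        members = [Partition(list(range(6)))] * 2
        er = EnsembleResult(members=members,
                            coassociation=np.eye(6),
                            config=EnsembleConfig(B=2, k=2, encode_dim=1))
        cons = consensus_partition(er, 6)
        assert cons.n_clusters == 6

    def test_k_exceeding_cells_rejected(self):
        members = [Partition([0, 1])] * 2
        er = EnsembleResult(members=members,
                            coassociation=coassociation_matrix(members),
                            config=EnsembleConfig(B=2, k=2, encode_dim=1))
        with pytest.raises(ValueError, match="cells"):
            consensus_partition(er, 5)

    def test_consensus_tracks_members_on_separated_data(self, three_type_norm):
        cfg = EnsembleConfig(B=5, projection_fraction=0.1, encode_dim=8,
                             encoder="pca_fallback", k=3, seed=0)
        er = run_ensemble(three_type_norm, cfg)
        cons = consensus_partition(er, 3)
        member_aris = [adjusted_rand_score(three_type_norm.labels, m.assignment)
                       for m in er.members]
        cons_ari = adjusted_rand_score(three_type_norm.labels, cons.assignment)
        assert cons_ari >= max(member_aris) - 0.05


class TestSklearnEstimator:
    def test_fitted_attributes(self, three_type_norm):
        est = SubspaceEnsembleClustering(n_clusters=3, ensemble_size=4,
                                         encoder="pca_fallback", encode_dim=8,
                                         random_state=0).fit(three_type_norm.X)
        assert est.labels_.shape == (three_type_norm.n_cells,)
        assert len(est.members_) == 4
        assert est.coassociation_.shape == (300, 300)
        assert adjusted_rand_score(three_type_norm.labels, est.labels_) >= 0.9

    def test_get_set_params_round_trip(self):
        est = SubspaceEnsembleClustering()
        params = est.get_params()
        assert params["ensemble_size"] == 20 and params["encoder"] == "autoencoder"
        est.set_params(n_clusters=5)
        assert est.n_clusters == 5


def test_member_seeds_are_stable_and_distinct():
    a = member_seeds(0, 20)
    assert a == member_seeds(0, 20)
    assert len(set(a)) == 20
    assert all(0 <= s < 2**31 for s in a)
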