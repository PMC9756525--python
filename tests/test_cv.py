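import numpy as np
import pytest

from cpinet.cv import (DEFAULT_FOLDS, audit_fold_assignment,
                       compound_distance_matrix, make_folds,
                       protein_distance_matrix, read_folds,
                       single_linkage_clusters, write_folds)
from cpinet.fixtures import (FixtureSpec, SMILES_VOCAB,
                             gen_dataset_in_memory)
from cpinet.io_data import CPIRecord


def components_oracle(dist: np.ndarray, threshold: float) -> list[set[int]]:
    """Brute-force DFS connected components of the dist<threshold graph."""
    n = dist.shape[0]
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            for j in range(n):
                if j != i and dist[i, j] < threshold and j not in comp:
                    stack.append(j)
        seen |= comp
        comps.append(comp)
    return comps


def random_distance_matrix(rng, n):
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestDistances:
    def test_identical_smiles_zero_distance(self):
        d = compound_distance_matrix(["CCO", "CCO"])
        assert d[0, 1] == 0.0

    def test_compound_matrix_symmetric_zero_diagonal(self):
        d = compound_distance_matrix(list(SMILES_VOCAB[:20]))
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 1

    def test_disjoint_fingerprints_distance_one(self):
        # methane vs a large heteroaromatic share no substructure bits
        d = compound_distance_matrix(
            ["C", "Cc1ccc(cc1)-c1cc(nn1-c1ccc(cc1)S(N)(=O)=O)C(F)(F)F"])
        assert d[0, 1] == 1.0

    def test_unparseable_smiles_named(self):
        with pytest.raises(ValueError, match="xyz"):
            compound_distance_matrix(["CC", "xyz"])

    def test_identical_proteins_zero_distance(self):
        d = protein_distance_matrix(["ACDEFGHIKL", "ACDEFGHIKL"])
        assert d[0, 1] == 0.0

    def test_no_identities_distance_one(self):
        d = protein_distance_matrix(["AAAA", "TTTT"])
        assert d[0, 1] == 1.0

    def test_protein_matrix_symmetric(self, rng):
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12))
                for _ in range(10)]
        d = protein_distance_matrix(seqs)
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            protein_distance_matrix(["ACD", ""])


class TestSingleLinkage:
    def test_threshold_below_min_gives_singletons(self, rng):
        d = random_distance_matrix(rng, 6)
        t = d[np.triu_indices(6, 1)].min() * 0.5
        labels = single_linkage_clusters(d, max(t, 1e-9))
        assert len(set(labels)) == 6

    def test_threshold_above_max_gives_one_cluster(self, rng):
        d = random_distance_matrix(rng, 6) * 0.5
        labels = single_linkage_clusters(d, 1.0)
        assert len(set(labels)) == 1

    def test_chaining(self):
        # a-b and b-c close, a-c far: one chained cluster at 0.3
        d = np.array([[0.0, 0.25, 0.9],
                      [0.25, 0.0, 0.25],
                      [0.9, 0.25, 0.0]])
        labels = single_linkage_clusters(d, 0.3)
        assert labels[0] == labels[1] == labels[2]

    def test_matches_connected_components_oracle(self, rng):
        for _ in range(50):
            d = random_distance_matrix(rng, 15)
            t = float(rng.uniform(0.05, 0.95))
            labels = single_linkage_clusters(d, t)
            for comp in components_oracle(d, t):
                assert len({labels[i] for i in comp}) == 1
            assert len(set(labels)) == len(components_oracle(d, t))

    def test_labels_dense_and_ordered_by_first_member(self, rng):
        d = random_distance_matrix(rng, 10)
        labels = single_linkage_clusters(d, 0.3)
        assert labels[0] == 0
        seen = []
        for lab in labels:
            if lab not in seen:
                seen.append(lab)
        assert seen == sorted(seen)

    def test_cluster_count_non_increasing_in_threshold(self):
        spec = FixtureSpec(n_pairs=20, d0=8, seed=7)
        records, proteins, _ = gen_dataset_in_memory(spec)
        smiles = sorted({r.smiles for r in records})
        d = compound_distance_matrix(smiles)
        counts = [len(set(single_linkage_clusters(d, t)))
                  for t in (0.3, 0.4, 0.5, 0.6)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError, match="threshold"):
            single_linkage_clusters(np.zeros((2, 2)), 1.5)
        with pytest.raises(ValueError, match="square"):
            single_linkage_clusters(np.zeros((2, 3)), 0.5)


@pytest.fixture(scope="module")
def cv_dataset():
    spec = FixtureSpec(n_pairs=60, d0=8, protein_length_range=(25, 40),
                       seed=11)
    records, proteins, _ = gen_dataset_in_memory(spec)
    sequences = {pid: e.sequence for pid, e in proteins.items()}
    return records, sequences


class TestMakeFolds:
    def test_singleton_compound_clusters_split_evenly(self):
        # 10 mutually dissimilar compounds, one pair each -> 2 clusters/fold
        smiles = list(SMILES_VOCAB[:10])
        records = [CPIRecord(f"p{i}", s, "prot0") for i, s in enumerate(smiles)]
        seqs = {"prot0": "ACDEFGHIKLMNPQRSTVWY"}
        fa = make_folds(records, seqs, "new_compound", threshold=0.3,
                        n_folds=5, seed=1)
        if len(set(fa.compound_cluster.values())) == 10:
            for fold in range(5):
                _, test = fa.train_test(fold)
                assert len({fa.compound_cluster[
                    next(r.smiles for r in records if r.pair_id == p)]
                    for p in test}) == 2

    @pytest.mark.parametrize("setting", ["new_compound", "new_protein",
                                         "both_new"])
    def test_settings_audit_clean(self, cv_dataset, setting):
        records, sequences = cv_dataset
        fa = make_folds(records, sequences, setting, threshold=0.4, seed=3)
        assert fa.n_folds == DEFAULT_FOLDS[setting]
        assert audit_fold_assignment(fa, records) > 0

    def test_both_new_grid_excludes_shared_rows_and_columns(self, cv_dataset):
        records, sequences = cv_dataset
        fa = make_folds(records, sequences, "both_new", threshold=0.4, seed=3)
        by_id = {r.pair_id: r for r in records}
        for fold in range(9):
            train, test = fa.train_test(fold)
            test_cc = {fa.compound_cluster[by_id[p].smiles] for p in test}
            test_pc = {fa.protein_cluster[by_id[p].protein_id] for p in test}
            train_cc = {fa.compound_cluster[by_id[p].smiles] for p in train}
            train_pc = {fa.protein_cluster[by_id[p].protein_id] for p in train}
            assert not (test_cc & train_cc)
            assert not (test_pc & train_pc)

    def test_same_seed_reproduces_folds(self, cv_dataset):
        records, sequences = cv_dataset
        fa1 = make_folds(records, sequences, "new_protein", 0.4, seed=9)
        fa2 = make_folds(records, sequences, "new_protein", 0.4, seed=9)
        assert fa1.fold_of_pair == fa2.fold_of_pair

    def test_too_few_clusters_errors(self):
        records = [CPIRecord(f"p{i}", "CCO", "prot0") for i in range(4)]
        seqs = {"prot0": "ACDEFGHIKL"}
        with pytest.raises(ValueError, match="1 cluster"):
            make_folds(records, seqs, "new_compound", 0.3, 5, seed=0)

    def test_folds_round_trip(self, tmp_path, cv_dataset):
        records, sequences = cv_dataset
        fa = make_folds(records, sequences, "new_compound", 0.4, seed=2)
        write_folds(fa, tmp_path / "folds.tsv")
        back = read_folds(tmp_path / "folds.tsv")
        assert set(back) == set(range(fa.n_folds))
        for fold in range(fa.n_folds):
            train, test = fa.train_test(fold)
            assert back[fold]["train"] == train
            assert back[fold]["test"] == test
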