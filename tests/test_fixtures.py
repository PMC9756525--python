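import hashlib
import json
import math

import numpy as np
import pytest

from cpinet.compound import smiles_to_graph
from cpinet.evaluation import site_auc_per_pair
from cpinet.fixtures import (FixtureSpec, SMILES_VOCAB, SyntheticProtein,
                             class_directions, gen_dataset,
                             gen_dataset_in_memory, gen_pair, gen_protein,
                             planted_probability_matrix)
from cpinet.io_data import (ProteinEntry, read_pairs_table,
                            read_protein_store, read_site_labels,
                            validate_dataset)
from cpinet.model import pim_from_sparse


class TestGenProtein:
    def test_deterministic_for_same_seed(self):
        p1 = gen_protein(20, 16, 7)
        p2 = gen_protein(20, 16, 7)
        assert p1.entry.sequence == p2.entry.sequence
        np.testing.assert_array_equal(p1.entry.embedding, p2.entry.embedding)

    def test_embedding_shape(self):
        p = gen_protein(33, 24, 0)
        assert p.entry.embedding.shape == (33, 24)
        assert len(p.classes) == 33

    def test_invalid_length_errors(self):
        with pytest.raises(ValueError):
            gen_protein(0, 16, 0)

    def test_class_directions_orthonormal(self):
        d = class_directions(64)
        gram = (d / 6.0) @ (d / 6.0).T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-10)

    def test_classes_recoverable_by_kmeans(self):
        """The planted class structure dominates the embedding noise."""
        from scipy.optimize import linear_sum_assignment
        from sklearn.cluster import KMeans
        sp = gen_protein(60, 768, np.random.default_rng(11))
        km = KMeans(n_clusters=3, n_init=10, random_state=0)
        km.fit(sp.entry.embedding)
        conf = np.zeros((3, 3))
        for a, b in zip(km.labels_, sp.classes):
            conf[a, b] += 1
        rows, cols = linear_sum_assignment(-conf)
        assert conf[rows, cols].sum() / len(sp.classes) >= 0.9


def _protein_with_classes(classes, d0=16):
    classes = np.asarray(classes)
    rng = np.random.default_rng(0)
    emb = class_directions(d0)[classes] + rng.normal(0, 0.5,
                                                     (len(classes), d0))
    seq = "A" * len(classes)
    return SyntheticProtein(ProteinEntry("p", seq, emb), classes)


class TestGenPair:
    def test_degenerate_rule_gives_exact_product_set(self):
        prot = _protein_with_classes([0, 1, 0, 2, 0])
        spec = FixtureSpec(p_hi=1.0, p_lo=0.0, missing_affinity_fraction=0.0)
        rec = gen_pair(prot, "NCCO", spec, np.random.default_rng(1), "p1")
        g = smiles_to_graph("NCCO")
        het = np.nonzero(g.heteroatom_mask)[0]
        expected = {(int(a), j) for a in het for j in (0, 2, 4)}
        assert rec.site_labels == expected

    def test_zero_rule_gives_empty_sites_and_offset_affinity(self):
        prot = _protein_with_classes([0, 1, 2])
        spec = FixtureSpec(p_hi=0.0, p_lo=0.0, affinity_noise_sd=0.0,
                           missing_affinity_fraction=0.0)
        rec = gen_pair(prot, "CCO", spec, np.random.default_rng(2), "p1")
        assert rec.site_labels == set()
        assert rec.affinity == pytest.approx(spec.affinity_offset)

    def test_site_count_matches_binomial_expectation(self):
        """Mean planted-site count over 50 draws is within 3 sigma of the
        binomial expectation."""
        classes = [0] * 20 + [1] * 20
        prot = _protein_with_classes(classes)
        smiles = "Nc1ccc(cc1)S(N)(=O)=O"   # 5 heteroatoms
        g = smiles_to_graph(smiles)
        n_het = int(g.heteroatom_mask.sum())
        n_lo = g.n_atoms * len(classes) - n_het * 20
        spec = FixtureSpec(missing_affinity_fraction=0.0)
        counts = [len(gen_pair(prot, smiles, spec,
                               np.random.default_rng(s), "p").site_labels)
                  for s in range(50)]
        mean_expected = 0.8 * n_het * 20 + 0.02 * n_lo
        var = (0.8 * 0.2 * n_het * 20 + 0.02 * 0.98 * n_lo) / 50
        assert abs(np.mean(counts) - mean_expected) <= 3 * math.sqrt(var)

    def test_affinity_tracks_log_site_count(self):
        prot = _protein_with_classes([0] * 30)
        spec = FixtureSpec(affinity_noise_sd=0.0,
                           missing_affinity_fraction=0.0)
        rec = gen_pair(prot, "NCCN", spec, np.random.default_rng(3), "p")
        expected = 2.0 * math.log1p(len(rec.site_labels)) + 4.0
        assert rec.affinity == pytest.approx(expected)


class TestGenDataset:
    def test_row_count_and_missing_affinity_fraction(self, tmp_path):
        spec = FixtureSpec(n_pairs=20, d0=8, seed=1)
        paths = gen_dataset(spec, tmp_path)
        records = read_pairs_table(paths["pairs"])
        assert len(records) == 20
        n_missing = sum(r.affinity is None for r in records)
        # Binomial(20, 0.4): mean 8, 3 sigma ~ 6.6
        assert abs(n_missing - 8) <= 6.6

    def test_regeneration_is_byte_identical(self, tmp_path):
        spec = FixtureSpec(n_pairs=8, d0=8, seed=3)
        paths1 = gen_dataset(spec, tmp_path / "a")
        paths2 = gen_dataset(spec, tmp_path / "b")
        for key in paths1:
            h1 = hashlib.sha256((paths1[key]).read_bytes()).hexdigest()
            h2 = hashlib.sha256((paths2[key]).read_bytes()).hexdigest()
            assert h1 == h2, key

    def test_readers_accept_output_and_validation_passes(self, tmp_path):
        spec = FixtureSpec(n_pairs=10, d0=8, seed=2)
        paths = gen_dataset(spec, tmp_path)
        records = read_pairs_table(paths["pairs"])
        proteins = read_protein_store(paths["fasta"], paths["embeddings"])
        labels = read_site_labels(paths["sites"])
        for rec in records:
            rec.site_labels = labels.get(rec.pair_id, set())
        validate_dataset(records, proteins)
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["seed"] == 2

    def test_oracle_scorer_attains_the_bayes_ceiling(self):
        """Scoring with the planted probabilities (the Bayes scorer)
        separates sampled contacts from non-contacts.

        With a two-valued score the Mann-Whitney AUC has a closed form
        from the realized counts: positives in hi-cells beat negatives in
        lo-cells, and equal scores tie (weight 1/2).  The per-pair AUC
        must match that ceiling exactly, and the ceiling itself sits far
        above chance."""
        spec = FixtureSpec(n_pairs=20, d0=8, seed=4)
        records, proteins, classes = gen_dataset_in_memory(spec)
        aucs = []
        for rec in records:
            g = smiles_to_graph(rec.smiles)
            probs = planted_probability_matrix(
                classes[rec.protein_id], g.heteroatom_mask)
            pim = pim_from_sparse(rec.site_labels, *probs.shape).pim
            val = site_auc_per_pair(probs, pim)
            if val is None:
                continue
            hi = probs > 0.5
            pos_hi = float(np.sum(pim[hi]))
            pos_lo = float(np.sum(pim[~hi]))
            neg_hi = float(np.sum(hi) - pos_hi)
            neg_lo = float(np.sum(~hi) - pos_lo)
            n_pos, n_neg = pos_hi + pos_lo, neg_hi + neg_lo
            ceiling = (pos_hi * neg_lo
                       + 0.5 * (pos_hi * neg_hi + pos_lo * neg_lo)) / (
                           n_pos * n_neg)
            assert val == pytest.approx(ceiling, abs=1e-12)
            aucs.append(val)
        assert np.mean(aucs) > 0.8
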