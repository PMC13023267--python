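import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet
from sklearn.decomposition import PCA as SkPCA

from snpcatalog.model import (
    GenotypeEntry,
    SampleMeta,
    VariantClass,
    VariantKey,
    VariantRecord,
)
from snpcatalog.structure import (
    DosageMatrix,
    build_dosage_matrix,
    cut_clusters,
    dendrogram_newick,
    hierarchical_clusters,
    pca,
)


def _records(matrix):
    """rows = samples s0..sN, columns = variants; None = missing."""
    n_samples, n_vars = len(matrix), len(matrix[0])
    samples = [f"s{i}" for i in range(n_samples)]
    records = []
    for j in range(n_vars):
        entries = {
            samples[i]: GenotypeEntry(gt=matrix[i][j]) for i in range(n_samples)
        }
        records.append(
            VariantRecord(VariantKey("chr1", j + 1, "A", "G"), VariantClass.SNP, entries)
        )
    return records, samples


def _simulated_matrix(fst, n_per_group, n_variants, seed, depth=30):
    from snpcatalog.genome import default_layout
    from snpcatalog.simulate import DatasetProfile, simulate_individual_calls, simulate_truth

    layout = default_layout()
    truth = simulate_truth(
        layout, n_variants, {"MED": fst, "RIV": fst, "SWA": fst}, seed=seed
    )
    meta = [
        SampleMeta(f"{g}_{i}", g, "M", "S1")
        for g in ("MED", "RIV", "SWA")
        for i in range(n_per_group)
    ]
    records, _ = simulate_individual_calls(
        truth, meta, DatasetProfile((depth, depth), genotype_error_rate=0.01),
        layout, seed=seed + 1,
    )
    matrix = build_dosage_matrix(records, [m.sample_id for m in meta])
    labels = np.repeat([0, 1, 2], n_per_group)
    return matrix, labels


class TestDosageMatrix:
    def test_dosage_and_mean_imputation(self):
        records, samples = _records([[0], [2], [None]])
        matrix = build_dosage_matrix(records, samples)
        np.testing.assert_allclose(matrix.values[:, 0], [0, 2, 1.0])

    def test_all_missing_variant_dropped(self):
        records, samples = _records([[0, None], [1, None]])
        matrix = build_dosage_matrix(records, samples)
        assert matrix.shape == (2, 1)
        assert [k.pos for k in matrix.keys] == [1]

    def test_entirely_missing_rejected(self):
        records, samples = _records([[None], [None]])
        with pytest.raises(ValueError, match="missing"):
            build_dosage_matrix(records, samples)


class TestPca:
    def test_identical_samples_coincide(self):
        records, samples = _records(
            [[0, 1, 2, 0], [0, 1, 2, 0], [2, 1, 0, 2], [1, 0, 1, 1]]
        )
        result = pca(build_dosage_matrix(records, samples), 2)
        np.testing.assert_allclose(
            result.coordinates[0], result.coordinates[1], atol=1e-10
        )

    def test_variance_explained_shape(self):
        rng = np.random.default_rng(0)
        matrix = DosageMatrix(
            [f"s{i}" for i in range(10)],
            [VariantKey("chr1", j + 1, "A", "G") for j in range(40)],
            rng.integers(0, 3, (10, 40)).astype(float),
        )
        result = pca(matrix, 5)
        ve = result.variance_explained
        assert np.all(ve[:-1] >= ve[1:] - 1e-12) and ve.sum() <= 1 + 1e-9
        assert np.all((0 <= ve) & (ve <= 1))

    def test_monomorphic_variant_dropped_before_scaling(self):
        records, samples = _records([[0, 1, 2], [0, 2, 0], [0, 0, 1]])
        result = pca(build_dosage_matrix(records, samples), 3)
        # the monomorphic first variant contributes nothing: 2 components max
        assert result.coordinates.shape == (3, 2)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 3, (8, 30)).astype(float)
        samples = [f"s{i}" for i in range(8)]
        keys = [VariantKey("chr1", j + 1, "A", "G") for j in range(30)]
        perm = rng.permutation(8)
        r1 = pca(DosageMatrix(samples, keys, values), 3)
        r2 = pca(DosageMatrix([samples[i] for i in perm], keys, values[perm]), 3)
        np.testing.assert_allclose(r1.coordinates[perm], r2.coordinates, atol=1e-8)

    def test_matches_sklearn_reference(self):
        """Same variance fractions as scikit-learn PCA on the scaled matrix."""
        rng = np.random.default_rng(2)
        values = rng.integers(0, 3, (12, 50)).astype(float)
        matrix = DosageMatrix(
            [f"s{i}" for i in range(12)],
            [VariantKey("chr1", j + 1, "A", "G") for j in range(50)],
            values,
        )
        result = pca(matrix, 5)
        x = values - values.mean(axis=0)
        sd = x.std(axis=0)
        x = x[:, sd > 0] / sd[sd > 0]
        ref = SkPCA(n_components=5).fit(x)
        # sklearn normalizes by (n-1); fractions of total variance agree
        ref_fraction = ref.explained_variance_ / (
            ref.explained_variance_.sum() / ref.explained_variance_ratio_.sum()
        )
        np.testing.assert_allclose(
            result.variance_explained, ref_fraction, atol=1e-8
        )

    def test_group_separation_increases_with_fst(self):
        """Between-group spread in PC1-PC2 grows with divergence."""
        spreads = []
        for fst in (0.02, 0.1, 0.3):
            matrix, labels = _simulated_matrix(fst, 8, 600, seed=40)
            coords = pca(matrix, 2).coordinates
            centroids = np.array([coords[labels == g].mean(axis=0) for g in range(3)])
            spreads.append(np.linalg.norm(centroids - centroids.mean(axis=0)))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_single_group_pc1_not_above_permutation_null(self):
        """No artifactual structure: PC1 variance within the permuted-dosage
        null for a homogeneous group (4 of 5 seeds)."""
        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            from snpcatalog.genome import default_layout
            from snpcatalog.simulate import (
                DatasetProfile,
                simulate_individual_calls,
                simulate_truth,
            )

            layout = default_layout()
            truth = simulate_truth(layout, 300, {"MED": 0.0, "RIV": 0.0, "SWA": 0.0}, seed=seed)
            meta = [SampleMeta(f"h{i}", "MED", "M", "S1") for i in range(20)]
            records, _ = simulate_individual_calls(
                truth, meta, DatasetProfile((30, 30)), layout, seed=seed + 50
            )
            matrix = build_dosage_matrix(records, [m.sample_id for m in meta])
            observed = pca(matrix, 2).variance_explained[0]
            null = []
            for _ in range(39):
                shuffled = matrix.values.copy()
                for j in range(shuffled.shape[1]):
                    rng.shuffle(shuffled[:, j])
                null.append(
                    pca(DosageMatrix(matrix.samples, matrix.keys, shuffled), 2)
                    .variance_explained[0]
                )
            p = (1 + sum(v >= observed for v in null)) / 40
            ok += p > 0.05
        assert ok >= 4


class TestHierarchicalClustering:
    def test_identical_samples_merge_at_zero(self):
        records, samples = _records([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        linkage = hierarchical_clusters(build_dosage_matrix(records, samples))
        assert linkage[0, 2] == 0.0
        assert sorted(linkage[0, :2]) == [0, 1]

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(5)
        matrix = DosageMatrix(
            [f"s{i}" for i in range(15)],
            [VariantKey("chr1", j + 1, "A", "G") for j in range(60)],
            rng.integers(0, 3, (15, 60)).astype(float),
        )
        linkage = hierarchical_clusters(matrix)
        heights = linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)
        # cophenetic distances are well-formed for average linkage
        assert np.all(cophenet(linkage) >= 0)

    def test_three_cluster_cut_recovers_groups(self):
        for seed in range(5):
            matrix, labels = _simulated_matrix(0.3, 6, 500, seed=60 + seed)
            linkage = hierarchical_clusters(matrix)
            cut = cut_clusters(linkage, 3)
            # perfect recovery: each true group maps to exactly one cluster
            mapping = {}
            for true, got in zip(labels, cut):
                mapping.setdefault(true, set()).add(got)
            assert all(len(v) == 1 for v in mapping.values())
            assert len({next(iter(v)) for v in mapping.values()}) == 3

    def test_newick_has_all_leaves(self):
        records, samples = _records([[0, 1], [2, 1], [1, 0]])
        matrix = build_dosage_matrix(records, samples)
        newick = dendrogram_newick(hierarchical_clusters(matrix), matrix.samples)
        assert newick.endswith(";")
        for s in samples:
            assert s in newick
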