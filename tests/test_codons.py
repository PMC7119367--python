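"""Codon counting, within-family usage vectors, and PCA."""

import numpy as np
import pytest
from scipy import stats

import hgtscan as h
from hgtscan.codons import (
    CODON_TO_AA,
    FAMILIES,
    SENSE_CODONS,
    USAGE_CODONS,
    CodonCounts,
)


def vec_from_counts(count_dict, **kw):
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for codon, n in count_dict.items():
        counts[SENSE_CODONS.index(codon)] = n
    cc = CodonCounts(counts=counts, n_genes=1, n_codons=int(counts.sum()))
    return h.usage_vector(cc, **kw)


def test_codon_tables_are_consistent():
    assert len(SENSE_CODONS) == 61
    assert len(USAGE_CODONS) == 59  # minus ATG and TGG
    assert len(FAMILIES) == 18
    assert "ATG" not in USAGE_CODONS and "TGG" not in USAGE_CODONS


def test_count_single_cds():
    cc = h.count_codons(["ATGAAATAA"])
    assert cc.as_dict() == {"ATG": 1, "AAA": 1}
    assert cc.n_codons == 2  # the stop codon is excluded


def test_count_skips_ambiguous_codons():
    cc = h.count_codons(["ATGANATAA"])
    assert cc.as_dict() == {"ATG": 1}


def test_counts_additive_over_disjoint_sets():
    a = h.count_codons(["ATGAAACCC"])
    b = h.count_codons(["ATGGGGTTT"])
    both = h.count_codons(["ATGAAACCC", "ATGGGGTTT"])
    assert np.array_equal((a + b).counts, both.counts)
    assert both.n_genes == 2


def test_count_empty_set_errors():
    with pytest.raises(ValueError, match="empty"):
        h.count_codons([])


def test_usage_vector_glu_family():
    v = vec_from_counts({"GAA": 1, "GAG": 1})
    glu = [i for i, c in enumerate(USAGE_CODONS) if CODON_TO_AA[c] == "E"]
    assert np.allclose(v.values[glu], 0.5)
    assert v.family_present.sum() == 1
    others = np.setdiff1d(np.arange(59), glu)
    assert np.all(v.values[others] == 0)


def test_usage_vector_dimension_and_family_sums(small_sim):
    counts = h.genome_codon_counts(small_sim.genome)
    v = h.usage_vector(counts)
    assert v.values.shape == (59,)
    for aa in FAMILIES:
        members = [i for i, c in enumerate(USAGE_CODONS) if CODON_TO_AA[c] == aa]
        assert abs(v.values[members].sum() - 1.0) < 1e-9


def test_uniform_usage_gives_equal_proportions():
    v = vec_from_counts({c: 7 for c in SENSE_CODONS})
    for i, codon in enumerate(USAGE_CODONS):
        k = sum(1 for c in USAGE_CODONS if CODON_TO_AA[c] == CODON_TO_AA[codon])
        assert abs(v.values[i] - 1.0 / k) < 1e-12


def test_usage_scale_invariance(small_sim):
    """Duplicating every gene leaves the usage vector unchanged."""
    genome = small_sim.genome
    from hgtscan.io import extract_cds

    cds = [extract_cds(genome, g) for g in genome.valid_genes()[:40]]
    v1 = h.usage_vector(h.count_codons(cds))
    v2 = h.usage_vector(h.count_codons(cds + cds))
    assert np.allclose(v1.values, v2.values)


def test_simulated_codons_follow_specified_distribution():
    """Background genes sample codons from the GC-reweighted profile: a
    chi-square goodness-of-fit at alpha=0.01 does not reject."""
    from hgtscan.simulate import SimulationSpec, reweight_to_gc, simulate_genome

    spec = SimulationSpec(seed=11, genome_bp=150_000, background_gc=0.60)
    sim = simulate_genome(spec)
    counts = h.genome_codon_counts(sim.genome)
    profile = reweight_to_gc(np.ones(61), 0.60)
    observed = counts.counts.astype(float)
    # each gene contributes one fixed ATG start; internal codons follow the profile
    n_genes = counts.n_genes
    observed[SENSE_CODONS.index("ATG")] -= n_genes
    n = observed.sum()
    _, p = stats.chisquare(observed, profile * n)
    assert p > 0.01


# -- gene windows ------------------------------------------------------------


def test_window_count():
    """n genes, window 10, step 1 -> n - 9 windows (3 for 12 genes)."""
    from hgtscan.simulate import SimulationSpec, simulate_genome

    spec = SimulationSpec(seed=2, genome_bp=14_000, n_genes=12)
    sim = simulate_genome(spec)
    n = len(sim.genome.valid_genes())
    assert n >= 11  # a dozen-ish genes at this size
    wins = h.gene_window_vectors(sim.genome, window_genes=10, step_genes=1)
    assert len(wins) == n - 9


def test_window_of_identical_genes_equals_single_gene_vector(small_sim):
    genome = small_sim.genome
    from hgtscan.io import extract_cds

    cds = extract_cds(genome, genome.valid_genes()[0])
    v_one = h.usage_vector(h.count_codons([cds]))
    v_ten = h.usage_vector(h.count_codons([cds] * 10))
    assert np.allclose(v_one.values, v_ten.values)


def test_too_few_genes_errors():
    from hgtscan.simulate import SimulationSpec, simulate_genome

    sim = simulate_genome(SimulationSpec(seed=3, genome_bp=8_000, n_genes=5))
    with pytest.raises(ValueError, match="window"):
        h.gene_window_vectors(sim.genome, window_genes=10)


def test_partition_windows_pool_to_genome_counts(small_sim):
    """With step == window the window counts partition the genome counts."""
    genome = small_sim.genome
    n_valid = len(genome.valid_genes())
    w = 10
    n_full = n_valid // w * w
    wins = h.gene_window_vectors(genome, window_genes=w, step_genes=w)
    from hgtscan.io import extract_cds

    pooled = h.count_codons(
        extract_cds(genome, g) for g in genome.valid_genes()[:n_full]
    )
    total = np.zeros(61, dtype=np.int64)
    for win, _vec in wins:
        total += h.count_codons(
            extract_cds(genome, g)
            for g in genome.valid_genes()
            if g.gene_id in win.gene_ids
        ).counts
    assert np.array_equal(total, pooled.counts)


# -- PCA ---------------------------------------------------------------------


def _random_vectors(n, seed=0):
    rng = np.random.default_rng(seed)
    return [
        h.CodonUsageVector(values=rng.random(59), family_present=np.ones(18, bool))
        for _ in range(n)
    ]


def test_pca_rank_one_data():
    a = h.CodonUsageVector(values=np.zeros(59), family_present=np.ones(18, bool))
    b = h.CodonUsageVector(values=np.ones(59), family_present=np.ones(18, bool))
    res = h.run_pca([a, a, b, b])
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_degenerate_input_errors():
    a = h.CodonUsageVector(values=np.ones(59), family_present=np.ones(18, bool))
    with pytest.raises(ValueError, match="identical"):
        h.run_pca([a, a, a])


def test_pca_scores_invariant_under_permutation():
    vectors = _random_vectors(15, seed=4)
    res = h.run_pca(vectors, labels=[str(i) for i in range(15)])
    perm = np.random.default_rng(0).permutation(15)
    res_p = h.run_pca(
        [vectors[i] for i in perm], labels=[str(i) for i in perm]
    )
    by_label = {lab: row for lab, row in zip(res_p.labels, res_p.scores)}
    for lab, row in zip(res.labels, res.scores):
        assert np.allclose(row, by_label[lab], atol=1e-9)


def test_pca_matches_sklearn_oracle():
    """Explained-variance ratios agree with scikit-learn's independent
    implementation to 1e-8 on random 20x59 matrices."""
    from sklearn.decomposition import PCA

    for seed in range(3):
        vectors = _random_vectors(20, seed=seed)
        res = h.run_pca(vectors)
        X = np.vstack([v.values for v in vectors])
        sk = PCA().fit(X)
        k = min(len(res.explained_variance_ratio), len(sk.explained_variance_ratio_))
        assert np.allclose(
            res.explained_variance_ratio[:k],
            sk.explained_variance_ratio_[:k],
            atol=1e-8,
        )


def test_pca_reconstruction():
    vectors = _random_vectors(12, seed=9)
    res = h.run_pca(vectors)
    X = np.vstack([v.values for v in vectors])
    reconstructed = res.scores @ res.loadings + res.mean
    assert np.allclose(reconstructed, X, atol=1e-8)


def test_pca_ratio_invariants():
    res = h.run_pca(_random_vectors(10, seed=2))
    r = res.explained_variance_ratio
    assert np.all(r >= 0)
    assert np.all(np.diff(r) <= 1e-12)
    assert r.sum() <= 1 + 1e-9


def test_island_windows_separate_from_background(small_sim):
    """Windows overlapping a planted island separate from background windows
    in codon-usage PCA space (positive silhouette)."""
    from sklearn.metrics import silhouette_score

    wins = h.gene_window_vectors(small_sim.genome, 10)
    res = h.run_pca([v for _, v in wins])
    spans = [(i.start, i.end) for i in small_sim.truth.islands]
    labels = np.array(
        [
            1 if any(s <= w.start and w.end <= e for s, e in spans) else 0
            for w, _ in wins
        ]
    )
    assert 0 < labels.sum() < len(labels)
    assert silhouette_score(res.scores[:, :2], labels) > 0
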