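"""Bait-group clustering, per-gene scoring and the 40-gene window scan."""

import random

import numpy as np
import pytest

import hgtscan as h
from hgtscan.baits import GeneScore, RegionHit, window_scan
from hgtscan.simulate import diverge_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(AA) for _ in range(n))


def make_scores(values, contig="c", start_index=0):
    return [
        GeneScore(
            gene_id=f"g{i}",
            index=start_index + i,
            contig=contig,
            start=1000 * i,
            end=1000 * i + 900,
            normalized_score=float(v),
            best_group=f"G{i % 5}" if v > 0 else None,
        )
        for i, v in enumerate(values)
    ]


def oracle_regions(values, window, threshold):
    """Brute-force enumeration: every qualifying window trimmed to its
    scoring genes, overlapping trimmed spans merged."""
    n = len(values)
    w = min(window, n)
    spans = []
    for i in range(n - w + 1):
        win = values[i : i + w]
        if sum(win) > threshold:
            scoring = [i + k for k, v in enumerate(win) if v > 0]
            if scoring:
                spans.append((scoring[0], scoring[-1]))
    merged = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


# -- build_bait_set ----------------------------------------------------------


def test_shared_protein_clusters_into_one_group():
    rng = random.Random(0)
    p = random_protein(rng, 150)
    nprng = np.random.default_rng(0)
    regions = {
        "RE1": {"a": p},
        "RE2": {"b": diverge_protein(p, 0.95, nprng)},
        "RE3": {"c": diverge_protein(p, 0.93, nprng)},
    }
    groups = h.build_bait_set(regions)
    assert len(groups) == 1
    assert len(groups[0].members) == 3
    assert set(groups[0].sources.values()) == {"RE1", "RE2", "RE3"}


def test_unrelated_proteins_stay_singletons():
    rng = random.Random(1)
    regions = {"RE1": {"a": random_protein(rng, 120), "b": random_protein(rng, 120)}}
    groups = h.build_bait_set(regions)
    assert len(groups) == 2
    assert all(len(g.members) == 1 for g in groups)


def test_empty_input_errors():
    with pytest.raises(ValueError):
        h.build_bait_set({})


def test_drop_unannotated_singletons():
    rng = random.Random(2)
    p = random_protein(rng, 150)
    regions = {
        "RE1": {"kept": p, "orphan": random_protein(rng, 120)},
        "RE2": {"kept2": p},
    }
    annotations = {"kept": "reductase", "kept2": "reductase", "orphan": "hypothetical protein"}
    groups = h.build_bait_set(
        regions, drop_unannotated_singletons=True, annotations=annotations
    )
    assert len(groups) == 1 and len(groups[0].members) == 2


def test_fixture_cassette_recovers_26_groups(ref_groups):
    """Three diverged cassette copies cluster back into exactly 26 groups,
    each with one member per repeat region."""
    assert len(ref_groups) == 26
    assert all(len(g.members) == 3 for g in ref_groups)
    assert all(
        set(g.sources.values()) == {"RE1", "RE2", "RE3"} for g in ref_groups
    )


# -- score_genome_genes ------------------------------------------------------


def test_verbatim_bait_scores_one(small_sim, small_groups):
    """A gene identical to a bait member self-normalizes to 1.0."""
    scores = h.score_genome_genes(small_sim.genome, small_groups)
    by_id = {s.gene_id: s for s in scores}
    for copy, gids in small_sim.truth.cassette_genes.items():
        for gid in gids:
            assert by_id[gid].normalized_score == pytest.approx(1.0)
            assert by_id[gid].best_group is not None


def test_genome_without_homologs_scores_zero():
    from hgtscan.simulate import SimulationSpec, simulate_genome

    sim = simulate_genome(SimulationSpec(seed=33, genome_bp=60_000))
    rng = random.Random(5)
    p = random_protein(rng, 200)
    groups = h.build_bait_set({"RE1": {"bait": p}})
    scores = h.score_genome_genes(sim.genome, groups)
    assert all(s.normalized_score == 0.0 for s in scores)
    assert len(scores) == len(sim.genome.genes)


def test_score_decreases_with_divergence():
    """Across 10 divergence levels the normalized score trends down and a
    ~50%-identity copy lands strictly between 0 and 1."""
    rng = random.Random(6)
    nprng = np.random.default_rng(6)
    bait = random_protein(rng, 250)
    groups = h.build_bait_set({"RE1": {"bait": bait}})
    scheme = h.ScoringScheme()
    levels = np.linspace(1.0, 0.35, 10)
    norms = []
    for t in levels:
        copy = bait if t == 1.0 else diverge_protein(bait, float(t), nprng)
        hit = h.smith_waterman(copy, bait, scheme)
        norms.append(min(hit.bit_score / groups[0].self_bits["RE1|bait"], 1.0))
    assert norms[0] == pytest.approx(1.0)
    mid = norms[5]
    assert 0.0 < mid < 1.0
    # monotone trend: each level at least as high as two levels later
    for i in range(len(norms) - 2):
        assert norms[i] > norms[i + 2]


# -- window_scan -------------------------------------------------------------


def test_all_zero_scores_give_no_regions():
    assert window_scan(make_scores([0.0] * 100)) == []


def test_block_of_ten_perfect_genes():
    values = [0.0] * 50 + [1.0] * 10 + [0.0] * 50
    hits = window_scan(make_scores(values), window_genes=40, threshold=5.0)
    assert len(hits) == 1
    hit = hits[0]
    assert hit.window_max_score == pytest.approx(10.0)
    assert (hit.first_gene_index, hit.last_gene_index) == (50, 59)
    assert hit.n_genes == 10


def test_window_scan_matches_bruteforce():
    rng = np.random.default_rng(8)
    for n in (60, 500, 5000):
        values = np.where(rng.random(n) < 0.05, rng.random(n), 0.0)
        hits = window_scan(make_scores(values.tolist()), 40, 2.0)
        expected = oracle_regions(values.tolist(), 40, 2.0)
        assert [(x.first_gene_index, x.last_gene_index) for x in hits] == expected


def test_raising_threshold_never_creates_regions():
    rng = np.random.default_rng(10)
    values = np.where(rng.random(800) < 0.1, rng.random(800), 0.0).tolist()
    low = window_scan(make_scores(values), 40, 5.0)
    high = window_scan(make_scores(values), 40, 7.0)
    assert len(high) <= len(low)
    for hh in high:
        assert any(
            ll.first_gene_index <= hh.first_gene_index
            and hh.last_gene_index <= ll.last_gene_index
            for ll in low
        )


def test_shift_covariance():
    """Shifting all genes by k positions shifts the called regions by k."""
    values = [0.0] * 30 + [1.0] * 8 + [0.0] * 60
    base = window_scan(make_scores(values), 40, 5.0)
    shifted = window_scan(make_scores([0.0] * 13 + values), 40, 5.0)
    assert len(base) == len(shifted) == 1
    assert shifted[0].first_gene_index == base[0].first_gene_index + 13
    assert shifted[0].last_gene_index == base[0].last_gene_index + 13


def test_short_contig_single_window():
    values = [1.0] * 6 + [0.0] * 4  # contig of 10 genes, window 40
    hits = window_scan(make_scores(values), 40, 5.0)
    assert len(hits) == 1
    assert hits[0].window_max_score == pytest.approx(6.0)


# -- genome_survey -----------------------------------------------------------


def test_survey_copy_number_and_groups(small_sim, small_groups):
    rows = h.genome_survey([("sim", small_sim.genome)], small_groups)
    (row,) = rows
    assert row.copy_number == 2
    assert all(hit.groups_matched == 8 for hit in row.hits)


def test_survey_rejects_duplicate_ids(small_sim, small_groups):
    with pytest.raises(ValueError, match="duplicate"):
        h.genome_survey(
            [("a", small_sim.genome), ("a", small_sim.genome)], small_groups
        )


def test_cassette_split_across_contigs_is_flagged(small_sim, small_groups):
    """A cassette split over two contigs yields two flagged partial hits."""
    genome = small_sim.genome
    # cut the chromosome between the two islands into two contigs
    isl = small_sim.truth.islands
    cut = (isl[0].end + isl[1].start) // 2
    seq = genome.records[0].sequence
    rec_a = h.GenomeRecord(id="ctgA", sequence=seq[:cut])
    rec_b = h.GenomeRecord(id="ctgB", sequence=seq[cut:])
    genes = []
    for g in genome.genes:
        if g.end <= cut:
            genes.append(
                h.GeneAnnotation(g.gene_id, "ctgA", g.start, g.end, g.strand)
            )
        elif g.start >= cut:
            genes.append(
                h.GeneAnnotation(g.gene_id, "ctgB", g.start - cut, g.end - cut, g.strand)
            )
    from hgtscan.io import build_proteome

    split = h.AnnotatedGenome(records=[rec_a, rec_b], genes=genes)
    build_proteome(split)
    # drop some cassette genes from each contig so each hit is partial
    copy0, copy1 = (
        small_sim.truth.cassette_genes[0],
        small_sim.truth.cassette_genes[1],
    )
    partial = h.AnnotatedGenome(
        records=[rec_a, rec_b],
        genes=[g for g in split.genes if g.gene_id not in copy0[:2] + copy1[6:]],
    )
    build_proteome(partial)
    rows = h.genome_survey([("split", partial)], small_groups)
    (row,) = rows
    assert row.copy_number == 2
    assert {hit.contig for hit in row.hits} == {"ctgA", "ctgB"}
    assert all(hit.groups_matched < len(small_groups) for hit in row.hits)
    assert all(hit.split_contig_flag for hit in row.hits)
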