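"""Pairwise comparison of repeat regions and cross-genome copy numbers.

Two regions are compared through their *congruent gene set*: peptides of
at least 100 amino acids are matched one-to-one by reciprocal best hit
under the significance filters (similarity >= 25%, E <= 1e-4).  From the
matching two summary statistics follow:

* **Jaccard gene-commonality** — shared genes over the union of genes of
  both regions, as a percentage; measures how much gene content the two
  regions still have in common.
* **mean amino-acid similarity** — the unweighted mean positives
  percentage over the matched pairs; measures how diverged the shared
  genes are.

A recent duplication shows high values of both; an older one erodes first
the similarity and then, through gene loss, the Jaccard value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .align import AlignmentHit, HitFilters, ScoringScheme, smith_waterman
from .baits import SurveyRow

#: the congruence filters: peptide length, positives similarity, E-value
MIN_PEPTIDE_LENGTH = 100
CONGRUENCE_FILTERS = HitFilters(min_similarity_pct=25.0, max_evalue=1e-4)


@dataclass
class CongruentSet:
    """One-to-one matched gene pairs of two proteomes, plus the leftovers."""

    pairs: list[tuple[str, str, AlignmentHit]]
    unmatched_a: list[str]
    unmatched_b: list[str]


@dataclass
class RegionComparison:
    """Jaccard gene-commonality and mean similarity of two regions."""

    jaccard_pct: float
    mean_similarity_pct: float
    n_shared: int
    n_union: int


def _filtered(proteome: Mapping[str, str], min_length: int) -> dict[str, str]:
    return {k: v for k, v in proteome.items() if len(v) >= min_length}


def congruent_genes(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    filters: HitFilters = CONGRUENCE_FILTERS,
    min_length: int = MIN_PEPTIDE_LENGTH,
) -> CongruentSet:
    """Reciprocal-best-hit matching of two proteomes under the filters.

    Peptides shorter than ``min_length`` are excluded before comparison
    (truncated gene fragments drop out here).  Candidate reciprocal pairs
    are resolved greedily by descending bit score, so the matching is
    one-to-one even under ties.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    scheme = scheme or ScoringScheme()
    A = _filtered(proteome_a, min_length)
    B = _filtered(proteome_b, min_length)
    if not A or not B:
        return CongruentSet([], sorted(A), sorted(B))
    hits: dict[tuple[str, str], AlignmentHit] = {}
    best_ab: dict[str, str] = {}
    best_ba: dict[str, str] = {}
    for aid in sorted(A):
        best: AlignmentHit | None = None
        for bid in sorted(B):
            h = smith_waterman(A[aid], B[bid], scheme, aid, bid)
            hits[(aid, bid)] = h
            if filters.passes(h) and (best is None or h.bit_score > best.bit_score):
                best = h
        if best is not None:
            best_ab[aid] = best.subject_id
    for bid in sorted(B):
        best = None
        for aid in sorted(A):
            h = hits[(aid, bid)]
            if filters.passes(h) and (best is None or h.bit_score > best.bit_score):
                best = h
        if best is not None:
            best_ba[bid] = best.query_id
    candidates = [
        (hits[(aid, bid)].bit_score, aid, bid)
        for aid, bid in best_ab.items()
        if best_ba.get(bid) == aid
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[str, str, AlignmentHit]] = []
    for _bit, aid, bid in candidates:
        if aid in used_a or bid in used_b:
            continue
        pairs.append((aid, bid, hits[(aid, bid)]))
        used_a.add(aid)
        used_b.add(bid)
    return CongruentSet(
        pairs=pairs,
        unmatched_a=sorted(set(A) - used_a),
        unmatched_b=sorted(set(B) - used_b),
    )


def jaccard_commonality(cs: CongruentSet) -> RegionComparison:
    """Jaccard percentage of a congruent set; similarity filled in too
    (0 when there are no pairs)."""
    n_shared = len(cs.pairs)
    n_union = n_shared + len(cs.unmatched_a) + len(cs.unmatched_b)
    if n_union == 0:
        raise ValueError("both proteomes empty after filtering")
    mean_sim = (
        sum(h.similarity_pct for _, _, h in cs.pairs) / n_shared
        if n_shared
        else 0.0
    )
    return RegionComparison(
        jaccard_pct=100.0 * n_shared / n_union,
        mean_similarity_pct=mean_sim,
        n_shared=n_shared,
        n_union=n_union,
    )


def mean_aa_similarity(cs: CongruentSet) -> float:
    """Unweighted mean positives percentage over the matched pairs."""
    if not cs.pairs:
        raise ValueError("no matched pairs: mean similarity undefined")
    return sum(h.similarity_pct for _, _, h in cs.pairs) / len(cs.pairs)


def compare_regions(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    scheme: ScoringScheme | None = None,
) -> RegionComparison:
    """Congruence, Jaccard and mean similarity of two region proteomes."""
    return jaccard_commonality(congruent_genes(proteome_a, proteome_b, scheme))


def copy_number_report(rows: Sequence[SurveyRow]) -> "object":
    """Genomes ranked by cassette copy number (pandas DataFrame).

    Ties are broken by the total number of bait groups matched across a
    genome's regions, then by genome id for determinism.
    """
    import pandas as pd

    ids = [r.genome_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    ordered = sorted(
        rows, key=lambda r: (-r.copy_number, -r.total_groups_matched, r.genome_id)
    )
    return pd.DataFrame(
        {
            "genome_id": [r.genome_id for r in ordered],
            "copy_number": [r.copy_number for r in ordered],
            "total_groups_matched": [r.total_groups_matched for r in ordered],
        }
    )
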