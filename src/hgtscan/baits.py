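"""Bait-set construction and sliding-window homology scans of genomes.

The bait set is built from the proteomes of the repeat regions carried by
the donor genome's islands: all region proteins are clustered by
single-linkage over significant pairwise alignments, so that the copies of
one ancestral cassette gene fall into one *bait group*.  A target genome
is then scored gene by gene: each gene's score is the best bit score
against any bait member, normalized by that member's self-alignment bit
score (hence in [0, 1], with 1 meaning a verbatim copy), zeroed when the
hit is not significant (E > 1e-4).

Region calling sums these normalized scores over a sliding window of 40
consecutive genes (step 1 gene); windows whose total exceeds 5 are merged
into regions.  Under the self-normalization the window total is bounded by
the number of cassette genes in the window, so the threshold of 5 reads as
"at least five well-conserved cassette genes within 40 consecutive genes".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import (
    AlignmentHit,
    HitFilters,
    ScoringScheme,
    encode,
    raw_score,
    score_statistics,
    smith_waterman,
)
from .io import AnnotatedGenome

#: clustering filters used when building the bait set: significant hit,
#: similarity >= 25%, alignment covering >= half the shorter protein.
DEFAULT_CLUSTER_FILTERS = HitFilters(
    min_similarity_pct=25.0, max_evalue=1e-4, min_shorter_coverage=0.5
)


@dataclass
class BaitGroup:
    """One putative-ortholog group of repeat-region proteins."""

    group_id: str
    members: dict[str, str]  # member id -> sequence
    sources: dict[str, str]  # member id -> region label
    self_bits: dict[str, float]  # member id -> self-alignment bit score


@dataclass
class GeneScore:
    """Normalized best-bait score of one positional gene."""

    gene_id: str
    index: int  # position in the genome gene order
    contig: str
    start: int
    end: int
    normalized_score: float
    best_group: str | None = None


@dataclass
class RegionHit:
    """A called bait-matching region of consecutive genes."""

    genome_id: str
    contig: str
    first_gene_index: int
    last_gene_index: int
    start: int
    end: int
    window_max_score: float
    groups_matched: int
    group_ids: tuple[str, ...] = ()
    split_contig_flag: bool = False

    @property
    def n_genes(self) -> int:
        return self.last_gene_index - self.first_gene_index + 1


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_bait_set(
    region_proteomes: Mapping[str, Mapping[str, str]],
    scheme: ScoringScheme | None = None,
    filters: HitFilters = DEFAULT_CLUSTER_FILTERS,
    drop_unannotated_singletons: bool = False,
    annotations: Mapping[str, str] | None = None,
) -> list[BaitGroup]:
    """Cluster repeat-region proteins into bait groups.

    ``region_proteomes`` maps a region label to its gene_id → protein map.
    Member ids are ``"<region>|<gene_id>"``.  Edges are pairwise local
    alignments passing ``filters``; connected components under
    single-linkage become groups, ordered (and numbered ``G001``…) by
    their lexicographically smallest member.

    ``drop_unannotated_singletons`` discards single-member groups whose
    gene has no informative product annotation (empty or "hypothetical
    protein" in ``annotations``), mimicking the removal of low-confidence
    annotations unique to one region.
    """
    if not region_proteomes:
        raise ValueError("no region proteomes supplied")
    scheme = scheme or ScoringScheme()
    members: dict[str, str] = {}
    sources: dict[str, str] = {}
    plain_id: dict[str, str] = {}
    for region in sorted(region_proteomes):
        for gid in sorted(region_proteomes[region]):
            mid = f"{region}|{gid}"
            members[mid] = region_proteomes[region][gid]
            sources[mid] = region
            plain_id[mid] = gid
    ids = sorted(members)
    uf = _UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            hit = smith_waterman(members[a], members[b], scheme, a, b)
            if filters.passes(hit):
                uf.union(a, b)
    clusters: dict[str, list[str]] = {}
    for mid in ids:
        clusters.setdefault(uf.find(mid), []).append(mid)
    groups: list[BaitGroup] = []
    for k, root in enumerate(sorted(clusters), 1):
        mids = sorted(clusters[root])
        if drop_unannotated_singletons and len(mids) == 1:
            product = (annotations or {}).get(plain_id[mids[0]], "")
            if not product or "hypothetical" in product.lower():
                continue
        group = BaitGroup(
            group_id=f"G{k:03d}",
            members={m: members[m] for m in mids},
            sources={m: sources[m] for m in mids},
            self_bits={},
        )
        for m in mids:
            raw = raw_score(members[m], members[m], scheme)
            bit, _ = score_statistics(raw, scheme, len(members[m]), len(members[m]))
            group.self_bits[m] = bit
        groups.append(group)
    # renumber after any drops
    for k, g in enumerate(groups, 1):
        g.group_id = f"G{k:03d}"
    return groups


def score_genome_genes(
    genome: AnnotatedGenome,
    baits: Sequence[BaitGroup],
    scheme: ScoringScheme | None = None,
    max_evalue: float = 1e-4,
    genome_id: str | None = None,
) -> list[GeneScore]:
    """Normalized best-bait score for every gene, in positional order.

    Genes without a valid translation keep their position with score 0
    (the window scan is positional).  Per gene the score is
    ``max over bait members of bit(gene, member) / self_bit(member)``,
    clipped to [0, 1]; hits with E > ``max_evalue`` contribute 0.
    """
    scheme = scheme or ScoringScheme()
    mat, go, ge = scheme.matrix, scheme.gap_open, scheme.gap_extend
    encoded_baits = [
        (g.group_id, mid, encode(seq), len(seq), g.self_bits[mid])
        for g in baits
        for mid, seq in sorted(g.members.items())
    ]
    out: list[GeneScore] = []
    from .align import _sw_score_rows

    for idx, gene in enumerate(genome.genes):
        aa = genome.proteome.get(gene.gene_id)
        best_norm = 0.0
        best_group: str | None = None
        if aa:
            ea = encode(aa)
            m = len(aa)
            for group_id, _mid, eb, n, self_bit in encoded_baits:
                raw = int(_sw_score_rows(ea, eb, mat, go, ge))
                bit, e_val = score_statistics(raw, scheme, m, n)
                if e_val > max_evalue:
                    continue
                norm = min(bit / self_bit, 1.0)
                if norm > best_norm:
                    best_norm = norm
                    best_group = group_id
        out.append(
            GeneScore(
                gene_id=gene.gene_id,
                index=idx,
                contig=gene.contig,
                start=gene.start,
                end=gene.end,
                normalized_score=best_norm,
                best_group=best_group,
            )
        )
    return out


def window_scan(
    scores: Sequence[GeneScore],
    window_genes: int = 40,
    threshold: float = 5.0,
    genome_id: str = "",
) -> list[RegionHit]:
    """Call bait-matching regions from per-gene scores.

    Per contig, every window of ``window_genes`` consecutive genes (step 1)
    whose score total strictly exceeds ``threshold`` qualifies.  Each
    qualifying window is trimmed to the span of its scoring genes (score
    > 0); overlapping trimmed spans are merged into one region.  Trimming
    before merging keeps a contiguous cassette in one region while two
    cassettes separated by a scoreless stretch are never bridged merely
    because their flanking windows overlap.  Contigs shorter than the
    window are scanned as a single full-contig window.
    """
    by_contig: dict[str, list[GeneScore]] = {}
    for s in scores:
        by_contig.setdefault(s.contig, []).append(s)
    hits: list[RegionHit] = []
    for contig in sorted(by_contig):
        cs = by_contig[contig]
        vals = np.array([s.normalized_score for s in cs])
        n = len(cs)
        w = min(window_genes, n)
        totals = np.convolve(vals, np.ones(w), mode="valid")  # len n-w+1
        qualifying = totals > threshold
        # trim each qualifying window to its scoring genes, merge overlaps
        spans: list[list[float]] = []
        for i in np.flatnonzero(qualifying):
            scoring = np.flatnonzero(vals[i : i + w] > 0)
            if scoring.size == 0:
                continue
            lo, hi = int(i + scoring[0]), int(i + scoring[-1])
            if spans and lo <= spans[-1][1]:
                spans[-1][1] = max(spans[-1][1], hi)
                spans[-1][2] = max(spans[-1][2], float(totals[i]))
            else:
                spans.append([lo, hi, float(totals[i])])
        for lo, hi, max_total in spans:
            lo_t, hi_t = int(lo), int(hi)
            groups = sorted(
                {
                    cs[k].best_group
                    for k in range(lo_t, hi_t + 1)
                    if cs[k].best_group is not None and vals[k] > 0
                }
            )
            hits.append(
                RegionHit(
                    genome_id=genome_id,
                    contig=contig,
                    first_gene_index=cs[lo_t].index,
                    last_gene_index=cs[hi_t].index,
                    start=cs[lo_t].start,
                    end=cs[hi_t].end,
                    window_max_score=max_total,
                    groups_matched=len(groups),
                    group_ids=tuple(groups),
                )
            )
    hits.sort(key=lambda h: (h.contig, h.start))
    return hits


@dataclass
class SurveyRow:
    genome_id: str
    copy_number: int
    hits: list[RegionHit] = field(default_factory=list)

    @property
    def total_groups_matched(self) -> int:
        return sum(h.groups_matched for h in self.hits)


def genome_survey(
    genomes: Sequence[tuple[str, AnnotatedGenome]],
    baits: Sequence[BaitGroup],
    scheme: ScoringScheme | None = None,
    window_genes: int = 40,
    threshold: float = 5.0,
    max_evalue: float = 1e-4,
) -> list[SurveyRow]:
    """Scan several genomes against one bait set; one row per genome.

    When one genome yields partial hits on two or more contigs — each
    matching only part of the bait set — the hits are flagged as a
    possible single region split across contigs by incomplete assembly.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    if len({gid for gid, _ in genomes}) != len(genomes):
        raise ValueError("duplicate genome ids in survey input")
    scheme = scheme or ScoringScheme()
    n_groups = len(baits)
    rows: list[SurveyRow] = []
    for genome_id, genome in genomes:
        scores = score_genome_genes(genome, baits, scheme, max_evalue, genome_id)
        hits = window_scan(scores, window_genes, threshold, genome_id)
        partial = [h for h in hits if h.groups_matched < n_groups]
        if len({h.contig for h in partial}) >= 2:
            for h in partial:
                h.split_contig_flag = True
        rows.append(SurveyRow(genome_id=genome_id, copy_number=len(hits), hits=hits))
    return rows


def survey_table(rows: Sequence[SurveyRow]) -> "object":
    """Survey rows as a flat pandas DataFrame (one line per region hit)."""
    import pandas as pd

    records = []
    for row in rows:
        if not row.hits:
            records.append(
                {
                    "genome_id": row.genome_id,
                    "copy_number": 0,
                    "contig": "",
                    "start": -1,
                    "end": -1,
                    "window_max_score": 0.0,
                    "groups_matched": 0,
                    "split_contig_flag": False,
                }
            )
        for h in row.hits:
            records.append(
                {
                    "genome_id": row.genome_id,
                    "copy_number": row.copy_number,
                    "contig": h.contig,
                    "start": h.start,
                    "end": h.end,
                    "window_max_score": round(h.window_max_score, 3),
                    "groups_matched": h.groups_matched,
                    "split_contig_flag": h.split_contig_flag,
                }
            )
    return pd.DataFrame(records)
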