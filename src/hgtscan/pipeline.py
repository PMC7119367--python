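"""End-to-end orchestration: islands → codon PCA → bait scan → comparisons.

The full analysis treats the GC signal and the bait-homology signal as
independent lines of evidence: island calls and bait-region hits are
cross-referenced in the report (does each called homology region fall
inside a low-GC island?) but neither is ever used to filter the other.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import baits as baits_mod
from . import codons, compare, gc
from .align import HitFilters, ScoringScheme
from .io import AnnotatedGenome


@dataclass
class PipelineConfig:
    """All stage parameters of the full analysis, with the pipeline defaults."""

    gc_window_bp: int = 10_000
    gc_step_bp: int = 1_000
    gc_threshold: float = 0.55
    min_island_bp: int = 50_000
    max_gap_windows: int = 2
    codon_window_genes: int = 10
    codon_stat: str = "proportion"
    bait_window_genes: int = 40
    bait_threshold: float = 5.0
    gap_open: int = 11
    gap_extend: int = 1
    max_evalue: float = 1e-4
    min_similarity_pct: float = 25.0
    min_peptide_length: int = 100
    seed: int = 0

    def gc_config(self) -> gc.GCScanConfig:
        return gc.GCScanConfig(
            window_bp=self.gc_window_bp,
            step_bp=self.gc_step_bp,
            gc_threshold=self.gc_threshold,
            min_island_bp=self.min_island_bp,
            max_gap_windows=self.max_gap_windows,
        )

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(gap_open=self.gap_open, gap_extend=self.gap_extend)

    def congruence_filters(self) -> HitFilters:
        return HitFilters(
            min_similarity_pct=self.min_similarity_pct,
            max_evalue=self.max_evalue,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        cfg.gc_config()  # validates window/step/threshold
        cfg.scheme()  # validates gap penalties
        return cfg


@dataclass
class AnalysisReport:
    """Machine-readable result of ``run_full_analysis``."""

    provenance: dict
    islands: dict[str, list[dict]]
    region_hits: dict[str, list[dict]]
    copy_numbers: list[dict]
    region_comparisons: list[dict]
    codon_pca: dict
    island_region_overlap: list[dict]

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _stage(name: str, genome_id: str = ""):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                where = f" (input {genome_id})" if genome_id else ""
                raise RuntimeError(f"pipeline stage {name!r} failed{where}: {exc}") from exc

    return _Ctx()


def run_full_analysis(
    genomes: Sequence[tuple[str, AnnotatedGenome]],
    repeat_regions: Mapping[str, Mapping[str, str]],
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    """Run every stage of the in-silico island analysis.

    ``genomes`` are (genome_id, annotated genome) pairs; the first genome
    is the reference whose gene windows are ordinated by codon PCA.
    ``repeat_regions`` maps region labels to their proteomes (used both to
    build the bait set and for the pairwise region comparisons).
    """
    if not genomes:
        raise ValueError("at least one annotated genome required")
    config = config or PipelineConfig()
    scheme = config.scheme()

    input_hashes = {
        gid: hashlib.sha256(
            "".join(r.sequence for r in g.records).encode()
        ).hexdigest()[:16]
        for gid, g in genomes
    }

    islands: dict[str, list[dict]] = {}
    for gid, genome in genomes:
        with _stage("gc_islands", gid):
            calls = gc.scan_genome(genome.records, config.gc_config())
        islands[gid] = [
            {
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "length_bp": c.length_bp,
                "mean_gc": round(c.mean_gc, 4),
            }
            for c in calls
        ]

    ref_id, ref_genome = genomes[0]
    with _stage("codon_usage", ref_id):
        windows = codons.gene_window_vectors(
            ref_genome, config.codon_window_genes, stat=config.codon_stat
        )
        pca = codons.run_pca([v for _, v in windows], [w.name for w, _ in windows])
    codon_block = {
        "reference_genome": ref_id,
        "window_genes": config.codon_window_genes,
        "explained_variance_ratio": [
            round(float(r), 6) for r in pca.explained_variance_ratio[:5]
        ],
        "windows": [
            {
                "label": w.name,
                "contig": w.contig,
                "start": w.start,
                "end": w.end,
                "pc1": round(float(s[0]), 6),
                "pc2": round(float(s[1]), 6) if pca.scores.shape[1] > 1 else 0.0,
            }
            for (w, _), s in zip(windows, pca.scores)
        ],
    }

    with _stage("bait_scan"):
        bait_groups = baits_mod.build_bait_set(repeat_regions, scheme)
        survey = baits_mod.genome_survey(
            genomes,
            bait_groups,
            scheme,
            window_genes=config.bait_window_genes,
            threshold=config.bait_threshold,
            max_evalue=config.max_evalue,
        )
    region_hits = {
        row.genome_id: [
            {
                "contig": h.contig,
                "start": h.start,
                "end": h.end,
                "first_gene_index": h.first_gene_index,
                "last_gene_index": h.last_gene_index,
                "window_max_score": round(h.window_max_score, 3),
                "groups_matched": h.groups_matched,
                "split_contig_flag": h.split_contig_flag,
            }
            for h in row.hits
        ]
        for row in survey
    }
    copy_numbers = compare.copy_number_report(survey).to_dict(orient="records")

    with _stage("region_compare"):
        comparisons = []
        labels = sorted(repeat_regions)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                cs = compare.congruent_genes(
                    repeat_regions[a],
                    repeat_regions[b],
                    scheme,
                    filters=config.congruence_filters(),
                    min_length=config.min_peptide_length,
                )
                rc = compare.jaccard_commonality(cs)
                comparisons.append(
                    {
                        "region_a": a,
                        "region_b": b,
                        "jaccard_pct": round(rc.jaccard_pct, 2),
                        "mean_similarity_pct": round(rc.mean_similarity_pct, 2),
                        "n_shared": rc.n_shared,
                        "n_union": rc.n_union,
                    }
                )

    overlap = []
    for gid, hits in region_hits.items():
        for h in hits:
            best = None
            for isl in islands.get(gid, []):
                if isl["contig"] != h["contig"]:
                    continue
                ov = _interval_overlap(
                    (isl["start"], isl["end"]), (h["start"], h["end"])
                )
                if ov > 0 and (best is None or ov > best[1]):
                    best = (isl, ov)
            frac = 0.0 if best is None else best[1] / (h["end"] - h["start"])
            overlap.append(
                {
                    "genome_id": gid,
                    "region": {"contig": h["contig"], "start": h["start"], "end": h["end"]},
                    "overlap_fraction": round(frac, 4),
                    "inside_island": best is not None
                    and best[0]["start"] <= h["start"]
                    and h["end"] <= best[0]["end"],
                    "island": None
                    if best is None
                    else {"start": best[0]["start"], "end": best[0]["end"]},
                }
            )

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "input_hashes": input_hashes,
        "package": "hgtscan",
    }
    return AnalysisReport(
        provenance=provenance,
        islands=islands,
        region_hits=region_hits,
        copy_numbers=copy_numbers,
        region_comparisons=comparisons,
        codon_pca=codon_block,
        island_region_overlap=overlap,
    )
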