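"""Synonymous codon-usage vectors and PCA.

A genome region acquired by horizontal transfer typically keeps, for many
millions of years, the synonymous codon preferences of its donor.  This
module quantifies those preferences as a 59-dimensional vector of
within-amino-acid-family codon proportions — the 61 sense codons minus ATG
(Met) and TGG (Trp), which have no synonymous alternative and therefore
carry no usage signal — and ordinates gene sets by PCA at genome, region,
or sliding-gene-window resolution.

Within-family proportions (each codon's count divided by the total count
of codons encoding the same amino acid) are used rather than raw codon
frequencies: they are insensitive to amino-acid composition, so vectors
remain comparable across genomes and across small gene windows.  An
``stat="frequency"`` switch is available for the raw-frequency variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import TRANSLATION_TABLE, AnnotatedGenome, extract_cds


def _build_tables():
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[TRANSLATION_TABLE]
    bases = "ACGT"
    codon_to_aa = {}
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                codon = b1 + b2 + b3
                if codon in table.stop_codons:
                    continue
                codon_to_aa[codon] = table.forward_table[codon]
    return codon_to_aa


#: codon → amino acid for the 61 sense codons (bacterial table).
CODON_TO_AA: dict[str, str] = _build_tables()

#: the 61 sense codons, grouped by amino acid, alphabetical within group.
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(CODON_TO_AA, key=lambda c: (CODON_TO_AA[c], c))
)

#: the 59 informative codons: sense codons minus the single-codon families.
USAGE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if c not in ("ATG", "TGG")
)

#: the 18 multi-codon amino-acid families, in USAGE_CODONS order.
FAMILIES: tuple[str, ...] = tuple(
    dict.fromkeys(CODON_TO_AA[c] for c in USAGE_CODONS)
)

_CODON_IDX = {c: i for i, c in enumerate(SENSE_CODONS)}
_USAGE_IDX = {c: i for i, c in enumerate(USAGE_CODONS)}
_FAMILY_IDX = {a: i for i, a in enumerate(FAMILIES)}
#: family index of each usage codon
_USAGE_FAMILY = np.array(
    [_FAMILY_IDX[CODON_TO_AA[c]] for c in USAGE_CODONS], dtype=np.int64
)


@dataclass
class CodonCounts:
    """Pooled sense-codon counts of a gene set (stop and N codons excluded)."""

    counts: np.ndarray  # shape (61,), SENSE_CODONS order
    n_genes: int
    n_codons: int

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        return CodonCounts(
            self.counts + other.counts,
            self.n_genes + other.n_genes,
            self.n_codons + other.n_codons,
        )

    def as_dict(self) -> dict[str, int]:
        return {
            c: int(n) for c, n in zip(SENSE_CODONS, self.counts) if n > 0
        }


@dataclass
class CodonUsageVector:
    """59 within-family synonymous codon proportions.

    For every amino-acid family present in the counts, the member
    proportions sum to 1; families with no observed codon are all-zero and
    flagged absent in ``family_present``.
    """

    values: np.ndarray  # shape (59,), USAGE_CODONS order
    family_present: np.ndarray  # shape (18,) bool, FAMILIES order
    label: str = ""


def count_codons(cds_sequences: Iterable[str]) -> CodonCounts:
    """Pool codon counts over a set of coding sequences.

    Stop codons and codons containing an ambiguity base are excluded.
    """
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    n_genes = 0
    for cds in cds_sequences:
        n_genes += 1
        for i in range(0, len(cds) - len(cds) % 3, 3):
            idx = _CODON_IDX.get(cds[i : i + 3])
            if idx is not None:
                counts[idx] += 1
    if n_genes == 0:
        raise ValueError("empty gene set")
    return CodonCounts(counts=counts, n_genes=n_genes, n_codons=int(counts.sum()))


def genome_codon_counts(
    genome: AnnotatedGenome, gene_ids: Sequence[str] | None = None
) -> CodonCounts:
    """Codon counts over a genome's valid genes (optionally a subset)."""
    genes = genome.valid_genes()
    if gene_ids is not None:
        wanted = set(gene_ids)
        genes = [g for g in genes if g.gene_id in wanted]
    return count_codons(extract_cds(genome, g) for g in genes)


def usage_vector(
    counts: CodonCounts, stat: str = "proportion", label: str = ""
) -> CodonUsageVector:
    """Within-family proportions (default) or raw frequencies of a count set."""
    if counts.n_codons == 0:
        raise ValueError("no codons counted")
    usage_counts = np.array(
        [counts.counts[_CODON_IDX[c]] for c in USAGE_CODONS], dtype=np.float64
    )
    family_totals = np.zeros(len(FAMILIES))
    np.add.at(family_totals, _USAGE_FAMILY, usage_counts)
    present = family_totals > 0
    values = np.zeros(len(USAGE_CODONS))
    if stat == "proportion":
        nz = family_totals[_USAGE_FAMILY] > 0
        values[nz] = usage_counts[nz] / family_totals[_USAGE_FAMILY][nz]
    elif stat == "frequency":
        values = usage_counts / counts.n_codons
    else:
        raise ValueError(f"unknown stat {stat!r}")
    return CodonUsageVector(values=values, family_present=present, label=label)


@dataclass
class GeneWindow:
    """Label of one sliding gene window: index span in the valid-gene order
    plus genomic coordinates of the spanned region."""

    contig: str
    first_gene_index: int
    last_gene_index: int
    start: int
    end: int
    gene_ids: tuple[str, ...]

    @property
    def name(self) -> str:
        return f"{self.contig}:genes[{self.first_gene_index}-{self.last_gene_index}]"


def gene_window_vectors(
    genome: AnnotatedGenome,
    window_genes: int = 10,
    step_genes: int = 1,
    stat: str = "proportion",
) -> list[tuple[GeneWindow, CodonUsageVector]]:
    """Codon-usage vector of every sliding window of consecutive valid genes.

    Windows never span contigs.  The default 10-gene window localizes
    donor-like codon usage to within a handful of genes while keeping the
    per-window codon sample large enough for stable proportions.
    """
    genes = genome.valid_genes()
    if len(genes) < window_genes:
        raise ValueError(
            f"{len(genes)} valid genes < window of {window_genes}"
        )
    out: list[tuple[GeneWindow, CodonUsageVector]] = []
    by_contig: dict[str, list[tuple[int, object]]] = {}
    for idx, g in enumerate(genes):
        by_contig.setdefault(g.contig, []).append((idx, g))
    for contig, items in by_contig.items():
        for i in range(0, len(items) - window_genes + 1, step_genes):
            chunk = items[i : i + window_genes]
            counts = count_codons(
                extract_cds(genome, g) for _, g in chunk
            )
            window = GeneWindow(
                contig=contig,
                first_gene_index=chunk[0][0],
                last_gene_index=chunk[-1][0],
                start=chunk[0][1].start,
                end=chunk[-1][1].end,
                gene_ids=tuple(g.gene_id for _, g in chunk),
            )
            vec = usage_vector(counts, stat=stat, label=window.name)
            out.append((window, vec))
    return out


@dataclass
class PCAResult:
    """Principal components of a set of codon-usage vectors."""

    loadings: np.ndarray  # (n_components, 59)
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_samples, n_components)
    labels: list[str]
    mean: np.ndarray


def run_pca(
    vectors: Sequence[CodonUsageVector],
    labels: Sequence[str] | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Column-centered PCA of usage vectors via covariance eigendecomposition.

    No variable scaling is applied; absent families contribute their
    centered zeros.  Sign convention: within each component the entry of
    largest absolute loading is made positive, which fixes the otherwise
    arbitrary eigenvector signs and makes runs deterministic.
    """
    if len(vectors) < 2:
        raise ValueError("PCA needs at least 2 vectors")
    X = np.vstack([v.values for v in vectors])
    labels = list(labels) if labels is not None else [
        v.label or f"v{i}" for i, v in enumerate(vectors)
    ]
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    if total <= 0:
        raise ValueError("degenerate input: all vectors identical (zero variance)")
    k = n_components or min(X.shape)
    eigvals, eigvecs = eigvals[:k], eigvecs[:, :k]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(eigvecs.shape[1])])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    scores = Xc @ eigvecs
    return PCAResult(
        loadings=eigvecs.T,
        explained_variance_ratio=eigvals / total,
        scores=scores,
        labels=labels,
        mean=mean,
    )
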