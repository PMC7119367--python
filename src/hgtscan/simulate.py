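"""Synthetic annotated bacterial genomes with planted genomic islands.

The generator emulates the compositional structure the island-detection
pipeline assumes: a high-GC host chromosome (~60% GC background) carrying
a few large islands of markedly lower GC (a 5–10 percentage-point drop)
and donor-like codon usage, with a multi-gene cassette duplicated into the
islands and diverged per copy to a controlled degree.  Every genome comes
with a machine-readable truth table (island intervals, cassette gene ids
per copy, realized compositions and divergences), so each pipeline stage
can be tested against known ground truth without downloading anything.

Generation is codon-by-codon inside genes — codons are sampled from a
profile exponentially re-weighted until the expected GC hits the target —
and base-by-base in the intergenic gaps, so GC content and codon usage are
controlled jointly.  Cassette proteins are generated once, diverged at the
protein level per copy, and only then back-translated with the island's
codon profile: nucleotide divergence between copies is a consequence, not
a control.  A single integer seed drives all randomness; identical specs
and seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .align import ScoringScheme, _CHAR_TO_IDX
from .codons import CODON_TO_AA, SENSE_CODONS
from .io import (
    AnnotatedGenome,
    GeneAnnotation,
    GenomeRecord,
    build_proteome,
    write_fasta,
    write_gff3,
)

_CODON_GC = np.array(
    [c.count("G") + c.count("C") for c in SENSE_CODONS], dtype=np.float64
)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reweight_to_gc(weights: np.ndarray, target_gc: float) -> np.ndarray:
    """Re-weight a sense-codon profile so expected per-base GC equals target.

    Solves for theta in w_i * exp(theta * gc_i) by bisection; feasible for
    any target strictly inside the profile's attainable GC range.
    """
    w0 = np.asarray(weights, dtype=np.float64)
    if w0.shape != (len(SENSE_CODONS),) or (w0 < 0).any() or w0.sum() <= 0:
        raise ValueError("weights must be a non-negative 61-vector")

    def expected_gc(theta: float) -> float:
        w = w0 * np.exp(theta * (_CODON_GC - 1.5))
        return float((w @ _CODON_GC) / (3.0 * w.sum())) - target_gc

    theta = brentq(expected_gc, -50.0, 50.0, xtol=1e-12)
    w = w0 * np.exp(theta * (_CODON_GC - 1.5))
    return w / w.sum()


def _family_conditionals(profile: np.ndarray) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per amino acid: its codons and their conditional probabilities."""
    fams: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa in sorted(set(CODON_TO_AA.values())):
        codons = [c for c in SENSE_CODONS if CODON_TO_AA[c] == aa]
        w = np.array([profile[SENSE_CODONS.index(c)] for c in codons])
        if w.sum() <= 0:
            w = np.ones(len(codons))
        fams[aa] = (codons, w / w.sum())
    return fams


# ---------------------------------------------------------------------------
# specs


@dataclass
class CassetteSpec:
    """A multi-gene cassette duplicated into the islands.

    ``similarity_targets`` gives, per copy, the target mean amino-acid
    similarity (BLAST positives fraction) to the ancestral cassette; a
    target of 1.0 keeps the ancestor verbatim.  ``identity_targets`` may
    be used instead to state the targets on the identity scale.
    ``ancestors`` optionally supplies the ancestral proteins themselves
    (one per group) — used to plant a cassette homologous to another
    genome's cassette, as in a cross-species survey; when absent the
    ancestors are sampled from the island codon profile.
    """

    n_groups: int = 26
    copies: int = 3
    similarity_targets: tuple[float, ...] | None = (1.0, 0.975, 0.87)
    identity_targets: tuple[float, ...] | None = None
    protein_length_mean: int = 300
    protein_length_sd: int = 60
    protein_length_min: int = 120
    ancestors: tuple[str, ...] | None = None

    def targets(self) -> tuple[str, tuple[float, ...]]:
        if self.identity_targets is not None:
            return "identity", tuple(self.identity_targets)
        return "similarity", tuple(self.similarity_targets)


@dataclass
class IslandSpec:
    length_bp: int
    gc: float = 0.50
    cassette_copy: int | None = None  # index into cassette copies, or None


@dataclass
class SimulationSpec:
    """Full description of one synthetic genome."""

    seed: int = 0
    genome_id: str = "simchr1"
    genome_bp: int = 1_000_000
    background_gc: float = 0.60
    islands: list[IslandSpec] = field(default_factory=list)
    cassette: CassetteSpec | None = None
    gene_length_mean_codons: int = 320
    gene_length_sd_codons: int = 100
    gene_length_min_codons: int = 80
    intergenic_fraction: float = 0.12
    circular: bool = False
    n_genes: int | None = None  # optional override of the density-derived count

    def validate(self) -> None:
        total_islands = sum(i.length_bp for i in self.islands)
        if total_islands >= 0.8 * self.genome_bp:
            raise ValueError("islands do not fit: combined length too large")
        for isl in self.islands:
            if not (0.0 < isl.gc < 1.0):
                raise ValueError("island GC must be in (0, 1)")
            if isl.cassette_copy is not None:
                if self.cassette is None:
                    raise ValueError("island references a cassette but none is specified")
                if not (0 <= isl.cassette_copy < self.cassette.copies):
                    raise ValueError("cassette_copy index out of range")
        if not (0.0 < self.background_gc < 1.0):
            raise ValueError("background GC must be in (0, 1)")
        if self.cassette is not None:
            kind, targets = self.cassette.targets()
            if len(targets) != self.cassette.copies:
                raise ValueError("one divergence target per cassette copy required")
            for t in targets:
                if not (0.25 < t <= 1.0):
                    raise ValueError(
                        f"cassette {kind} target {t} outside (0.25, 1]: "
                        "copies would not remain alignable"
                    )
            if (
                self.cassette.ancestors is not None
                and len(self.cassette.ancestors) != self.cassette.n_groups
            ):
                raise ValueError("cassette ancestors must match n_groups")

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SimulationSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        islands = [IslandSpec(**i) for i in data.pop("islands", [])]
        cassette = data.pop("cassette", None)
        if cassette is not None:
            for key in ("similarity_targets", "identity_targets", "ancestors"):
                if cassette.get(key) is not None:
                    cassette[key] = tuple(cassette[key])
            cassette = CassetteSpec(**cassette)
        return cls(islands=islands, cassette=cassette, **data)


# ---------------------------------------------------------------------------
# protein divergence


def _substitution_weights(scheme: ScoringScheme, positive: bool | None):
    """For each residue: candidate replacements and BLOSUM-softmax weights.

    ``positive`` restricts candidates to positive-scoring (conservative)
    or non-positive (non-conservative) replacements; None allows all.
    """
    letters = "ACDEFGHIKLMNPQRSTVWY"
    table: dict[str, tuple[list[str], np.ndarray]] = {}
    for a in letters:
        cands, weights = [], []
        for b in letters:
            if b == a:
                continue
            s = scheme.matrix[_CHAR_TO_IDX[a], _CHAR_TO_IDX[b]]
            if positive is True and s <= 0:
                continue
            if positive is False and s > 0:
                continue
            cands.append(b)
            weights.append(2.0 ** (s / 2.0))
        if cands:
            w = np.array(weights)
            table[a] = (cands, w / w.sum())
    return table


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def diverge_protein(p: str, target_identity: float, seed=0) -> str:
    """Substitute residues until global identity to *p* hits the target.

    Length is preserved; replacements are BLOSUM-weighted toward plausible
    amino acids.  Exact: the number of substituted positions is
    ``round((1 - target) * len(p))``, so identity lands within one residue
    of the target.
    """
    if not (0.25 < target_identity <= 1.0):
        raise ValueError("target identity must be in (0.25, 1]")
    rng = _as_rng(seed)
    n_sub = round((1.0 - target_identity) * len(p))
    return _substitute(p, n_sub, 0, rng)


def diverge_protein_to_similarity(
    p: str, target_similarity: float, seed=0, conservative_extra: float = 0.5
) -> str:
    """Diverge until the positives similarity to *p* hits the target.

    ``round((1 - target) * len(p))`` positions receive non-conservative
    (non-positive-scoring) replacements, which lower both identity and
    similarity; an additional ``conservative_extra`` times as many
    positions receive conservative replacements, which lower identity
    only.  Positions are aligned one-to-one, so the global similarity
    equals the target exactly up to rounding.
    """
    if not (0.25 < target_similarity <= 1.0):
        raise ValueError("target similarity must be in (0.25, 1]")
    rng = _as_rng(seed)
    n_nonpos = round((1.0 - target_similarity) * len(p))
    n_cons = round(conservative_extra * n_nonpos)
    return _substitute(p, n_nonpos, n_cons, rng)


def _substitute(p: str, n_nonpos: int, n_cons: int, rng) -> str:
    scheme = ScoringScheme()
    nonpos = _substitution_weights(scheme, positive=False)
    cons = _substitution_weights(scheme, positive=True)
    chars = list(p)
    positions = rng.permutation(len(p))
    taken = 0
    done_nonpos = 0
    done_cons = 0
    for pos in positions:
        if done_nonpos >= n_nonpos and done_cons >= n_cons:
            break
        a = chars[pos]
        if done_nonpos < n_nonpos and a in nonpos:
            cands, w = nonpos[a]
            chars[pos] = cands[rng.choice(len(cands), p=w)]
            done_nonpos += 1
        elif done_cons < n_cons and a in cons:
            cands, w = cons[a]
            chars[pos] = cands[rng.choice(len(cands), p=w)]
            done_cons += 1
    return "".join(chars)


def pairwise_positional_stats(a: str, b: str) -> tuple[float, float]:
    """Identity and positives-similarity fractions of two equal-length
    proteins compared position by position (the generator's own bookkeeping
    measure, independent of any alignment)."""
    if len(a) != len(b):
        raise ValueError("positional comparison requires equal lengths")
    scheme = ScoringScheme()
    ident = sum(1 for x, y in zip(a, b) if x == y)
    pos = sum(1 for x, y in zip(a, b) if scheme.score(x, y) > 0)
    return ident / len(a), pos / len(a)


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class TruthIsland:
    island_id: str
    start: int
    end: int
    target_gc: float
    realized_gc: float
    cassette_copy: int | None


@dataclass
class TruthTable:
    islands: list[TruthIsland]
    cassette_genes: dict[int, list[str]]  # copy index -> gene ids, group order
    gene_origin: dict[str, str]  # gene_id -> background / island_<i> / cassette_<copy>_<grp>
    pair_targets: dict[str, float]  # "copyI-copyJ" -> target (similarity or identity)
    pair_realized_similarity: dict[str, float]
    pair_realized_identity: dict[str, float]
    target_kind: str = "similarity"


@dataclass
class SimulatedGenome:
    genome: AnnotatedGenome
    truth: TruthTable
    spec: SimulationSpec
    proteins: dict[str, str] = field(default_factory=dict)

    def region_proteomes(self) -> dict[str, dict[str, str]]:
        """Cassette-copy proteomes keyed 'RE<copy+1>' (for bait building)."""
        out: dict[str, dict[str, str]] = {}
        for copy, gids in sorted(self.truth.cassette_genes.items()):
            out[f"RE{copy + 1}"] = {g: self.genome.proteome[g] for g in gids}
        return out

    def write_outputs(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.records, outdir / "genome.fasta")
        write_gff3(self.genome, outdir / "genome.gff3")
        recs = [
            type("P", (), {"id": gid, "sequence": seq})()
            for gid, seq in sorted(self.genome.proteome.items())
        ]
        write_fasta(recs, outdir / "proteins.faa")
        self.spec.to_json(outdir / "spec.json")
        with open(outdir / "truth_islands.tsv", "w") as fh:
            fh.write("island_id\tstart\tend\ttarget_gc\trealized_gc\tcassette_copy\n")
            for isl in self.truth.islands:
                copy = "" if isl.cassette_copy is None else str(isl.cassette_copy)
                fh.write(
                    f"{isl.island_id}\t{isl.start}\t{isl.end}\t"
                    f"{isl.target_gc:.3f}\t{isl.realized_gc:.4f}\t{copy}\n"
                )
        with open(outdir / "truth_genes.tsv", "w") as fh:
            fh.write("gene_id\torigin\n")
            for gid in sorted(self.truth.gene_origin):
                fh.write(f"{gid}\t{self.truth.gene_origin[gid]}\n")


def _sample_gene(rng, profile, mean, sd, min_codons) -> tuple[str, str]:
    """One random CDS (with ATG start and TAA stop) and its protein."""
    n = max(min_codons, int(round(rng.normal(mean, sd))))
    internal = rng.choice(len(SENSE_CODONS), size=n - 1, p=profile)
    codons = ["ATG"] + [SENSE_CODONS[i] for i in internal] + ["TAA"]
    cds = "".join(codons)
    protein = "M" + "".join(CODON_TO_AA[SENSE_CODONS[i]] for i in internal)
    return cds, protein


def _sample_intergenic(rng, gc, length) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join("ACGT"[i] for i in idx)


def _back_translate(protein: str, fams, rng) -> str:
    codons = []
    for aa in protein:
        choices, probs = fams[aa]
        codons.append(choices[rng.choice(len(choices), p=probs)])
    return "".join(codons) + "TAA"


_Segment = tuple  # ("gap", seq) | ("gene", gene_id, coding_seq, strand, protein, origin)


def _build_gene_run(
    rng,
    profile,
    spec: SimulationSpec,
    target_bp: int,
    gc: float,
    origin: str,
    id_prefix: str,
    counter: list[int],
    fixed_genes: list[tuple[str, str, str]] | None = None,
) -> list[_Segment]:
    """Alternating gap/gene segments totalling ~target_bp.

    ``fixed_genes`` (id, cds, protein) are inserted as a contiguous block
    at a random position among the generated filler genes.
    """
    mean_gap = max(
        20,
        int(
            spec.intergenic_fraction
            / (1 - spec.intergenic_fraction)
            * spec.gene_length_mean_codons
            * 3
        ),
    )
    genes: list[_Segment] = []
    fixed_block: list[_Segment] = []
    fixed_len = 0
    if fixed_genes:
        for gid, cds, protein in fixed_genes:
            strand = "+" if rng.random() < 0.5 else "-"
            fixed_block.append(("gene", gid, cds, strand, protein, origin))
            fixed_len += len(cds) + mean_gap
    budget = target_bp - fixed_len
    used = 0
    while used < budget - (spec.gene_length_min_codons * 3 + mean_gap):
        cds, protein = _sample_gene(
            rng,
            profile,
            spec.gene_length_mean_codons,
            spec.gene_length_sd_codons,
            spec.gene_length_min_codons,
        )
        counter[0] += 1
        gid = f"{id_prefix}{counter[0]:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(("gene", gid, cds, strand, protein, origin))
        used += len(cds) + mean_gap
    if fixed_block:
        at = int(rng.integers(0, len(genes) + 1))
        genes = genes[:at] + fixed_block + genes[at:]
    segments: list[_Segment] = []
    gene_bp = sum(len(g[2]) for g in genes)
    n_gaps = len(genes) + 1
    remaining_bp = max(target_bp - gene_bp, n_gaps * 2)
    gap_lengths = rng.multinomial(remaining_bp - 2 * n_gaps, np.ones(n_gaps) / n_gaps) + 2
    for gap_len, gene in zip(gap_lengths, genes):
        segments.append(("gap", _sample_intergenic(rng, gc, int(gap_len))))
        segments.append(gene)
    segments.append(("gap", _sample_intergenic(rng, gc, int(gap_lengths[-1]))))
    return segments


def simulate_genome(spec: SimulationSpec) -> SimulatedGenome:
    """Generate one annotated genome with planted islands per the spec."""
    spec.validate()
    if spec.n_genes is not None:
        import dataclasses

        genic = spec.n_genes * (spec.gene_length_mean_codons * 3 + 6)
        frac = float(np.clip(1.0 - genic / spec.genome_bp, 0.02, 0.6))
        spec = dataclasses.replace(spec, intergenic_fraction=frac, n_genes=None)
    rng = np.random.default_rng(spec.seed)
    base_weights = np.ones(len(SENSE_CODONS))
    bg_profile = reweight_to_gc(base_weights, spec.background_gc)

    counter = [0]
    # cassette ancestors and per-copy proteins
    cassette_proteins: dict[int, list[tuple[str, str, str]]] = {}
    pair_targets: dict[str, float] = {}
    target_kind = "similarity"
    if spec.cassette is not None:
        cas = spec.cassette
        target_kind, targets = cas.targets()
        island_gcs = [i.gc for i in spec.islands if i.cassette_copy is not None]
        cas_gc = island_gcs[0] if island_gcs else spec.background_gc
        cas_profile = reweight_to_gc(base_weights, cas_gc)
        fams = _family_conditionals(cas_profile)
        if cas.ancestors is not None:
            ancestors = list(cas.ancestors)
        else:
            ancestors = []
            for g in range(cas.n_groups):
                _, protein = _sample_gene(
                    rng,
                    cas_profile,
                    cas.protein_length_mean,
                    cas.protein_length_sd,
                    cas.protein_length_min,
                )
                ancestors.append(protein)
        for copy in range(cas.copies):
            genes_of_copy = []
            for g, anc in enumerate(ancestors):
                if targets[copy] >= 1.0:
                    protein = anc
                elif target_kind == "similarity":
                    protein = diverge_protein_to_similarity(anc, targets[copy], rng)
                else:
                    protein = diverge_protein(anc, targets[copy], rng)
                cds = _back_translate(protein, fams, rng)
                counter[0] += 1
                gid = f"{spec.genome_id}_g{counter[0]:05d}"
                genes_of_copy.append((gid, cds, protein))
            cassette_proteins[copy] = genes_of_copy
            if copy > 0:
                pair_targets[f"copy0-copy{copy}"] = targets[copy]

    # island segment runs
    island_runs: list[tuple[IslandSpec, list[_Segment]]] = []
    for k, isl in enumerate(spec.islands):
        profile = reweight_to_gc(base_weights, isl.gc)
        fixed = (
            [
                (gid, cds, protein)
                for gid, cds, protein in cassette_proteins[isl.cassette_copy]
            ]
            if isl.cassette_copy is not None
            else None
        )
        run = _build_gene_run(
            rng,
            profile,
            spec,
            isl.length_bp,
            isl.gc,
            f"island_{k}",
            f"{spec.genome_id}_g",
            counter,
            fixed_genes=fixed,
        )
        island_runs.append((isl, run))

    # background run
    bg_bp = spec.genome_bp - sum(i.length_bp for i in spec.islands)
    bg_run = _build_gene_run(
        rng, bg_profile, spec, bg_bp, spec.background_gc,
        "background", f"{spec.genome_id}_g", counter,
    )

    # insert island runs at jittered, well-separated gap positions: island k
    # goes near background fraction (k+1)/(n+1), so neighbouring islands are
    # always separated by a long stretch of background
    gap_positions = [
        i for i, seg in enumerate(bg_run) if seg[0] == "gap" and 0 < i < len(bg_run) - 1
    ]
    n_isl = len(island_runs)
    if len(gap_positions) < n_isl:
        raise ValueError("background too short to place islands")
    insert_at: list[int] = []
    for k in range(n_isl):
        frac = (k + 1) / (n_isl + 1) + float(rng.uniform(-0.3, 0.3)) / (n_isl + 1)
        target = int(np.clip(frac, 0.02, 0.98) * len(gap_positions))
        idx = gap_positions[min(target, len(gap_positions) - 1)]
        while idx in insert_at:
            idx = gap_positions[(gap_positions.index(idx) + 1) % len(gap_positions)]
        insert_at.append(idx)

    assembled: list[_Segment] = []
    island_marks: list[tuple[int, IslandSpec, int]] = []  # (segment idx, spec, spec idx)
    run_iter = iter(sorted(zip(insert_at, range(n_isl))))
    next_insert = next(run_iter, None)
    for i, seg in enumerate(bg_run):
        assembled.append(seg)
        while next_insert is not None and next_insert[0] == i:
            k = next_insert[1]
            island_marks.append((len(assembled), spec.islands[k], k))
            assembled.extend(island_runs[k][1])
            next_insert = next(run_iter, None)

    # flatten to sequence + annotations
    seq_parts: list[str] = []
    pos = 0
    genes: list[GeneAnnotation] = []
    gene_origin: dict[str, str] = {}
    island_intervals: list[tuple[int, int, IslandSpec, int]] = []
    seg_starts: dict[int, int] = {}
    for i, seg in enumerate(assembled):
        seg_starts[i] = pos
        if seg[0] == "gap":
            seq_parts.append(seg[1])
            pos += len(seg[1])
        else:
            _, gid, cds, strand, protein, origin = seg
            genomic = cds if strand == "+" else _revcomp(cds)
            seq_parts.append(genomic)
            genes.append(
                GeneAnnotation(
                    gene_id=gid,
                    contig=spec.genome_id,
                    start=pos,
                    end=pos + len(cds),
                    strand=strand,
                    product=origin,
                )
            )
            gene_origin[gid] = origin
            pos += len(cds)
    sequence = "".join(seq_parts)
    # island absolute intervals: from first segment of the run to its end
    for seg_idx, isl, k in island_marks:
        start = seg_starts[seg_idx]
        run_len = sum(
            len(s[1]) if s[0] == "gap" else len(s[2])
            for s in island_runs[k][1]
        )
        island_intervals.append((start, start + run_len, isl, k))

    record = GenomeRecord(
        id=spec.genome_id, sequence=sequence, circular=spec.circular
    )
    genome = AnnotatedGenome(records=[record], genes=genes)
    build_proteome(genome)

    from .gc import gc_fraction

    truth_islands = [
        TruthIsland(
            island_id=f"island_{k}",
            start=s,
            end=e,
            target_gc=isl.gc,
            realized_gc=gc_fraction(sequence[s:e]),
            cassette_copy=isl.cassette_copy,
        )
        for s, e, isl, k in sorted(island_intervals)
    ]
    cassette_genes = {
        copy: [gid for gid, _, _ in triples]
        for copy, triples in cassette_proteins.items()
    }
    pair_sim: dict[str, float] = {}
    pair_ident: dict[str, float] = {}
    if spec.cassette is not None:
        for copy in range(1, spec.cassette.copies):
            idents, sims = [], []
            for (g0, _, p0), (gc_, _, pc) in zip(
                cassette_proteins[0], cassette_proteins[copy]
            ):
                ident, sim = pairwise_positional_stats(p0, pc)
                idents.append(ident)
                sims.append(sim)
            pair_ident[f"copy0-copy{copy}"] = float(np.mean(idents))
            pair_sim[f"copy0-copy{copy}"] = float(np.mean(sims))

    truth = TruthTable(
        islands=truth_islands,
        cassette_genes=cassette_genes,
        gene_origin=gene_origin,
        pair_targets=pair_targets,
        pair_realized_similarity=pair_sim,
        pair_realized_identity=pair_ident,
        target_kind=target_kind,
    )
    return SimulatedGenome(
        genome=genome,
        truth=truth,
        spec=spec,
        proteins=dict(genome.proteome),
    )


# ---------------------------------------------------------------------------
# the reference fixture


#: Frozen spec of the benchmark genome used throughout the test suite:
#: ~1 Mb, ~900 genes, 60% GC background, three 79/87/98-kb islands at 50%
#: GC, each carrying one copy of a 26-gene cassette whose copies mirror a
#: recent (similarity 0.975) and an older (0.87) duplication.
REFERENCE_SPEC = SimulationSpec(
    seed=1845,
    genome_id="simchr1",
    genome_bp=1_000_000,
    background_gc=0.60,
    islands=[
        IslandSpec(length_bp=79_000, gc=0.50, cassette_copy=0),
        IslandSpec(length_bp=87_000, gc=0.50, cassette_copy=1),
        IslandSpec(length_bp=98_000, gc=0.50, cassette_copy=2),
    ],
    cassette=CassetteSpec(
        n_groups=26, copies=3, similarity_targets=(1.0, 0.975, 0.87)
    ),
)


def make_reference_fixture(outdir=None) -> SimulatedGenome:
    """Generate the frozen benchmark genome (optionally writing its files)."""
    sim = simulate_genome(REFERENCE_SPEC)
    if outdir is not None:
        sim.write_outputs(outdir)
    return sim
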