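# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic genomes do and do not
emulate, and the numerical conventions that make runs reproducible.

## GC-anomaly island calling

The GC fraction of a window is `(G+C)/(A+C+G+T)`; ambiguity bases (N) are
excluded from numerator and denominator, and a sequence with no
unambiguous base has no defined GC. Windows start at multiples of the
step; on linear contigs a final partial window is kept iff it covers at
least half a window, and on circular contigs the scan wraps across the
origin.

An island call is a maximal run of windows below the GC threshold,
tolerating up to `max_gap_windows` consecutive above-threshold windows
inside the run. Defaults: **window 10 kb, step 1 kb, threshold 0.55,
minimum island 50 kb, gap tolerance 2 windows**. The threshold is the
published sub-55% criterion for these islands; window, step and minimum
length are this package's choices, sized so that islands in the
80–100 kb range are comfortably recovered while single-gene GC dips and
short compositional wobbles are not called.

Interval convention: a run whose first and last qualifying windows start
at s₀ and s₁ is reported as `[s₀ + (w−step)//2, s₁ + w − (w−step−(w−step)//2))`
— the span of the window *centers*, widened by half a step on each side.
Because a window qualifies roughly when more than half of its content is
island, centering makes the boundary error on the order of the step
(~1 kb) rather than the window (~10 kb). With step = window the formula
degenerates to the plain union of the qualifying windows. The reported
`mean_gc` is recomputed from the underlying sequence, not averaged over
overlapping windows, to avoid step-induced weighting bias. A circular
run that crosses the origin is reported with `end` past the contig
length (interpret modulo the length); runs that abut the origin from
both sides are not stitched — a known limitation.

## Synonymous codon usage

A gene set is summarized by pooled sense-codon counts (stop codons and
N-containing codons excluded) and converted to a 59-dimensional usage
vector: each codon's count divided by the total count of its
amino-acid family, with ATG (Met) and TGG (Trp) dropped because
single-codon families carry no usage information. Within-family
proportions — rather than raw codon frequencies or RSCU — make vectors
insensitive to amino-acid composition, so genomes, regions and small
gene windows remain directly comparable; the raw-frequency variant
remains available via `stat="frequency"`. A family absent from a small
window is all-zero and masked in `family_present`.

PCA is computed on the column-centered vectors via eigendecomposition of
the covariance matrix, without variable scaling; masked families simply
contribute their centered zeros. Eigenvector signs are fixed by making
each component's largest-magnitude loading positive, which makes scores
deterministic. Window resolution defaults to **10 consecutive valid
genes, step 1**, never spanning contigs: small enough to localize a
transferred block, large enough (~3,000 codons) for stable proportions.

## Local protein alignment and statistics

The similarity engine is an exact affine-gap Smith–Waterman (no
heuristic seeding) over BLOSUM62 with gap open 11 and extend 1; a gap of
length L costs `11 + L·1`, both penalties charged on the first gap
position. The unknown residue X scores 0 against everything. Identity
and similarity percentages are taken over all aligned columns, gaps
included; a "similar" column is one with positive substitution score
(the positives convention). The DP inner loops are numba-compiled; a
score-only two-row kernel serves the high-volume scans and a
full-matrix kernel with traceback serves hits that need column counts.

Raw scores convert to bit scores and E-values by the Karlin–Altschul
formulas with the classical gapped BLOSUM62/11/1 parameters λ = 0.267
nats, K = 0.041, and search space m·n (query × subject length). No
composition-based statistics and no length-adjusted effective search
space are applied, so E-values are conservative approximations; the
pipeline's significance cutoff (E ≤ 1e-4) is applied to these
approximations. An exhaustive pure-Python DP in the test suite serves as
the independent oracle for the engine.

The "similarity ≥ 25%" congruence filter is interpreted on the positives
scale (not identity); this is the more permissive and, for a filter
described as *similarity*, the more literal reading. It is switchable
through `HitFilters`.

## Bait sets and the 40-gene window scan

All repeat-region proteins are clustered by single linkage over
significant pairwise alignments (E ≤ 1e-4, similarity ≥ 25%, alignment
covering ≥ 50% of the shorter protein); each connected component is one
bait group — the operational stand-in for a manually reconciled
ancestral gene arrangement. Optionally, single-member groups without an
informative product annotation can be dropped, mirroring the removal of
low-confidence annotations unique to one region.

Each gene of a target genome receives
`max over bait members of bit(gene, member) / bit(member, member)`,
clipped to [0, 1], zero unless the hit reaches E ≤ 1e-4; taking the max
over a group's members prevents paralogous baits from double counting.
Genes whose CDS failed validation keep their position with score 0,
because the scan is positional. The window statistic is the sum of these
normalized scores over **40 consecutive genes, step 1 gene**; a window
qualifies when its total strictly exceeds **5**. Under self-normalized
scores the window total is bounded by the number of cassette genes in
the window, so the threshold reads as "at least five well-conserved
cassette genes within 40 consecutive genes".

Each qualifying window is trimmed to the span of its scoring genes and
overlapping trimmed spans are merged into one region. Trimming *before*
merging keeps one contiguous cassette in one region while preventing two
cassettes separated by a scoreless stretch from being bridged merely
because their flanking 40-gene windows overlap. Contigs shorter than the
window are scanned as a single full-contig window. In a multi-contig
genome whose partial hits are spread over two or more contigs, the hits
are flagged as a possible single region split by incomplete assembly.

## Region comparison

Congruent gene sets use reciprocal best hits: peptides shorter than
100 aa are removed, each remaining peptide's best passing hit is
computed in both directions, and mutual best pairs are accepted greedily
by descending bit score, yielding a one-to-one matching (truncated gene
fragments fall out via the length filter, with no special casing).
Jaccard gene-commonality is `100·n_shared/(n_shared + unmatched_A +
unmatched_B)` with the post-filter gene as the counting unit; mean
amino-acid similarity is the unweighted mean positives percentage over
matched pairs. Copy-number reports rank genomes by the number of called
regions, ties broken by total bait groups matched, then by genome id.

## The synthetic genomes

The generator emulates exactly the statistical structure the analysis
assumes: a host chromosome of uniform background composition carrying a
few large islands of different composition, with a duplicated, diverged
cassette inside the islands.

* **Genes** are generated codon by codon: sense-codon weights are
  exponentially re-weighted (`w·e^{θ·gc(codon)}`, θ solved by bisection)
  until the expected per-base GC equals the target, then codons are
  sampled iid; each gene gets an ATG start and TAA stop. Intergenic gaps
  are iid bases at the regional GC. Gene lengths are normal (mean 320,
  sd 100, minimum 80 codons) and the intergenic fraction is 12%, giving
  the ~1 gene/kb density typical of bacterial chromosomes.
* **Islands** are inserted at jittered, well-separated positions
  (neighbouring islands always separated by a long background stretch);
  island genes use the island-GC codon profile, so lowered GC and
  shifted codon usage arise jointly, as they do in real transfers.
* **Cassettes**: ancestral proteins are generated once, each copy is
  diverged at the protein level, and only then back-translated with the
  island's family-conditional codon profile — nucleotide divergence is a
  consequence, never a control. `diverge_protein` substitutes
  `round((1−t)·L)` positions (BLOSUM-weighted toward plausible
  replacements) so global identity hits the target within one residue;
  `diverge_protein_to_similarity` instead places non-positive-scoring
  replacements to hit a positives-similarity target, plus half as many
  conservative replacements that lower identity only. The benchmark
  fixture states its copy targets on the similarity scale (0.975 and
  0.87 to the ancestral copy) because similarity is what the region
  comparison measures; identity is lower and recorded in the truth
  table. Supplying `ancestors` explicitly plants a cassette homologous
  to another genome's, which is how cross-genome survey panels are
  built.
* One integer seed drives all randomness; identical specs give
  byte-identical FASTA/GFF3/truth outputs. The ~1-Mb benchmark
  (`REFERENCE_SPEC`, seed 1845: three 79/87/98-kb islands at 50% GC in a
  60% background, each carrying one copy of a 26-gene cassette) is
  committed as its spec, from which it regenerates bit-for-bit.

What the simulator does **not** emulate: indels and rearrangements
within cassette genes, codon substitution models, amino-acid
composition gradients, repeats/low-complexity tracts, pseudogenes,
annotation errors, and sequencing artifacts. Tests passing on these
genomes therefore demonstrate the correctness and calibration of the
algorithms under their stated assumptions — not robustness to the
annotation noise and compositional amelioration of real genomes, where
boundary accuracy and weak-homolog sensitivity will be worse.

## Problem sizes and numerical choices

The test and acceptance runs use the ~1-Mb benchmark (~930 genes), a
three-genome survey panel of 160–320 kb with 2/1/0 planted copies at
similarity 0.85, and twenty 120-kb island-free genomes for the
false-positive count; these sizes make every effect several standard
errors wide while keeping a full run in minutes on one core. Ties in
best-hit selection break deterministically (higher bit, lower E, then
lexicographic id); region and island outputs are sorted by coordinate;
PCA signs are fixed as above; all floating-point tolerances in tests are
stated per check (1e-8 for eigenvalue ratios, one residue for divergence
targets, ±3 percentage points for similarity recovery).

## Known limitations

Karlin–Altschul parameters are fixed rather than estimated, so E-values
for strongly biased compositions are approximate; the GC caller reports
step-resolution boundaries and cannot separate two islands closer than
the gap tolerance; circular-origin islands are not stitched; bait-group
clustering can over-merge genuinely distinct families linked by a
promiscuous domain (single linkage); and the whole-assembly checks in
the acceptance suite require a locally supplied copy of the deposited
chromosome, which cannot be redistributed with the package.
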