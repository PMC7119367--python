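"""Generate a small annotated genome with one planted low-GC island.

The generator emulates a ~60%-GC host chromosome carrying an island of
donor-like composition (50% GC) with a 6-gene cassette, and emits FASTA,
GFF3, protein FASTA and a truth table.
"""

from hgtscan import gc_fraction
from hgtscan.simulate import CassetteSpec, IslandSpec, SimulationSpec, simulate_genome

spec = SimulationSpec(
    seed=42,
    genome_bp=200_000,
    background_gc=0.60,
    islands=[IslandSpec(length_bp=55_000, gc=0.50, cassette_copy=0)],
    cassette=CassetteSpec(n_groups=6, copies=1, similarity_targets=(1.0,)),
)
sim = simulate_genome(spec)
sim.write_outputs("scratch/example_genome")

record = sim.genome.records[0]
island = sim.truth.islands[0]
print(f"genome: {len(record):,} bp, {len(sim.genome.genes)} genes")
print(f"whole-genome GC: {gc_fraction(record.sequence):.3f}")
print(
    f"planted island: {island.start:,}-{island.end:,} "
    f"(realized GC {island.realized_gc:.3f}, target {island.target_gc:.2f})"
)
print(f"cassette genes: {', '.join(sim.truth.cassette_genes[0])}")
# The island's GC sits ~10 points below the host background — the
# compositional anomaly every downstream detector keys on.
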