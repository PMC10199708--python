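"""Build a small synthetic genome with planted telomeres, a centromeric
satellite region, TE/gene annotations and truth files.

The truth set records every planted structure so downstream examples
can measure recovery.
"""

from t2tannot import CentromerePlan, SimulationSpec, TelomerePlan, simulate_genome

spec = SimulationSpec(
    chrom_lengths=(700_000, 650_000),
    seed=7,
    telomeres=TelomerePlan(missing_arms=((1, "left"),)),  # chr2 lacks a left-arm telomere
    centromeres=CentromerePlan(array_bp=(80_000, 120_000)),
)
sim = simulate_genome(spec)
sim.write("scratch_example_genome")

for g in sim.genome:
    print(f"{g.chrom_id}: {g.length:,} bp")
for t in sim.truth.telomeres:
    print(f"planted telomere {t['chrom']} {t['arm']}: {t['copies']} copies, "
          f"[{t['start']:,}, {t['end']:,})")
for chrom, c in sim.truth.centromeres.items():
    print(f"planted centromere {chrom}: [{c['start']:,}, {c['end']:,}), "
          f"{c['period']}-bp monomer, {c['array_bp']:,} bp of satellite")
print(f"{sum(f.kind == 'gene' for f in sim.features)} genes, "
      f"{sum(f.kind == 'TE' for f in sim.features)} TEs placed")
# Three telomeres (one arm deliberately missing), one centromeric region per
# chromosome; features avoid the planted arrays and thin out around them.
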