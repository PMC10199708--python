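"""Discover the telomeric repeat unit and call telomeres on every arm.

The unit search scans 150-kb terminal windows for tandem units of
5-12 bp; the caller then measures the maximal run of that unit per arm.
"""

from t2tannot import (
    CentromerePlan,
    SimulationSpec,
    TelomerePlan,
    call_telomeres,
    find_telomere_unit,
    simulate_genome,
)

spec = SimulationSpec(
    chrom_lengths=(700_000, 650_000),
    seed=7,
    telomeres=TelomerePlan(missing_arms=((1, "left"),)),
    centromeres=CentromerePlan(array_bp=(80_000, 120_000)),
)
sim = simulate_genome(spec)

unit = find_telomere_unit(sim.genome)
print(f"telomeric unit (canonical): {unit.unit}   terminal coverage {unit.coverage_bp:,.0f} bp")

for call in call_telomeres(sim.genome, unit.unit):
    state = (
        f"{call.copies:,.0f} copies, {call.array_length:,} bp"
        if call.present
        else "absent"
    )
    print(f"{call.chrom_id} {call.arm:>5} arm: {state}")
# The canonical unit AAACCCT is the rotation/strand-normalized form of
# TTTAGGG; copies x 7 equals the array length for exact planted arrays,
# and the deliberately omitted arm is reported absent.
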