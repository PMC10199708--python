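"""Standard benchmark scenarios with planted truth.

These functions freeze the study conditions used to validate the
package: a 19-chromosome genome with telomeres on all arms except two
short arms and one centromeric satellite region per chromosome; a 5-Mb
genome carrying a known genome fraction of the dominant satellite
family; a higher-order (dimer) repeat whose base period is too diverged
to detect directly; and a clone-panel SNP set with nine planted
heterozygosity hotspots at genome scale.  Each returns plain results
computed by running the ordinary library entry points, so they double
as reproducibility entry points for the headline numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centromeres import call_centromeres
from .hetscan import FilterConfig, call_hotspots, filter_variants, window_heterozygosity
from .io import GenomeSequence
from .repeats import _BASES, encode, group_harmonics, scan_genome, scan_tandem_arrays
from .simulate import (
    CentromerePlan,
    SimulationSpec,
    SNPPlan,
    TelomerePlan,
    random_monomer,
    simulate_genome,
    simulate_snp_samples,
)
from .telomeres import call_telomeres, find_telomere_unit

#: Hotspot intervals (chrom, start, end in bp) for the clone-panel
#: benchmark: nine multi-window regions on eight chromosomes, two of
#: them on chromosome 10.
HOTSPOT_INTERVALS: tuple[tuple[str, int, int], ...] = (
    ("chr1", 1_100_000, 1_300_000),
    ("chr2", 4_200_000, 7_200_000),
    ("chr3", 9_400_000, 9_900_000),
    ("chr4", 21_800_000, 22_900_000),
    ("chr7", 15_300_000, 26_200_000),
    ("chr10", 700_000, 6_500_000),
    ("chr10", 17_600_000, 18_300_000),
    ("chr11", 7_100_000, 7_800_000),
    ("chr16", 13_000_000, 13_500_000),
)

#: Chromosome lengths (bp) for the clone-panel benchmark; 19
#: chromosomes totalling ~472 Mb, sized like a mid-size plant genome.
HOTSPOT_CHROM_LENGTHS: dict[str, int] = {
    f"chr{i + 1}": int(mb * 1_000_000)
    for i, mb in enumerate(
        [26.5, 21.0, 22.5, 26.0, 27.5, 24.0, 30.0, 24.5, 25.5, 20.0,
         21.5, 26.0, 25.5, 27.0, 23.5, 24.5, 19.5, 31.0, 26.5]
    )
}


def nineteen_chromosome_spec(seed: int) -> SimulationSpec:
    """The 19-chromosome recovery genome: 1-2 Mb chromosomes, telomeres on
    every arm except the short arms of chromosomes 15 and 17, and one
    centromeric 107-bp-family satellite region per chromosome with
    TE/gene density depleted five-fold around it."""
    rng = np.random.default_rng(seed)
    lengths = tuple(int(x) for x in rng.integers(1_000_000, 2_000_001, 19))
    return SimulationSpec(
        chrom_lengths=lengths,
        seed=seed,
        telomeres=TelomerePlan(missing_arms=((14, "left"), (16, "left"))),
        centromeres=CentromerePlan(array_bp=(100_000, 500_000)),
    )


@dataclass
class RecoveryResult:
    arms_present: int
    arms_planted: int
    centromeres_called: int
    centromeres_planted: int
    jaccards: list[float]
    genome_bp: int


def telomere_centromere_recovery(seed: int) -> RecoveryResult:
    """Simulate the 19-chromosome genome, then run unit discovery, telomere
    calling, the tandem scan, harmonic grouping and centromere calling
    with all defaults; report arm and centromere recovery."""
    spec = nineteen_chromosome_spec(seed)
    sim = simulate_genome(spec)
    unit = find_telomere_unit(sim.genome)
    calls = call_telomeres(sim.genome, unit.unit) if unit else []
    arms_present = sum(c.present for c in calls)

    arrays = scan_genome(sim.genome)
    families = group_harmonics(arrays)
    cen_calls, _ = call_centromeres(sim.chrom_lengths, arrays, families, sim.features)
    jaccards = []
    for c in cen_calls:
        t = sim.truth.centromeres[c.chrom_id]
        inter = max(0, min(c.end, t["end"]) - max(c.start, t["start"]))
        union = (c.end - c.start) + (t["end"] - t["start"]) - inter
        jaccards.append(round(inter / union, 4))
    return RecoveryResult(
        arms_present=arms_present,
        arms_planted=len(sim.truth.telomeres),
        centromeres_called=len(cen_calls),
        centromeres_planted=len(sim.truth.centromeres),
        jaccards=jaccards,
        genome_bp=sum(spec.chrom_lengths),
    )


def diverged_dimer_period(seed: int, n_copies: int = 20, n_subs: int = 25) -> tuple[int, int]:
    """Detected period of a higher-order repeat whose unit is two copies of
    a 107-bp monomer with the second copy diverged at ``n_subs`` positions.

    The divergence drops the 107-bp shifted identity below the detection
    threshold while the 214-bp dimer remains exact, so the scanner must
    report the dimer period (harmonic grouping later reduces it to the
    base family).  Returns (detected period, sequence length scanned).
    """
    rng = np.random.default_rng(seed)
    mon = random_monomer(rng, 107)
    second = encode(mon).copy()
    subs = rng.choice(107, n_subs, replace=False)
    second[subs] = (second[subs] + rng.integers(1, 4, n_subs)) % 4
    dimer = mon + _BASES[second].tobytes().decode("ascii")
    bg = _BASES[rng.integers(0, 4, 10_000)].tobytes().decode("ascii")
    seq = bg[:5000] + dimer * n_copies + bg[5000:]
    arrays = scan_tandem_arrays(seq)
    if not arrays:
        return 0, len(seq)
    best = max(arrays, key=lambda a: a.span)
    return best.period, len(seq)


def repeat_fraction_spec(seed: int) -> SimulationSpec:
    """A 5-Mb three-chromosome genome with 107-bp-family satellite arrays
    totalling exactly 3.95% of the sequence (197.5 kb), at 2% per-copy
    substitution with the default share of 2x/3x concatemer blocks."""
    return SimulationSpec(
        chrom_lengths=(2_000_000, 1_600_000, 1_400_000),
        seed=seed,
        centromeres=CentromerePlan(
            array_bp_overrides={0: 80_000, 1: 60_000, 2: 57_500},
        ),
    )


def repeat_fraction_recovery(seed: int) -> tuple[float, int]:
    """Recovered genome percentage of the planted 107-bp family.

    Runs the tandem scan and harmonic grouping on the 5-Mb genome and
    sums the bp of the family whose base period is 107.  Returns
    (percent, genome length).
    """
    spec = repeat_fraction_spec(seed)
    sim = simulate_genome(spec)
    genome_length = sum(spec.chrom_lengths)
    arrays = scan_genome(sim.genome)
    families = group_harmonics(arrays)
    fam_bp = sum(f.total_bp for f in families if f.base_period == 107)
    return round(100.0 * fam_bp / genome_length, 4), genome_length


def hotspot_snp_plan(background_rate: float = 8e-5, multiplier: float = 10.0) -> SNPPlan:
    return SNPPlan(
        background_rate=background_rate,
        hotspots=tuple((c, s, e, multiplier) for c, s, e in HOTSPOT_INTERVALS),
    )


def hotspot_recovery(seed: int):
    """Simulate the clone-panel SNP set, apply the strict filter, window
    heterozygosity at 100 kb, and call top-5% hotspot fragments.

    Returns (fragments, n_sites_filtered).
    """
    table, _ = simulate_snp_samples(HOTSPOT_CHROM_LENGTHS, hotspot_snp_plan(), seed=seed)
    filtered, _ = filter_variants(table, FilterConfig())
    profile = window_heterozygosity(filtered, HOTSPOT_CHROM_LENGTHS)
    fragments = call_hotspots(profile)
    return fragments, len(filtered)
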