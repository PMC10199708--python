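"""Synthetic genomes with planted truth for benchmarking the annotation stack.

The simulator emits exactly the structures the analyses assume:

* 7-bp telomeric tandem arrays (TTTAGGG by default) at chromosome
  termini, exact by default (the unit is a single conserved 7-mer);
* centromeric satellite arrays built from a randomly generated base
  monomer (107 bp by default; the real consensus is genome-specific, so
  truth monomers are synthetic by construction) with a configurable
  fraction of copies emitted as literal 2x/3x concatemers and 2%
  per-copy substitution by default;
* chromosome-specific alternative monomers (e.g. 135, 66, 56, 187 bp);
* TE-like and gene features with density depletion in a pericentromeric
  zone (annotation-level intervals over background sequence — every
  consumer works on densities, not TE sequence);
* ordered gene models carrying domain accessions, with planted
  tandem-like domain clusters;
* four-sample heterozygous SNP sets with localized hotspots and a
  controlled all-sample sharing fraction.

Everything is deterministic given the mandatory seed, and every planted
structure is recorded in a machine-readable :class:`TruthSet`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import Feature, GenomeSequence, VariantTable, write_bed, write_fasta, write_gff3, write_vcf
from .repeats import _BASES, encode

logger = logging.getLogger(__name__)

TELOMERE_UNIT = "TTTAGGG"


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

@dataclass
class TelomerePlan:
    unit: str = TELOMERE_UNIT
    copies_range: tuple[int, int] = (200, 2000)
    #: arms without a telomere, as (chromosome index, "left"|"right")
    missing_arms: tuple[tuple[int, str], ...] = ()
    mutation_rate: float = 0.0


@dataclass
class CentromerePlan:
    monomer_length: int = 107
    monomer: str | None = None              # generated from the seed when None
    array_bp: tuple[int, int] = (100_000, 500_000)
    #: per-chromosome override of total array bp (index -> bp)
    array_bp_overrides: dict[int, int] = field(default_factory=dict)
    dimer_fraction: float = 0.2
    trimer_fraction: float = 0.1
    mutation_rate: float = 0.02
    n_blocks: int = 2
    block_gap: int = 10_000
    position: float = 0.5                   # array midpoint as fraction of chrom length
    max_len_fraction: float = 0.35
    #: chromosome-specific alternative monomer lengths (index -> bp)
    alt_monomer_lengths: dict[int, int] = field(default_factory=dict)


@dataclass
class TEPlan:
    families: tuple[str, ...] = ("Gypsy", "Copia", "MULE-MuDR", "Helitron")
    coverage: float = 0.30                  # fraction of chromosome covered
    length_range: tuple[int, int] = (300, 5000)
    depletion_factor: float = 5.0
    pericentromere_flank: int = 50_000


@dataclass
class ClusterPlan:
    accession: str
    chrom_index: int = 0
    n_genes: int = 8
    seed_len: int = 4                       # consecutive carriers seeding the cluster
    span_ordinals: int = 20                 # extra members scattered within this many ordinals


@dataclass
class GenePlan:
    genes_per_mb: float = 100.0
    length_range: tuple[int, int] = (1000, 4000)
    vocabulary: tuple[str, ...] = (
        "WAK", "PPR", "ABC", "Integrase", "Peptidase", "RT", "TPS",
        "MCO", "Pkinase", "LRR", "Myb", "bZIP", "F-box", "UDPGT",
    )
    domains_per_gene: tuple[int, int] = (1, 3)
    depletion_factor: float = 5.0
    clusters: tuple[ClusterPlan, ...] = ()


@dataclass
class SNPPlan:
    n_samples: int = 4
    background_rate: float = 5e-5           # heterozygous sites per bp
    #: (chrom_id, start, end, rate multiplier)
    hotspots: tuple[tuple[str, int, int, float], ...] = ()
    #: base rate the hotspot multiplier applies to; defaults to background_rate
    hotspot_reference_rate: float | None = None
    shared_fraction: float = 0.853
    gq_fail_fraction: float = 0.05          # sites given one sub-threshold GQ
    gq_range: tuple[int, int] = (30, 99)
    gq_fail_range: tuple[int, int] = (2, 29)


@dataclass
class SimulationSpec:
    chrom_lengths: tuple[int, ...]
    seed: int
    chrom_prefix: str = "chr"
    telomeres: TelomerePlan = field(default_factory=TelomerePlan)
    centromeres: CentromerePlan = field(default_factory=CentromerePlan)
    tes: TEPlan = field(default_factory=TEPlan)
    genes: GenePlan = field(default_factory=GenePlan)
    snps: SNPPlan = field(default_factory=SNPPlan)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for rate in (
            self.telomeres.mutation_rate,
            self.centromeres.mutation_rate,
            self.centromeres.dimer_fraction,
            self.centromeres.trimer_fraction,
            self.snps.shared_fraction,
            self.snps.gq_fail_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")

    def chrom_id(self, i: int) -> str:
        return f"{self.chrom_prefix}{i + 1}"


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedArray:
    chrom_id: str
    start: int
    end: int
    monomer: str
    copies: float

    @property
    def period(self) -> int:
        return len(self.monomer)


@dataclass
class TruthSet:
    """Machine-readable record of everything the simulator planted."""

    telomeres: list[dict] = field(default_factory=list)    # chrom, arm, start, end, copies
    centromeres: dict[str, dict] = field(default_factory=dict)  # chrom -> region + monomer
    arrays: list[PlantedArray] = field(default_factory=list)
    clusters: dict[str, list[str]] = field(default_factory=dict)  # accession -> gene ids
    hotspots: list[dict] = field(default_factory=list)     # chrom, start, end, multiplier
    sharing_class: list[str] = field(default_factory=list)  # per VCF site: "all" | "partial"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "telomeres": self.telomeres,
            "centromeres": self.centromeres,
            "arrays": [asdict(a) for a in self.arrays],
            "clusters": self.clusters,
            "hotspots": self.hotspots,
            "sharing_class": self.sharing_class,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# low-level planting
# ---------------------------------------------------------------------------

def random_monomer(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _mutate_copies(codes: np.ndarray, n_copies: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Stack n_copies of a unit, substituting each position at ``rate`` per copy."""
    mat = np.tile(codes, (n_copies, 1)).astype(np.int8)
    if rate > 0:
        hit = rng.random(mat.shape) < rate
        # substitute to one of the three other bases
        mat[hit] = (mat[hit] + rng.integers(1, 4, hit.sum())) % 4
    return mat


def plant_tandem_array(
    seq: np.ndarray,
    monomer: str,
    copies: float,
    per_copy_mutation_rate: float,
    position: int,
    rng: np.random.Generator,
    chrom_id: str = "seq",
    period_range: tuple[int, int] | None = (30, 500),
) -> PlantedArray:
    """Splice a tandem array into an encoded sequence (in place).

    The inserted span is ``round(copies * len(monomer))`` bp: full copies
    plus a partial trailing copy for fractional counts.  Each copy is
    substituted per position at the stated rate from the seeded
    generator.  Arrays exceeding the chromosome bounds raise
    ``ValueError``.
    """
    p = len(monomer)
    if period_range is not None and not (period_range[0] <= p <= period_range[1]):
        raise ValueError(f"monomer length {p} outside {period_range}")
    if copies < 1:
        raise ValueError("copies must be >= 1")
    span = int(round(copies * p))
    if position < 0 or position + span > len(seq):
        raise ValueError(
            f"array [{position}, {position + span}) exceeds chromosome bounds (length {len(seq)})"
        )
    codes = encode(monomer)
    n_copies = int(np.ceil(span / p))
    mat = _mutate_copies(codes, n_copies, per_copy_mutation_rate, rng)
    seq[position : position + span] = mat.ravel()[:span]
    return PlantedArray(chrom_id, position, position + span, monomer, round(span / p, 4))


def _centromere_block(
    monomer: str,
    target_bp: int,
    plan: CentromerePlan,
    rng: np.random.Generator,
) -> np.ndarray:
    """Build one satellite block of ~target_bp from monomer/dimer/trimer copies."""
    codes = encode(monomer)
    p = len(monomer)
    pieces: list[np.ndarray] = []
    emitted = 0
    p_mono = 1.0 - plan.dimer_fraction - plan.trimer_fraction
    while emitted < target_bp:
        u = rng.random()
        k = 1 if u < p_mono else (2 if u < p_mono + plan.dimer_fraction else 3)
        unit = np.tile(codes, k)
        copy = _mutate_copies(unit, 1, plan.mutation_rate, rng).ravel()
        pieces.append(copy)
        emitted += k * p
    block = np.concatenate(pieces)[:target_bp]
    return block


# ---------------------------------------------------------------------------
# feature placement
# ---------------------------------------------------------------------------

def _place_intervals(
    rng: np.random.Generator,
    chrom_length: int,
    n_target: int,
    length_range: tuple[int, int],
    forbidden: list[tuple[int, int]],
    depleted: list[tuple[int, int]],
    depletion_factor: float,
) -> list[tuple[int, int]]:
    """Greedy non-overlapping placement avoiding forbidden zones.

    Candidates falling in a depleted zone are kept with probability
    1/depletion_factor.  Returns sorted intervals.
    """
    forb = sorted(forbidden)
    placed: list[tuple[int, int]] = []
    starts = np.sort(rng.integers(0, chrom_length, n_target * 3))
    lengths = rng.integers(length_range[0], length_range[1] + 1, len(starts))
    accept_p = 1.0 / depletion_factor if depletion_factor > 0 else 1.0
    keep_roll = rng.random(len(starts))
    last_end = -1
    n_placed = 0
    for s, ln, roll in zip(starts, lengths, keep_roll):
        if n_placed >= n_target:
            break
        e = int(s) + int(ln)
        if e > chrom_length or s <= last_end:
            continue
        if any(s < fe and e > fs for fs, fe in forb):
            continue
        if any(s < de and e > ds for ds, de in depleted) and roll > accept_p:
            continue
        placed.append((int(s), e))
        last_end = e
        n_placed += 1
    return placed


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    spec: SimulationSpec
    genome: list[GenomeSequence]
    features: list[Feature]
    domains: dict[str, set[str]]
    truth: TruthSet

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {g.chrom_id: g.length for g in self.genome}

    def write(self, outdir: str | Path) -> None:
        """Emit genome.fasta, features.gff3, domains.tsv, truth.json + truth BEDs."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fasta")
        write_gff3(self.features, out / "features.gff3")
        from .clusters import build_gene_records, write_domains_tsv

        recs = build_gene_records([f for f in self.features if f.kind == "gene"], self.domains)
        write_domains_tsv(recs, out / "domains.tsv")
        self.truth.to_json(out / "truth.json")
        write_bed(
            [(t["chrom"], t["start"], t["end"], f"telomere_{t['arm']}") for t in self.truth.telomeres],
            out / "truth_telomeres.bed",
        )
        write_bed(
            [(c, v["start"], v["end"], "centromere") for c, v in self.truth.centromeres.items()],
            out / "truth_centromeres.bed",
        )
        write_bed(
            [(a.chrom_id, a.start, a.end, f"array_p{a.period}") for a in self.truth.arrays],
            out / "truth_arrays.bed",
        )


def simulate_genome(spec: SimulationSpec) -> SimulatedGenome:
    """Build a genome + annotations + truth from a :class:`SimulationSpec`.

    Deterministic given the seed: background is i.i.d. uniform ACGT,
    telomeres are planted flush with the termini, the centromeric region
    sits at ``position`` of each chromosome as ``n_blocks`` satellite
    blocks separated by short background gaps, and TE/gene features are
    placed greedily, never overlapping planted arrays, with density
    depleted inside the pericentromeric zone.
    """
    rng = np.random.default_rng(spec.seed)
    cen = spec.centromeres
    base_monomer = cen.monomer or random_monomer(rng, cen.monomer_length)
    alt_monomers = {
        i: random_monomer(rng, ln) for i, ln in sorted(cen.alt_monomer_lengths.items())
    }

    genome: list[GenomeSequence] = []
    features: list[Feature] = []
    domains: dict[str, set[str]] = {}
    truth = TruthSet()
    gene_counter = 0

    for ci, L in enumerate(spec.chrom_lengths):
        chrom = spec.chrom_id(ci)
        seq = rng.integers(0, 4, L).astype(np.int8)
        occupied: list[tuple[int, int]] = []

        # --- telomeres -----------------------------------------------------
        tel = spec.telomeres
        unit_len = len(tel.unit)
        for arm in ("left", "right"):
            if (ci, arm) in tel.missing_arms:
                continue
            copies = int(rng.integers(tel.copies_range[0], tel.copies_range[1] + 1))
            span = copies * unit_len
            pos = 0 if arm == "left" else L - span
            planted = plant_tandem_array(
                seq, tel.unit, copies, tel.mutation_rate, pos, rng,
                chrom_id=chrom, period_range=None,
            )
            occupied.append((planted.start, planted.end))
            truth.telomeres.append(
                {"chrom": chrom, "arm": arm, "start": planted.start, "end": planted.end, "copies": copies}
            )

        # --- centromere ----------------------------------------------------
        monomer = alt_monomers.get(ci, base_monomer)
        if ci in cen.array_bp_overrides:
            total_bp = cen.array_bp_overrides[ci]
        else:
            cap = int(cen.max_len_fraction * L)
            hi = min(cen.array_bp[1], cap)
            lo = min(cen.array_bp[0], hi)
            total_bp = int(rng.integers(lo, hi + 1))
        block_bps = _split_blocks(total_bp, cen.n_blocks, len(monomer), rng)
        span = sum(block_bps) + cen.block_gap * (len(block_bps) - 1)
        start = int(round(cen.position * L - span / 2))
        if start < 0 or start + span > L:
            raise ValueError(
                f"{chrom}: centromeric region [{start}, {start + span}) does not fit in length {L}"
            )
        for s, e in occupied:
            if start < e and start + span > s:
                raise ValueError(
                    f"{chrom}: centromere [{start}, {start + span}) collides with [{s}, {e})"
                )
        cursor = start
        block_truth: list[PlantedArray] = []
        for bbp in block_bps:
            block = _centromere_block(monomer, bbp, cen, rng)
            seq[cursor : cursor + bbp] = block
            pa = PlantedArray(chrom, cursor, cursor + bbp, monomer, round(bbp / len(monomer), 4))
            block_truth.append(pa)
            truth.arrays.append(pa)
            occupied.append((cursor, cursor + bbp))
            cursor += bbp + cen.block_gap
        truth.centromeres[chrom] = {
            "start": start,
            "end": start + span,
            "monomer": monomer,
            "period": len(monomer),
            "array_bp": total_bp,
            "blocks": [[a.start, a.end] for a in block_truth],
        }

        # --- TE and gene features -----------------------------------------
        peri = (
            max(0, start - spec.tes.pericentromere_flank),
            min(L, start + span + spec.tes.pericentromere_flank),
        )
        mean_te_len = (spec.tes.length_range[0] + spec.tes.length_range[1]) / 2
        n_te = int(spec.tes.coverage * L / mean_te_len)
        te_ivs = _place_intervals(
            rng, L, n_te, spec.tes.length_range, occupied, [peri], spec.tes.depletion_factor
        )
        for s, e in te_ivs:
            fam = spec.tes.families[rng.integers(0, len(spec.tes.families))]
            features.append(Feature(chrom, s, e, kind="TE", subtype=fam, id=f"TE_{chrom}_{s}"))
        n_gene = int(spec.genes.genes_per_mb * L / 1e6)
        gene_ivs = _place_intervals(
            rng, L, n_gene, spec.genes.length_range,
            occupied + te_ivs, [peri], spec.genes.depletion_factor,
        )
        cluster_accs = {c.accession for c in spec.genes.clusters}
        background_vocab = [a for a in spec.genes.vocabulary if a not in cluster_accs]
        for s, e in gene_ivs:
            gene_counter += 1
            gid = f"gene_{gene_counter:05d}"
            features.append(Feature(chrom, s, e, kind="gene", id=gid))
            k = int(rng.integers(spec.genes.domains_per_gene[0], spec.genes.domains_per_gene[1] + 1))
            picks = rng.choice(len(background_vocab), size=min(k, len(background_vocab)), replace=False)
            domains[gid] = {background_vocab[i] for i in picks}

        genome.append(GenomeSequence(chrom, _BASES[seq].tobytes().decode("ascii")))

    # --- planted domain clusters (over the ordered gene models) ------------
    _plant_clusters(spec, features, domains, truth, rng)

    return SimulatedGenome(spec, genome, features, domains, truth)


def _split_blocks(total_bp: int, n_blocks: int, period: int, rng: np.random.Generator) -> list[int]:
    """Split a satellite-bp budget into blocks of whole-ish copy counts."""
    n_blocks = max(1, min(n_blocks, total_bp // max(2 * period, 1)))
    cuts = np.sort(rng.integers(1, total_bp, n_blocks - 1)) if n_blocks > 1 else np.array([], int)
    bounds = np.concatenate([[0], cuts, [total_bp]])
    sizes = np.diff(bounds)
    # rebalance tiny blocks into the largest one
    sizes = sizes.tolist()
    min_bp = 2 * period
    while len(sizes) > 1 and min(sizes) < min_bp:
        i = sizes.index(min(sizes))
        small = sizes.pop(i)
        sizes[sizes.index(max(sizes))] += small
    return [int(s) for s in sizes]


def _plant_clusters(
    spec: SimulationSpec,
    features: list[Feature],
    domains: dict[str, set[str]],
    truth: TruthSet,
    rng: np.random.Generator,
) -> None:
    genes_by_chrom: dict[int, list[Feature]] = {}
    chrom_index = {spec.chrom_id(i): i for i in range(len(spec.chrom_lengths))}
    for f in features:
        if f.kind == "gene":
            genes_by_chrom.setdefault(chrom_index[f.chrom_id], []).append(f)
    for plan in spec.genes.clusters:
        genes = sorted(genes_by_chrom.get(plan.chrom_index, []), key=lambda f: f.start)
        if len(genes) < plan.n_genes:
            raise ValueError(
                f"cluster {plan.accession}: only {len(genes)} genes on chromosome "
                f"{plan.chrom_index + 1}, need {plan.n_genes}"
            )
        span = max(plan.span_ordinals, plan.n_genes)
        start_ord = int(rng.integers(0, max(1, len(genes) - span)))
        members = list(range(start_ord, start_ord + plan.seed_len))
        pool = [
            i
            for i in range(max(0, start_ord - plan.span_ordinals),
                           min(len(genes), start_ord + plan.seed_len + plan.span_ordinals))
            if i not in members
        ]
        extra = rng.choice(len(pool), size=plan.n_genes - plan.seed_len, replace=False)
        members += [pool[i] for i in extra]
        ids = []
        for i in sorted(members):
            gid = genes[i].id
            domains[gid] = domains.get(gid, set()) | {plan.accession}
            ids.append(gid)
        truth.clusters[plan.accession] = ids


# ---------------------------------------------------------------------------
# SNP simulation
# ---------------------------------------------------------------------------

def _merge_hotspots(
    hotspots: list[tuple[str, int, int, float]],
) -> list[tuple[str, int, int, float]]:
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, s, e, m in hotspots:
        by_chrom.setdefault(chrom, []).append((s, e, m))
    merged: list[tuple[str, int, int, float]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur = list(ivs[0])
        for s, e, m in ivs[1:]:
            if s < cur[1]:
                logger.warning("%s: overlapping hotspot intervals merged", chrom)
                cur[1] = max(cur[1], e)
                cur[2] = max(cur[2], m)
            else:
                merged.append((chrom, cur[0], cur[1], cur[2]))
                cur = [s, e, m]
        merged.append((chrom, cur[0], cur[1], cur[2]))
    return merged


def simulate_snp_samples(
    chrom_lengths: dict[str, int],
    plan: SNPPlan,
    seed: int,
) -> tuple[VariantTable, TruthSet]:
    """Simulate a joint multi-sample heterozygous SNP set.

    Site positions follow a Poisson process at ``background_rate``
    per bp, elevated by the stated multiplier inside hotspot intervals.
    Each site is heterozygous either in all samples (probability
    ``shared_fraction``) or in 1..n-1 uniformly chosen samples; a
    ``gq_fail_fraction`` of sites gets one sub-threshold GQ so the
    filter stage has something to remove.  Hotspot intervals are
    recorded (merged if overlapping) in the returned truth.
    """
    rng = np.random.default_rng(seed)
    hotspots = _merge_hotspots([(c, s, e, m) for c, s, e, m in plan.hotspots])
    for chrom, s, e, _ in hotspots:
        if chrom not in chrom_lengths or e > chrom_lengths[chrom] or s < 0:
            raise ValueError(f"hotspot [{s}, {e}) outside chromosome {chrom}")

    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for chrom in chrom_lengths:
        L = chrom_lengths[chrom]
        n_bg = rng.poisson(plan.background_rate * L)
        pos = [rng.integers(0, L, n_bg)]
        ref = plan.hotspot_reference_rate if plan.hotspot_reference_rate is not None else plan.background_rate
        for hc, s, e, mult in hotspots:
            if hc != chrom:
                continue
            extra = max(ref * mult - plan.background_rate, 0.0)
            n_hs = rng.poisson(extra * (e - s))
            pos.append(rng.integers(s, e, n_hs))
        p = np.unique(np.concatenate(pos)) if pos else np.zeros(0, np.int64)
        positions.append(p)
        chroms.extend([chrom] * len(p))

    pos_all = np.concatenate(positions) if positions else np.zeros(0, np.int64)
    n = len(pos_all)
    S = plan.n_samples
    shared = rng.random(n) < plan.shared_fraction
    het = np.zeros((n, S), dtype=bool)
    het[shared] = True
    n_partial = int((~shared).sum())
    k_het = rng.integers(1, S, n_partial)  # 1..S-1 samples heterozygous
    partial_idx = np.flatnonzero(~shared)
    for i, k in zip(partial_idx, k_het):
        het[i, rng.choice(S, size=int(k), replace=False)] = True

    alleles = np.zeros((n, S, 2), dtype=np.int8)
    alleles[..., 1] = het.astype(np.int8)  # het -> 0/1, otherwise 0/0 (homozygous ref)

    gq = rng.integers(plan.gq_range[0], plan.gq_range[1] + 1, (n, S)).astype(np.int32)
    fail_sites = rng.random(n) < plan.gq_fail_fraction
    fail_sample = rng.integers(0, S, n)
    low = rng.integers(plan.gq_fail_range[0], plan.gq_fail_range[1] + 1, n)
    gq[np.flatnonzero(fail_sites), fail_sample[fail_sites]] = low[fail_sites]

    ref_alt = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4

    table = VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=pos_all,
        ref=[ref_alt[i] for i in ref_idx],
        alts=[(ref_alt[i],) for i in alt_idx],
        alleles=alleles,
        gq=gq,
        samples=[f"sample{i + 1}" for i in range(S)],
    )
    truth = TruthSet(
        hotspots=[{"chrom": c, "start": int(s), "end": int(e), "multiplier": m} for c, s, e, m in hotspots],
        sharing_class=["all" if sh else "partial" for sh in shared],
    )
    return table, truth
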