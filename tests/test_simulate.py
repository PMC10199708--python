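"""Synthetic-genome generator: planted structure, truth consistency, determinism."""

import logging

import numpy as np
import pytest

from t2tannot.io import GenomeSequence
from t2tannot.repeats import encode, scan_tandem_arrays
from t2tannot.simulate import (
    CentromerePlan,
    ClusterPlan,
    GenePlan,
    SimulationSpec,
    SNPPlan,
    TelomerePlan,
    plant_tandem_array,
    random_monomer,
    simulate_genome,
    simulate_snp_samples,
)


def small_spec(seed=7, **kwargs):
    defaults = dict(
        chrom_lengths=(700_000, 650_000),
        seed=seed,
        centromeres=CentromerePlan(array_bp=(80_000, 120_000)),
    )
    defaults.update(kwargs)
    return SimulationSpec(**defaults)


class TestPlantTandemArray:
    def test_exact_array_length(self, monomer_107, rng):
        seq = rng.integers(0, 4, 5000).astype(np.int8)
        planted = plant_tandem_array(seq, monomer_107, 10, 0.0, 1000, rng)
        assert planted.end - planted.start == 1070
        assert np.array_equal(seq[1000:1107], encode(monomer_107))

    def test_fractional_copies_rounding(self, monomer_107, rng):
        seq = rng.integers(0, 4, 5000).astype(np.int8)
        planted = plant_tandem_array(seq, monomer_107, 10.5, 0.0, 1000, rng)
        assert planted.end - planted.start == round(10.5 * 107) == 1124

    def test_mutation_rate_identity_expectation(self, monomer_107, rng):
        seq = rng.integers(0, 4, 20_000).astype(np.int8)
        planted = plant_tandem_array(seq, monomer_107, 100, 0.05, 1000, rng)
        mat = seq[planted.start : planted.start + 100 * 107].reshape(100, 107)
        ident = (mat == encode(monomer_107)[None, :]).mean()
        assert ident == pytest.approx(0.95, abs=0.02)

    def test_out_of_bounds_error(self, monomer_107, rng):
        seq = rng.integers(0, 4, 2000).astype(np.int8)
        with pytest.raises(ValueError, match="exceeds"):
            plant_tandem_array(seq, monomer_107, 10, 0.0, 1500, rng)

    def test_period_range_enforced(self, rng):
        seq = rng.integers(0, 4, 2000).astype(np.int8)
        with pytest.raises(ValueError, match="outside"):
            plant_tandem_array(seq, "ACGTA", 10, 0.0, 0, rng)


class TestSimulateGenome:
    def test_truth_lists_all_telomere_arms(self):
        sim = simulate_genome(small_spec())
        assert len(sim.truth.telomeres) == 4
        assert {(t["chrom"], t["arm"]) for t in sim.truth.telomeres} == {
            ("chr1", "left"), ("chr1", "right"), ("chr2", "left"), ("chr2", "right"),
        }

    def test_missing_arms_respected(self):
        sim = simulate_genome(small_spec(telomeres=TelomerePlan(missing_arms=((0, "left"),))))
        assert ("chr1", "left") not in {(t["chrom"], t["arm"]) for t in sim.truth.telomeres}
        assert len(sim.truth.telomeres) == 3

    def test_seeded_determinism_byte_identical(self, tmp_path):
        a = simulate_genome(small_spec(seed=42))
        b = simulate_genome(small_spec(seed=42))
        assert [g.seq for g in a.genome] == [g.seq for g in b.genome]
        assert a.truth.centromeres == b.truth.centromeres
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        assert (tmp_path / "a/genome.fasta").read_bytes() == (tmp_path / "b/genome.fasta").read_bytes()

    def test_planted_fraction_arithmetic(self):
        # explicit per-chromosome budgets: 200 kb in a 5-Mb genome = 4.0%
        spec = SimulationSpec(
            chrom_lengths=(2_000_000, 1_600_000, 1_400_000),
            seed=3,
            centromeres=CentromerePlan(array_bp_overrides={0: 80_000, 1: 60_000, 2: 60_000}),
        )
        sim = simulate_genome(spec)
        total = sum(a.end - a.start for a in sim.truth.arrays)
        assert total == 200_000
        assert total / sum(spec.chrom_lengths) == pytest.approx(0.04)

    def test_truth_arrays_rescannable(self):
        """Re-extracting a planted mutation-free array reproduces copy number."""
        spec = small_spec(
            centromeres=CentromerePlan(array_bp=(60_000, 80_000), mutation_rate=0.0, n_blocks=1)
        )
        sim = simulate_genome(spec)
        chrom = {g.chrom_id: g.seq for g in sim.genome}
        for planted in sim.truth.arrays:
            sub = chrom[planted.chrom_id][planted.start : planted.end]
            (found,) = scan_tandem_arrays(sub, min_period=100, max_period=120)
            assert found.period == planted.period
            assert abs(found.copies - planted.copies) <= 1.0

    def test_genes_never_overlap_planted_arrays(self):
        sim = simulate_genome(small_spec())
        arrays = [(a.chrom_id, a.start, a.end) for a in sim.truth.arrays]
        for t in sim.truth.telomeres:
            arrays.append((t["chrom"], t["start"], t["end"]))
        for f in sim.features:
            for c, s, e in arrays:
                if f.chrom_id == c:
                    assert not (f.start < e and f.end > s), (f, (c, s, e))

    def test_te_depletion_in_pericentromere(self):
        spec = small_spec(seed=11)
        sim = simulate_genome(spec)
        te = [f for f in sim.features if f.kind == "TE" and f.chrom_id == "chr1"]
        cen = sim.truth.centromeres["chr1"]
        L = sim.genome[0].length
        flank = spec.tes.pericentromere_flank
        zone = (max(0, cen["start"] - flank), min(L, cen["end"] + flank))
        inside_bp = sum(f.length for f in te if f.start < zone[1] and f.end > zone[0])
        outside_bp = sum(f.length for f in te) - inside_bp
        dens_in = inside_bp / (zone[1] - zone[0])
        dens_out = outside_bp / (L - (zone[1] - zone[0]))
        assert dens_in < dens_out / 2

    def test_infeasible_packing_raises(self):
        spec = small_spec(
            chrom_lengths=(210_000,),
            telomeres=TelomerePlan(copies_range=(2000, 2000)),
            centromeres=CentromerePlan(array_bp_overrides={0: 190_000}, n_blocks=1),
        )
        with pytest.raises(ValueError, match="collides|does not fit"):
            simulate_genome(spec)

    def test_planted_cluster_membership_recorded(self):
        spec = small_spec(
            genes=GenePlan(clusters=(ClusterPlan("NB-ARC", chrom_index=0, n_genes=8),))
        )
        sim = simulate_genome(spec)
        members = sim.truth.clusters["NB-ARC"]
        assert len(members) == 8
        assert all(sim.domains[g] >= {"NB-ARC"} for g in members)
        carriers = [g for g, d in sim.domains.items() if "NB-ARC" in d]
        assert sorted(carriers) == sorted(members)  # background never carries it


class TestSimulateSnpSamples:
    LENGTHS = {"chr1": 2_000_000, "chr2": 1_500_000}

    def test_shared_fraction_binomial(self):
        plan = SNPPlan(background_rate=3e-3, shared_fraction=0.853)
        table, truth = simulate_snp_samples(self.LENGTHS, plan, seed=5)
        n = len(table)
        shared = sum(c == "all" for c in truth.sharing_class)
        assert n > 5000
        se = np.sqrt(0.853 * 0.147 / n)
        assert shared / n == pytest.approx(0.853, abs=4 * se)

    def test_sharing_labels_partition_sites(self):
        plan = SNPPlan(background_rate=1e-4)
        table, truth = simulate_snp_samples(self.LENGTHS, plan, seed=6)
        assert len(truth.sharing_class) == len(table)
        het_counts = table.het_matrix.sum(axis=1)
        for label, k in zip(truth.sharing_class, het_counts):
            assert (label == "all") == (k == 4)
            assert 1 <= k <= 4

    def test_hotspot_rate_ratio(self):
        plan = SNPPlan(
            background_rate=2e-4,
            hotspots=(("chr1", 500_000, 1_000_000, 10.0),),
            gq_fail_fraction=0.0,
        )
        table, _ = simulate_snp_samples(self.LENGTHS, plan, seed=8)
        pos = table.pos[table.chrom == "chr1"]
        inside = ((pos >= 500_000) & (pos < 1_000_000)).sum() / 500_000
        outside = ((pos < 500_000) | (pos >= 1_000_000)).sum() / 1_500_000
        assert inside / outside == pytest.approx(10.0, rel=0.25)

    def test_zero_background_all_sites_in_hotspot(self):
        plan = SNPPlan(background_rate=0.0, hotspot_reference_rate=1e-4,
                       hotspots=(("chr1", 100_000, 200_000, 10.0),))
        table, _ = simulate_snp_samples(self.LENGTHS, plan, seed=9)
        assert len(table) > 0
        assert ((table.pos >= 100_000) & (table.pos < 200_000)).all()

    def test_overlapping_hotspots_merged_with_warning(self, caplog):
        plan = SNPPlan(hotspots=(("chr1", 0, 200_000, 10.0), ("chr1", 100_000, 300_000, 10.0)))
        with caplog.at_level(logging.WARNING):
            _, truth = simulate_snp_samples(self.LENGTHS, plan, seed=10)
        assert len(truth.hotspots) == 1
        assert (truth.hotspots[0]["start"], truth.hotspots[0]["end"]) == (0, 300_000)
        assert any("merged" in r.message for r in caplog.records)

    def test_gq_failure_fraction(self):
        plan = SNPPlan(background_rate=1e-3, gq_fail_fraction=0.10)
        table, _ = simulate_snp_samples(self.LENGTHS, plan, seed=12)
        frac_fail = (table.gq < 30).any(axis=1).mean()
        assert frac_fail == pytest.approx(0.10, abs=0.02)

    def test_hotspot_outside_chromosome_error(self):
        plan = SNPPlan(hotspots=(("chr1", 0, 3_000_000, 10.0),))
        with pytest.raises(ValueError):
            simulate_snp_samples(self.LENGTHS, plan, seed=1)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(chrom_lengths=(500_000,), seed=1,
                           snps=SNPPlan(shared_fraction=1.5))
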