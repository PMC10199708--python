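"""Gene-cluster detection, hit filtering and R-gene classification.

The enumeration oracle re-derives clusters by brute force over every
(accession, seed window) combination, independently of the sweep in
``find_domain_clusters``.
"""

import numpy as np
import pytest

from t2tannot.clusters import (
    GeneRecord,
    SimilarityHit,
    build_gene_records,
    classify_r_genes,
    cluster_region_report,
    filter_similarity_hits,
    find_domain_clusters,
    score_protein_pairs,
)
from t2tannot.io import Feature


def genes_from_domains(domain_lists, chrom="chr1", gene_len=1000, gap=500):
    """GeneRecords at regular spacing; element i of each list is a domain set."""
    out = []
    for i, doms in enumerate(domain_lists):
        start = i * (gene_len + gap)
        out.append(
            GeneRecord(f"g{i}", chrom, i, start, start + gene_len,
                       frozenset([doms] if isinstance(doms, str) else doms))
        )
    return out


def oracle_clusters(domain_lists, seed_run=3, extend=30):
    """Brute-force enumeration of (accession, member-set) clusters."""
    n = len(domain_lists)
    sets = [set([d] if isinstance(d, str) else d) for d in domain_lists]
    accs = sorted(set().union(*sets)) if sets else []
    result = {}
    for acc in accs:
        windows = []
        for i in range(n - seed_run + 1):
            if all(acc in sets[i + j] for j in range(seed_run)):
                # maximal run containing i
                lo = i
                while lo > 0 and acc in sets[lo - 1]:
                    lo -= 1
                hi = i + seed_run - 1
                while hi + 1 < n and acc in sets[hi + 1]:
                    hi += 1
                members = frozenset(
                    j
                    for j in range(max(0, lo - extend), min(n, hi + extend + 1))
                    if acc in sets[j]
                )
                windows.append(members)
        merged = []
        for m in sorted(windows, key=min):
            if merged and min(m) <= max(merged[-1]):
                merged[-1] = merged[-1] | m
            else:
                merged.append(set(m))
        if merged:
            result[acc] = [frozenset(m) for m in merged]
    return result


class TestFindDomainClusters:
    def test_worked_example(self):
        genes = genes_from_domains(["A", "A", "A", "B", "A", "B", "B", "B", "C", "A"])
        clusters = find_domain_clusters(genes)
        by_acc = {c.accession: sorted(c.ordinals) for c in clusters}
        assert by_acc == {"A": [0, 1, 2, 4, 9], "B": [3, 5, 6, 7]}

    def test_run_below_seed_length_no_cluster(self):
        genes = genes_from_domains(["A", "A"])
        assert find_domain_clusters(genes) == []

    def test_distant_runs_stay_separate(self):
        doms = ["A"] * 3 + ["X"] * 70 + ["A"] * 3
        clusters = find_domain_clusters(genes_from_domains(doms))
        a_clusters = [c for c in clusters if c.accession == "A"]
        assert len(a_clusters) == 2
        assert sorted(a_clusters[0].ordinals) == [0, 1, 2]
        assert sorted(a_clusters[1].ordinals) == [73, 74, 75]

    def test_overlapping_extensions_merge(self):
        doms = ["A"] * 3 + ["X"] * 20 + ["A"] + ["X"] * 20 + ["A"] * 3
        clusters = find_domain_clusters(genes_from_domains(doms))
        a_clusters = [c for c in clusters if c.accession == "A"]
        assert len(a_clusters) == 1
        assert sorted(a_clusters[0].ordinals) == [0, 1, 2, 23, 44, 45, 46]

    def test_multi_domain_genes_seed_on_common_accession(self):
        genes = genes_from_domains([{"A", "Z"}, {"A", "Y"}, {"A"}, {"Q"}, {"A", "W"}])
        (c,) = find_domain_clusters(genes)
        assert c.accession == "A" and sorted(c.ordinals) == [0, 1, 2, 4]

    def test_strict_single_domain_mode(self):
        genes = genes_from_domains([{"A", "Z"}, {"A"}, {"A"}, {"A"}, {"Q"}])
        strict = find_domain_clusters(genes, strict_single_domain=True)
        (c,) = strict
        # the seed run is ordinals 1-3; the multi-domain gene 0 still extends
        assert sorted(c.ordinals) == [0, 1, 2, 3]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        vocab = list("ABCDE")
        doms = [
            {vocab[j] for j in rng.choice(5, size=rng.integers(1, 3), replace=False)}
            for _ in range(n)
        ]
        got = {}
        for c in find_domain_clusters(genes_from_domains(doms)):
            got.setdefault(c.accession, []).append(frozenset(c.ordinals))
        exp = oracle_clusters(doms)
        assert {a: sorted(v, key=min) for a, v in got.items()} == {
            a: sorted(v, key=min) for a, v in exp.items()
        }

    def test_permutation_safety(self):
        doms = ["A", "A", "A", "B", "A", "B", "B", "B", "C", "A"]
        genes = genes_from_domains(doms)
        shuffled = list(genes)
        np.random.default_rng(0).shuffle(shuffled)
        a = find_domain_clusters(genes)
        b = find_domain_clusters(shuffled)
        assert [(c.cluster_id, c.member_ids) for c in a] == [
            (c.cluster_id, c.member_ids) for c in b
        ]

    def test_appending_unrelated_gene_preserves_memberships(self):
        doms = ["A", "A", "A", "B", "A"]
        before = find_domain_clusters(genes_from_domains(doms))
        after = find_domain_clusters(genes_from_domains(doms + ["Z"]))
        assert {c.member_ids for c in before} == {c.member_ids for c in after}

    def test_require_hits_mode_drops_unsupported_members(self):
        genes = genes_from_domains(["A", "A", "A", "X", "A"])
        hits = [
            SimilarityHit("g0", "g1", 1e-20, 80.0),
            SimilarityHit("g1", "g0", 1e-20, 80.0),
            SimilarityHit("g1", "g2", 1e-18, 75.0),
            SimilarityHit("g2", "g1", 1e-18, 75.0),
        ]
        (c,) = find_domain_clusters(genes, require_hits=hits)
        assert sorted(c.ordinals) == [0, 1, 2]  # g4 has no in-cluster hit


class TestFilterHits:
    GENES = genes_from_domains([{"PF00931"}, {"PF00931", "PF1"}, {"PF2"}])

    def test_passing_hit_kept(self):
        hits = [SimilarityHit("g0", "g1", 1e-6, 45.0)]
        kept = filter_similarity_hits(hits, self.GENES)
        assert {(h.query, h.subject) for h in kept} == {("g0", "g1"), ("g1", "g0")}

    @pytest.mark.parametrize(
        "evalue,identity,qs",
        [
            (1e-4, 45.0, ("g0", "g1")),   # e-value too large
            (1e-6, 30.0, ("g0", "g1")),   # identity boundary is strict
            (1e-5, 45.0, ("g0", "g1")),   # e-value boundary is strict
            (1e-6, 45.0, ("g0", "g2")),   # no shared domain
        ],
    )
    def test_failing_hits_dropped(self, evalue, identity, qs):
        assert filter_similarity_hits([SimilarityHit(*qs, evalue, identity)], self.GENES) == []

    def test_unknown_gene_error(self):
        with pytest.raises(KeyError):
            filter_similarity_hits([SimilarityHit("g0", "nope", 1e-9, 50.0)], self.GENES)

    def test_self_hit_rejected_at_construction(self):
        with pytest.raises(ValueError):
            SimilarityHit("g0", "g0", 1e-9, 99.0)


class TestClassifyRGenes:
    @pytest.mark.parametrize(
        "domains,expected",
        [
            ({"NB-ARC", "LRR"}, True),
            ({"TIR"}, True),
            ({"C-JID", "WAK"}, True),
            ({"LRR"}, False),
            ({"LRR", "Pkinase"}, True),  # receptor-kinase architecture
            ({"Pkinase"}, False),
            (set(), False),
        ],
    )
    def test_default_rule(self, domains, expected):
        genes = [GeneRecord("g", "chr1", 0, 0, 100, frozenset(domains))]
        flags, count = classify_r_genes(genes)
        assert flags["g"] is expected and count == int(expected)

    def test_custom_rule(self):
        genes = [GeneRecord("g", "chr1", 0, 0, 100, frozenset({"FOO"}))]
        flags, _ = classify_r_genes(genes, rule={"direct": {"FOO"}, "copresent": []})
        assert flags["g"]


class TestRegionReport:
    def test_counts_and_straddling(self):
        genes = genes_from_domains(["A"] * 5, gene_len=1000, gap=0)  # genes at 0..5000
        (c,) = find_domain_clusters(genes)
        count, tally = cluster_region_report([c], "chr1", 0, 5000)
        assert count == 5 and tally == {"A": 5}
        count, _ = cluster_region_report([c], "chr1", 0, 2500)  # straddles gene 2
        assert count == 3  # overlap rule: the straddled gene counts
        count, _ = cluster_region_report([c], "chr1", 9000, 9500)
        assert count == 0


class TestBuildGeneRecords:
    def test_ordinals_follow_start_coordinates(self):
        feats = [
            Feature("chr1", 5000, 6000, kind="gene", id="b"),
            Feature("chr1", 1000, 2000, kind="gene", id="a"),
            Feature("chr2", 100, 200, kind="gene", id="c"),
        ]
        recs = build_gene_records(feats, {"a": {"X"}})
        assert [(r.gene_id, r.chrom_id, r.ordinal) for r in recs] == [
            ("a", "chr1", 0), ("b", "chr1", 1), ("c", "chr2", 0),
        ]
        assert recs[0].domains == {"X"} and recs[1].domains == frozenset()


class TestScoreProteinPairs:
    def test_identical_and_unrelated_pairs(self):
        prots = {
            "p1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3,
            "p2": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3,
            "p3": "GWNDEWHHLPCCVYMRTFFA" * 5,
        }
        hits = {(h.query, h.subject): h for h in score_protein_pairs(prots)}
        ident = hits[("p1", "p2")]
        assert ident.identity == 100.0 and ident.evalue < 1e-5
        if ("p1", "p3") in hits:
            assert hits[("p1", "p3")].evalue > ident.evalue
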