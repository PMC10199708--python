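"""Domain-run gene-cluster detection and R-gene domain-architecture classification.

The cluster algorithm works on genes ordered along each chromosome
(ordinals by start coordinate), each carrying a set of protein-domain
accessions.  A run of >= ``seed_run`` consecutive genes all carrying the
same accession seeds a cluster; the cluster then collects every gene
carrying that accession within ``extend`` ordinals up- and downstream of
the seed run.  Distances are gene ordinals, not bp.  Clusters of the
same accession whose collected ranges overlap are merged.

Pairwise protein-similarity hits (BLAST outfmt-6-like) are filtered by
e-value < 1e-5, identity > 30% and a shared-domain requirement; under
the default pipeline they describe the duplication landscape but do not
constrain membership, while an optional mode additionally requires each
member to have a kept hit to another member.

R genes (plant disease-resistance genes) are flagged from domain
architecture: NB-ARC / TIR / C-JID directly, or a leucine-rich-repeat
accession co-occurring with a protein-kinase accession.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .io import Feature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """An ordered gene with its domain accessions.

    ``ordinal`` is the 0-based position index along the chromosome
    (consecutive per chromosome, by start coordinate).
    """

    gene_id: str
    chrom_id: str
    ordinal: int
    start: int
    end: int
    domains: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    evalue: float
    identity: float  # percent

    def __post_init__(self) -> None:
        if self.query == self.subject:
            raise ValueError(f"self-hit for {self.query}")
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass
class GeneCluster:
    cluster_id: str
    accession: str
    chrom_id: str
    members: list[GeneRecord]

    @property
    def ordinals(self) -> list[int]:
        return [g.ordinal for g in self.members]

    @property
    def span(self) -> tuple[int, int]:
        return (min(g.start for g in self.members), max(g.end for g in self.members))

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(g.gene_id for g in self.members)


def build_gene_records(
    gene_features: list[Feature],
    domains: dict[str, set[str]],
) -> list[GeneRecord]:
    """Order gene features per chromosome and attach domain sets.

    ``domains`` maps gene_id -> accession set (genes absent from the map
    get an empty set).  Returns records sorted by (chrom, ordinal).
    """
    out: list[GeneRecord] = []
    by_chrom: dict[str, list[Feature]] = {}
    for f in gene_features:
        if f.kind == "gene":
            by_chrom.setdefault(f.chrom_id, []).append(f)
    for chrom in sorted(by_chrom):
        feats = sorted(by_chrom[chrom], key=lambda f: (f.start, f.end, f.id))
        for i, f in enumerate(feats):
            out.append(
                GeneRecord(
                    gene_id=f.id or f"{chrom}:{f.start}",
                    chrom_id=chrom,
                    ordinal=i,
                    start=f.start,
                    end=f.end,
                    domains=frozenset(domains.get(f.id, set())),
                )
            )
    return out


# ---------------------------------------------------------------------------
# similarity-hit filtering
# ---------------------------------------------------------------------------

def filter_similarity_hits(
    hits: list[SimilarityHit],
    genes: list[GeneRecord],
    max_evalue: float = 1e-5,
    min_identity: float = 30.0,
) -> list[SimilarityHit]:
    """Keep hits with e-value < threshold, identity strictly > threshold,
    and at least one shared domain accession between query and subject.

    The boundary is strict on both rules (e-value == 1e-5 or identity ==
    30.0 are dropped).  The symmetric closure is applied: if A->B is
    kept, B->A is present in the output.  Hits naming unknown genes
    raise ``KeyError``.
    """
    dom = {g.gene_id: g.domains for g in genes}
    kept_pairs: set[tuple[str, str]] = set()
    kept: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.query not in dom:
            raise KeyError(f"hit references unknown gene {h.query!r}")
        if h.subject not in dom:
            raise KeyError(f"hit references unknown gene {h.subject!r}")
        if not (h.evalue < max_evalue and h.identity > min_identity):
            continue
        if not (dom[h.query] & dom[h.subject]):
            continue
        kept[(h.query, h.subject)] = h
        kept_pairs.add((h.query, h.subject))
    # symmetric closure
    for q, s in list(kept_pairs):
        if (s, q) not in kept:
            h = kept[(q, s)]
            kept[(s, q)] = SimilarityHit(s, q, h.evalue, h.identity)
    return sorted(kept.values(), key=lambda h: (h.query, h.subject))


# ---------------------------------------------------------------------------
# cluster detection
# ---------------------------------------------------------------------------

def _seed_runs(flags: list[bool], seed_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= seed_run, as inclusive (start, end)."""
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            if j - i + 1 >= seed_run:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def find_domain_clusters(
    genes: list[GeneRecord],
    seed_run: int = 3,
    extend: int = 30,
    require_hits: list[SimilarityHit] | None = None,
    strict_single_domain: bool = False,
) -> list[GeneCluster]:
    """Detect gene clusters seeded by runs of a shared domain accession.

    For each accession, every maximal run of >= ``seed_run`` consecutive
    genes carrying it seeds a cluster collecting all carriers within
    ``extend`` ordinals of the run; same-accession clusters with
    overlapping collected ordinal ranges are merged.  With
    ``strict_single_domain`` a gene counts toward a seed run only when
    the accession is its sole domain (extension is unchanged).  With
    ``require_hits``, members lacking a kept similarity hit to another
    member are dropped (clusters falling below ``seed_run`` members are
    discarded).  Cluster IDs are deterministic:
    ``<chrom>:<accession>:<leftmost ordinal>``.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom_id, []).append(g)
    hit_partners: dict[str, set[str]] = {}
    if require_hits is not None:
        for h in require_hits:
            hit_partners.setdefault(h.query, set()).add(h.subject)

    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: g.ordinal)
        if [g.ordinal for g in ordered] != list(range(len(ordered))):
            raise ValueError(f"{chrom}: gene ordinals are not consecutive from 0")
        accessions = sorted({a for g in ordered for a in g.domains})
        for acc in accessions:
            carries = [acc in g.domains for g in ordered]
            if strict_single_domain:
                seed_flags = [acc in g.domains and len(g.domains) == 1 for g in ordered]
            else:
                seed_flags = carries
            runs = _seed_runs(seed_flags, seed_run)
            if not runs:
                continue
            # collect members per run, then merge overlapping collected ranges
            collected: list[list[int]] = []
            for r0, r1 in runs:
                lo, hi = max(0, r0 - extend), min(len(ordered) - 1, r1 + extend)
                members = [i for i in range(lo, hi + 1) if carries[i]]
                collected.append(members)
            merged: list[list[int]] = []
            for members in collected:
                if merged and members[0] <= merged[-1][-1]:
                    merged[-1] = sorted(set(merged[-1]) | set(members))
                else:
                    merged.append(members)
            for members in merged:
                recs = [ordered[i] for i in members]
                if require_hits is not None:
                    ids = {g.gene_id for g in recs}
                    recs = [
                        g
                        for g in recs
                        if hit_partners.get(g.gene_id, set()) & (ids - {g.gene_id})
                    ]
                    if len(recs) < seed_run:
                        continue
                clusters.append(
                    GeneCluster(
                        cluster_id=f"{chrom}:{acc}:{recs[0].ordinal}",
                        accession=acc,
                        chrom_id=chrom,
                        members=recs,
                    )
                )
    clusters.sort(key=lambda c: (c.chrom_id, c.members[0].ordinal, c.accession))
    return clusters


# ---------------------------------------------------------------------------
# R-gene classification
# ---------------------------------------------------------------------------

#: Default domain-architecture rule for plant disease-resistance genes.
DEFAULT_RGENE_RULE = {
    "direct": {"NB-ARC", "TIR", "C-JID"},
    "copresent": [({"LRR", "Leucine rich repeat"}, {"Pkinase", "Protein kinase"})],
}


def classify_r_genes(
    genes: list[GeneRecord],
    rule: dict | None = None,
) -> tuple[dict[str, bool], int]:
    """Flag genes whose domain architecture matches the R-gene rule.

    Default rule: any of NB-ARC / TIR / C-JID present, or a
    leucine-rich-repeat accession co-occurring with a protein-kinase
    accession.  The rule is data-driven: ``{"direct": set, "copresent":
    [(set_a, set_b), ...]}``.  Returns per-gene flags and the count.
    """
    rule = rule if rule is not None else DEFAULT_RGENE_RULE
    direct = set(rule.get("direct", set()))
    copresent = [(set(a), set(b)) for a, b in rule.get("copresent", [])]
    flags: dict[str, bool] = {}
    for g in genes:
        hit = bool(g.domains & direct)
        if not hit:
            hit = any(g.domains & a and g.domains & b for a, b in copresent)
        flags[g.gene_id] = hit
    return flags, sum(flags.values())


def cluster_region_report(
    clusters: list[GeneCluster],
    chrom_id: str,
    start: int,
    end: int,
) -> tuple[int, dict[str, int]]:
    """Count clustered genes inside a genomic interval, tallied by accession.

    A member gene counts iff its interval overlaps [start, end) by >= 1 bp
    (genes counted once per accession they cluster under).
    """
    count = 0
    tally: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    for c in clusters:
        if c.chrom_id != chrom_id:
            continue
        for g in c.members:
            if g.start < end and g.end > start and (c.accession, g.gene_id) not in seen:
                seen.add((c.accession, g.gene_id))
                count += 1
                tally[c.accession] = tally.get(c.accession, 0) + 1
    return count, tally


# ---------------------------------------------------------------------------
# toy protein similarity scoring (for synthetic hit tables)
# ---------------------------------------------------------------------------

def score_protein_pairs(
    proteins: dict[str, str],
    pairs: list[tuple[str, str]] | None = None,
    search_space: float | None = None,
) -> list[SimilarityHit]:
    """Score protein pairs with a local BLOSUM62 alignment into hit records.

    Intended for synthetic tests only (toy proteins <= ~500 aa) so that no
    external aligner is needed.  Identity is percent matching columns of
    the best local alignment; the e-value is a Karlin-Altschul estimate
    (gapped BLOSUM62 constants K=0.041, lambda=0.267) over
    ``search_space`` (defaults to total residue count squared).
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    if pairs is None:
        ids = sorted(proteins)
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    total = sum(len(s) for s in proteins.values())
    space = search_space if search_space is not None else float(total) ** 2
    K, lam = 0.041, 0.267
    hits: list[SimilarityHit] = []
    for q, s in pairs:
        alns = aligner.align(proteins[q], proteins[s])
        if len(alns) == 0 or alns.score <= 0:
            continue
        aln = alns[0]
        a, b = aln[0], aln[1]
        ncol = len(a)
        nid = sum(1 for x, y in zip(a, b) if x == y and x != "-")
        identity = 100.0 * nid / ncol if ncol else 0.0
        evalue = K * space * math.exp(-lam * aln.score)
        hits.append(SimilarityHit(q, s, evalue, round(identity, 2)))
        hits.append(SimilarityHit(s, q, evalue, round(identity, 2)))
    return hits


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_domains_tsv(path) -> dict[str, set[str]]:
    """Read a gene->domains table (gene_id, position index, comma-separated accessions)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        accs = {a for a in str(row["domains"]).split(",") if a}
        out[row["gene_id"]] = accs
    return out


def write_domains_tsv(genes: list[GeneRecord], path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "ordinal": g.ordinal, "domains": ",".join(sorted(g.domains))}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[SimilarityHit]:
    """Read an outfmt-6-like hit table (query, subject, pident, evalue)."""
    df = pd.read_csv(path, sep="\t")
    return [
        SimilarityHit(str(r["query"]), str(r["subject"]), float(r["evalue"]), float(r["pident"]))
        for _, r in df.iterrows()
    ]


def write_hits_tsv(hits: list[SimilarityHit], path) -> None:
    pd.DataFrame(
        [
            {"query": h.query, "subject": h.subject, "pident": h.identity, "evalue": h.evalue}
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def clusters_to_dataframe(clusters: list[GeneCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "accession": c.accession,
                "chrom": c.chrom_id,
                "n_genes": len(c.members),
                "start": c.span[0],
                "end": c.span[1],
                "members": ",".join(g.gene_id for g in c.members),
            }
            for c in clusters
        ],
        columns=["cluster_id", "accession", "chrom", "n_genes", "start", "end", "members"],
    )
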