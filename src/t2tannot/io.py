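"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is **0-based, half-open** ``[start, end)``.
GFF3 (1-based inclusive) and VCF (1-based positions) are converted at the
boundary, in both directions, so that round trips preserve the on-disk
coordinates exactly.  BED is already 0-based half-open and passes through
unchanged.

Sequence alphabet is ``{A, C, G, T, N}``.  Lowercase is uppercased, ``U``
is mapped to ``T``, and any other letter becomes ``N`` with a logged
warning.  ``N`` never matches anything in downstream repeat scans.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_CLEAN_RE = re.compile(r"[^ACGTN]")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome-level sequence."""

    chrom_id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.chrom_id:
            raise ValueError("chrom_id must be non-empty")


@dataclass(frozen=True)
class Feature:
    """A genomic feature on 0-based half-open coordinates.

    ``kind`` is one of ``gene``, ``TE``, ``rDNA`` or ``custom``; ``subtype``
    carries the TE superfamily (Gypsy, Copia, MULE-MuDR, Helitron, ...)
    where applicable.
    """

    chrom_id: str
    start: int
    end: int
    kind: str = "custom"
    subtype: str = ""
    id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid feature interval [{self.start}, {self.end}) on {self.chrom_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantSite:
    """One VCF record; ``pos`` is 0-based internally.

    ``alleles`` holds one ``(a, b)`` pair of allele indices per sample
    (0 = REF, 1.. = ALT index + 1, -1 = missing); ``gq`` one genotype
    quality per sample.
    """

    chrom_id: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    alleles: tuple[tuple[int, int], ...]
    gq: tuple[int, ...]

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    def is_het(self, sample: int) -> bool:
        a, b = self.alleles[sample]
        return a >= 0 and b >= 0 and a != b

    def is_missing(self, sample: int) -> bool:
        a, b = self.alleles[sample]
        return a < 0 or b < 0


class VariantTable:
    """Columnar container for a multi-sample variant set.

    Stores per-site arrays (chrom, 0-based pos, alleles, GQ) so the
    filtering and windowing stages can run vectorised over hundreds of
    thousands of sites; iteration yields :class:`VariantSite` views.
    """

    def __init__(
        self,
        chrom: Sequence[str],
        pos: np.ndarray,
        ref: Sequence[str],
        alts: Sequence[tuple[str, ...]],
        alleles: np.ndarray,
        gq: np.ndarray,
        samples: Sequence[str],
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = list(ref)
        self.alts = list(alts)
        self.alleles = np.asarray(alleles, dtype=np.int8)  # (n, S, 2)
        self.gq = np.asarray(gq, dtype=np.int32)           # (n, S)
        self.samples = list(samples)
        n = len(self.pos)
        if not (
            len(self.chrom) == len(self.ref) == len(self.alts) == n
            and self.alleles.shape == (n, len(self.samples), 2)
            and self.gq.shape == (n, len(self.samples))
        ):
            raise ValueError("inconsistent VariantTable array shapes")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_alleles(self) -> np.ndarray:
        return np.array([1 + len(a) for a in self.alts], dtype=np.int64)

    @property
    def het_matrix(self) -> np.ndarray:
        """(n, S) boolean: sample genotype is heterozygous (and called)."""
        a, b = self.alleles[..., 0], self.alleles[..., 1]
        return (a >= 0) & (b >= 0) & (a != b)

    @property
    def missing_matrix(self) -> np.ndarray:
        return (self.alleles < 0).any(axis=2)

    def __getitem__(self, i: int) -> VariantSite:
        return VariantSite(
            chrom_id=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref=self.ref[i],
            alts=tuple(self.alts[i]),
            alleles=tuple((int(a), int(b)) for a, b in self.alleles[i]),
            gq=tuple(int(q) for q in self.gq[i]),
        )

    def __iter__(self) -> Iterator[VariantSite]:
        for i in range(len(self)):
            yield self[i]

    def subset(self, mask: np.ndarray) -> "VariantTable":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return VariantTable(
            self.chrom[idx],
            self.pos[idx],
            [self.ref[i] for i in idx],
            [self.alts[i] for i in idx],
            self.alleles[idx],
            self.gq[idx],
            self.samples,
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _normalize_seq(raw: str, record_id: str) -> str:
    s = raw.upper().replace("U", "T")
    if _CLEAN_RE.search(s):
        bad = sorted(set(_CLEAN_RE.findall(s)))
        logger.warning(
            "record %s: mapping unknown letters %s to N", record_id, "".join(bad)
        )
        s = _CLEAN_RE.sub("N", s)
    return s


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records.

    Sequences are uppercased, U→T, unknown letters→N (logged).  An empty
    file or duplicate record IDs raise ``ValueError`` naming the record.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record ID: {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, _normalize_seq(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.chrom_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

#: GFF3 column-3 types mapped to internal feature kinds.
GFF3_KIND_MAP = {
    "gene": "gene",
    "transposable_element": "TE",
    "repeat_region": "TE",
    "dispersed_repeat": "TE",
    "rRNA_gene": "rDNA",
    "rRNA": "rDNA",
}


def _te_subtype(attributes: dict) -> str:
    """Extract a TE superfamily from a ``Classification=LTR/Gypsy``-style attribute."""
    for key in ("Classification", "classification", "te_class"):
        if key in attributes:
            value = attributes[key][0] if isinstance(attributes[key], list) else attributes[key]
            return value.split("/")[-1]
    return ""


def read_gff3(path: str | Path) -> list[Feature]:
    """Read GFF3 features, converting 1-based inclusive to 0-based half-open.

    Kind mapping: column 3 per :data:`GFF3_KIND_MAP` (anything else is
    ``custom``); TE subtype from a ``Classification=LTR/Gypsy``-style
    attribute (the part after the slash).
    """
    import gffutils

    feats: list[Feature] = []
    for lineno, f in enumerate(gffutils.DataIterator(str(path)), start=1):
        if f.end < f.start:
            raise ValueError(f"{path}: feature end < start at record {lineno}")
        attrs = dict(f.attributes)
        kind = GFF3_KIND_MAP.get(f.featuretype, "custom")
        subtype = _te_subtype(attrs) if kind == "TE" else ""
        fid = attrs.get("ID", [""])[0] if "ID" in attrs else ""
        feats.append(
            Feature(
                chrom_id=f.seqid,
                start=f.start - 1,
                end=f.end,
                kind=kind,
                subtype=subtype,
                id=fid,
                strand=f.strand if f.strand in "+-" else ".",
            )
        )
    return feats


_KIND_TO_GFF3 = {"gene": "gene", "TE": "transposable_element", "rDNA": "rRNA_gene"}


def write_gff3(features: Iterable[Feature], path: str | Path) -> None:
    """Write features back to GFF3 (1-based inclusive), preserving coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = _KIND_TO_GFF3.get(f.kind, f.kind)
            attrs = []
            if f.id:
                attrs.append(f"ID={f.id}")
            if f.subtype:
                attrs.append(f"Classification={'LTR/' if f.subtype in ('Gypsy', 'Copia') else ''}{f.subtype}")
            fh.write(
                "\t".join(
                    [
                        f.chrom_id,
                        "t2tannot",
                        ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[VariantTable, list[str]]:
    """Read a VCF 4.x into a :class:`VariantTable` (positions 0-based).

    Multi-allelic records are preserved; missing genotypes get allele index
    -1.  A file without the GT FORMAT field raises ``ValueError``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if "GT" not in {f for f in _format_ids(vcf)}:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    chrom, pos, ref, alts, alleles, gq = [], [], [], [], [], []
    for rec in vcf:
        chrom.append(rec.CHROM)
        pos.append(rec.POS - 1)
        ref.append(rec.REF)
        alts.append(tuple(rec.ALT))
        pair = [(g[0], g[1]) for g in rec.genotypes]
        alleles.append(pair)
        q = rec.format("GQ")
        if q is None:
            gq.append([0] * len(samples))
        else:
            gq.append([int(v) if v >= 0 else 0 for v in q.ravel()[: len(samples)]])
    n = len(pos)
    return (
        VariantTable(
            chrom,
            np.array(pos, dtype=np.int64),
            ref,
            alts,
            np.array(alleles, dtype=np.int8).reshape(n, len(samples), 2),
            np.array(gq, dtype=np.int32).reshape(n, len(samples)),
            samples,
        ),
        samples,
    )


def _format_ids(vcf) -> Iterator[str]:
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                yield h["ID"]
        except KeyError:
            continue


def write_vcf(
    table: VariantTable,
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write a :class:`VariantTable` as uncompressed VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=t2tannot\n")
        for cid, clen in (contigs or {}).items():
            fh.write(f"##contig=<ID={cid},length={clen}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(len(table)):
            alt = ",".join(table.alts[i]) or "."
            cols = [
                str(table.chrom[i]),
                str(int(table.pos[i]) + 1),
                ".",
                table.ref[i],
                alt,
                ".",
                "PASS",
                ".",
                "GT:GQ",
            ]
            for s in range(table.n_samples):
                a, b = table.alleles[i, s]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                cols.append(f"{gt}:{table.gq[i, s]}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    chrom_id: str
    start: int
    end: int
    name: str = ""
    score: float | None = None


def _as_bed(rec) -> BedRecord:
    if isinstance(rec, BedRecord):
        return rec
    if isinstance(rec, Feature):
        return BedRecord(rec.chrom_id, rec.start, rec.end, rec.id)
    chrom, start, end, *rest = rec
    name = rest[0] if rest else ""
    score = rest[1] if len(rest) > 1 else None
    return BedRecord(chrom, int(start), int(end), str(name), score)


def write_bed(records: Iterable, path: str | Path) -> None:
    """Write intervals as BED (0-based half-open), sorted by (chrom, start).

    Accepts :class:`BedRecord`, :class:`Feature` or plain
    ``(chrom, start, end[, name[, score]])`` tuples.  Negative coordinates
    raise ``ValueError``.  An empty input yields an empty file.
    """
    recs = sorted((_as_bed(r) for r in records), key=lambda r: (r.chrom_id, r.start, r.end))
    with open(path, "w") as fh:
        for r in recs:
            if r.start < 0 or r.end < 0:
                raise ValueError(f"negative BED coordinate: {r}")
            cols = [r.chrom_id, str(r.start), str(r.end)]
            if r.name or r.score is not None:
                cols.append(r.name or ".")
            if r.score is not None:
                cols.append(f"{r.score:g}")
            fh.write("\t".join(cols) + "\n")


def read_bed(path: str | Path) -> list[BedRecord]:
    out: list[BedRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            score = float(parts[4]) if len(parts) > 4 else None
            out.append(BedRecord(parts[0], int(parts[1]), int(parts[2]), name, score))
    return out
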