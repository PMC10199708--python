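"""Centromere localization from satellite-array density and gene/TE depletion.

A centromere is called, at most once per chromosome, as the maximal run
of windows carrying arrays of the chromosome's centromeric monomer
family, bridged across gaps up to ``max_gap`` bp, subject to the
depletion criterion that mean gene+TE density inside the candidate is
lower than outside.  Call boundaries snap to the outermost contributing
arrays.  Genes whose intervals overlap a call by at least 1 bp are
reported as "captured" genes.

The depletion test is an explicit, quantitative formalization of what
is otherwise done by eye in a genome browser: candidates are ranked by
total satellite bp and the best one passing the inside<outside test
wins; the rest are kept as diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Feature
from .repeats import MonomerFamily, TandemArray

logger = logging.getLogger(__name__)


@dataclass
class DensityProfile:
    """Per-window covered bp for one track on one chromosome."""

    chrom_id: str
    window: int
    chrom_length: int
    covered_bp: np.ndarray  # float64, length ceil(chrom_length / window)

    @property
    def n_windows(self) -> int:
        return len(self.covered_bp)


@dataclass
class CentromereCall:
    chrom_id: str
    start: int
    end: int
    family_base: int
    array_bp: int
    n_arrays: int
    gene_te_density_inside: float
    gene_te_density_outside: float

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class CandidateRegion:
    """A satellite-dense candidate region (diagnostics for multi-region chromosomes)."""

    chrom_id: str
    start: int
    end: int
    array_bp: int
    n_arrays: int
    passed_depletion: bool | None = None


def density_profile(
    intervals,
    chrom_length: int,
    window: int = 100_000,
    chrom_id: str = "",
) -> DensityProfile:
    """Per-window bp covered by a set of intervals (features or arrays).

    Windows tile from 0; an interval spanning a boundary contributes to
    both windows, conserving total covered bp.  Accepts objects with
    ``start``/``end`` attributes or plain (start, end) pairs.  An
    interval extending beyond the chromosome end raises ``ValueError``.
    """
    n_win = int(np.ceil(chrom_length / window)) if chrom_length else 0
    cov = np.zeros(max(n_win, 1), dtype=np.float64)
    for iv in intervals:
        s, e = (iv.start, iv.end) if hasattr(iv, "start") else (iv[0], iv[1])
        if s < 0 or e > chrom_length:
            raise ValueError(
                f"interval [{s}, {e}) outside chromosome {chrom_id or '?'} of length {chrom_length}"
            )
        w0, w1 = s // window, (e - 1) // window
        if w0 == w1:
            cov[w0] += e - s
        else:
            cov[w0] += (w0 + 1) * window - s
            for w in range(w0 + 1, w1):
                cov[w] += window
            cov[w1] += e - w1 * window
    return DensityProfile(chrom_id, window, chrom_length, cov[:n_win] if n_win else cov[:0])


def select_centromeric_family(
    families: list[MonomerFamily],
    chrom_ids: list[str],
    override_factor: float = 2.0,
) -> dict[str, MonomerFamily | None]:
    """Pick the centromeric monomer family per chromosome.

    Default is the genome-wide most-abundant family (by total bp); a
    chromosome-specific family overrides it when its bp on that
    chromosome exceeds the default family's bp there by
    ``override_factor`` (the chr3/chr18-style pattern where an
    alternative monomer, e.g. 135 bp or 66 bp, locally dominates the
    genome-wide 107-bp family).
    """
    if not families:
        return {c: None for c in chrom_ids}
    default = max(families, key=lambda f: (f.total_bp, -f.base_period))

    def chrom_bp(fam: MonomerFamily, chrom: str) -> int:
        return sum(a.span for a in fam.arrays if a.chrom_id == chrom)

    selection: dict[str, MonomerFamily | None] = {}
    for chrom in chrom_ids:
        local = [(chrom_bp(f, chrom), f) for f in families]
        local = [(bp, f) for bp, f in local if bp > 0]
        if not local:
            logger.warning("%s: no monomer families present; no centromeric family selected", chrom)
            selection[chrom] = None
            continue
        best_bp, best = max(local, key=lambda t: (t[0], -t[1].base_period))
        default_bp = chrom_bp(default, chrom)
        if best is not default and best_bp > override_factor * default_bp:
            selection[chrom] = best
        elif default_bp > 0:
            selection[chrom] = default
        else:
            selection[chrom] = best
    return selection


def _candidate_regions(
    arrays: list[TandemArray],
    max_gap: int,
) -> list[list[TandemArray]]:
    """Group sorted arrays into runs separated by gaps <= max_gap."""
    groups: list[list[TandemArray]] = []
    for a in sorted(arrays, key=lambda x: x.start):
        if groups and a.start - groups[-1][-1].end <= max_gap:
            groups[-1].append(a)
        else:
            groups.append([a])
    return groups


def call_centromere(
    chrom_id: str,
    chrom_length: int,
    target_arrays: list[TandemArray],
    gene_features: list[Feature],
    te_features: list[Feature],
    family_base: int,
    min_array_bp: int = 50_000,
    max_gap: int = 500_000,
) -> tuple[CentromereCall | None, list[CandidateRegion]]:
    """Call at most one centromere on a chromosome.

    Candidates are maximal runs of target-family arrays bridged across
    gaps <= ``max_gap``; the call is the candidate maximizing total array
    bp among those with >= ``min_array_bp`` whose mean gene+TE density
    inside is below the mean outside.  Boundaries snap to the outermost
    contributing arrays.
    """
    diagnostics: list[CandidateRegion] = []
    if not target_arrays:
        return None, diagnostics
    groups = _candidate_regions(target_arrays, max_gap)
    cands = []
    for g in groups:
        start, end = g[0].start, g[-1].end
        bp = sum(a.span for a in g)
        cands.append((bp, start, end, g))
        diagnostics.append(CandidateRegion(chrom_id, start, end, bp, len(g)))
    cands.sort(key=lambda t: (-t[0], t[1]))

    depletion_ivs = [(f.start, f.end) for f in gene_features] + [
        (f.start, f.end) for f in te_features
    ]

    def densities(start: int, end: int) -> tuple[float, float]:
        inside = sum(max(0, min(e, end) - max(s, start)) for s, e in depletion_ivs)
        total = sum(e - s for s, e in depletion_ivs)
        out_len = chrom_length - (end - start)
        d_in = inside / (end - start) if end > start else 0.0
        d_out = (total - inside) / out_len if out_len > 0 else 0.0
        return d_in, d_out

    for bp, start, end, g in cands:
        if bp < min_array_bp:
            continue
        d_in, d_out = densities(start, end)
        passed = d_in < d_out
        for diag in diagnostics:
            if diag.start == start and diag.end == end:
                diag.passed_depletion = passed
        if not passed:
            logger.info(
                "%s: candidate %d-%d rejected by depletion test (inside %.4f >= outside %.4f)",
                chrom_id, start, end, d_in, d_out,
            )
            continue
        return (
            CentromereCall(
                chrom_id=chrom_id,
                start=start,
                end=end,
                family_base=family_base,
                array_bp=bp,
                n_arrays=len(g),
                gene_te_density_inside=round(d_in, 6),
                gene_te_density_outside=round(d_out, 6),
            ),
            diagnostics,
        )
    logger.warning("%s: no centromere candidate passed (min_array_bp=%d)", chrom_id, min_array_bp)
    return None, diagnostics


def call_centromeres(
    chrom_lengths: dict[str, int],
    arrays: list[TandemArray],
    families: list[MonomerFamily],
    features: list[Feature],
    min_array_bp: int = 50_000,
    max_gap: int = 500_000,
    override_factor: float = 2.0,
) -> tuple[list[CentromereCall], list[CandidateRegion]]:
    """Genome-wide centromere calling: family selection then per-chromosome call."""
    selection = select_centromeric_family(families, list(chrom_lengths), override_factor)
    genes = [f for f in features if f.kind == "gene"]
    tes = [f for f in features if f.kind == "TE"]
    calls: list[CentromereCall] = []
    all_diag: list[CandidateRegion] = []
    for chrom, length in chrom_lengths.items():
        fam = selection[chrom]
        if fam is None:
            continue
        target = [a for a in fam.arrays if a.chrom_id == chrom]
        call, diag = call_centromere(
            chrom,
            length,
            target,
            [g for g in genes if g.chrom_id == chrom],
            [t for t in tes if t.chrom_id == chrom],
            family_base=fam.base_period,
            min_array_bp=min_array_bp,
            max_gap=max_gap,
        )
        all_diag.extend(diag)
        if call is not None:
            calls.append(call)
    return calls, all_diag


def captured_genes(
    calls: list[CentromereCall],
    genes: list[Feature],
) -> tuple[dict[str, list[Feature]], int]:
    """Genes overlapping each centromere call by >= 1 bp, sorted by position.

    Returns a mapping chrom_id -> gene list plus the total count.
    """
    out: dict[str, list[Feature]] = {}
    total = 0
    for call in calls:
        hits = sorted(
            (
                g
                for g in genes
                if g.kind == "gene"
                and g.chrom_id == call.chrom_id
                and g.start < call.end
                and g.end > call.start
            ),
            key=lambda g: g.start,
        )
        out[call.chrom_id] = hits
        total += len(hits)
    return out, total


def centromeres_to_dataframe(calls: list[CentromereCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom_id,
                "start": c.start,
                "end": c.end,
                "family_base": c.family_base,
                "array_bp": c.array_bp,
                "n_arrays": c.n_arrays,
                "gene_te_density_inside": c.gene_te_density_inside,
                "gene_te_density_outside": c.gene_te_density_outside,
            }
            for c in calls
        ],
        columns=[
            "chrom", "start", "end", "family_base", "array_bp",
            "n_arrays", "gene_te_density_inside", "gene_te_density_outside",
        ],
    )
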