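"""Multi-sample heterozygosity filtering, sharing partition, windowed
profiles and hotspot-fragment calling.

The variant filter mirrors strict joint-genotyping practice for clone
panels: biallelic sites only, no missing genotypes, all genotype
qualities >= 30, minor allele frequency >= 0.01 (which also removes
invariant sites).  Filtered heterozygous sites are partitioned into
those heterozygous in every sample versus in only a subset, counted in
non-overlapping 100-kb windows, and the top-5% windows are merged into
continuous hotspot fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import VariantTable

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Variant-filter thresholds (defaults follow strict clone-panel practice)."""

    biallelic_only: bool = True
    min_gq: int = 30
    max_missing_fraction: float = 0.0
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing_fraction <= 1 and 0 <= self.min_maf <= 0.5):
            raise ValueError("filter thresholds out of range")


@dataclass
class SharingSummary:
    shared_all: int
    partial: int

    @property
    def total(self) -> int:
        return self.shared_all + self.partial

    @property
    def percent_shared(self) -> float:
        """Percentage of sites heterozygous in all samples, 1 decimal."""
        if self.total == 0:
            return 0.0
        return round(self.shared_all / self.total * 100, 1)


@dataclass
class WindowProfile:
    """Per-chromosome pooled heterozygous-site counts in tiling windows."""

    window: int
    chrom_lengths: dict[str, int]
    counts: dict[str, np.ndarray]                 # chrom -> int64 vector
    per_sample: dict[str, np.ndarray] | None = None  # chrom -> (n_win, S)

    @property
    def total_windows(self) -> int:
        return sum(len(v) for v in self.counts.values())

    def all_counts(self) -> np.ndarray:
        if not self.counts:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate([self.counts[c] for c in sorted(self.counts)])


@dataclass
class HotspotFragment:
    chrom_id: str
    start: int
    end: int
    n_windows: int          # qualifying windows in the fragment
    mean_count: float       # mean count over the fragment's window range

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_variants(
    table: VariantTable,
    config: FilterConfig | None = None,
) -> tuple[VariantTable, dict[str, int]]:
    """Apply the strict site filter; report a per-rule removal tally.

    Rules are applied in order (alleles, missing, GQ, MAF) with
    first-failing-rule attribution.  MAF is the minor allele frequency
    over all samples' called genotypes.
    """
    cfg = config or FilterConfig()
    n = len(table)
    fail = np.zeros(n, dtype=np.int8)  # 0 pass, 1 alleles, 2 missing, 3 gq, 4 maf

    if cfg.biallelic_only:
        fail[(table.n_alleles != 2) & (fail == 0)] = 1

    missing_frac = table.missing_matrix.mean(axis=1)
    fail[(missing_frac > cfg.max_missing_fraction) & (fail == 0)] = 2

    gq_ok = (table.gq >= cfg.min_gq) | table.missing_matrix  # GQ judged on called genotypes
    fail[(~gq_ok.all(axis=1)) & (fail == 0)] = 3

    alleles = table.alleles
    called = alleles >= 0
    n_called = called.sum(axis=(1, 2))
    alt_count = ((alleles > 0) & called).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, alt_count / np.maximum(n_called, 1), 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    fail[(maf < cfg.min_maf) & (fail == 0)] = 4

    tally = {
        "alleles": int((fail == 1).sum()),
        "missing": int((fail == 2).sum()),
        "gq": int((fail == 3).sum()),
        "maf": int((fail == 4).sum()),
        "passed": int((fail == 0).sum()),
    }
    return table.subset(fail == 0), tally


# ---------------------------------------------------------------------------
# sharing partition
# ---------------------------------------------------------------------------

def partition_sharing(table: VariantTable) -> SharingSummary:
    """Partition filtered sites into all-sample-het vs partially-het.

    Sites heterozygous in zero samples (possible only on unfiltered
    input) are excluded with a warning; every retained site falls in
    exactly one class.
    """
    het = table.het_matrix
    n_het = het.sum(axis=1)
    zero = int((n_het == 0).sum())
    if zero:
        logger.warning("%d sites heterozygous in no sample excluded from sharing partition", zero)
    shared = int((n_het == table.n_samples).sum())
    partial = int(((n_het > 0) & (n_het < table.n_samples)).sum())
    return SharingSummary(shared_all=shared, partial=partial)


# ---------------------------------------------------------------------------
# windowed heterozygosity
# ---------------------------------------------------------------------------

def window_heterozygosity(
    table: VariantTable,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    per_sample: bool = False,
) -> WindowProfile:
    """Pooled heterozygous-site count per non-overlapping window.

    A site at 0-based position p belongs to window floor(p / window);
    shared sites count once in the pooled profile.  Sites on unknown
    chromosomes or beyond the chromosome length raise ``ValueError``.
    """
    het_any = table.het_matrix.any(axis=1)
    counts: dict[str, np.ndarray] = {}
    per_s: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_win = int(np.ceil(length / window))
        mask = (table.chrom == chrom) & het_any
        pos = table.pos[mask]
        if len(pos) and (pos.max() >= length or pos.min() < 0):
            raise ValueError(f"site beyond chromosome {chrom} length {length}")
        counts[chrom] = np.bincount(pos // window, minlength=n_win).astype(np.int64)
        if per_sample:
            mat = np.zeros((n_win, table.n_samples), dtype=np.int64)
            for s in range(table.n_samples):
                m_s = (table.chrom == chrom) & table.het_matrix[:, s]
                mat[:, s] = np.bincount(table.pos[m_s] // window, minlength=n_win)
            per_s[chrom] = mat
    unknown = set(np.unique(table.chrom)) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"sites on unknown chromosomes: {sorted(unknown)}")
    return WindowProfile(window, dict(chrom_lengths), counts, per_s if per_sample else None)


# ---------------------------------------------------------------------------
# hotspot fragments
# ---------------------------------------------------------------------------

def call_hotspots(
    profile: WindowProfile,
    top_fraction: float = 0.05,
    max_bridge_windows: int = 1,
    min_windows: int = 2,
) -> list[HotspotFragment]:
    """Merge top-quantile windows into continuous hotspot fragments.

    The threshold is the empirical (1 - top_fraction) quantile of
    genome-wide window counts restricted to nonzero windows (so sparse
    genomes do not collapse the threshold to 0).  Qualifying windows
    (count >= threshold) merge into fragments, bridging up to
    ``max_bridge_windows`` consecutive non-qualifying windows; fragments
    with fewer than ``min_windows`` qualifying windows are dropped.
    Fragment coordinates run from the first qualifying window start to
    the last qualifying window end (clipped to the chromosome).
    """
    all_counts = profile.all_counts()
    if len(all_counts) < 20:
        raise ValueError("fewer than 20 windows genome-wide: top-quantile threshold degenerate")
    nonzero = all_counts[all_counts > 0]
    if len(nonzero) == 0:
        return []
    threshold = float(np.quantile(nonzero, 1.0 - top_fraction))
    fragments: list[HotspotFragment] = []
    w = profile.window
    for chrom in sorted(profile.counts):
        counts = profile.counts[chrom]
        qual = counts >= threshold
        idx = np.flatnonzero(qual)
        if len(idx) == 0:
            continue
        groups: list[list[int]] = [[int(idx[0])]]
        for i in idx[1:]:
            if int(i) - groups[-1][-1] <= max_bridge_windows + 1:
                groups[-1].append(int(i))
            else:
                groups.append([int(i)])
        for g in groups:
            if len(g) < min_windows:
                continue
            start = g[0] * w
            end = min((g[-1] + 1) * w, profile.chrom_lengths[chrom])
            fragments.append(
                HotspotFragment(
                    chrom_id=chrom,
                    start=start,
                    end=end,
                    n_windows=len(g),
                    mean_count=round(float(counts[g[0] : g[-1] + 1].mean()), 2),
                )
            )
    return fragments


def windows_to_dataframe(profile: WindowProfile) -> pd.DataFrame:
    rows = []
    for chrom in sorted(profile.counts):
        for i, c in enumerate(profile.counts[chrom]):
            rows.append(
                {
                    "chrom": chrom,
                    "start": i * profile.window,
                    "end": min((i + 1) * profile.window, profile.chrom_lengths[chrom]),
                    "het_sites": int(c),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "het_sites"])


def hotspots_to_dataframe(fragments: list[HotspotFragment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": f.chrom_id,
                "start": f.start,
                "end": f.end,
                "n_windows": f.n_windows,
                "mean_count": f.mean_count,
            }
            for f in fragments
        ],
        columns=["chrom", "start", "end", "n_windows", "mean_count"],
    )
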