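"""Telomere repeat-unit discovery and per-arm telomere calling.

Telomeres are terminal tandem arrays of a short conserved unit (7 bp in
grapevine and most plants: TTTAGGG / CCCTAAA, one unit read on the two
strands).  Discovery scans a terminal window (default 150 kb) at both
ends of every chromosome for tandem runs of units 5-12 bp long and
reports the canonical unit covering the most bp across all windows.
Calling then locates, per arm, the maximal run of that unit (any
rotation, either strand) inside the terminal window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeSequence
from .repeats import canonical_monomer, encode, primitive_root, revcomp

logger = logging.getLogger(__name__)

LEFT = "left"
RIGHT = "right"


@dataclass
class TelomereCall:
    """Telomere presence call for one chromosome arm.

    ``left`` is the arm at sequence start (conventionally the short arm),
    ``right`` the arm at sequence end.  Coordinates are 0-based half-open
    on the chromosome; ``copies`` is fractional (array span / unit length).
    """

    chrom_id: str
    arm: str
    present: bool
    unit: str
    copies: float
    array_start: int
    array_end: int

    @property
    def array_length(self) -> int:
        return self.array_end - self.array_start


@dataclass
class TelomereUnitResult:
    """Discovered telomeric unit plus per-chromosome supporting coverage."""

    unit: str | None
    unit_length: int
    coverage_bp: float
    evidence: pd.DataFrame  # columns: unit, chrom, arm, bp

    def __bool__(self) -> bool:
        return self.unit is not None


def _terminal_windows(rec: GenomeSequence, window: int):
    """Yield (arm, offset, subsequence) for both chromosome ends."""
    w = min(window, rec.length)
    if w < window:
        logger.warning(
            "%s: terminal window %d truncated to chromosome length %d",
            rec.chrom_id, window, rec.length,
        )
    yield LEFT, 0, rec.seq[:w]
    yield RIGHT, rec.length - w, rec.seq[rec.length - w:]


def _tandem_runs(seq: str, k: int) -> list[tuple[int, int]]:
    """Maximal intervals [s, e) tiled by tandem copies of some k-bp unit.

    A position i is in-phase when seq[i] == seq[i+k]; a maximal run of
    in-phase positions of length L corresponds to an array of span L + k.
    """
    codes = encode(seq)
    if len(codes) < 2 * k:
        return []
    valid = codes >= 0
    m = (codes[:-k] == codes[k:]) & valid[:-k] & valid[k:]
    if not m.any():
        return []
    padded = np.concatenate([[False], m, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e) + k) for s, e in zip(edges[::2], edges[1::2]) if e - s >= k]


def find_telomere_unit(
    genome: list[GenomeSequence],
    terminal_window: int = 150_000,
    min_unit: int = 5,
    max_unit: int = 12,
    min_copies: int = 20,
) -> TelomereUnitResult:
    """Discover the telomeric repeat unit from chromosome-terminal windows.

    For each unit length 5-12 bp, tandem runs inside the terminal windows
    are attributed to the canonical form of their repeating unit; units
    whose primitive root is shorter than ``min_unit`` (e.g. an AT
    dinucleotide tract read at length 6) are excluded.  A unit is only
    tallied where it has at least one run of ``min_copies`` copies, so
    incidental two-copy background repeats never win.  The winner is the
    canonical unit covering the most bp summed over all windows; the
    per-chromosome coverage table is returned as supporting evidence.
    """
    tally: dict[str, float] = {}
    rows: list[dict] = []
    for rec in genome:
        for arm, offset, sub in _terminal_windows(rec, terminal_window):
            for k in range(min_unit, max_unit + 1):
                for s, e in _tandem_runs(sub, k):
                    copies = (e - s) / k
                    if copies < min_copies:
                        continue
                    unit = sub[s : s + k]
                    if "N" in unit:
                        continue
                    root = primitive_root(unit)
                    if len(root) < min_unit:
                        continue
                    canon = canonical_monomer(unit)
                    tally[canon] = tally.get(canon, 0.0) + (e - s)
                    rows.append({"unit": canon, "chrom": rec.chrom_id, "arm": arm, "bp": e - s})
    evidence = pd.DataFrame(rows, columns=["unit", "chrom", "arm", "bp"])
    if not tally:
        logger.warning("no telomeric repeat unit found in any terminal window")
        return TelomereUnitResult(None, 0, 0.0, evidence)
    # deterministic: most bp, ties by shorter then lexicographic unit
    best = max(tally, key=lambda u: (tally[u], -len(u), [-ord(c) for c in u]))
    return TelomereUnitResult(best, len(best), tally[best], evidence)


def _unit_kmers(unit: str) -> set[bytes]:
    """All rotations of the unit and of its reverse complement, as bytes."""
    out: set[bytes] = set()
    for s in (unit, revcomp(unit)):
        doubled = s + s
        for i in range(len(s)):
            out.add(doubled[i : i + len(s)].encode("ascii"))
    return out


def _max_unit_array(sub: str, unit: str, bridge: int) -> tuple[int, int] | None:
    """Largest run of phase-consistent unit copies, bridging gaps <= ``bridge`` bp.

    Inside an exact tandem array every position starts some rotation of
    the unit, so raw match coverage spills a few bases into flanking
    sequence.  Chaining only matches in the same phase (start positions
    congruent modulo the unit length, consecutive within one unit plus
    the bridge) keeps the span an exact multiple of the unit length.
    """
    k = len(unit)
    kmers = _unit_kmers(unit)
    raw = np.frombuffer(sub.encode("ascii"), dtype=np.uint8)
    if len(raw) < k:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(raw, k)
    match = np.zeros(len(windows), dtype=bool)
    for km in kmers:  # <= 2k rotation vectors
        kv = np.frombuffer(km, dtype=np.uint8)
        match |= (windows == kv).all(axis=1)
    if not match.any():
        return None
    starts = np.flatnonzero(match)
    max_step = k + bridge
    best: tuple[int, int] | None = None
    for r in range(k):
        cls = starts[starts % k == r]
        if len(cls) == 0:
            continue
        breaks = np.flatnonzero(np.diff(cls) > max_step)
        run_bounds = np.concatenate([[0], breaks + 1, [len(cls)]])
        for a, b in zip(run_bounds[:-1], run_bounds[1:]):
            s, e = int(cls[a]), int(cls[b - 1]) + k
            if best is None or e - s > best[1] - best[0]:
                best = (s, e)
    return best


def call_telomeres(
    genome: list[GenomeSequence],
    unit: str,
    terminal_window: int = 150_000,
    min_copies: float = 50,
    bridge_units: int = 1,
) -> list[TelomereCall]:
    """Call telomere presence/length/copies for both arms of every chromosome.

    Per arm, the call is the maximal run of the unit (any rotation,
    either strand) in the terminal window; runs interrupted by at most
    ``bridge_units`` unit-lengths of non-matching sequence are bridged.
    An arm is ``present`` iff the run reaches ``min_copies`` copies.
    """
    if not unit:
        raise ValueError("telomere unit must be non-empty")
    k = len(unit)
    canon = canonical_monomer(unit)
    calls: list[TelomereCall] = []
    for rec in genome:
        for arm, offset, sub in _terminal_windows(rec, terminal_window):
            hit = _max_unit_array(sub, unit, bridge=bridge_units * k)
            if hit is None:
                calls.append(TelomereCall(rec.chrom_id, arm, False, canon, 0.0, 0, 0))
                continue
            s, e = hit
            copies = (e - s) / k
            present = copies >= min_copies
            calls.append(
                TelomereCall(
                    chrom_id=rec.chrom_id,
                    arm=arm,
                    present=present,
                    unit=canon,
                    copies=round(copies, 1) if present else 0.0,
                    array_start=offset + s if present else 0,
                    array_end=offset + e if present else 0,
                )
            )
    return calls


def telomeres_to_dataframe(calls: list[TelomereCall]) -> pd.DataFrame:
    """Tabular export: chrom, arm, present, unit, copies, start, end, length."""
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom_id,
                "arm": c.arm,
                "present": c.present,
                "unit": c.unit,
                "copies": c.copies,
                "start": c.array_start,
                "end": c.array_end,
                "length": c.array_length,
            }
            for c in calls
        ],
        columns=["chrom", "arm", "present", "unit", "copies", "start", "end", "length"],
    )
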