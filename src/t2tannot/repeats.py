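"""Tandem-repeat array detection and monomer-family (harmonic) grouping.

The scanner looks for satellite-like arrays whose repeating unit (the
*monomer*) is ``min_period``–``max_period`` bp long.  Detection works by
shifted self-identity: inside a tandem array of period *p* the sequence
matches itself at lag *p*, so a sliding window of length *p* over the
match vector ``seq[i] == seq[i+p]`` stays above the identity threshold
for the whole array.  Candidate spans are then trimmed to the outermost
matching positions, a consensus monomer is called by per-column majority
vote, and arrays are reported with fractional copy numbers
(span / period, one decimal in text output).

Harmonic ambiguity: an exact tandem of period *p* also matches at lag
2*p*, 3*p*, ....  The scanner processes periods in ascending order and
suppresses re-detections whose period is an integer multiple of an
already-accepted overlapping array, so each array is reported at the
smallest period that clears the identity threshold.  Deliberate
higher-order units (e.g. a diverged dimer of a base monomer) survive
because the base period fails the threshold; :func:`group_harmonics`
re-attaches them to their base family afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes A=0,C=1,G=2,T=3; anything else -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_monomer(unit: str) -> str:
    """Canonical (rotation- and strand-independent) form of a repeat unit.

    Returns the lexicographically smallest string among all rotations of
    the unit and all rotations of its reverse complement, so e.g. the
    telomeric unit TTTAGGG and its complement-strand reading CCCTAAA map
    to the same canonical string.  Idempotent by construction.
    """
    if not unit:
        raise ValueError("empty repeat unit")
    if set(unit) - set("ACGT"):
        raise ValueError(f"non-ACGT character in repeat unit {unit!r}")
    candidates = []
    for s in (unit, revcomp(unit)):
        doubled = s + s
        candidates.extend(doubled[i : i + len(s)] for i in range(len(s)))
    return min(candidates)


def primitive_root(unit: str) -> str:
    """Smallest string whose tandem repetition yields ``unit`` (e.g. ATATAT -> AT)."""
    n = len(unit)
    for d in range(1, n + 1):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return unit[:d]
    return unit


@dataclass
class TandemArray:
    """A maximal tandem-repeat interval.

    ``copies`` is fractional (span / period); ``identity`` is the mean
    per-copy identity to the majority-vote consensus.
    """

    chrom_id: str
    start: int
    end: int
    period: int
    consensus: str
    copies: float
    identity: float

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def canonical(self) -> str:
        return canonical_monomer(self.consensus)


@dataclass
class MonomerFamily:
    """A base monomer plus the integer-multiple (harmonic) units built from it."""

    base_period: int
    base_consensus: str
    arrays: list[TandemArray] = field(default_factory=list)

    @property
    def member_periods(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for a in self.arrays:
            out[a.period] = out.get(a.period, 0) + 1
        return out

    @property
    def total_bp(self) -> int:
        return sum(a.span for a in self.arrays)

    def genome_fraction(self, genome_length: int) -> float:
        return self.total_bp / genome_length


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open [i, j) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _consensus_and_identity(codes: np.ndarray, start: int, end: int, period: int) -> tuple[str, float]:
    """Majority-vote consensus over full copies; mean per-copy identity to it."""
    nfull = (end - start) // period
    mat = codes[start : start + nfull * period].reshape(nfull, period)
    counts = np.zeros((4, period), dtype=np.int32)
    valid = mat >= 0
    for b in range(4):
        counts[b] = (mat == b).sum(axis=0)
    cons_codes = counts.argmax(axis=0).astype(np.int8)
    consensus = _BASES[cons_codes].tobytes().decode("ascii")
    matches = (mat == cons_codes[None, :]) & valid
    identity = float(matches.sum(axis=1).mean() / period)
    return consensus, identity


def _trim_to_match_runs(m: np.ndarray, lo: int, hi: int, period: int, run: int = 16) -> tuple[int, int] | None:
    """First and last index in [lo, hi) opening/closing a run of consecutive matches.

    A run of ``min(run, period)`` consecutive lag-p matches has chance
    probability ~0.25^16 in random sequence, so boundaries snap to the
    array proper rather than to isolated background matches.  Returns
    (first run start, last run end index) or None when no run exists.
    """
    k = min(run, period)
    region = m[lo:hi]
    if len(region) < k:
        return None
    c = np.concatenate([[0], np.cumsum(region, dtype=np.int64)])
    full = np.flatnonzero(c[k:] - c[:-k] == k)  # run of k starting at lo+i
    if len(full) == 0:
        return None
    return lo + int(full[0]), lo + int(full[-1]) + k - 1


def _extend_by_copies(
    codes: np.ndarray,
    start: int,
    end: int,
    period: int,
    cons: np.ndarray,
    min_identity: float,
) -> tuple[int, int]:
    """Grow an array by whole copies while flanking copies match the consensus.

    Recovers boundary copies whose windowed identity dipped below the
    detection threshold even though the copy itself still matches.
    """
    n = len(codes)
    while start - period >= 0:
        prev = codes[start - period : start]
        if float(((prev == cons) & (prev >= 0)).mean()) >= min_identity:
            start -= period
        else:
            break
    while end + period <= n:
        phase = (end - start) % period
        cons_rot = cons[(phase + np.arange(period)) % period]
        nxt = codes[end : end + period]
        if float(((nxt == cons_rot) & (nxt >= 0)).mean()) >= min_identity:
            end += period
        else:
            break
    return start, end


def _harmonic_of(p_large: int, p_small: int, tol: int = 0) -> bool:
    if p_large <= p_small:
        return False
    k = round(p_large / p_small)
    return k >= 2 and abs(p_large - k * p_small) <= tol


def _overlap(a: TandemArray, b: TandemArray) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _resolve_overlaps(accepted: list[TandemArray], cand: TandemArray) -> bool:
    """Apply the overlap/harmonic tie-break; may evict accepted arrays.

    Returns True if ``cand`` should be kept.  Rules: a candidate whose
    period is an integer multiple of an overlapping accepted array's
    period is a harmonic re-detection and is dropped (smallest period
    wins).  Non-harmonic overlaps below 50% of the shorter span coexist;
    larger overlaps are decided by identity x span score.
    """
    evict: list[int] = []
    for i, acc in enumerate(accepted):
        ov = _overlap(acc, cand)
        if ov == 0:
            continue
        if _harmonic_of(cand.period, acc.period):
            return False
        if ov < 0.5 * min(acc.span, cand.span):
            continue
        if cand.identity * cand.span > acc.identity * acc.span:
            evict.append(i)
        else:
            return False
    for i in reversed(evict):
        del accepted[i]
    return True


def scan_tandem_arrays(
    seq: str,
    chrom_id: str = "seq",
    min_period: int = 30,
    max_period: int = 500,
    min_copies: float = 2.0,
    min_identity: float = 0.80,
) -> list[TandemArray]:
    """Detect maximal tandem arrays with period in [min_period, max_period].

    Returns arrays sorted by start coordinate.  N positions never match.
    An empty result is valid (e.g. plain random sequence).
    """
    n = len(seq)
    out: list[TandemArray] = []
    if n < 2 * min_period:
        return out
    codes = encode(seq)
    valid = codes >= 0
    max_period = min(max_period, (n - 1) // 2)
    for period in range(min_period, max_period + 1):
        m = (codes[:-period] == codes[period:]) & valid[:-period] & valid[period:]
        if len(m) < period + 1:
            continue
        # w[j] = matches in m[j : j+period]; window identity over one period
        c = np.cumsum(m, dtype=np.int64)
        w = np.empty(len(m) - period + 1, dtype=np.int64)
        w[0] = c[period - 1]
        w[1:] = c[period:] - c[:-period]
        need = int(np.ceil(min_identity * period))
        ok = w >= need
        spans: list[list[int]] = []
        for j0, j1 in _bool_runs(ok):
            # candidate m-region [j0, j1-1 + period); snap boundaries to the
            # outermost run of consecutive matches, so isolated chance matches
            # in the flanking background never extend the array
            bounds = _trim_to_match_runs(m, int(j0), int(j1) - 1 + period, period)
            if bounds is None:
                continue
            spans.append([bounds[0], bounds[1] + period + 1])
        # a diverged array can fragment where the windowed identity dips;
        # rejoin pieces interrupted by at most a few periods
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s - merged[-1][1] <= 3 * period:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for start, end in merged:
            if (end - start) / period < min_copies:
                continue
            consensus, identity = _consensus_and_identity(codes, start, end, period)
            if identity < min_identity:
                continue
            start, end = _extend_by_copies(codes, start, end, period,
                                           encode(consensus), min_identity)
            consensus, identity = _consensus_and_identity(codes, start, end, period)
            copies = (end - start) / period
            cand = TandemArray(
                chrom_id=chrom_id,
                start=start,
                end=end,
                period=period,
                consensus=consensus,
                copies=round(copies, 1),
                identity=round(identity, 4),
            )
            if _resolve_overlaps(out, cand):
                out.append(cand)
    out.sort(key=lambda a: (a.start, a.period))
    return out


def scan_genome(
    genome,
    min_period: int = 30,
    max_period: int = 500,
    min_copies: float = 2.0,
    min_identity: float = 0.80,
) -> list[TandemArray]:
    """Run :func:`scan_tandem_arrays` over every chromosome of a genome."""
    arrays: list[TandemArray] = []
    for rec in genome:
        arrays.extend(
            scan_tandem_arrays(
                rec.seq,
                chrom_id=rec.chrom_id,
                min_period=min_period,
                max_period=max_period,
                min_copies=min_copies,
                min_identity=min_identity,
            )
        )
    return arrays


# ---------------------------------------------------------------------------
# harmonic grouping
# ---------------------------------------------------------------------------

def _best_rotation_identity(piece: str, base: str) -> float:
    """Best identity of ``piece`` against all rotations of ``base`` and its rc."""
    if len(piece) != len(base):
        return 0.0
    p = np.frombuffer(piece.encode(), dtype=np.uint8)
    best = 0.0
    for s in (base, revcomp(base)):
        doubled = np.frombuffer((s + s).encode(), dtype=np.uint8)
        for r in range(len(base)):
            ident = float((p == doubled[r : r + len(base)]).mean())
            if ident > best:
                best = ident
    return best


def _multiple_identity(consensus: str, k: int, base: str) -> float:
    """Mean best-rotation identity of the k base-length pieces of a consensus."""
    p = len(base)
    pieces = [consensus[i * p : (i + 1) * p] for i in range(k)]
    return float(np.mean([_best_rotation_identity(piece, base) for piece in pieces]))


def group_harmonics(
    arrays: list[TandemArray],
    length_tolerance: int = 0,
    identity_min: float = 0.80,
) -> list[MonomerFamily]:
    """Group arrays whose periods are integer multiples of a shared base monomer.

    An array of period k*p joins the family with base period p iff its
    consensus, cut into k pieces of length p, matches the family's base
    monomer at >= ``identity_min`` under rotation (either strand).  Each
    array joins at most one family; the smallest qualifying base period
    wins.  Arrays matching no existing family found their own.
    """
    families: list[MonomerFamily] = []
    for arr in sorted(arrays, key=lambda a: (a.period, a.start)):
        placed = False
        for fam in sorted(families, key=lambda f: f.base_period):
            b = fam.base_period
            if arr.period < b:
                continue
            k = round(arr.period / b)
            if k < 1 or abs(arr.period - k * b) > length_tolerance:
                continue
            if k * b != arr.period:
                continue  # zero tolerance default: exact multiples only
            if _multiple_identity(arr.consensus, k, fam.base_consensus) >= identity_min:
                fam.arrays.append(arr)
                placed = True
                break
        if not placed:
            families.append(
                MonomerFamily(base_period=arr.period, base_consensus=arr.consensus, arrays=[arr])
            )
    families.sort(key=lambda f: -f.total_bp)
    return families


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_repeat_units(arrays: list[TandemArray], genome_length: int) -> pd.DataFrame:
    """Per-period abundance table, ranked by genome bp covered.

    Columns: period, n_arrays, total_copies, total_bp, genome_fraction.
    Ties in total_bp break by ascending period.  Note: "distinct repeat
    units" are counted per distinct period here; arrays of the same
    period but different consensus are pooled.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    rows: dict[int, list] = {}
    for a in arrays:
        row = rows.setdefault(a.period, [0, 0.0, 0])
        row[0] += 1
        row[1] += a.copies
        row[2] += a.span
    df = pd.DataFrame(
        [
            {
                "period": p,
                "n_arrays": v[0],
                "total_copies": round(v[1], 1),
                "total_bp": v[2],
                "genome_fraction": v[2] / genome_length,
            }
            for p, v in rows.items()
        ],
        columns=["period", "n_arrays", "total_copies", "total_bp", "genome_fraction"],
    )
    if len(df):
        df = df.sort_values(["total_bp", "period"], ascending=[False, True]).reset_index(drop=True)
    return df


def arrays_to_dataframe(arrays: list[TandemArray], families: list[MonomerFamily] | None = None) -> pd.DataFrame:
    """Tabular export: chrom, start, end, period, copies, identity, consensus, canonical, family_base."""
    fam_of: dict[int, int] = {}
    if families:
        for fam in families:
            for a in fam.arrays:
                fam_of[id(a)] = fam.base_period
    return pd.DataFrame(
        [
            {
                "chrom": a.chrom_id,
                "start": a.start,
                "end": a.end,
                "period": a.period,
                "copies": a.copies,
                "identity": a.identity,
                "consensus": a.consensus,
                "canonical": a.canonical,
                "family_base": fam_of.get(id(a), a.period),
            }
            for a in arrays
        ],
        columns=[
            "chrom", "start", "end", "period", "copies",
            "identity", "consensus", "canonical", "family_base",
        ],
    )
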