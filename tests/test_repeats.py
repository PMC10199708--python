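"""Tandem-repeat scanner, canonical monomers and harmonic grouping.

Includes the brute-force oracle: a plain-Python detector that walks
copy-by-copy per phase and period, counting consecutive copies whose
identity to the previous copy clears the threshold.  The oracle shares
no code with the scanner's windowed shifted-identity formulation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from t2tannot.repeats import (
    TandemArray,
    canonical_monomer,
    group_harmonics,
    revcomp,
    scan_tandem_arrays,
    summarize_repeat_units,
)
from t2tannot.simulate import random_monomer
from tests.conftest import random_dna

DNA = st.text(alphabet="ACGT", min_size=1, max_size=30)


# ---------------------------------------------------------------------------
# canonical monomer
# ---------------------------------------------------------------------------

class TestCanonicalMonomer:
    def test_strand_equivalence_of_telomere_unit(self):
        assert canonical_monomer("TTTAGGG") == canonical_monomer("CCCTAAA")

    def test_telomere_unit_value(self):
        # brute-force minimum over all 14 rotations of both strands
        brute = min(
            (s + s)[i : i + 7]
            for s in ("TTTAGGG", revcomp("TTTAGGG"))
            for i in range(7)
        )
        assert canonical_monomer("TTTAGGG") == brute == "AAACCCT"

    def test_homopolymer_fixed_point(self):
        assert canonical_monomer("AAAA") == "AAAA"

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            canonical_monomer("ACGN")

    @settings(deadline=None, derandomize=True)
    @given(DNA)
    def test_idempotent_and_invariant(self, unit):
        c = canonical_monomer(unit)
        assert canonical_monomer(c) == c
        assert canonical_monomer(revcomp(unit)) == c
        for r in range(len(unit)):
            assert canonical_monomer(unit[r:] + unit[:r]) == c


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def oracle_scan(seq, min_period=30, max_period=500, min_identity=0.80, min_copies=2):
    """Copy-walking tandem detector (independent of the scanner).

    For every period and phase, consecutive full copies are compared to
    the previous copy; runs whose every step clears the identity
    threshold are arrays.  Reports (start, end, period) in whole-copy
    granularity, deduplicated to the maximal span per overlapping group.
    """
    n = len(seq)
    hits = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        for phase in range(p):
            starts = list(range(phase, n - p + 1, p))
            run_begin = None
            prev = None
            for s in starts:
                cur = seq[s : s + p]
                if prev is not None:
                    ident = sum(a == b and a != "N" for a, b in zip(prev, cur)) / p
                    if ident >= min_identity:
                        if run_begin is None:
                            run_begin = s - p
                    elif run_begin is not None:
                        if (s - run_begin) / p >= min_copies:
                            hits.append((run_begin, s, p))
                        run_begin = None
                prev = cur
            if run_begin is not None and (starts[-1] + p - run_begin) / p >= min_copies:
                hits.append((run_begin, starts[-1] + p, p))
    # keep the maximal span among overlapping same-harmonic-group hits
    out = []
    for h in sorted(hits, key=lambda h: (h[0] - h[1], h[2])):
        if not any(h[0] < e and h[1] > s for s, e, _ in out):
            out.append(h)
    return sorted(out)


class TestScannerVsOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_planted_arrays_agree(self, seed):
        rng = np.random.default_rng(seed)
        period = int(rng.integers(30, 120))
        mon = random_monomer(rng, period)
        copies = int(rng.integers(3, 8))
        bg = random_dna(rng, 2000 - copies * period)
        cut = len(bg) // 2
        seq = bg[:cut] + mon * copies + bg[cut:]
        got = scan_tandem_arrays(seq)
        exp = oracle_scan(seq)
        assert len(got) == len(exp) == 1
        (g,), (e,) = got, exp
        # period up to harmonic ambiguity; span within one period
        assert g.period % e[2] == 0 or e[2] % g.period == 0
        assert abs(g.start - e[0]) <= g.period and abs(g.end - e[1]) <= g.period

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_random_sequence_both_empty(self, seed):
        seq = random_dna(np.random.default_rng(seed), 2000)
        assert scan_tandem_arrays(seq) == []
        assert oracle_scan(seq) == []


class TestScanner:
    def test_planted_exact_array(self, monomer_107, background_10kb):
        seq = background_10kb[:3000] + monomer_107 * 20 + background_10kb[3000:]
        (a,) = scan_tandem_arrays(seq)
        assert (a.period, a.copies, a.identity) == (107, 20.0, 1.0)
        assert (a.start, a.end) == (3000, 3000 + 20 * 107)
        assert a.consensus in (monomer_107 * 2)  # consensus is a rotation of the monomer

    def test_fractional_trailing_copy(self, monomer_107, background_10kb):
        seq = background_10kb[:3000] + monomer_107 * 10 + monomer_107[:54] + background_10kb[3000:]
        (a,) = scan_tandem_arrays(seq)
        assert a.period == 107 and a.copies == pytest.approx(10.5, abs=0.2)

    def test_no_arrays_in_random_sequence(self, rng):
        assert scan_tandem_arrays(random_dna(rng, 5000)) == []

    def test_strand_rotation_invariance(self, monomer_107, rng):
        bg = random_dna(rng, 6000)
        seq = bg[:2000] + monomer_107 * 12 + bg[2000:]
        fwd = scan_tandem_arrays(seq)
        rev = scan_tandem_arrays(revcomp(seq))
        assert len(fwd) == len(rev) == 1
        assert fwd[0].canonical == rev[0].canonical
        n = len(seq)
        assert (rev[0].start, rev[0].end) == (n - fwd[0].end, n - fwd[0].start)

    def test_n_bases_never_match(self, monomer_107, background_10kb):
        # an N-filled gap longer than the bridge breaks the array in two
        seq = (
            background_10kb[:2000]
            + monomer_107 * 6
            + "N" * 500
            + monomer_107 * 6
            + background_10kb[2000:]
        )
        arrays = scan_tandem_arrays(seq)
        assert len(arrays) == 2
        assert all(a.period == 107 and a.copies == 6.0 for a in arrays)

    def test_planted_recovery_precision_recall(self):
        """>= 95% recall/precision, boundary error <= 1 period, at 5% mutation."""
        from t2tannot.repeats import encode, _BASES
        from t2tannot.simulate import _mutate_copies

        rng = np.random.default_rng(99)
        truth = []
        pieces = []
        cursor = 0
        for i in range(10):
            gap = random_dna(rng, 8000)
            pieces.append(gap)
            cursor += len(gap)
            period = int(rng.integers(40, 200))
            mon = random_monomer(rng, period)
            copies = int(rng.integers(10, 30))
            mat = _mutate_copies(encode(mon), copies, 0.05, rng)
            arr = _BASES[mat.ravel()].tobytes().decode()
            pieces.append(arr)
            truth.append((cursor, cursor + len(arr), period))
            cursor += len(arr)
        pieces.append(random_dna(rng, 8000))
        seq = "".join(pieces)
        found = scan_tandem_arrays(seq)

        def matches(t, a):
            return (
                min(t[1], a.end) - max(t[0], a.start) > 0
                and (a.period % t[2] == 0 or t[2] % a.period == 0)
                and abs(a.start - t[0]) <= t[2]
                and abs(a.end - t[1]) <= t[2]
            )

        recalled = sum(any(matches(t, a) for a in found) for t in truth)
        precise = sum(any(matches(t, a) for t in truth) for a in found)
        assert recalled / len(truth) >= 0.95
        assert precise / len(found) >= 0.95


# ---------------------------------------------------------------------------
# harmonic grouping
# ---------------------------------------------------------------------------

def _arr(chrom, start, period, consensus, copies=10.0, identity=1.0):
    return TandemArray(chrom, start, start + int(round(copies * period)), period,
                       consensus, copies, identity)


class TestGroupHarmonics:
    def test_literal_concatemers_join_base_family(self, monomer_107):
        arrays = [
            _arr("chr1", 0, 107, monomer_107),
            _arr("chr1", 5000, 214, monomer_107 * 2),
            _arr("chr1", 20000, 321, monomer_107 * 3),
        ]
        fams = group_harmonics(arrays)
        assert len(fams) == 1
        fam = fams[0]
        assert fam.base_period == 107
        assert fam.member_periods == {107: 1, 214: 1, 321: 1}

    def test_135_270_405_family(self, rng):
        mon = random_monomer(rng, 135)
        arrays = [
            _arr("chr3", 0, 135, mon),
            _arr("chr3", 9000, 270, mon * 2),
            _arr("chr3", 30000, 405, mon * 3),
        ]
        fams = group_harmonics(arrays)
        assert len(fams) == 1 and fams[0].base_period == 135

    def test_rotated_concatemer_still_joins(self, monomer_107):
        rotated = monomer_107[30:] + monomer_107[:30]
        arrays = [_arr("c", 0, 107, monomer_107), _arr("c", 5000, 214, rotated * 2)]
        fams = group_harmonics(arrays)
        assert len(fams) == 1 and fams[0].base_period == 107

    def test_unrelated_same_multiple_stays_apart(self, monomer_107, rng):
        other = random_monomer(rng, 214)
        arrays = [_arr("c", 0, 107, monomer_107), _arr("c", 5000, 214, other)]
        fams = group_harmonics(arrays)
        assert sorted(f.base_period for f in fams) == [107, 214]

    def test_singleton_family(self, rng):
        mon = random_monomer(rng, 187)
        fams = group_harmonics([_arr("chr14", 0, 187, mon)])
        assert len(fams) == 1 and fams[0].base_period == 187 and fams[0].total_bp == 1870

    def test_family_bp_conserved_and_bounded(self, monomer_107, rng):
        arrays = [
            _arr("c", 0, 107, monomer_107, copies=20),
            _arr("c", 10000, 214, monomer_107 * 2, copies=5),
            _arr("c", 30000, 187, random_monomer(rng, 187), copies=8),
        ]
        fams = group_harmonics(arrays)
        assert sum(f.total_bp for f in fams) == sum(a.span for a in arrays)
        assert sum(f.total_bp for f in fams) <= 50000


class TestSummarize:
    def test_empty(self):
        assert len(summarize_repeat_units([], 1000)) == 0

    def test_fraction_arithmetic(self, monomer_107):
        arrays = [_arr("c", 0, 107, monomer_107, copies=10.0)]
        df = summarize_repeat_units(arrays, 107_000)
        assert df.loc[0, "genome_fraction"] == pytest.approx(0.01)

    def test_ranking_by_bp_then_period(self, monomer_107, rng):
        arrays = [
            _arr("c", 0, 107, monomer_107, copies=40),        # 4280 bp
            _arr("c", 10000, 321, monomer_107 * 3, copies=8), # 2568 bp
            _arr("c", 30000, 135, random_monomer(rng, 135), copies=8),  # 1080 bp
        ]
        df = summarize_repeat_units(arrays, 100_000)
        assert list(df["period"]) == [107, 321, 135]
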