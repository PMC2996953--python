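"""LTR-pair detection: seeds, chaining, refinement, flanks/TSDs, scanning.

The brute-force seed oracle enumerates matches by exhaustive shifted
comparison (numpy), independently of the detector's k-mer index.
"""

import numpy as np
import pytest

from ltrkit.detect import (
    CandidatePair,
    DetectionParams,
    chain_hits,
    check_flank_and_tsd,
    find_seed_pairs,
    refine_pair,
    scan_genome,
    seed_hits,
)
from ltrkit._align import revcomp
from ltrkit.model import GenomeSequence, Interval, RepeatMode


def _rand_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def oracle_seed_hits_direct(seq: str, params: DetectionParams):
    """Exhaustive direct-repeat seed enumeration by shifted comparison."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n, k = len(a), params.seed_length
    lo, hi = params.separation_window
    is_n = a == ord("N")
    hits = []
    for s in range(lo, min(hi, n - k) + 1):
        eq = (a[: n - s] == a[s:]) & ~is_n[: n - s] & ~is_n[s:]
        if len(eq) < k:
            continue
        c = np.cumsum(eq)
        runs = c[k - 1 :] - np.concatenate(([0], c[:-k]))
        for i in np.nonzero(runs == k)[0]:
            hits.append((int(i), int(i) + s))
    return sorted(hits)


def oracle_seed_hits_inverted(seq: str, params: DetectionParams):
    """Exhaustive inverted-repeat seed enumeration: matches between the
    sequence and its reverse complement, mapped back to forward coordinates."""
    n, k = len(seq), params.seed_length
    lo, hi = params.separation_window
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    is_na = a == ord("N")
    is_nb = b == ord("N")
    hits = []
    for d in range(-(n - 1), n):
        i0 = max(0, -d)
        i1 = min(n, n - d)
        if i1 - i0 < k:
            continue
        eq = (a[i0:i1] == b[i0 + d : i1 + d]) & ~is_na[i0:i1] & ~is_nb[i0 + d : i1 + d]
        c = np.cumsum(eq)
        runs = c[k - 1 :] - np.concatenate(([0], c[:-k]))
        for off in np.nonzero(runs == k)[0]:
            i = i0 + int(off)
            jp = i + d  # start in revcomp coordinates
            j = n - k - jp  # start of the partner seed on the forward strand
            sep = j - i
            if j > i and lo <= sep <= hi:
                hits.append((i, j))
    return sorted(set(hits))


SMALL = dict(min_ltr_len=100, max_ltr_len=500, min_element_len=2000, max_element_len=8000)


class TestSeedPairs:
    def test_planted_direct_repeat_gives_one_block(self):
        rng = np.random.default_rng(0)
        ltr = _rand_dna(rng, 300)
        seq = _rand_dna(rng, 2000) + ltr + _rand_dna(rng, 5000) + ltr + _rand_dna(rng, 2000)
        g = GenomeSequence("s", seq)
        params = DetectionParams(**SMALL)
        blocks = find_seed_pairs(g, params, "direct")
        assert len(blocks) == 1
        b = blocks[0]
        assert abs(b.start1 - 2000) <= 5 and abs(b.end1 - 2300) <= 5
        assert abs(b.start2 - 7300) <= 5 and abs(b.end2 - 7600) <= 5

    def test_inverted_repeat_found_only_in_inverted_mode(self):
        rng = np.random.default_rng(1)
        ltr = _rand_dna(rng, 300)
        seq = _rand_dna(rng, 1000) + ltr + _rand_dna(rng, 4500) + revcomp(ltr) + _rand_dna(rng, 1000)
        g = GenomeSequence("s", seq)
        params = DetectionParams(**SMALL)
        assert len(find_seed_pairs(g, params, "inverted")) == 1
        assert len(find_seed_pairs(g, params, "direct")) == 0

    def test_tandem_repeat_below_window_gives_no_block(self):
        rng = np.random.default_rng(2)
        unit = _rand_dna(rng, 300)
        seq = _rand_dna(rng, 2000) + unit + _rand_dna(rng, 500) + unit + _rand_dna(rng, 2000)
        g = GenomeSequence("s", seq)
        assert find_seed_pairs(g, DetectionParams(**SMALL), "direct") == []

    @pytest.mark.parametrize("mode", ["direct", "inverted"])
    def test_seed_enumeration_matches_brute_force(self, mode):
        """Detector seed hits equal the exhaustive shifted-comparison oracle
        on a sequence with planted repeats and an N run."""
        rng = np.random.default_rng(3)
        ltr = _rand_dna(rng, 250)
        partner = ltr if mode == "direct" else revcomp(ltr)
        seq = (
            _rand_dna(rng, 800)
            + ltr
            + _rand_dna(rng, 1500)
            + "N" * 50
            + _rand_dna(rng, 1500)
            + partner
            + _rand_dna(rng, 800)
        )
        params = DetectionParams(
            min_ltr_len=100, max_ltr_len=400, min_element_len=1500, max_element_len=6000
        )
        mine = seed_hits(seq, params, mode)
        oracle = (
            oracle_seed_hits_direct(seq, params)
            if mode == "direct"
            else oracle_seed_hits_inverted(seq, params)
        )
        assert mine == oracle
        assert len(mine) > 0


class TestRefinePair:
    def _scan_one(self, seq, params, mode="direct"):
        g = GenomeSequence("s", seq)
        blocks = find_seed_pairs(g, params, mode)
        assert blocks, "no anchor block found"
        pairs = [refine_pair(g, b, params) for b in blocks]
        pairs = [p for p in pairs if p is not None]
        return g, pairs

    def test_identical_ltrs_give_similarity_100(self):
        rng = np.random.default_rng(4)
        ltr = "TGT" + _rand_dna(rng, 294) + "ACA"
        seq = _rand_dna(rng, 1000) + ltr + _rand_dna(rng, 4000) + ltr + _rand_dna(rng, 1000)
        _, pairs = self._scan_one(seq, DetectionParams(**SMALL))
        assert pairs and pairs[0].similarity == 100.0
        assert (pairs[0].ltr5.start, pairs[0].ltr3.end) == (1000, 1000 + 300 + 4000 + 300)

    def test_twenty_bp_insert_drops_similarity_to_926(self):
        """A single 20 bp insert in one LTR of a 250 bp pair yields 250
        matches over 270 columns = 92.6% — the signature of a recent element
        whose low LTR similarity comes from one indel, not accumulated point
        mutations."""
        rng = np.random.default_rng(5)
        ltr = "TGT" + _rand_dna(rng, 244) + "ACA"
        ins = _rand_dna(rng, 20)
        ltr_ins = ltr[:125] + ins + ltr[125:]
        from ltrkit._align import dna_similarity

        # the alignment definition itself: 250 matches over 270 columns
        assert dna_similarity(ltr, ltr_ins) == pytest.approx(100 * 250 / 270, abs=0.1)
        seq = _rand_dna(rng, 1000) + ltr + _rand_dna(rng, 4000) + ltr_ins + _rand_dna(rng, 1000)
        _, pairs = self._scan_one(seq, DetectionParams(**SMALL))
        assert pairs
        # detected boundaries may wobble a few bp around the exact copies
        assert pairs[0].similarity == pytest.approx(100 * 250 / 270, abs=1.5)

    def test_heavily_diverged_pair_rejected(self):
        """25% scattered mismatches put the pair below the 80% floor."""
        rng = np.random.default_rng(6)
        ltr = "TGT" + _rand_dna(rng, 294) + "ACA"
        chars = list(ltr)
        positions = rng.choice(np.arange(3, 297), size=75, replace=False)
        for p in positions:
            chars[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[p]]
        ltr2 = "".join(chars)
        seq = _rand_dna(rng, 1000) + ltr + _rand_dna(rng, 4000) + ltr2 + _rand_dna(rng, 1000)
        g = GenomeSequence("s", seq)
        params = DetectionParams(**SMALL)
        pairs = [refine_pair(g, b, params) for b in find_seed_pairs(g, params, "direct")]
        assert all(p is None for p in pairs)


class TestFlankAndTsd:
    def _pair(self, seq, s1, e1, s2, e2):
        g = GenomeSequence("s", seq)
        return g, CandidatePair(
            scaffold="s",
            ltr5=Interval("s", s1, e1),
            ltr3=Interval("s", s2, e2),
            similarity=99.0,
            mode=RepeatMode.DIRECT,
        )

    def test_tgt_aca_flank_and_tsd_detected(self):
        rng = np.random.default_rng(7)
        ltr = "TGT" + _rand_dna(rng, 100) + "ACA"
        tsd = "GATCA"
        seq = _rand_dna(rng, 500) + tsd + ltr + _rand_dna(rng, 3000) + ltr + tsd + _rand_dna(rng, 500)
        s1 = 505
        g, pair = self._pair(seq, s1, s1 + 106, s1 + 106 + 3000, s1 + 106 + 3000 + 106)
        out = check_flank_and_tsd(g, pair, DetectionParams(**SMALL))
        assert out.flank_motif == "TGT/ACA"
        assert out.tsd == "GATCA"

    def test_longest_tsd_preferred(self):
        rng = np.random.default_rng(8)
        ltr = "TGT" + _rand_dna(rng, 100) + "ACA"
        tsd = "AACCGG"
        seq = _rand_dna(rng, 500) + tsd + ltr + _rand_dna(rng, 3000) + ltr + tsd + _rand_dna(rng, 500)
        s1 = 506
        g, pair = self._pair(seq, s1, s1 + 106, s1 + 106 + 3000, s1 + 106 + 3000 + 106)
        out = check_flank_and_tsd(g, pair, DetectionParams(**SMALL))
        assert out.tsd == "AACCGG"

    def test_require_tsd_rejects_when_absent(self):
        rng = np.random.default_rng(9)
        ltr = "TGT" + _rand_dna(rng, 100) + "ACA"
        seq = _rand_dna(rng, 500) + ltr + _rand_dna(rng, 3000) + ltr + _rand_dna(rng, 500)
        g, pair = self._pair(seq, 500, 606, 3606, 3712)
        strict = DetectionParams(require_tsd=True, **SMALL)
        relaxed = DetectionParams(**SMALL)
        assert check_flank_and_tsd(g, pair, strict) is None
        assert check_flank_and_tsd(g, pair, relaxed) is not None


class TestScanGenome:
    def test_planted_elements_recovered(self, planted):
        genomes, manifest, _ = planted
        direct_truth = [e for e in manifest["elements"] if e["repeat_mode"] == "direct"]
        cands = scan_genome(genomes, DetectionParams(), "direct")
        assert len(cands) == len(direct_truth)
        for cand, truth in zip(cands, direct_truth):
            assert abs(cand.ltr5.start - truth["start"]) <= 15
            assert abs(cand.ltr3.end - truth["end"]) <= 15

    def test_dirs_mode_finds_only_inverted_plants(self, planted):
        genomes, manifest, _ = planted
        dirs_truth = [e for e in manifest["elements"] if e["repeat_mode"] == "inverted"]
        cands = scan_genome(genomes, DetectionParams.dirs(), "inverted")
        assert len(cands) == len(dirs_truth)
        assert all(c.mode is RepeatMode.INVERTED for c in cands)
        direct_starts = {
            e["start"] for e in manifest["elements"] if e["repeat_mode"] == "direct"
        }
        for cand in cands:
            assert all(abs(cand.ltr5.start - s) > 100 for s in direct_starts)

    def test_random_background_yields_no_candidates(self):
        rng = np.random.default_rng(10)
        g = GenomeSequence("r", _rand_dna(rng, 100_000))
        assert scan_genome([g], DetectionParams(), "direct") == []

    def test_scan_is_deterministic(self, planted):
        genomes, _, _ = planted
        a = scan_genome(genomes, DetectionParams(), "direct")
        b = scan_genome(genomes, DetectionParams(), "direct")
        assert a == b

    def test_raising_similarity_floor_never_adds_candidates(self, planted):
        genomes, _, _ = planted
        counts = [
            len(scan_genome(genomes, DetectionParams(min_pair_similarity=s), "direct"))
            for s in (80.0, 90.0, 97.0, 99.5)
        ]
        assert counts == sorted(counts, reverse=True)
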