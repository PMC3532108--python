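"""Structural detector: paired repeats, motifs, library recovery."""

import numpy as np
import pytest

from trimkit import detector, synthetic
from trimkit.core_io import GenomeAssembly, Scaffold, revcomp
from trimkit.detector import (
    LibraryScanParams,
    LtrScanParams,
    MotifParams,
    ParameterError,
    detect_pbs,
    detect_ppt,
    find_ltr_pairs,
    find_ltr_pairs_assembly,
    scan_solo_and_truncated,
)


def _perfect_scaffold(ltr, internal, flank_seed=0):
    """Background + TSD-flanked perfect element at a known position."""
    rng = np.random.default_rng(flank_seed)
    left = synthetic._random_seq(rng, 3000, 0.37)
    right = synthetic._random_seq(rng, 3000, 0.37)
    element = ltr + internal + ltr
    seq = left + "ATAT" + element + "ATAT" + right
    start = 3004
    return Scaffold("s", seq), start, start + len(element)


class TestFindLtrPairs:
    def test_perfect_pair_recovered_exactly(self, ltr_template, internal_template):
        scaf, start, end = _perfect_scaffold(ltr_template, internal_template)
        hits = find_ltr_pairs(scaf)
        assert len(hits) == 1
        h = hits[0]
        assert (h.element_interval.start, h.element_interval.end) == (start, end)
        assert h.ltr_identity == 1.0
        assert h.tsd == "ATAT"
        assert h.termini_ok == (True, True)
        assert h.ltr5.length == h.ltr3.length == len(ltr_template)

    def test_random_scaffold_has_no_hits(self):
        rng = np.random.default_rng(17)
        scaf = Scaffold("r", synthetic._random_seq(rng, 50_000, 0.37))
        assert find_ltr_pairs(scaf) == []

    def test_identity_threshold_is_monotone(self, ltr_template, internal_template):
        # second copy mutated every 4th position (periodic, so no >=100 bp
        # window reaches 80% identity) with an intact 15-bp seed at the end
        ltr2 = list(ltr_template)
        for i in range(0, len(ltr2) - 15, 4):
            ltr2[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[ltr2[i]]
        ltr2 = "".join(ltr2)
        identity = sum(a == b for a, b in zip(ltr_template, ltr2)) / len(ltr2)
        assert 0.70 < identity < 0.80
        left = synthetic._random_seq(np.random.default_rng(22), 2000, 0.37)
        right = synthetic._random_seq(np.random.default_rng(23), 2000, 0.37)
        scaf = Scaffold("s", left + ltr_template + internal_template + ltr2 + right)
        strict = find_ltr_pairs(scaf, LtrScanParams(min_identity=0.80))
        lax = find_ltr_pairs(scaf, LtrScanParams(min_identity=0.70))
        assert strict == []
        assert len(lax) == 1

    def test_parameter_contradiction_rejected(self):
        with pytest.raises(ParameterError):
            LtrScanParams(min_ltr=300, max_ltr=200)
        with pytest.raises(ParameterError):
            LtrScanParams(min_ltr=40)

    def test_output_invariant_to_scaffold_order(self, small_planted):
        planted, _ = small_planted
        fwd = find_ltr_pairs_assembly(planted)
        rev = find_ltr_pairs_assembly(GenomeAssembly(planted.scaffolds[::-1]))
        key = lambda h: (h.scaffold_id, h.element_interval.start)
        assert sorted([(h.scaffold_id, h.element_interval.start,
                        h.element_interval.end) for h in fwd]) == \
               sorted([(h.scaffold_id, h.element_interval.start,
                        h.element_interval.end) for h in rev])

    def test_agrees_with_brute_force_on_small_scaffold(self):
        """Exhaustive repeat-pair oracle on a small sequence."""
        rng = np.random.default_rng(33)
        ltr = "TG" + synthetic._random_seq(rng, 56, 0.4) + "CA"  # 60 bp
        internal = synthetic._random_seq(rng, 80, 0.4)
        left = synthetic._random_seq(rng, 150, 0.4)
        right = synthetic._random_seq(rng, 150, 0.4)
        seq = left + ltr + internal + ltr + right
        params = LtrScanParams(k=12, min_ltr=50, max_ltr=80, min_internal=50,
                               max_internal=200, max_element=400,
                               min_identity=0.9)
        hits = find_ltr_pairs(Scaffold("t", seq), params)
        # oracle: exhaustive search over all (start, separation, length)
        # placements, scored with the detector's published objective
        # (+2/-3 plus termini and TSD bonuses)
        best = None
        n = len(seq)
        for L in range(params.min_ltr, params.max_ltr + 1):
            for a in range(0, n - L):
                for d in range(L + params.min_internal,
                               min(params.max_element - L,
                                   L + params.max_internal, n - L - a) + 1):
                    m = sum(seq[a + i] == seq[a + d + i] for i in range(L))
                    if m / L < params.min_identity:
                        continue
                    score = 2 * m - 3 * (L - m)
                    tg = seq[a : a + 2] == "TG" and seq[a + d : a + d + 2] == "TG"
                    ca = (seq[a + L - 2 : a + L] == "CA"
                          and seq[a + d + L - 2 : a + d + L] == "CA")
                    tsd = (a >= 4 and a + d + L + 4 <= n
                           and seq[a - 4 : a] == seq[a + d + L : a + d + L + 4])
                    total = (score + detector._TERMINI_BONUS * (tg + ca)
                             + detector._TSD_BONUS * tsd)
                    if best is None or total > best[0]:
                        best = (total, a, d, L)
        assert best is not None and len(hits) == 1
        _, a, d, L = best
        h = hits[0]
        assert (h.ltr5.start, h.ltr5.end) == (a, a + L)
        assert (h.ltr3.start, h.ltr3.end) == (a + d, a + d + L)


class TestMotifs:
    TRNA = ("tRNA-Leu-synthetic",
            "GCCGAAGTGGCGAAATCGGTAGACGCAGTTGATTCAAAATCAACCGTAGAAATACGTGCCGGTTCGAATCCCCA")

    def test_exact_pbs_at_offset_zero(self):
        trna = self.TRNA[1]
        probe = revcomp(trna[-15:])
        # choose following bases so that any longer window gains 2 mismatches
        block16 = {"A": "C", "C": "A", "G": "T", "T": "G"}[revcomp(trna[-16])]
        block17 = {"A": "C", "C": "A", "G": "T", "T": "G"}[revcomp(trna[-17])]
        internal = probe + block16 + block17 + "ACGTACGT"
        hit = detect_pbs(internal, [self.TRNA])
        assert hit is not None
        assert hit.interval.start == 0
        assert hit.interval.end == 15
        assert hit.score == 15
        assert hit.matched_trna == "tRNA-Leu-synthetic"

    def test_no_pbs_in_incompatible_sequence(self):
        hit = detect_pbs("C" * 40, [("t1", "A" * 40)])
        assert hit is None

    def test_pbs_tie_broken_by_trna_order(self):
        # two tRNAs whose 3' ends produce equal 12-base matches
        window = "TTTTACGTACGTACGT"
        probe12 = window[:12]
        t1 = ("first", "G" * 30 + revcomp(probe12))
        t2 = ("second", "C" * 30 + revcomp(probe12))
        hit = detect_pbs(window, [t1, t2],
                         MotifParams(pbs_max_mismatch=0))
        assert hit.matched_trna == "first"
        assert hit.score == 12

    def test_empty_trna_set_rejected(self):
        with pytest.raises(ParameterError):
            detect_pbs("ACGT" * 10, [])

    def test_pure_purine_ppt(self):
        internal = "CT" * 40 + "AAGGGAGGGAAGGAG"
        hit = detect_ppt(internal)
        assert hit is not None
        assert hit.score == 15
        assert hit.interval.end == len(internal)

    def test_pyrimidine_tail_has_no_ppt(self):
        assert detect_ppt("CT" * 40) is None

    def test_ppt_nearest_to_three_prime_ltr_wins(self):
        # a 30-bp purine run admits many qualifying windows; the one closest
        # to the 3' LTR (rightmost) must be returned
        internal = "C" * 30 + "GAAGGGAGGGAAGGA" + "AGGAGGGAAGGGAAG" + "CC"
        hit = detect_ppt(internal, MotifParams(ppt_search=40, ppt_min_purine=1.0))
        assert hit.interval.end == len(internal) - 2
        assert hit.score == 15


class TestLibraryScan:
    def test_planted_solo_with_tsd(self, small_planted, ltr_template):
        planted, registry = small_planted
        elements = scan_solo_and_truncated(planted, {"lib": ltr_template})
        solos = [e for e in elements if e.category == "solo_ltr"]
        truth = registry.by_category("solo_ltr")[0]
        match = [e for e in solos
                 if e.element_interval.start == truth.interval.start
                 and e.element_interval.end == truth.interval.end]
        assert match and match[0].tsd == truth.tsd

    def test_partial_ltr_fragment_is_truncated(self, ltr_template):
        rng = np.random.default_rng(41)
        frag = ltr_template[: int(0.6 * len(ltr_template))]
        seq = (synthetic._random_seq(rng, 2000, 0.37) + frag
               + synthetic._random_seq(rng, 2000, 0.37))
        asm = GenomeAssembly([Scaffold("s", seq)])
        elements = scan_solo_and_truncated(asm, {"lib": ltr_template})
        assert [e.category for e in elements] == ["truncated"]

    def test_hits_inside_complete_candidates_are_absorbed(
            self, ltr_template, internal_template):
        scaf, start, end = _perfect_scaffold(ltr_template, internal_template)
        asm = GenomeAssembly([scaf])
        complete = find_ltr_pairs(scaf)
        elements = scan_solo_and_truncated(asm, {"lib": ltr_template}, complete)
        assert all(not e.element_interval.overlaps(complete[0].element_interval)
                   for e in elements)
        assert elements == []

    def test_empty_library_rejected(self, small_planted):
        with pytest.raises(ParameterError):
            scan_solo_and_truncated(small_planted[0], {})

    def test_minus_strand_solo_found(self, ltr_template):
        rng = np.random.default_rng(47)
        seq = (synthetic._random_seq(rng, 2000, 0.37) + revcomp(ltr_template)
               + synthetic._random_seq(rng, 2000, 0.37))
        asm = GenomeAssembly([Scaffold("s", seq)])
        elements = scan_solo_and_truncated(asm, {"lib": ltr_template})
        assert len(elements) == 1
        assert elements[0].category == "solo_ltr"
        assert elements[0].element_interval.strand == "-"
        assert (elements[0].element_interval.start,
                elements[0].element_interval.end) == (2000, 2000 + len(ltr_template))
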