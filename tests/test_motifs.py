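"""Shuffles, PSSM scanning, k-mer enrichment and abstract shapes."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import brute_pssm_tail
from sdscan.motifs import (
    MotifStat,
    abstract_shape,
    build_pssm,
    dicodon_shuffle,
    dinucleotide_shuffle,
    generate_background,
    kmer_enrichment,
    pssm_best_match,
    pssm_pvalue,
    pssm_scan,
    shape_motif_test,
    sub_shapes,
)

dna = st.text(alphabet="ACGT", min_size=2, max_size=60)


class TestShuffles:
    @given(dna)
    def test_dinucleotide_counts_and_endpoints_preserved(self, seq):
        out = dinucleotide_shuffle(seq, np.random.default_rng(0))
        assert Counter(zip(seq, seq[1:])) == Counter(zip(out, out[1:]))
        assert out[0] == seq[0] and out[-1] == seq[-1]
        assert Counter(out) == Counter(seq)

    def test_aatt_unique_arrangement(self):
        rng = np.random.default_rng(1)
        assert {dinucleotide_shuffle("AATT", rng) for _ in range(100)} == {"AATT"}

    def test_seeded_reproducibility(self):
        s = "ACGTACGGTTACCAGTACGT"
        a = dinucleotide_shuffle(s, np.random.default_rng(42))
        b = dinucleotide_shuffle(s, np.random.default_rng(42))
        assert a == b

    def test_dicodon_pairs_preserved(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(["AAA", "CCC", "GGG", "TTT", "ACG", "GCA"], 30))
        out = dicodon_shuffle(seq, rng)

        def pairs(s):
            cods = [s[i : i + 3] for i in range(0, len(s), 3)]
            return Counter(zip(cods, cods[1:]))

        assert pairs(seq) == pairs(out)

    def test_two_codons_unchanged(self):
        assert dicodon_shuffle("AAACCC", np.random.default_rng(0)) == "AAACCC"

    def test_remainder_held_fixed_with_warning(self):
        with pytest.warns(UserWarning):
            out = dicodon_shuffle("AAACCCGGGTT", np.random.default_rng(0))
        assert out.endswith("TT") and len(out) == 11

    def test_shuffle_actually_moves(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(["AAA", "CCC", "GGG", "TTT", "ACG"], 30))
        moved = sum(dicodon_shuffle(seq, np.random.default_rng(s)) != seq
                    for s in range(20))
        assert moved > 10


class TestPssm:
    def test_single_site_zero_pseudocount_consensus_maximal(self):
        p = build_pssm(["GGAGG"], pseudocount=0.0)
        top = p.score("GGAGG")
        assert all(p.score("GGAGG"[:k] + b + "GGAGG"[k + 1 :]) < top
                   for k in range(5) for b in "ACT" if "GGAGG"[k] != b)

    def test_identical_sites_consensus_beats_one_mismatch(self):
        p = build_pssm(["GGAGG"] * 5, pseudocount=0.5)
        assert p.score("GGAGG") > p.score("GGCGG")

    def test_column_frequencies_round_trip(self):
        sites = ["ACG", "ACG", "ATG", "GCG"]
        p = build_pssm(sites, pseudocount=0.0)
        # invert log-odds back to frequencies and compare with counts
        freq = p.background[:, None] * 2.0**p.log_odds
        counts = np.zeros((4, 3))
        for s in sites:
            for k, b in enumerate(s):
                counts["ACGT".index(b), k] += 1
        observed = counts > 0  # zero-count cells carry the floored log-odds
        assert np.allclose(freq[observed], (counts / len(sites))[observed])

    @pytest.mark.parametrize("width", [1, 2, 3])
    def test_pvalue_dp_equals_enumeration(self, width):
        rng = np.random.default_rng(width)
        sites = ["".join(rng.choice(list("ACGT"), width)) for _ in range(6)]
        p = build_pssm(sites, pseudocount=0.5,
                       background=[0.3, 0.2, 0.2, 0.3])
        for _ in range(20):
            w = "".join(rng.choice(list("ACGT"), width))
            got = pssm_pvalue(p, p.score(w))
            assert got == pytest.approx(brute_pssm_tail(p, p.score(w)), abs=1e-12)

    def test_pvalues_monotone_in_score(self):
        p = build_pssm(["GGAGG", "GGAGG", "GGTGG"], pseudocount=0.5)
        scores = sorted(p.score("".join(w)) for w in
                        (["GGAGG"], ["GGTGG"], ["AAAAA"], ["GCAGG"]))
        ps = [pssm_pvalue(p, s) for s in scores]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_uniform_pssm_every_window_p1(self):
        p = build_pssm(["A", "C", "G", "T"], pseudocount=0.0)
        matches = pssm_scan(p, "ACGTACGT", p_threshold=0.5)
        assert matches == []  # every window has p = 1
        assert pssm_pvalue(p, p.score("A")) == pytest.approx(1.0)

    def test_perfect_match_p_positive(self):
        p = build_pssm(["GGAGG"] * 3, pseudocount=0.5)
        m = pssm_best_match(p, "TTTTGGAGGTTTT")
        assert m.position == 4 and 0 < m.p_value < 0.01

    def test_unequal_site_lengths_error(self):
        with pytest.raises(ValueError):
            build_pssm(["ACG", "AC"])


class TestBackgroundAndEnrichment:
    def test_background_size_and_composition(self):
        rng = np.random.default_rng(0)
        seqs = ["ACGTACGTAC", "GGGTTTCCCA"]
        bg = generate_background(seqs, n_copies=5, rng=rng)
        assert len(bg) == 10
        for i, b in enumerate(bg):
            assert Counter(b) == Counter(seqs[i // 5])

    def test_planted_motif_top_ranked(self):
        rng = np.random.default_rng(7)
        motif = "GGAGGT"
        target = []
        for i in range(80):
            s = "".join(rng.choice(list("ACGT"), 30))
            if i < 48:  # 60% carry the motif
                s = s[:10] + motif + s[16:]
            target.append(s)
        background = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(400)]
        stats = kmer_enrichment(target, background, k=6,
                                n_label_permutations=20, rng=rng)
        assert stats[0].motif == motif
        assert stats[0].p_corrected <= 1 / 21 + 1e-12

    def test_target_equals_background_null(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), 25)) for _ in range(60)]
        stats = kmer_enrichment(seqs, list(seqs), k=4,
                                n_label_permutations=10, rng=rng)
        assert min(s.p_corrected for s in stats) > 0.5

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            kmer_enrichment(["ACGT"], [], k=2)


class TestShapes:
    @pytest.mark.parametrize(
        "structure, shape",
        [
            ("((((....))))", "[]"),
            ("((..((...))))", "[_[]]"),
            (".((...))..((...)).", "[]_[]"),
            ("((..((...))..))", "[_[]_]"),
            ("((...))", "[]"),
            ("............", ""),
            ("((((....))))(((...)))", "[][]"),
        ],
    )
    def test_reduction_rules(self, structure, shape):
        assert abstract_shape(structure) == shape

    @pytest.mark.parametrize("stem", [2, 4, 8])
    @pytest.mark.parametrize("loop", [3, 5, 9])
    def test_invariant_under_stem_and_loop_resizing(self, stem, loop):
        hairpin = "(" * stem + "." * loop + ")" * stem
        assert abstract_shape(hairpin) == "[]"
        nested = "((.." + hairpin + "))"
        assert abstract_shape(nested) == "[_[]]"

    def test_levels(self):
        assert abstract_shape("((((....))))", level="keep-all") == "[_]"
        assert abstract_shape("((..((...))))", level="drop-all-unpaired") == "[[]]"

    def test_unbalanced_rejected(self):
        for bad in ("((..)", "))((", "(.x.)"):
            with pytest.raises(ValueError):
                abstract_shape(bad)

    def test_sub_shapes_balanced_and_trimmed(self):
        assert sub_shapes("[]_[]") == {"[]", "[]_[]"}
        assert sub_shapes("[_[]]") == {"[_[]]", "[]"}
        assert all(s == s.strip("_") for s in sub_shapes("[_[]_[]_]"))


class TestShapeMotifTest:
    def _regions(self, rng, n=20):
        out = []
        for _ in range(n):
            s = "".join(rng.choice(list("ACGT"), 50))
            out.append(s)
        return out

    def test_hairpin_motif_ubiquitous_hence_insignificant(self):
        """A single hairpin appears in essentially every folded natural-like
        region and every shuffled null, so its empirical p is ~1."""
        rng = np.random.default_rng(12)
        stats = shape_motif_test(self._regions(rng), n_iter=30, rng=rng)
        by_motif = {s.motif: s for s in stats}
        assert "[]" in by_motif
        assert by_motif["[]"].p_value > 0.5

    def test_planted_complementarity_significant(self):
        """A stem designed across the coding boundary survives in targets but
        is destroyed by shuffling the non-coding half."""
        rng = np.random.default_rng(13)
        regions = []
        for _ in range(15):
            mid = "".join(rng.choice(list("A"), 4))
            arm = "GCGCGCGCGC"
            # arm in non-coding half pairs its complement in the fixed half
            nc = ("".join(rng.choice(list("AT"), 11)) + arm + mid)[:25]
            cod = "GCGCGCGCGC"[::-1].translate(str.maketrans("GC", "CG")) + \
                "".join(rng.choice(list("AT"), 15))
            regions.append(nc + cod)
        stats = shape_motif_test(regions, n_iter=99, rng=rng)
        assert min(s.p_value for s in stats) <= 0.05

    def test_plus_one_rule_never_zero(self):
        rng = np.random.default_rng(14)
        stats = shape_motif_test(self._regions(rng, 5), n_iter=10, rng=rng)
        assert all(s.p_value >= 1 / 11 for s in stats)
        assert all(isinstance(s, MotifStat) for s in stats)

    def test_n_iter_validation(self):
        with pytest.raises(ValueError):
            shape_motif_test(["A" * 50], n_iter=0)
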