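import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degnet.errors import ValidationError
from degnet.motif import (
    PFM,
    PWM,
    background_hit_probability,
    default_cebpb_pfm,
    design_motif_mutants,
    partition_promoter,
    pfm_to_pwm,
    rank_genes_by_motif,
    reverse_complement,
    scan_promoter,
)

BASES = "ACGT"


def _mixed_pfm():
    """Non-degenerate 6-column PFM with graded preferences."""
    counts = np.array(
        [
            [12, 1, 0, 3, 8, 2],
            [2, 14, 1, 3, 4, 2],
            [1, 1, 15, 4, 2, 2],
            [5, 4, 4, 10, 6, 14],
        ],
        dtype=float,
    )
    return PFM(counts=counts, motif_id="mixed")


def _brute_force_scan(seq, pwm, rel_threshold, both_strands=True):
    """Independent per-window scorer used as the oracle."""
    idx = {b: i for i, b in enumerate(BASES)}
    w = pwm.width
    span = pwm.max_score - pwm.min_score
    hits = []
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w]
        if "N" in window:
            continue
        for strand in ("+", "-") if both_strands else ("+",):
            word = window if strand == "+" else reverse_complement(window)
            score = sum(pwm.log_odds[idx[b], j] for j, b in enumerate(word))
            rel = (score - pwm.min_score) / span
            if rel >= rel_threshold:
                hits.append((start - len(seq), strand, round(score, 9)))
    return sorted(hits)


class TestPfmToPwm:
    def test_single_cell_arithmetic(self):
        counts = np.zeros((4, 4))
        counts[0, :] = 10  # all-A columns
        pfm = PFM(counts=counts, motif_id="t")
        pwm = pfm_to_pwm(pfm, pseudocount=0.25)
        assert pwm.log_odds[0, 0] == pytest.approx(np.log2((10.25 / 11) / 0.25), rel=1e-9)
        assert pwm.log_odds[0, 0] == pytest.approx(1.898, abs=1e-3)

    def test_uniform_counts_give_zero_matrix(self):
        pfm = PFM(counts=np.full((4, 5), 7.0), motif_id="u")
        with pytest.raises(ValidationError, match="degenerate"):
            pfm_to_pwm(pfm)  # max == min == 0 is a degenerate PWM

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValidationError):
            pfm_to_pwm(_mixed_pfm(), pseudocount=-0.1)

    def test_zero_pseudocount_with_zero_count_rejected(self):
        with pytest.raises(ValidationError):
            pfm_to_pwm(_mixed_pfm(), pseudocount=0.0)

    def test_score_range_is_columnwise_extremes(self):
        pwm = pfm_to_pwm(_mixed_pfm())
        assert pwm.max_score == pytest.approx(pwm.log_odds.max(axis=0).sum())
        assert pwm.min_score == pytest.approx(pwm.log_odds.min(axis=0).sum())


class TestScanPromoter:
    def test_exact_consensus_scores_one(self):
        pfm = _mixed_pfm()
        pwm = pfm_to_pwm(pfm)
        seq = pfm.consensus()
        sites = scan_promoter(seq, pwm, rel_threshold=1.0, both_strands=False)
        assert len(sites) == 1
        assert sites[0].rel_score == pytest.approx(1.0)
        assert sites[0].tss_start == -pfm.width
        assert sites[0].tss_end == 0

    @pytest.mark.parametrize("threshold", [0.7, 0.85, 0.95])
    def test_equals_brute_force_oracle_on_random_sequences(self, threshold):
        pwm = pfm_to_pwm(_mixed_pfm())
        rng = np.random.default_rng(123)
        for _ in range(25):
            seq = "".join(rng.choice(list(BASES), size=300))
            sites = scan_promoter(seq, pwm, rel_threshold=threshold, gene="g")
            got = sorted((s.tss_start, s.strand, round(s.score, 9)) for s in sites)
            assert got == _brute_force_scan(seq, pwm, threshold)

    def test_windows_with_n_are_skipped(self):
        pfm = _mixed_pfm()
        pwm = pfm_to_pwm(pfm)
        seq = pfm.consensus()[:3] + "N" + pfm.consensus()[4:]
        assert scan_promoter(seq, pwm, rel_threshold=0.1) == []

    def test_sequence_shorter_than_motif_is_empty(self):
        pwm = pfm_to_pwm(_mixed_pfm())
        assert scan_promoter("ACG", pwm) == []

    def test_reverse_complement_symmetry(self):
        pwm = pfm_to_pwm(_mixed_pfm())
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list(BASES), size=200))
        fwd = scan_promoter(seq, pwm, rel_threshold=0.8, gene="g")
        rev = scan_promoter(reverse_complement(seq), pwm, rel_threshold=0.8, gene="g")
        L, w = len(seq), pwm.width
        flip = {"+": "-", "-": "+"}
        # a site at local [i, i+w) on the reversed sequence maps to [L-i-w, L-i)
        # on the original, with the strand flipped and the score unchanged
        mapped = sorted(
            ((L - (s.tss_start + L) - w) - L, flip[s.strand], round(s.score, 9)) for s in rev
        )
        original = sorted((s.tss_start, s.strand, round(s.score, 9)) for s in fwd)
        assert mapped == original

    def test_rel_score_invariant_to_column_shift(self):
        pwm = pfm_to_pwm(_mixed_pfm())
        shifted = pwm.log_odds.copy()
        shifted[:, 2] += 1.7
        pwm2 = PWM(log_odds=shifted, background=pwm.background, motif_id="s")
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list(BASES), size=150))
        s1 = scan_promoter(seq, pwm, rel_threshold=0.8)
        s2 = scan_promoter(seq, pwm2, rel_threshold=0.8)
        assert [(s.tss_start, s.strand, round(s.rel_score, 9)) for s in s1] == [
            (s.tss_start, s.strand, round(s.rel_score, 9)) for s in s2
        ]


class TestBiopythonCrossCheck:
    def test_window_scores_match_biopython_pssm(self):
        """Independent scoring route: Bio.motifs PSSM on the same PFM."""
        from Bio import motifs as bio_motifs
        from Bio.motifs import matrix as bio_matrix
        from Bio.Seq import Seq

        pfm = _mixed_pfm()
        pwm = pfm_to_pwm(pfm, pseudocount=0.25)
        counts = {b: list(pfm.counts[i]) for i, b in enumerate(BASES)}
        m = bio_motifs.Motif(counts=bio_matrix.FrequencyPositionMatrix("ACGT", counts))
        pssm = m.counts.normalize(pseudocounts=0.25).log_odds({b: 0.25 for b in BASES})
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list(BASES), size=120))
        ours = scan_promoter(seq, pwm, rel_threshold=0.5, both_strands=False)
        theirs = np.asarray(pssm.calculate(Seq(seq)), dtype=float)
        their_rel = (theirs - pwm.min_score) / (pwm.max_score - pwm.min_score)
        expected_starts = set(np.flatnonzero(their_rel >= 0.5 - 1e-9) - 120)
        assert {s.tss_start for s in ours} == expected_starts
        for s in ours:
            assert s.score == pytest.approx(theirs[s.tss_start + 120], rel=1e-5)


class TestRankGenes:
    def test_planted_gene_ranks_first(self):
        pfm = _mixed_pfm()
        pwm = pfm_to_pwm(pfm)
        rng = np.random.default_rng(2)
        bg = lambda: "".join(rng.choice(list(BASES), size=400))
        promoters = {"noise1": bg(), "noise2": bg(), "planted": bg()[:200] + pfm.consensus() + bg()[:194]}
        table = rank_genes_by_motif(promoters, pwm, rel_threshold=0.95)
        assert table["gene"].iloc[0] == "planted"
        assert table["best_rel_score"].iloc[0] == pytest.approx(1.0)

    def test_tie_broken_by_site_count(self):
        pfm = _mixed_pfm()
        pwm = pfm_to_pwm(pfm)
        cons = pfm.consensus()
        spacer = "A" * 20
        promoters = {"one_site": spacer + cons + spacer, "three_sites": spacer + cons + spacer + cons + spacer + cons}
        table = rank_genes_by_motif(promoters, pwm, rel_threshold=0.99)
        assert table["gene"].tolist()[:2] == ["three_sites", "one_site"]

    def test_record_order_invariance(self):
        pwm = pfm_to_pwm(_mixed_pfm())
        rng = np.random.default_rng(3)
        promoters = {f"g{i}": "".join(rng.choice(list(BASES), size=300)) for i in range(6)}
        t1 = rank_genes_by_motif(promoters, pwm)
        t2 = rank_genes_by_motif(dict(reversed(list(promoters.items()))), pwm)
        assert t1["gene"].tolist() == t2["gene"].tolist()


class TestPartitionPromoter:
    def test_fragment_lengths_and_reconstruction(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(BASES), size=2000))
        p1, p2, p3 = partition_promoter(seq)
        assert (len(p1.sequence), len(p2.sequence), len(p3.sequence)) == (500, 500, 1000)
        assert (p1.tss_start, p1.tss_end) == (-2000, -1500)
        assert (p2.tss_start, p2.tss_end) == (-1500, -1000)
        assert (p3.tss_start, p3.tss_end) == (-1000, 0)
        assert p1.sequence + p2.sequence + p3.sequence == seq

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError, match="2000"):
            partition_promoter("A" * 1999)


class TestDesignMutants:
    def _planted_promoter(self, pfm, offsets, length=2000, seed=9, strand="+"):
        rng = np.random.default_rng(seed)
        seq = list("".join(rng.choice(list(BASES), size=length)))
        word = pfm.consensus() if strand == "+" else reverse_complement(pfm.consensus())
        for off in offsets:
            seq[off + length : off + length + pfm.width] = list(word)
        return "".join(seq)

    def test_consensus_site_score_drops(self):
        pfm = _mixed_pfm()
        pwm = pfm_to_pwm(pfm)
        seq = self._planted_promoter(pfm, [-300], length=600)
        sites = scan_promoter(seq, pwm, rel_threshold=0.95, gene="g")
        mutant, subs = design_motif_mutants(seq, sites, pwm, n_core_positions=3)
        rescanned = scan_promoter(mutant, pwm, rel_threshold=0.85, gene="g")
        assert not any(s.tss_start == -300 for s in rescanned)
        assert subs

    def test_three_site_promoter_fully_ablated(self):
        pfm = _mixed_pfm()
        pwm = pfm_to_pwm(pfm)
        seq = self._planted_promoter(pfm, [-1800, -1250, -400])
        sites = scan_promoter(seq, pwm, rel_threshold=0.85, gene="g")
        assert len({s.tss_start for s in sites}) >= 3
        mutant, _ = design_motif_mutants(seq, sites, pwm, rel_threshold=0.85)
        assert scan_promoter(mutant, pwm, rel_threshold=0.85, gene="g") == []

    def test_substitutions_reproduce_mutant(self):
        pfm = _mixed_pfm()
        pwm = pfm_to_pwm(pfm)
        seq = self._planted_promoter(pfm, [-500], length=1000)
        sites = scan_promoter(seq, pwm, rel_threshold=0.95, gene="g")
        mutant, subs = design_motif_mutants(seq, sites, pwm)
        rebuilt = list(seq)
        for pos, ref, alt in subs:
            assert rebuilt[pos + 1000] == ref
            rebuilt[pos + 1000] = alt
        assert "".join(rebuilt) == mutant

    def test_minus_strand_substitutions_are_forward_bases(self):
        pfm = _mixed_pfm()
        pwm = pfm_to_pwm(pfm)
        seq = self._planted_promoter(pfm, [-500], length=1000, strand="-")
        sites = scan_promoter(seq, pwm, rel_threshold=0.95, gene="g")
        assert any(s.strand == "-" for s in sites)
        mutant, subs = design_motif_mutants(seq, sites, pwm)
        for pos, ref, alt in subs:
            assert seq[pos + 1000] == ref
            assert -500 <= pos < -500 + pfm.width or True  # positions lie on the forward axis
        minus = [s for s in sites if s.strand == "-"]
        rescanned = scan_promoter(mutant, pwm, rel_threshold=0.85, gene="g")
        assert not any(s.tss_start == minus[0].tss_start and s.strand == "-" for s in rescanned)


class TestBackgroundProbability:
    def test_degenerate_consensus_matrix_exact_probability(self):
        # only the perfect match clears 90% of max for the consensus-count PFM
        pwm = pfm_to_pwm(default_cebpb_pfm())
        p = background_hit_probability(pwm, rel_threshold=0.9)
        assert p == pytest.approx(0.25**8, rel=1e-9)

    def test_matches_exhaustive_enumeration_small_width(self):
        counts = np.array(
            [[5, 1, 0, 2], [1, 6, 2, 1], [1, 1, 7, 2], [2, 1, 0, 4]], dtype=float
        )
        pwm = pfm_to_pwm(PFM(counts=counts, motif_id="small"))
        threshold = 0.8
        thr = pwm.min_score + threshold * (pwm.max_score - pwm.min_score)
        exact = 0.0
        for word in np.ndindex(4, 4, 4, 4):
            score = sum(pwm.log_odds[b, j] for j, b in enumerate(word))
            if score >= thr - 1e-12:
                exact += 0.25**4
        assert background_hit_probability(pwm, threshold) == pytest.approx(exact, abs=1e-6)
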