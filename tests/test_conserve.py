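"""Local alignment, homologous-site mapping, class assignment and
conservation scoring."""

from functools import lru_cache

import numpy as np
import pytest

from psiquant import conserve
from psiquant.conserve import AlignmentScoring, smith_waterman
from psiquant.synthdata import make_orthologue_fixture

SCORING = AlignmentScoring(match=2, mismatch=-1, gap=-2)


def brute_force_local_score(a: str, b: str, sc: AlignmentScoring) -> float:
    """Independent oracle: maximise the global alignment score over every
    substring pair, with global scores from a plain top-down recursion."""

    def global_score(x: str, y: str) -> float:
        @lru_cache(maxsize=None)
        def f(i: int, j: int) -> float:
            if i == 0 and j == 0:
                return 0.0
            cands = []
            if i > 0 and j > 0:
                cands.append(
                    f(i - 1, j - 1)
                    + (sc.match if x[i - 1] == y[j - 1] else sc.mismatch)
                )
            if i > 0:
                cands.append(f(i - 1, j) + sc.gap)
            if j > 0:
                cands.append(f(i, j - 1) + sc.gap)
            return max(cands)

        return f(len(x), len(y))

    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, global_score(a[i0:i1], b[j0:j1]))
    return best


class TestSmithWaterman:
    def test_identical_sequences_full_match(self):
        aln = smith_waterman("ACGT", "ACGT", SCORING)
        assert aln.score == 8
        assert aln.columns == [(1, 1), (2, 2), (3, 3), (4, 4)]

    def test_no_similarity_empty_alignment(self):
        aln = smith_waterman("GGG", "CCC", SCORING)
        assert aln.score == 0
        assert aln.columns == []

    def test_matches_exhaustive_enumeration_on_short_pairs(self, rng):
        for _ in range(60):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 9)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 9)))
            assert smith_waterman(a, b, SCORING).score == pytest.approx(
                brute_force_local_score(a, b, SCORING)
            )

    def test_score_symmetric_and_monotone_in_match_reward(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=20))
            b = "".join(rng.choice(list("ACGT"), size=20))
            assert smith_waterman(a, b, SCORING).score == smith_waterman(
                b, a, SCORING
            ).score
            richer = AlignmentScoring(match=3, mismatch=-1, gap=-2)
            assert smith_waterman(a, b, richer).score >= smith_waterman(
                a, b, SCORING
            ).score

    def test_alignment_columns_reproduce_the_score(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=30))
        b = "".join(rng.choice(list("ACGT"), size=30))
        aln = smith_waterman(a, b, SCORING)
        total = 0.0
        for i, j in aln.columns:
            if i is None or j is None:
                total += SCORING.gap
            elif a[i - 1] == b[j - 1]:
                total += SCORING.match
            else:
                total += SCORING.mismatch
        assert total == pytest.approx(aln.score)

    def test_agrees_with_independent_aligner(self, rng):
        """Cross-check the optimal score against biotite's aligner under the
        same scoring model."""
        biotite_seq = pytest.importorskip("biotite.sequence")
        import biotite.sequence.align as bsa

        alph = biotite_seq.NucleotideSequence.alphabet_unamb
        mat = bsa.SubstitutionMatrix(
            alph, alph, np.where(np.eye(4, dtype=int), 2, -1)
        )
        for _ in range(5):
            a = "".join(rng.choice(list("ACGT"), size=80))
            b = "".join(rng.choice(list("ACGT"), size=80))
            ours = smith_waterman(a, b, SCORING).score
            theirs = bsa.align_optimal(
                biotite_seq.NucleotideSequence(a),
                biotite_seq.NucleotideSequence(b),
                mat, gap_penalty=-2, local=True,
            )[0].score
            assert ours == pytest.approx(theirs)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT", SCORING)


class TestHomologousSiteMapping:
    def test_identity_alignment_maps_position_to_itself(self):
        aln = smith_waterman("AATAA", "AATAA", SCORING)
        mapped = conserve.map_homologous_sites(aln, [3], "AATAA")
        assert mapped["aligned_base"].iloc[0] == "T"
        assert mapped["pos_b"].iloc[0] == 3

    def test_position_outside_local_window_is_none(self):
        # only the first half aligns
        aln = smith_waterman("ACGTACGT" + "TTTTTTTT", "ACGTACGT", SCORING)
        mapped = conserve.map_homologous_sites(aln, [16], "ACGTACGT")
        assert mapped["aligned_base"].iloc[0] == "none"

    def test_matches_column_walk_oracle(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=25))
            b = "".join(rng.choice(list("ACGT"), size=25))
            aln = smith_waterman(a, b, SCORING)
            positions = list(rng.integers(1, 26, size=5))
            mapped = conserve.map_homologous_sites(aln, positions, b)
            # independent walk over the column list
            walk = {}
            for i, j in aln.columns:
                if i is not None:
                    walk[i] = j
            for pos, row in zip(positions, mapped.itertuples()):
                if pos not in walk:
                    assert row.aligned_base == "none"
                elif walk[pos] is None:
                    assert row.aligned_base == "gap"
                else:
                    assert row.aligned_base == b[walk[pos] - 1]


class TestClassAssignment:
    def test_one_to_one_conserved_u(self):
        assert conserve.classify_site_pair(["T"]) == 3

    def test_homologous_but_not_u(self):
        assert conserve.classify_site_pair(["C"]) == 2

    def test_no_homologous_site(self):
        assert conserve.classify_site_pair(["none"]) == 1
        assert conserve.classify_site_pair(["gap"]) == 1

    def test_multiple_homologous_u_partners(self):
        assert conserve.classify_site_pair(["T", "T"]) == 4
        assert conserve.classify_site_pair(["T", "C", "T"]) == 4

    def test_partition_and_planted_class_recovery(self):
        fixture = make_orthologue_fixture(seed=2, n_per_class=5)
        results = []
        for gid, group in fixture.truth.groupby("gene_a"):
            out = conserve.classify_conservation(
                fixture.seqs_a[gid], fixture.partners[gid], group["pos"].tolist()
            )
            results.append((out["class"].iloc[0], group["true_class"].iloc[0]))
        assert all(got == want for got, want in results)
        got_classes = [g for g, _ in results]
        conserved = sum(1 for c in got_classes if c in (3, 4))
        non_conserved = sum(1 for c in got_classes if c in (1, 2))
        assert conserved + non_conserved == len(results)


class TestConservationScore:
    def test_identical_sequences_constant_track_scales_to_zero(self):
        with pytest.warns(UserWarning):
            prof = conserve.conservation_score(["ACGT"] * 4, window=2)
        assert np.allclose(prof.raw, 1.0)
        assert np.allclose(prof.scaled, 0.0)

    def test_half_split_column_pairwise_identity(self):
        # column A,A,C,C -> 2 identical pairs of C(4,2)=6
        prof = conserve.conservation_score(["A", "A", "C", "C"], window=1)
        assert prof.raw[0] == pytest.approx(2 / 6)

    def test_min_max_scaling(self):
        msa = ["AAC", "AAC", "AAG", "ATG"]  # columns raw 1, 2/6... construct directly
        prof = conserve.conservation_score(msa, window=1)
        lo, hi = prof.raw.min(), prof.raw.max()
        expect = (prof.raw - lo) / (hi - lo)
        assert np.allclose(prof.scaled, expect)

    def test_invariant_under_row_reordering(self, rng):
        msa = ["".join(rng.choice(list("ACGT-"), size=40)) for _ in range(5)]
        p1 = conserve.conservation_score(msa, window=5)
        p2 = conserve.conservation_score(msa[::-1], window=5)
        assert np.allclose(p1.raw, p2.raw)
        assert np.allclose(p1.scaled, p2.scaled)

    def test_all_gap_column_scores_zero(self):
        prof = conserve.conservation_score(["A-A", "A-A", "C-C"], window=1)
        assert prof.raw[1] == 0.0


class TestDensityConservationCorrelation:
    def test_sites_in_conserved_windows_correlate_positively(self):
        scaled = np.concatenate([np.ones(50), np.zeros(50), np.ones(50),
                                 np.zeros(50), np.ones(50)])
        prof = conserve.ConservationProfile(raw=scaled, scaled=scaled, window=50)
        sites = [5, 10, 20, 110, 115, 120, 210, 215, 220, 230]
        r, p = conserve.density_conservation_correlation(prof, sites, window=50)
        assert r > 0

    def test_hand_computed_five_window_case(self):
        scaled = np.repeat([0.1, 0.3, 0.5, 0.7, 0.9], 10)
        prof = conserve.ConservationProfile(raw=scaled, scaled=scaled, window=10)
        sites = [1, 2, 12, 22, 23, 24, 32, 33, 42, 43, 44, 45]
        density = np.array([2, 1, 3, 2, 4], dtype=float)
        cons = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        dx, cx = density - density.mean(), cons - cons.mean()
        expect = float((dx * cx).sum() / np.sqrt((dx**2).sum() * (cx**2).sum()))
        r, _ = conserve.density_conservation_correlation(prof, sites, window=10)
        assert r == pytest.approx(expect)

    def test_too_few_windows_rejected(self):
        prof = conserve.ConservationProfile(
            raw=np.ones(60), scaled=np.ones(60), window=50
        )
        with pytest.raises(ValueError):
            conserve.density_conservation_correlation(prof, [1], window=50)


def test_center_star_msa_handles_indels():
    msa = conserve.center_star_msa(["ACGTACGT", "ACGACGT", "ACGTACGTT"])
    assert len({len(row) for row in msa}) == 1
    assert msa[0].replace("-", "") == "ACGTACGT"
    assert msa[1].replace("-", "") == "ACGACGT"
    assert msa[2].replace("-", "") == "ACGTACGTT"
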