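import math

import numpy as np
import pytest

from viromimic import _kernels
from viromimic.align_core import (
    AA20,
    SearchParams,
    SubstitutionMatrix,
    blosum62,
    compute_ka_params,
    evalue,
    mask_low_complexity,
    min_score_for_evalue,
    reverse_complement,
    seeded_search,
    smith_waterman_affine,
    translate,
)
from viromimic.fragmenter import fragment_set
from viromimic.mimicry_sim import mutate_to_identity, reverse_translate
from viromimic.seqio import SeqRecord

from conftest import random_dna, random_protein
from oracles import sw_affine_score, window_entropy


def toy_matrix():
    scores = np.full((4, 4), -1, dtype=int)
    np.fill_diagonal(scores, 1)
    return SubstitutionMatrix("toy", "ACGT", scores, np.full(4, 0.25))


class TestTranslate:
    @pytest.mark.parametrize(
        "nuc,frame,expected",
        [
            ("ATGGCC", 1, "MA"),
            ("ATGGCC", 2, "W"),     # TGG; trailing CC dropped
            ("CAT", -1, "M"),       # reverse complement ATG
            ("ATGTAAGCC", 1, "M*A"),  # stop emitted as '*'
            ("ATGNNA", 1, "MX"),    # ambiguous codon -> X
        ],
    )
    def test_examples(self, nuc, frame, expected):
        assert translate(nuc, frame) == expected

    def test_minus_frames_offset_from_reverse_complement(self):
        nuc = "ATGGCCTTA"
        for f in (1, 2, 3):
            assert translate(nuc, -f) == translate(reverse_complement(nuc), f)

    def test_invalid_frame(self):
        with pytest.raises(ValueError):
            translate("ATG", 0)
        with pytest.raises(ValueError):
            translate("ATG", 4)


class TestMasking:
    def test_zero_entropy_window_fully_masked(self):
        assert mask_low_complexity("A" * 12) == "X" * 12

    def test_diverse_window_unmasked(self):
        protein = "ACDEFGHIKLMN"  # 12 distinct residues, entropy log2(12)
        assert window_entropy(protein) > 2.0
        assert mask_low_complexity(protein) == protein

    def test_two_letter_junction_masked(self):
        protein = "QQQQQQNNNNNN"
        assert window_entropy(protein) == pytest.approx(1.0)
        assert mask_low_complexity(protein) == "X" * 12

    def test_shorter_than_window_returned_unmasked(self):
        assert mask_low_complexity("AAAA") == "AAAA"

    def test_only_low_entropy_stretch_masked(self):
        rng = np.random.default_rng(0)
        flank = random_protein(rng, 40)
        protein = flank + "A" * 20 + flank
        masked = mask_low_complexity(protein)
        assert "X" * 20 in masked
        assert masked[:25] == protein[:25]  # distal flank untouched


class TestKarlinAltschul:
    def test_blosum62_within_published_values(self, matrix):
        ka = compute_ka_params(matrix)
        assert ka.lambda_ == pytest.approx(0.3176, rel=0.01)
        assert ka.K == pytest.approx(0.134, rel=0.01)
        assert ka.H == pytest.approx(0.4012, rel=0.01)

    def test_toy_matrix_lambda_is_ln3(self):
        ka = compute_ka_params(toy_matrix())
        assert math.isclose(ka.lambda_, math.log(3.0), rel_tol=1e-9)

    def test_non_negative_expected_score_rejected(self):
        scores = np.ones((4, 4), dtype=int)
        with pytest.raises(ValueError):
            SubstitutionMatrix("bad", "ACGT", scores, np.full(4, 0.25))


class TestSmithWaterman:
    def test_identity_alignment_scores_sum_of_self_scores(self, matrix):
        protein = "MKTAYIAKQR"
        aln = smith_waterman_affine(protein, protein, matrix)
        assert aln.raw_score == sum(matrix.score(c, c) for c in protein)
        assert aln.aligned_a == aln.aligned_b == protein

    def test_all_negative_comparison_yields_empty_alignment(self):
        aln = smith_waterman_affine("AAAA", "CCCC", toy_matrix())
        assert aln.raw_score == 0
        assert aln.aligned_a == "" and aln.n_columns == 0

    def test_affine_gap_cost_semantics(self):
        # bridging a 2-residue insertion costs open + 2*extend and beats the
        # best ungapped block (12 - 3 = 9 > 6)
        a = "ACGTACGTACGT"
        b = "ACGTAC" + "CC" + "GTACGT"
        aln = smith_waterman_affine(a, b, toy_matrix(), gap_open=1, gap_extend=1)
        assert aln.raw_score == 12 - (1 + 2 * 1)
        assert aln.aligned_a.count("-") == 2

    def test_matches_naive_oracle_on_random_pairs(self, matrix):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = random_protein(rng, int(rng.integers(5, 50)))
            b = random_protein(rng, int(rng.integers(5, 50)))
            expected = sw_affine_score(a, b, matrix.score, 11, 1)
            assert smith_waterman_affine(a, b, matrix).raw_score == expected

    def test_empty_input_rejected(self, matrix):
        with pytest.raises(ValueError):
            smith_waterman_affine("", "ACD", matrix)


class TestEvalue:
    def test_direct_formula_without_edge_correction(self, ka):
        e = evalue(50, 100, 10000, ka, n_seqs=1, edge_correction=False)
        expected = ka.K * 100 * 10000 * math.exp(-ka.lambda_ * 50)
        assert e == pytest.approx(expected)
        assert e == pytest.approx(1.7e-2, rel=0.05)

    def test_linear_in_database_size(self, ka):
        e1 = evalue(40, 100, 10000, ka, edge_correction=False)
        e2 = evalue(40, 100, 20000, ka, edge_correction=False)
        assert e2 == pytest.approx(2 * e1)

    def test_strictly_decreasing_in_score(self, ka):
        es = [evalue(s, 100, 10000, ka) for s in range(20, 80, 5)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_non_positive_score_rejected(self, ka):
        with pytest.raises(ValueError):
            evalue(0, 100, 10000, ka)


def _plant_verbatim(rng, n_fragments):
    """A protein whose 60-aa segment is reverse-translated into one fragment."""
    protein = random_protein(rng, 200)
    segment = protein[70:130]
    nuc = reverse_translate(segment, seed=rng)
    genome = random_dna(rng, n_fragments * 200)
    pos = 400  # fragment boundary-aligned so one fragment holds the mimic
    genome = genome[:pos] + nuc + genome[pos + len(nuc):]
    frags = fragment_set([SeqRecord(id="g", residues=genome)], 200, 200)
    return protein, frags


class TestSeededSearch:
    def test_verbatim_mimic_found_in_large_database(self):
        rng = np.random.default_rng(11)
        protein, frags = _plant_verbatim(rng, 10_000)
        hits = seeded_search([SeqRecord(id="q", residues=protein)], frags)
        top = min(hits, key=lambda h: h.evalue)
        assert top.subject_id == "g_400"
        assert top.pct_identity == 100.0
        assert top.aln_len >= 60
        assert top.frame == 1
        assert top.evalue < 1e-10

    def test_empty_inputs_yield_empty_table(self, matrix):
        assert len(seeded_search([], [], matrix=matrix)) == 0
        q = [SeqRecord(id="q", residues="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")]
        assert len(seeded_search(q, [], matrix=matrix)) == 0

    def test_planted_seventy_percent_mimic_is_top_hit(self):
        rng = np.random.default_rng(5)
        protein = random_protein(rng, 250)
        nuc = mutate_to_identity(
            reverse_translate(protein[100:200], seed=rng), 0.7, seed=rng)
        genome = random_dna(rng, 40_000)
        genome = genome[:10_000] + nuc + genome[10_000 + len(nuc):]
        frags = fragment_set([SeqRecord(id="g", residues=genome)], 200, 100)
        decoys = [SeqRecord(id=f"d{i}", residues=random_protein(rng, 250))
                  for i in range(5)]
        hits = seeded_search([SeqRecord(id="q", residues=protein)] + decoys,
                             frags)
        top = min((h for h in hits if h.query_id == "q"),
                  key=lambda h: h.evalue)
        assert top.subject_id in {"g_10000", "g_9800", "g_10200"}
        assert top.evalue < 1e-10

    def test_reverse_complement_symmetry(self):
        """Searching the reverse complement flips frames, not statistics."""
        rng = np.random.default_rng(9)
        protein, frags = _plant_verbatim(rng, 100)
        rc_frags = [SeqRecord(id=f.fragment_id,
                              residues=reverse_complement(f.residues))
                    for f in frags]
        q = [SeqRecord(id="q", residues=protein)]
        fwd = seeded_search(q, frags)
        rev = seeded_search(q, rc_frags)
        fwd_set = sorted((h.subject_id, h.raw_score, h.frame) for h in fwd)
        rev_set = sorted((h.subject_id, h.raw_score, -h.frame) for h in rev)
        assert fwd_set == rev_set
        assert sorted(round(h.evalue, 12) for h in fwd) == sorted(
            round(h.evalue, 12) for h in rev)

    def test_gapped_scores_bounded_by_exact_sw(self, matrix, ka):
        rng = np.random.default_rng(21)
        queries = [SeqRecord(id=f"q{i}", residues=random_protein(rng, 120))
                   for i in range(5)]
        frags = fragment_set(
            [SeqRecord(id="g", residues=random_dna(rng, 20_000))], 200, 100)
        params = SearchParams(evalue_report_max=1e5, gap_trigger_evalue=1e5)
        hits = seeded_search(queries, frags, params=params, matrix=matrix, ka=ka)
        frag_by_id = {f.fragment_id: f for f in frags}
        query_by_id = {q.id: q for q in queries}
        S = matrix.kernel_matrix()
        for h in hits:
            prot = translate(frag_by_id[h.subject_id].residues, h.frame)
            # the search aligns the hard-masked query, so bound against it
            masked = mask_low_complexity(query_by_id[h.query_id].residues)
            exact = _kernels.sw_score(
                matrix.encode_seq(masked),
                matrix.encode_seq(prot), S, 11, 1)
            assert h.raw_score <= exact

    def test_recall_of_strong_pairs_vs_exact_dp(self, matrix, ka):
        """>=95% of pairs whose exact SW score clears the E<1e-4 bar are found."""
        rng = np.random.default_rng(33)
        proteins = [SeqRecord(id=f"p{i}", residues=random_protein(rng, 300))
                    for i in range(15)]
        genome = list(random_dna(rng, 30_000))
        # plant mimics of the first five proteins at 70% identity
        for k in range(5):
            nuc = mutate_to_identity(
                reverse_translate(proteins[k].residues[50:150], seed=rng),
                0.7, seed=rng)
            pos = 3000 + 5000 * k
            genome[pos:pos + len(nuc)] = list(nuc)
        frags = fragment_set(
            [SeqRecord(id="g", residues="".join(genome))], 200, 100)
        hits = seeded_search(proteins, frags, matrix=matrix, ka=ka)
        found = {(h.query_id, h.subject_id) for h in hits if h.evalue < 1e-4}

        S = matrix.kernel_matrix()
        translated = {
            f.fragment_id: [matrix.encode_seq(translate(f.residues, fr))
                            for fr in (1, 2, 3, -1, -2, -3)]
            for f in frags
        }
        n_total = sum(len(c) for codes in translated.values() for c in codes)
        n_seqs = 6 * len(frags)
        strong = set()
        for p in proteins:
            thresh = min_score_for_evalue(1e-4, len(p.residues), n_total, ka,
                                          n_seqs)
            pc = matrix.encode_seq(p.residues)
            for fid, codes in translated.items():
                best = max(
                    (_kernels.sw_score(pc, c, S, 11, 1) for c in codes
                     if len(c) >= 3),
                    default=0,
                )
                if best >= thresh:
                    strong.add((p.id, fid))
        assert strong, "fixture must produce strong pairs"
        recall = len(strong & found) / len(strong)
        assert recall >= 0.95

    def test_deterministic_output(self):
        rng = np.random.default_rng(2)
        protein, frags = _plant_verbatim(rng, 50)
        q = [SeqRecord(id="q", residues=protein)]
        h1 = seeded_search(q, frags)
        h2 = seeded_search(q, frags)
        assert [vars(a) for a in h1] == [vars(b) for b in h2]
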