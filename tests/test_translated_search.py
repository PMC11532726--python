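"""Six-frame translation, local alignment, statistics, and the builtin search."""

from __future__ import annotations

import random
import shutil

import numpy as np
import pytest

from eescan.io_formats import SequenceRecord
from eescan.simulate import reverse_translate
from eescan.translated_search import (
    ExternalBackendError,
    KarlinAltschulParams,
    SearchParams,
    _matrix_lookup,
    bits_to_evalue,
    build_word_index,
    get_ka_params,
    load_matrix,
    local_align_protein,
    reverse_complement,
    run_builtin_search,
    run_external_search,
    score_to_bits,
    seed_candidates,
    six_frame_translate,
    translate_frame,
)

from _oracles import sw_affine_bruteforce

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestSixFrameTranslation:
    def test_forward_frame_standard_code(self):
        rec = SequenceRecord(id="c", residues="ATGAAA")
        assert translate_frame(rec, 1).peptide == "MK"

    def test_reverse_frame_is_revcomp_translation(self):
        rec = SequenceRecord(id="c", residues="TTTCAT")
        assert translate_frame(rec, -1).peptide == "MK"

    def test_ambiguous_codon_translates_to_x(self):
        rec = SequenceRecord(id="c", residues="ATGANA")
        assert translate_frame(rec, 1).peptide == "MX"

    def test_stop_codon_is_star(self):
        rec = SequenceRecord(id="c", residues="ATGTAA")
        assert translate_frame(rec, 1).peptide == "M*"

    def test_short_contig_empty_translations(self):
        rec = SequenceRecord(id="c", residues="AT")
        assert all(ft.peptide == "" for ft in six_frame_translate(rec))

    @pytest.mark.parametrize("frame", [1, 2, 3, -1, -2, -3])
    def test_coordinate_map_roundtrip(self, frame):
        """Translating the mapped nucleotide triple reproduces each peptide letter."""
        rng = random.Random(42 + frame)
        seq = "".join(rng.choice("ACGT") for _ in range(100))
        rec = SequenceRecord(id="c", residues=seq)
        ft = translate_frame(rec, frame)
        for p in range(1, len(ft.peptide) + 1):
            s, e = ft.nt_span(p, p)
            assert e - s + 1 == 3
            triple = seq[s - 1 : e]
            if frame < 0:
                triple = reverse_complement(triple)
            assert translate_frame(SequenceRecord(id="t", residues=triple), 1).peptide == ft.peptide[p - 1]


class TestLocalAlignment:
    def test_self_alignment_scores_diagonal_sum(self):
        matrix = load_matrix("BLOSUM45")
        pep = "MKVLATTASDGQW"
        res = local_align_protein(pep, pep)
        expected = sum(matrix[a, a] for a in pep)
        assert res.raw_score == expected
        assert (res.q_start, res.q_end) == (1, len(pep))
        assert (res.s_start, res.s_end) == (1, len(pep))
        assert res.percent_identity == 100.0

    def test_no_positive_alignment_returns_none(self):
        # tryptophan-free vs all-tryptophan: every pair scores negatively
        assert local_align_protein("PPPPP", "WWWWW") is None

    def test_unknown_matrix_rejected(self):
        with pytest.raises(KeyError, match="NOSUCH"):
            local_align_protein("MK", "MK", matrix_name="NOSUCH75")

    def test_matches_bruteforce_dp_on_random_pairs(self):
        """Spot-check against the cubic affine-gap oracle (the full sweep is in acceptance)."""
        rng = random.Random(99)
        score_of = _matrix_lookup(load_matrix("BLOSUM45")).__getitem__
        for _ in range(40):
            q = "".join(rng.choice(AA) for _ in range(rng.randint(1, 25)))
            s = "".join(rng.choice(AA) for _ in range(rng.randint(1, 25)))
            expected = sw_affine_bruteforce(q, s, score_of, 14, 2)
            res = local_align_protein(q, s)
            got = 0 if res is None else res.raw_score
            assert got == expected, (q, s)


class TestStatistics:
    def test_bitscore_zero_at_formula_zero(self):
        ka = KarlinAltschulParams(lam=0.2, K=0.05, matrix_name="BLOSUM45", gap_open=14, gap_extend=2)
        raw_zero = np.log(ka.K) / ka.lam
        assert score_to_bits(raw_zero, ka) == pytest.approx(0.0, abs=1e-12)

    def test_bits_monotone_in_raw_score(self):
        ka = get_ka_params("BLOSUM45", 14, 2)
        bits = [score_to_bits(s, ka) for s in range(0, 500, 50)]
        assert all(b2 > b1 for b1, b2 in zip(bits, bits[1:]))

    def test_doubling_database_doubles_evalue(self):
        e1 = bits_to_evalue(50.0, 1000, 5000)
        e2 = bits_to_evalue(50.0, 1000, 10000)
        assert e2 == pytest.approx(2 * e1)

    def test_missing_ka_triple_named(self):
        with pytest.raises(KeyError, match="open=7"):
            get_ka_params("BLOSUM45", 7, 7)


class TestSeeding:
    def test_shared_word_gives_seed(self):
        subjects = [SequenceRecord(id="s", residues="AAAMKVAAA")]
        index = build_word_index(subjects, 3)
        assert len(seed_candidates("MKV", index, 3)) >= 1

    def test_query_shorter_than_word_gives_no_seeds(self):
        index = build_word_index([SequenceRecord(id="s", residues="MKVL")], 3)
        assert seed_candidates("MK", index, 3) == []

    def test_word_size_one_equals_exhaustive(self):
        """In the exhaustive limit (word 1) seeding changes nothing."""
        rng = random.Random(5)
        rng_np = np.random.default_rng(5)
        protein = SequenceRecord(id="P1", residues="".join(rng.choice(AA) for _ in range(60)))
        coding = reverse_translate(protein.residues, rng_np)
        flanks = ["".join(rng.choice("ACGT") for _ in range(400)) for _ in range(2)]
        contig = SequenceRecord(id="c1", residues=flanks[0] + coding + flanks[1])
        params = SearchParams(word_size=1, ungapped_trigger=15.0)
        seeded = run_builtin_search([contig], [protein], params)
        exhaustive = run_builtin_search([contig], [protein], params, exhaustive=True)
        key = lambda h: (h.subject_id, h.frame, h.q_start, h.q_end, h.s_start, h.s_end)
        assert {key(h) for h in seeded} == {key(h) for h in exhaustive}


def _planted_contig(seed=21, flank=1_500, protein_len=80):
    rng = random.Random(seed)
    rng_np = np.random.default_rng(seed)
    protein = SequenceRecord(id="P1", residues="".join(rng.choice(AA) for _ in range(protein_len)))
    coding = reverse_translate(protein.residues, rng_np)
    left = "".join(rng.choice("ACGT") for _ in range(flank))
    right = "".join(rng.choice("ACGT") for _ in range(flank))
    contig = SequenceRecord(id="c1", residues=left + coding + right)
    return contig, protein, flank + 1, flank + len(coding)


class TestBuiltinSearch:
    def test_planted_copy_recovered_exactly(self):
        contig, protein, start, end = _planted_contig()
        hits = run_builtin_search([contig], [protein], SearchParams())
        assert hits
        best = max(hits, key=lambda h: h.bit_score)
        assert best.subject_id == "P1"
        assert best.percent_identity == 100.0
        assert (best.q_start, best.q_end) == (start, end)

    def test_random_inputs_give_no_hits(self):
        rng = random.Random(77)
        contig = SequenceRecord(id="c1", residues="".join(rng.choice("ACGT") for _ in range(20_000)))
        proteins = [
            SequenceRecord(id=f"P{i}", residues="".join(rng.choice(AA) for _ in range(200)))
            for i in range(3)
        ]
        assert run_builtin_search([contig], proteins, SearchParams()) == []

    def test_empty_database_rejected(self):
        contig, *_ = _planted_contig()
        with pytest.raises(ValueError, match="empty"):
            run_builtin_search([contig], [], SearchParams())

    def test_strand_symmetry(self):
        """Searching the reverse complement flips strands and reflects coordinates."""
        contig, protein, _, _ = _planted_contig(seed=31)
        L = len(contig.residues)
        rc = SequenceRecord(id="c1", residues=reverse_complement(contig.residues))
        fwd = run_builtin_search([contig], [protein], SearchParams())
        rev = run_builtin_search([rc], [protein], SearchParams())
        as_set = lambda hits, reflect: {
            (
                h.subject_id,
                (L - h.q_end + 1, L - h.q_start + 1) if reflect else (h.q_start, h.q_end),
                h.s_start,
                h.s_end,
                {"+": "-", "-": "+"}[h.strand] if reflect else h.strand,
            )
            for h in hits
        }
        assert as_set(fwd, False) == as_set(rev, True)

    def test_determinism(self):
        contig, protein, _, _ = _planted_contig(seed=41)
        a = run_builtin_search([contig], [protein], SearchParams())
        b = run_builtin_search([contig], [protein], SearchParams())
        assert a == b

    def test_hits_sorted_by_contig_and_position(self, small_fixture):
        hits = run_builtin_search(small_fixture.genome, small_fixture.proteins, SearchParams())
        keys = [(h.query_id, h.q_start) for h in hits]
        assert keys == sorted(keys)


class TestExternalBackend:
    def test_missing_binary_error_names_builtin_flag(self, tmp_path, monkeypatch):
        monkeypatch.setenv("PATH", str(tmp_path))  # nothing resolvable
        contig, protein, _, _ = _planted_contig()
        with pytest.raises(ExternalBackendError, match="--backend builtin"):
            run_external_search([contig], [protein], SearchParams(backend="external-blastx"), tmp_path)

    def test_unknown_backend_rejected(self, tmp_path):
        contig, protein, _, _ = _planted_contig()
        with pytest.raises(ValueError, match="unknown external backend"):
            run_external_search([contig], [protein], SearchParams(backend="frobnicate"), tmp_path)

    @pytest.mark.skipif(shutil.which("blastx") is None, reason="blastx not installed")
    def test_blastx_concordance_on_planted_fixture(self, tmp_path, small_fixture):
        """External and builtin backends recover the same planted loci."""
        from eescan.element_calling import hits_to_candidates

        params = SearchParams(backend="external-blastx")
        ext = run_external_search(small_fixture.genome, small_fixture.proteins, params, tmp_path)
        builtin = run_builtin_search(small_fixture.genome, small_fixture.proteins, SearchParams())
        ext_c = sorted(hits_to_candidates(ext), key=lambda c: (c.contig_id, c.start))
        blt_c = sorted(hits_to_candidates(builtin), key=lambda c: (c.contig_id, c.start))
        assert len(ext_c) == len(blt_c)
        for e, b in zip(ext_c, blt_c):
            assert e.contig_id == b.contig_id
            assert abs(e.start - b.start) <= 3 and abs(e.end - b.end) <= 3
            # tabular output rounds bitscores to 3 significant digits
            assert abs(e.bit_score - b.bit_score) <= 1.0
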