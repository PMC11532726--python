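"""Two-pass merging of fragmented elements and its union-find oracle."""

from __future__ import annotations

import random

import pytest

from eescan.element_calling import AnnotatedElement
from eescan.merging import (
    MergeParams,
    gap_between,
    merge_elements,
    merge_junction,
    merge_oracle,
    merge_taxon,
)


def make_element(
    contig="c1",
    start=100,
    end=200,
    subject="P1",
    family="FamA",
    genus="GenA",
    bits=100.0,
    strand="+",
):
    return AnnotatedElement(
        element_id=f"{contig}:{start}-{end}:{strand}",
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        best_subject=subject,
        bit_score=bits,
        e_value=1e-30,
        percent_identity=95.0,
        family=family,
        genus=genus,
    )


# taxonomy is a function of the subject protein, as metadata transfer makes
# it in the pipeline (same accession -> same family/genus)
_TAXONOMY = {
    "P1": ("FamA", "GenA"),
    "P2": ("FamA", "GenB"),
    "P3": ("FamB", "GenC"),
    "P4": ("NA", "NA"),
}


def random_elements(rng: random.Random, n: int) -> list[AnnotatedElement]:
    out = []
    used = set()
    for _ in range(n):
        start = rng.randint(1, 30_000)
        end = start + rng.randint(50, 2_000)
        key = (start, end)
        if key in used:
            continue
        used.add(key)
        subject = rng.choice(sorted(_TAXONOMY))
        family, genus = _TAXONOMY[subject]
        out.append(
            make_element(
                contig=rng.choice(["c1", "c2"]),
                start=start,
                end=end,
                subject=subject,
                family=family,
                genus=genus,
                bits=round(rng.uniform(50, 300), 1),
                strand=rng.choice("+-"),
            )
        )
    return out


def signature(merged):
    return sorted(
        (m.contig_id, m.start, m.end, tuple(sorted(x.element_id for x in m.members)))
        for m in merged
    )


class TestGap:
    def test_strictly_between(self):
        a, b = make_element(start=100, end=200), make_element(start=350, end=400)
        assert gap_between(a, b) == 149

    def test_overlap_counts_zero(self):
        assert gap_between(make_element(start=100, end=200), make_element(start=150, end=300)) == 0

    def test_abutting_counts_zero(self):
        assert gap_between(make_element(start=100, end=200), make_element(start=201, end=300)) == 0

    def test_cross_contig_rejected(self):
        with pytest.raises(ValueError, match="contig"):
            gap_between(make_element(contig="c1"), make_element(contig="c2", start=300, end=400))


class TestJunctionMerge:
    def test_same_subject_within_range_merges(self):
        a = make_element(start=1_000, end=1_500)
        b = make_element(start=1_581, end=2_000)  # gap 80
        merged = merge_junction([a, b], range_junction=100)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end, merged[0].n_fragments) == (1_000, 2_000, 2)

    def test_same_pair_beyond_range_stays_split(self):
        a = make_element(start=1_000, end=1_500)
        b = make_element(start=1_581, end=2_000)
        assert len(merge_junction([a, b], range_junction=50)) == 2

    def test_rj_zero_merges_only_contact(self):
        a = make_element(start=1_000, end=1_500)
        abut = make_element(start=1_501, end=1_700)
        apart = make_element(start=1_703, end=1_900)
        merged = merge_junction([a, abut, apart], range_junction=0)
        assert sorted(m.n_fragments for m in merged) == [1, 2]

    def test_different_subjects_never_junction_merge(self):
        a = make_element(start=1_000, end=1_500, subject="P1")
        b = make_element(start=1_510, end=2_000, subject="P2")
        assert len(merge_junction([a, b], range_junction=100)) == 2


class TestTaxonMerge:
    def test_chain_of_three_within_limit(self):
        a = make_element(start=1_000, end=2_000)
        b = make_element(start=2_501, end=3_000, subject="P2")  # gap 500
        c = make_element(start=12_001, end=13_000, subject="P3")  # gap 9000 from b
        merged = merge_taxon([a, b, c], "family", 10_000)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end, merged[0].n_fragments) == (1_000, 13_000, 3)

    def test_foreign_family_does_not_block_chaining(self):
        a = make_element(start=1_000, end=2_000, family="FamA")
        foreign = make_element(start=3_000, end=3_500, subject="P9", family="FamB")
        b = make_element(start=5_000, end=6_000, subject="P2", family="FamA")
        merged = merge_taxon([a, foreign, b], "family", 10_000)
        spans = sorted((m.start, m.end, m.family) for m in merged)
        assert (1_000, 6_000, "FamA") in spans and (3_000, 3_500, "FamB") in spans

    def test_merge_level_none_is_identity(self):
        els = [make_element(start=s, end=s + 100) for s in (1_000, 1_200, 1_400)]
        merged = merge_taxon(els, "none", 10_000)
        assert [(m.start, m.end) for m in merged] == [(e.start, e.end) for e in els]
        assert all(m.n_fragments == 1 for m in merged)

    def test_na_taxa_never_merge_together(self):
        a = make_element(start=1_000, end=2_000, family="NA")
        b = make_element(start=2_100, end=3_000, subject="P2", family="NA")
        assert len(merge_taxon([a, b], "family", 10_000)) == 2

    def test_invalid_merge_level_rejected(self):
        with pytest.raises(ValueError, match="merge_level"):
            merge_taxon([make_element()], "species", 10_000)


class TestMergeProperties:
    def test_matches_union_find_oracle(self):
        rng = random.Random(55)
        for _ in range(150):
            els = random_elements(rng, rng.randint(0, 20))
            params = MergeParams(
                merge_level=rng.choice(["family", "genus", "none"]),
                limit_merge=rng.choice([0, 100, 1_000, 10_000]),
                range_junction=rng.choice([0, 50, 100, 1_000]),
            )
            assert signature(merge_elements(els, params)) == signature(merge_oracle(els, params))

    def test_conservation(self):
        rng = random.Random(56)
        els = random_elements(rng, 30)
        merged = merge_elements(els, MergeParams())
        members = [m.element_id for g in merged for m in g.members]
        assert sorted(members) == sorted(e.element_id for e in els)
        assert sum(m.n_fragments for m in merged) == len(els)

    def test_idempotence(self):
        rng = random.Random(57)
        els = random_elements(rng, 25)
        params = MergeParams()
        once = merge_elements(els, params)
        twice = merge_taxon(merge_junction(once, params.range_junction), params.merge_level, params.limit_merge)
        assert signature(once) == signature(twice)

    def test_order_invariance(self):
        rng = random.Random(58)
        els = random_elements(rng, 25)
        params = MergeParams()
        shuffled = els[:]
        rng.shuffle(shuffled)
        assert signature(merge_elements(els, params)) == signature(merge_elements(shuffled, params))

    def test_separation_within_taxon_group(self):
        rng = random.Random(59)
        els = random_elements(rng, 40)
        params = MergeParams(limit_merge=1_000, range_junction=100)
        merged = merge_elements(els, params)
        by_group = {}
        for m in merged:
            if m.taxon_key != "NA":
                by_group.setdefault((m.contig_id, m.taxon_key), []).append((m.start, m.end))
        for spans in by_group.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 - e1 - 1 > params.limit_merge

    def test_singleton_passthrough(self):
        el = make_element()
        merged = merge_elements([el], MergeParams())
        assert len(merged) == 1 and merged[0].members == (el,)

    def test_all_same_taxon_close_gives_one_per_contig(self):
        els = [make_element(start=s, end=s + 50, subject=f"P{i}") for i, s in enumerate(range(1_000, 3_000, 200))]
        merged = merge_elements(els, MergeParams(limit_merge=500, range_junction=0))
        assert len(merged) == 1 and merged[0].n_fragments == len(els)
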