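"""Merging of fragmented cis elements (pipeline step V).

Endogenized insertions shatter over evolutionary time through substitutions,
indels and transposable-element insertions, so one ancient event often
surfaces as several nearby loci. Merging is two-pass:

* pass 1 ("range junction", ``-rj``) joins neighbors on the same contig
  hitting the *same subject protein* whose gap is at most ``range_junction``
  nt — the signature of a single shattered insertion;
* pass 2 ("limit merge", ``-lm``) joins neighbors sharing the same taxon at
  the configured merge level (family or genus) whose gap is at most
  ``limit_merge`` nt — large-scale shattering such as a fragmented whole
  bacterial-genome integration.

Gaps count the bases strictly between two spans (overlap counts as 0) and
chaining is transitive with a running maximum end, which makes the chain
merge equal to the transitive closure of the pairwise mergeable relation.
Elements whose merge-level taxon is the "NA" sentinel are never merged with
each other: an unknown taxon is no evidence of common origin.

The two-pass composition is idempotent in the pipeline's regime — taxonomy
a function of the subject accession (metadata transfer guarantees this)
and ``range_junction <= limit_merge``. With ``range_junction`` above
``limit_merge``, spans grown by the taxon pass can newly fall within
junction range of each other, so a second application may merge further.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .io_formats import NA
from .element_calling import AnnotatedElement

__all__ = [
    "MergeParams",
    "MergedElement",
    "gap_between",
    "merge_junction",
    "merge_taxon",
    "merge_elements",
    "merge_oracle",
]

MERGE_LEVELS = ("family", "genus", "none")


@dataclass(frozen=True)
class MergeParams:
    """Taxonomic merge level and nucleotide distance thresholds."""

    merge_level: str = "family"
    limit_merge: int = 10_000
    range_junction: int = 100

    def __post_init__(self) -> None:
        if self.merge_level not in MERGE_LEVELS:
            raise ValueError(f"merge_level must be one of {MERGE_LEVELS}, got {self.merge_level!r}")
        if self.limit_merge < 0 or self.range_junction < 0:
            raise ValueError("distance thresholds must be >= 0")


@dataclass(frozen=True)
class MergedElement:
    """A span unifying fragments of one putative endogenization event.

    ``members`` are the original annotated elements; the representative
    annotation (subject, scores, strand, taxonomy) comes from the member with
    the highest bitscore. Coordinates span the gaps between fragments;
    ``fragment_coords`` preserves the original pieces.
    """

    element_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    best_subject: str
    bit_score: float
    e_value: float
    percent_identity: float
    species: str
    genus: str
    family: str
    molecule_type: str
    protein_product: str
    host: str
    members: tuple[AnnotatedElement, ...]
    taxon_key: str = NA

    @property
    def n_fragments(self) -> int:
        return len(self.members)

    @property
    def fragment_coords(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted((m.start, m.end) for m in self.members))

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("merged element with no members")
        if self.start != min(m.start for m in self.members):
            raise ValueError("merged start is not the minimum member start")
        if self.end != max(m.end for m in self.members):
            raise ValueError("merged end is not the maximum member end")
        if abs(self.bit_score - max(m.bit_score for m in self.members)) > 1e-9:
            raise ValueError("merged bitscore is not the maximum member bitscore")


def gap_between(a, b) -> int:
    """Bases strictly between two spans on one contig (overlap/abutment -> 0).

    ``a`` and ``b`` must satisfy ``a.start <= b.start``.
    """
    if a.contig_id != b.contig_id:
        raise ValueError(f"gap_between across contigs {a.contig_id!r} vs {b.contig_id!r}")
    if a.start > b.start:
        raise ValueError("gap_between requires a.start <= b.start")
    return max(0, b.start - a.end - 1)


def _as_merged(el: AnnotatedElement | MergedElement, taxon_key: str = NA) -> MergedElement:
    if isinstance(el, MergedElement):
        return el
    return MergedElement(
        element_id=el.element_id,
        contig_id=el.contig_id,
        start=el.start,
        end=el.end,
        strand=el.strand,
        best_subject=el.best_subject,
        bit_score=el.bit_score,
        e_value=el.e_value,
        percent_identity=el.percent_identity,
        species=el.species,
        genus=el.genus,
        family=el.family,
        molecule_type=el.molecule_type,
        protein_product=el.protein_product,
        host=el.host,
        members=(el,),
        taxon_key=taxon_key,
    )


def _fuse(group: Sequence[MergedElement], taxon_key: str) -> MergedElement:
    if len(group) == 1:
        g = group[0]
        if g.taxon_key == taxon_key:
            return g
        return _refuse_with_key(g, taxon_key)
    members = tuple(
        sorted(
            (m for g in group for m in g.members),
            key=lambda m: (m.start, m.end, m.element_id),
        )
    )
    best = min(group, key=lambda g: (-g.bit_score, g.e_value, g.best_subject, g.start))
    start = min(g.start for g in group)
    end = max(g.end for g in group)
    return MergedElement(
        element_id=f"{best.contig_id}:{start}-{end}:{best.strand}",
        contig_id=best.contig_id,
        start=start,
        end=end,
        strand=best.strand,
        best_subject=best.best_subject,
        bit_score=best.bit_score,
        e_value=best.e_value,
        percent_identity=best.percent_identity,
        species=best.species,
        genus=best.genus,
        family=best.family,
        molecule_type=best.molecule_type,
        protein_product=best.protein_product,
        host=best.host,
        members=members,
        taxon_key=taxon_key,
    )


def _refuse_with_key(g: MergedElement, taxon_key: str) -> MergedElement:
    return MergedElement(
        **{
            **{f: getattr(g, f) for f in (
                "element_id", "contig_id", "start", "end", "strand", "best_subject",
                "bit_score", "e_value", "percent_identity", "species", "genus",
                "family", "molecule_type", "protein_product", "host", "members",
            )},
            "taxon_key": taxon_key,
        }
    )


def _sorted_canonical(elements: Iterable[MergedElement]) -> list[MergedElement]:
    return sorted(elements, key=lambda e: (e.contig_id, e.start, e.end, e.element_id))


def _chain_merge(
    elements: Iterable[MergedElement],
    group_key: Callable[[MergedElement], tuple],
    threshold: int,
    taxon_key_of: Callable[[MergedElement], str] = lambda e: NA,
) -> list[MergedElement]:
    """Chain-merge sorted neighbors with gap <= threshold within each group.

    A running maximum end is kept so the result equals the transitive
    closure of the pairwise relation "same group and gap <= threshold".
    """
    groups: dict[tuple, list[MergedElement]] = {}
    for el in elements:
        groups.setdefault(group_key(el), []).append(el)
    out: list[MergedElement] = []
    for key, group in groups.items():
        group.sort(key=lambda e: (e.start, e.end, e.element_id))
        taxon_key = taxon_key_of(group[0])
        chain: list[MergedElement] = []
        chain_end = -1
        for el in group:
            if chain and max(0, el.start - chain_end - 1) <= threshold:
                chain.append(el)
                chain_end = max(chain_end, el.end)
            else:
                if chain:
                    out.append(_fuse(chain, taxon_key))
                chain = [el]
                chain_end = el.end
        if chain:
            out.append(_fuse(chain, taxon_key))
    return _sorted_canonical(out)


def merge_junction(
    elements: Iterable[AnnotatedElement | MergedElement], range_junction: int
) -> list[MergedElement]:
    """Pass 1: join same-contig fragments hitting the same subject protein."""
    merged_in = [_as_merged(el) for el in elements]
    return _chain_merge(
        merged_in, lambda e: (e.contig_id, e.best_subject), range_junction
    )


def merge_taxon(
    elements: Iterable[AnnotatedElement | MergedElement],
    merge_level: str,
    limit_merge: int,
) -> list[MergedElement]:
    """Pass 2: join same-contig neighbors sharing the merge-level taxon.

    Elements with an "NA" taxon form singleton groups (never merged with
    each other). ``merge_level="none"`` is the identity apart from wrapping.
    """
    if merge_level not in MERGE_LEVELS:
        raise ValueError(f"merge_level must be one of {MERGE_LEVELS}, got {merge_level!r}")
    merged_in = [_as_merged(el) for el in elements]
    if merge_level == "none":
        return _sorted_canonical(merged_in)

    def key(e: MergedElement) -> tuple:
        taxon = getattr(e, merge_level)
        if taxon == NA:
            # unknowns are not evidence of common origin: unique group
            return (e.contig_id, f"__na__{e.element_id}")
        return (e.contig_id, taxon)

    return _chain_merge(merged_in, key, limit_merge, lambda e: getattr(e, merge_level))


def merge_elements(
    elements: Iterable[AnnotatedElement], params: MergeParams = MergeParams()
) -> list[MergedElement]:
    """Both merge passes: range-junction joining then taxon-level merging."""
    return merge_taxon(
        merge_junction(elements, params.range_junction),
        params.merge_level,
        params.limit_merge,
    )


# ---------------------------------------------------------------------------
# Exhaustive reference implementation (test oracle)
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _closure_pass(
    items: list[MergedElement],
    same_group: Callable[[MergedElement, MergedElement], bool],
    threshold: int,
    taxon_key_of: Callable[[MergedElement], str],
) -> list[MergedElement]:
    # pairwise closure with span growth: iterate unions until fixed point
    uf = _UnionFind(len(items))
    changed = True
    while changed:
        changed = False
        comps: dict[int, list[int]] = {}
        for i in range(len(items)):
            comps.setdefault(uf.find(i), []).append(i)
        spans = {
            root: (
                min(items[i].start for i in idxs),
                max(items[i].end for i in idxs),
            )
            for root, idxs in comps.items()
        }
        roots = sorted(comps)
        for a_i, ra in enumerate(roots):
            for rb in roots[a_i + 1 :]:
                ia, ib = comps[ra][0], comps[rb][0]
                if not same_group(items[ia], items[ib]):
                    continue
                (sa, ea), (sb, eb) = spans[ra], spans[rb]
                gap = max(0, max(sa, sb) - min(ea, eb) - 1)
                if gap <= threshold:
                    uf.union(ia, ib)
                    changed = True
    comps = {}
    for i in range(len(items)):
        comps.setdefault(uf.find(i), []).append(i)
    out = []
    for idxs in comps.values():
        group = [items[i] for i in idxs]
        out.append(_fuse(sorted(group, key=lambda e: (e.start, e.end, e.element_id)),
                         taxon_key_of(group[0])))
    return _sorted_canonical(out)


def merge_oracle(
    elements: Iterable[AnnotatedElement], params: MergeParams = MergeParams()
) -> list[MergedElement]:
    """Exhaustive union-find closure equivalent of :func:`merge_elements`.

    Intended for small inputs in tests; computes the transitive closure of
    the pairwise mergeable relation for each pass directly.
    """
    items = [_as_merged(el) for el in elements]
    pass1 = _closure_pass(
        items,
        lambda a, b: a.contig_id == b.contig_id and a.best_subject == b.best_subject,
        params.range_junction,
        lambda e: NA,
    )
    if params.merge_level == "none":
        return pass1
    level = params.merge_level

    def same_taxon(a: MergedElement, b: MergedElement) -> bool:
        ta, tb = getattr(a, level), getattr(b, level)
        return a.contig_id == b.contig_id and ta == tb and ta != NA

    return _closure_pass(
        pass1, same_taxon, params.limit_merge, lambda e: getattr(e, level)
    )
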