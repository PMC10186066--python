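"""Reciprocal best hits and discovery of the N most similar additional OGs.

Best hits are resolved per (query, target species); reciprocal best hits
(RBH) are cross-species pairs where each gene is the other's best hit.
For an expanded OG the "most similar additional OGs" are ranked by the
number of RBH links connecting the focal OG to the candidate, with maximum
bitscore as tiebreak. Genes not assigned to any OG act as one-gene
pseudo-OGs so singletons can surface as neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RBHPair",
    "OGNeighborhood",
    "best_hits",
    "reciprocal_best_hits",
    "additional_ogs",
]

#: OG label prefix for genes without an orthogroup assignment.
SINGLETON_PREFIX = "singleton:"


@dataclass(frozen=True)
class RBHPair:
    """An unordered reciprocal-best-hit gene pair (canonical order:
    ``gene_a < gene_b``)."""

    gene_a: str
    gene_b: str
    bitscore_ab: float
    bitscore_ba: float
    evalue_ab: float
    evalue_ba: float

    @property
    def max_bitscore(self) -> float:
        return max(self.bitscore_ab, self.bitscore_ba)


@dataclass
class OGNeighborhood:
    """Ranked most-similar additional OGs for one focal OG."""

    focal_og: str
    ranked: list[tuple[str, int, float]]  # (og_id, link_count, max_bitscore)
    extended_hits: pd.DataFrame = field(default_factory=pd.DataFrame)


def _iter_hits(hits: pd.DataFrame):
    return zip(
        hits["query"], hits["subject"], hits["bitscore"], hits["evalue"]
    )


def best_hits(hits: pd.DataFrame) -> dict[str, dict]:
    """Best hit per query over the whole table (self-hits removed).

    Ties break by max bitscore, then min evalue, then lexicographically
    smallest subject id. Returns query -> ``{"subject", "bitscore",
    "evalue"}``.
    """
    best: dict[str, tuple[float, float, str]] = {}
    for q, s, bit, ev in _iter_hits(hits):
        if q == s:
            continue
        cand = (-float(bit), float(ev), s)
        if q not in best or cand < best[q]:
            best[q] = cand
    return {
        q: {"subject": s, "bitscore": -negbit, "evalue": ev}
        for q, (negbit, ev, s) in best.items()
    }


def _best_per_target_species(
    hits: pd.DataFrame, gene_to_species: Mapping[str, str]
) -> dict[tuple[str, str], tuple[float, float, str]]:
    """(query, target species) -> (-bitscore, evalue, subject) of the best
    cross-species hit."""
    best: dict[tuple[str, str], tuple[float, float, str]] = {}
    for q, s, bit, ev in _iter_hits(hits):
        if q == s:
            continue
        try:
            qs, ss = gene_to_species[q], gene_to_species[s]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} absent from species map") from None
        if qs == ss:  # RBH is defined across species pairs only
            continue
        key = (q, ss)
        cand = (-float(bit), float(ev), s)
        if key not in best or cand < best[key]:
            best[key] = cand
    return best


def reciprocal_best_hits(
    hits: pd.DataFrame,
    gene_to_species: Mapping[str, str],
) -> list[RBHPair]:
    """Reciprocal best hits from a (possibly concatenated all-vs-all)
    directed hit table.

    ``(a, b)`` is emitted iff b is a's best hit in b's species and a is b's
    best hit in a's species. Output is sorted by (gene_a, gene_b) and
    symmetric under direction swap of the inputs.
    """
    best = _best_per_target_species(hits, gene_to_species)
    pairs: list[RBHPair] = []
    for (q, _), (negbit, ev, s) in best.items():
        if q >= s:  # canonical orientation; partner pass handles the rest
            continue
        back = best.get((s, gene_to_species[q]))
        if back is None or back[2] != q:
            continue
        pairs.append(
            RBHPair(
                gene_a=q,
                gene_b=s,
                bitscore_ab=-negbit,
                bitscore_ba=-back[0],
                evalue_ab=ev,
                evalue_ba=back[1],
            )
        )
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def og_of(gene: str, og_membership: Mapping[str, str]) -> str:
    """OG of a gene; unassigned genes become one-gene pseudo-OGs."""
    return og_membership.get(gene, f"{SINGLETON_PREFIX}{gene}")


def additional_ogs(
    focal_og: str,
    rbh_pairs: Sequence[RBHPair],
    og_membership: Mapping[str, str],
    n: int,
    hits: pd.DataFrame | None = None,
) -> OGNeighborhood:
    """Rank the ``n`` most similar additional OGs for ``focal_og``.

    A candidate's score is the number of RBH links between focal genes and
    candidate genes; ties resolve by the maximum bitscore over those links,
    then by OG id. ``extended_hits`` collects every hit row whose query or
    subject lies in the focal OG or a selected additional OG.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    links: dict[str, int] = {}
    maxbit: dict[str, float] = {}
    for p in rbh_pairs:
        og_a = og_of(p.gene_a, og_membership)
        og_b = og_of(p.gene_b, og_membership)
        if (og_a == focal_og) == (og_b == focal_og):
            continue  # internal link or unrelated pair
        cand = og_b if og_a == focal_og else og_a
        links[cand] = links.get(cand, 0) + 1
        maxbit[cand] = max(maxbit.get(cand, 0.0), p.max_bitscore)
    ranked = sorted(
        ((og, links[og], maxbit[og]) for og in links),
        key=lambda t: (-t[1], -t[2], t[0]),
    )[:n]
    extended = pd.DataFrame()
    if hits is not None:
        selected = {focal_og} | {og for og, _, _ in ranked}
        genes = {
            g for g in set(hits["query"]) | set(hits["subject"])
            if og_of(g, og_membership) in selected
        }
        mask = hits["query"].isin(genes) | hits["subject"].isin(genes)
        extended = hits[mask].reset_index(drop=True)
    return OGNeighborhood(focal_og=focal_og, ranked=ranked, extended_hits=extended)


def neighborhoods_to_frame(
    neighborhoods: Iterable[OGNeighborhood],
) -> pd.DataFrame:
    """Flatten neighborhoods into the ``neighborhood`` TSV layout."""
    recs = []
    for nb in neighborhoods:
        for rank, (og, n_links, mb) in enumerate(nb.ranked, start=1):
            recs.append(
                {
                    "focal_og": nb.focal_og,
                    "rank": rank,
                    "neighbor_og": og,
                    "links": n_links,
                    "max_bitscore": mb,
                }
            )
    return pd.DataFrame(
        recs, columns=["focal_og", "rank", "neighbor_og", "links", "max_bitscore"]
    )
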