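"""Per-hypothesis calling of expanded orthologous groups.

A *hypothesis* declares a set of species expected to show gene-family
expansion (``expanded_in``) against a set expected not to (``compared_to``),
plus three numeric cutoffs: the minimum number of ``expanded_in`` species
that must fulfil the criteria (``nmin_expanded_in``), the minimum factor of
expansion (``min_expansion_factor``) and the minimum number of additional
genes (``min_expansion_difference``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .formats_io import OrthoGroupTable, SpeciesProfile

__all__ = [
    "Hypothesis",
    "ExpansionCall",
    "adjusted_counts",
    "pairwise_expanded",
    "call_expansion",
    "call_all",
]


@dataclass(frozen=True)
class Hypothesis:
    """One expansion question: which OGs are expanded in ``expanded_in``
    relative to ``compared_to``?"""

    index: int
    name: str
    expanded_in: frozenset[str]
    compared_to: frozenset[str]
    nmin_expanded_in: int = 1
    min_expansion_factor: float = 2.0
    min_expansion_difference: int = 0
    ploidy_normalize: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "expanded_in", frozenset(self.expanded_in))
        object.__setattr__(self, "compared_to", frozenset(self.compared_to))
        if not self.expanded_in:
            raise ValueError(f"hypothesis {self.index}: expanded_in is empty")
        if not self.compared_to:
            raise ValueError(f"hypothesis {self.index}: compared_to is empty")
        overlap = self.expanded_in & self.compared_to
        if overlap:
            raise ValueError(
                f"hypothesis {self.index}: expanded_in and compared_to "
                f"overlap: {sorted(overlap)}"
            )
        if self.nmin_expanded_in < 1:
            raise ValueError(f"hypothesis {self.index}: nmin_expanded_in must be >= 1")
        if self.nmin_expanded_in > len(self.expanded_in):
            raise ValueError(
                f"hypothesis {self.index}: nmin_expanded_in "
                f"({self.nmin_expanded_in}) exceeds |expanded_in| "
                f"({len(self.expanded_in)})"
            )
        if self.min_expansion_factor < 1:
            raise ValueError(
                f"hypothesis {self.index}: min_expansion_factor must be >= 1"
            )
        if self.min_expansion_difference < 0:
            raise ValueError(
                f"hypothesis {self.index}: min_expansion_difference must be >= 0"
            )

    @property
    def species(self) -> frozenset[str]:
        return self.expanded_in | self.compared_to


@dataclass
class ExpansionCall:
    """Result of evaluating one hypothesis on one OG."""

    og_id: str
    hypothesis_index: int
    counts: dict[str, int]
    adjusted: dict[str, float]
    qualifying: dict[str, bool]
    expanded: bool


def adjusted_counts(
    row: Mapping[str, list[str]],
    species_profiles: Mapping[str, "SpeciesProfile"] | None,
    normalize: bool,
) -> dict[str, float]:
    """Per-species gene counts, optionally ploidy-normalised.

    With ``normalize`` the raw count is scaled by ``2 / ploidy`` so that a
    tetraploid carrying twice the copies of a diploid scores the same.
    """
    counts = {sp: float(len(genes)) for sp, genes in row.items()}
    if not normalize:
        return counts
    if species_profiles is None:
        raise ValueError("ploidy normalisation requires species profiles")
    out: dict[str, float] = {}
    for sp, c in counts.items():
        try:
            ploidy = species_profiles[sp].ploidy
        except KeyError:
            raise ValueError(f"no species profile for {sp!r}") from None
        if ploidy < 1:
            raise ValueError(f"species {sp!r}: ploidy must be >= 1, got {ploidy}")
        out[sp] = c * 2.0 / ploidy
    return out


def pairwise_expanded(
    count_a: float, count_b: float, factor: float, difference: float
) -> bool:
    """True iff species A's count qualifies as expanded against species B's.

    Requires ``count_a >= 1`` (an absent family is never expanded),
    ``count_a >= factor * count_b`` and ``count_a - count_b >= difference``.
    Equality counts as expanded. The ``count_a >= 1`` guard matters when
    ``count_b == 0``: the factor condition is then vacuous and only the
    difference condition gates the call.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    return (
        count_a >= 1
        and count_a >= factor * count_b
        and count_a - count_b >= difference
    )


def call_expansion(
    og_id: str,
    row: Mapping[str, list[str]],
    hypothesis: Hypothesis,
    species_profiles: Mapping[str, "SpeciesProfile"] | None = None,
    comparison: str = "all",
) -> ExpansionCall:
    """Evaluate one hypothesis on one OG row.

    An ``expanded_in`` species *qualifies* iff :func:`pairwise_expanded`
    holds against every ``compared_to`` species (``comparison="all"``,
    default) or against at least one (``comparison="any"``). The OG is
    expanded iff at least ``nmin_expanded_in`` species qualify.
    """
    if comparison not in ("all", "any"):
        raise ValueError(f"comparison must be 'all' or 'any', got {comparison!r}")
    missing = sorted(hypothesis.species - set(row))
    if missing:
        raise KeyError(
            f"OG {og_id}: species missing from orthogroup table: {missing}"
        )
    counts = {sp: len(row[sp]) for sp in sorted(hypothesis.species)}
    adjusted = adjusted_counts(
        {sp: row[sp] for sp in hypothesis.species},
        species_profiles,
        hypothesis.ploidy_normalize,
    )
    agg = all if comparison == "all" else any
    qualifying: dict[str, bool] = {}
    for sp in sorted(hypothesis.expanded_in):
        qualifying[sp] = agg(
            pairwise_expanded(
                adjusted[sp],
                adjusted[other],
                hypothesis.min_expansion_factor,
                hypothesis.min_expansion_difference,
            )
            for other in hypothesis.compared_to
        )
    n_qualifying = sum(qualifying.values())
    return ExpansionCall(
        og_id=og_id,
        hypothesis_index=hypothesis.index,
        counts=counts,
        adjusted={sp: adjusted[sp] for sp in sorted(adjusted)},
        qualifying=qualifying,
        expanded=n_qualifying >= hypothesis.nmin_expanded_in,
    )


def call_all(
    table: "OrthoGroupTable",
    hypotheses: Iterable[Hypothesis],
    species_profiles: Mapping[str, "SpeciesProfile"] | None = None,
    comparison: str = "all",
) -> dict[int, list[ExpansionCall]]:
    """Evaluate every hypothesis on every OG, preserving input row order."""
    out: dict[int, list[ExpansionCall]] = {}
    for hyp in hypotheses:
        calls: list[ExpansionCall] = []
        for og_id, row in table.rows.items():
            try:
                calls.append(
                    call_expansion(og_id, row, hyp, species_profiles, comparison)
                )
            except (KeyError, ValueError) as exc:
                raise type(exc)(f"hypothesis {hyp.index} ({hyp.name}): {exc}") from exc
        out[hyp.index] = calls
    return out


def expanded_og_ids(calls: Iterable[ExpansionCall]) -> list[str]:
    """OG ids flagged expanded, in call order."""
    return [c.og_id for c in calls if c.expanded]
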