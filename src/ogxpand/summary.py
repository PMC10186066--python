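"""Per-OG integration tables: gene counts, expansion flags, DEG counts,
conservation and species membership patterns."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expansion import ExpansionCall, Hypothesis
from .formats_io import DERecord, OrthoGroupTable

__all__ = [
    "OGSummaryRow",
    "significant_genes",
    "summarize",
    "membership_counts",
    "size_distribution",
    "summary_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class OGSummaryRow:
    """One OG under one hypothesis: counts, expansion flag, DEG counts,
    conservation and presence pattern, restricted to the hypothesis
    species."""

    og_id: str
    counts: dict[str, int]
    expanded: bool
    deg_counts: dict[str, int]
    total_genes: int
    conserved: bool
    membership_pattern: frozenset[str]


def significant_genes(
    de_records: Iterable[DERecord],
    alpha: float,
    min_abs_log2fc: float = 0.0,
) -> dict[str, set[str]]:
    """Per-species sets of significant genes: padj present and <= alpha
    (inclusive), optionally also requiring ``|log2fc| >= min_abs_log2fc``.

    Missing padj never counts as significant. Duplicate (species, gene)
    rows collapse to the first occurrence with a single warning.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    out: dict[str, set[str]] = {}
    seen: set[tuple[str, str]] = set()
    warned = False
    for rec in de_records:
        key = (rec.species, rec.gene_id)
        if key in seen:
            if not warned:
                logger.warning(
                    "duplicate DE rows (first occurrence wins), e.g. %s/%s",
                    rec.species, rec.gene_id,
                )
                warned = True
            continue
        seen.add(key)
        out.setdefault(rec.species, set())
        if rec.padj is None or rec.padj > alpha:
            continue
        if abs(rec.log2fc) < min_abs_log2fc:
            continue
        out[rec.species].add(rec.gene_id)
    return out


def summarize(
    table: OrthoGroupTable,
    calls: Sequence[ExpansionCall],
    deg_sets: Mapping[str, set[str]],
    hypothesis: Hypothesis,
) -> list[OGSummaryRow]:
    """Build one summary row per OG, restricted to the hypothesis species.

    DEG counts intersect each OG's per-species gene list with the
    per-species significant sets. Significant genes that belong to no OG
    are permitted (they are unassigned singletons) and logged once.
    """
    call_by_og = {c.og_id: c for c in calls}
    missing = set(table.rows) - set(call_by_og)
    if missing:
        raise ValueError(f"no expansion call for OGs: {sorted(missing)[:5]}...")
    species = sorted(hypothesis.species)
    rows: list[OGSummaryRow] = []
    assigned: set[str] = set()
    for og_id, row in table.rows.items():
        counts = {sp: len(row[sp]) for sp in species}
        deg_counts = {
            sp: len(set(row[sp]) & deg_sets.get(sp, set())) for sp in species
        }
        for sp in species:
            assigned.update(set(row[sp]) & deg_sets.get(sp, set()))
        pattern = frozenset(sp for sp in species if counts[sp] > 0)
        rows.append(
            OGSummaryRow(
                og_id=og_id,
                counts=counts,
                expanded=call_by_og[og_id].expanded,
                deg_counts=deg_counts,
                total_genes=sum(counts.values()),
                conserved=pattern == hypothesis.species,
                membership_pattern=pattern,
            )
        )
    n_unassigned = sum(len(s) for s in deg_sets.values()) - len(assigned)
    if n_unassigned > 0:
        logger.info(
            "%d significant genes are not assigned to any OG", n_unassigned
        )
    return rows


def membership_counts(
    table: OrthoGroupTable,
    species_subset: Sequence[str],
    unassigned_genes: Sequence[str] = (),
) -> tuple[dict[frozenset[str], int], int]:
    """Count OGs per species presence pattern over ``species_subset``.

    Every OG maps to exactly one pattern (the set of subset species with
    >= 1 gene); OGs with no genes in the subset fall under the empty
    pattern. Returns the pattern -> count map and the singleton gene count:
    genes in OGs of total size 1 (within the subset) plus the supplied
    unassigned genes.
    """
    if not species_subset:
        raise ValueError("species_subset must be non-empty")
    patterns: Counter[frozenset[str]] = Counter()
    singletons = 0
    for row in table.rows.values():
        counts = {sp: len(row.get(sp, [])) for sp in species_subset}
        patterns[frozenset(sp for sp, c in counts.items() if c > 0)] += 1
        if sum(counts.values()) == 1:
            singletons += 1
    return dict(patterns), singletons + len(unassigned_genes)


def size_distribution(
    table: OrthoGroupTable,
    og_ids: Iterable[str] | None = None,
    species_subset: Sequence[str] | None = None,
) -> dict[int, int]:
    """Histogram of OG total gene count (number of OGs per group size)."""
    ids = table.og_ids if og_ids is None else list(og_ids)
    species = table.species_order if species_subset is None else list(species_subset)
    hist: Counter[int] = Counter()
    for og_id in ids:
        row = table.rows[og_id]
        hist[sum(len(row.get(sp, [])) for sp in species)] += 1
    return dict(hist)


def summary_to_frame(rows: Sequence[OGSummaryRow]) -> pd.DataFrame:
    """Flatten summary rows into the ``og_summary`` TSV layout."""
    if not rows:
        return pd.DataFrame(
            columns=["og_id", "total_genes", "expanded", "conserved", "pattern"]
        )
    species = sorted(rows[0].counts)
    recs = []
    for r in rows:
        rec: dict = {"og_id": r.og_id}
        for sp in species:
            rec[f"count_{sp}"] = r.counts[sp]
        for sp in species:
            rec[f"deg_{sp}"] = r.deg_counts[sp]
        rec["total_genes"] = r.total_genes
        rec["expanded"] = r.expanded
        rec["conserved"] = r.conserved
        rec["pattern"] = ";".join(sorted(r.membership_pattern))
        recs.append(rec)
    return pd.DataFrame(recs)


def frame_to_summary(df: pd.DataFrame) -> list[OGSummaryRow]:
    """Inverse of :func:`summary_to_frame` (used when testing sets from a
    saved bundle)."""
    species = [c[len("count_"):] for c in df.columns if c.startswith("count_")]
    rows = []
    for _, rec in df.iterrows():
        counts = {sp: int(rec[f"count_{sp}"]) for sp in species}
        deg = {sp: int(rec[f"deg_{sp}"]) for sp in species}
        pattern = frozenset(
            s for s in str(rec["pattern"]).split(";") if s and s != "nan"
        )
        rows.append(
            OGSummaryRow(
                og_id=rec["og_id"],
                counts=counts,
                expanded=bool(rec["expanded"]),
                deg_counts=deg,
                total_genes=int(rec["total_genes"]),
                conserved=bool(rec["conserved"]),
                membership_pattern=pattern,
            )
        )
    return rows
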