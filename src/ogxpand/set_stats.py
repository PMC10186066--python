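"""Exact over-representation statistics for OG sets (urn model).

The p-value is the upper tail P[X >= k] of a hypergeometric distribution:
``N`` background OGs of which ``K`` are successes; ``n`` are sampled and
``k`` of those are successes. For small ``N`` the tail is summed with
exact integer binomial coefficients (bit-for-bit reproducible); above
``EXACT_N_LIMIT`` it falls back to log-space summation (scipy).

Set membership is expressed through a tiny predicate language evaluated on
:class:`~ogxpand.summary.OGSummaryRow` objects, e.g.::

    expanded & deg[Hordeum_vulgare]>=1 & count[Hordeum_vulgare]>4
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import comb
from typing import Callable, Iterable, Sequence

from scipy.stats import hypergeom as _scipy_hypergeom

from .summary import OGSummaryRow

__all__ = [
    "UrnSpec",
    "SetPredicate",
    "SetTestResult",
    "hypergeom_sf",
    "fisher_one_sided",
    "fisher_two_sided",
    "overrepresentation",
]

#: Largest background size for which the exact integer path is used.
EXACT_N_LIMIT = 10_000


@dataclass(frozen=True)
class UrnSpec:
    """Hypergeometric urn: N background, K successes in background,
    n sampled, k successes in sample."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N):
            raise ValueError(f"urn requires 0 <= K <= N, got K={self.K}, N={self.N}")
        if not (0 <= self.n <= self.N):
            raise ValueError(f"urn requires 0 <= n <= N, got n={self.n}, N={self.N}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"urn requires 0 <= k <= min(K, n), got k={self.k}, "
                f"K={self.K}, n={self.n}"
            )
        if self.n - self.k > self.N - self.K:
            raise ValueError(
                f"urn overfull: n-k={self.n - self.k} failures exceed "
                f"N-K={self.N - self.K}"
            )


def hypergeom_sf(urn: UrnSpec) -> float:
    """Upper-tail probability P[X >= k] for the urn; 0 < p <= 1.

    Exact integer binomial-coefficient summation for N <= 10^4; log-space
    summation (scipy) above.
    """
    if urn.k == 0:
        return 1.0
    if urn.N > EXACT_N_LIMIT:
        return float(_scipy_hypergeom.sf(urn.k - 1, urn.N, urn.K, urn.n))
    kmax = min(urn.K, urn.n)
    num = sum(
        comb(urn.K, i) * comb(urn.N - urn.K, urn.n - i)
        for i in range(urn.k, kmax + 1)
    )
    return num / comb(urn.N, urn.n)


def fisher_one_sided(urn: UrnSpec) -> float:
    """One-sided (greater) Fisher exact test on the 2x2 table implied by
    the urn; identical to :func:`hypergeom_sf` by construction."""
    a = urn.k
    b = urn.n - urn.k
    c = urn.K - urn.k
    d = urn.N - urn.K - urn.n + urn.k
    if min(a, b, c, d) < 0:
        raise ValueError(f"urn implies a negative 2x2 cell: {(a, b, c, d)}")
    return hypergeom_sf(UrnSpec(N=a + b + c + d, K=a + c, n=a + b, k=a))


def fisher_two_sided(urn: UrnSpec) -> float:
    """Two-sided Fisher exact p: sum of all tables as or less probable
    than the observed one."""
    if urn.N > EXACT_N_LIMIT:
        from scipy.stats import fisher_exact

        table = [[urn.k, urn.n - urn.k], [urn.K - urn.k, urn.N - urn.K - urn.n + urn.k]]
        return float(fisher_exact(table, alternative="two-sided")[1])
    kmin = max(0, urn.n - (urn.N - urn.K))
    kmax = min(urn.K, urn.n)
    den = comb(urn.N, urn.n)
    obs = comb(urn.K, urn.k) * comb(urn.N - urn.K, urn.n - urn.k)
    num = sum(
        t
        for i in range(kmin, kmax + 1)
        if (t := comb(urn.K, i) * comb(urn.N - urn.K, urn.n - i)) <= obs
    )
    return min(1.0, num / den)


# ---------------------------------------------------------------------------
# predicate language
# ---------------------------------------------------------------------------

_ATOM_RE = re.compile(
    r"""^(?:
        (?P<kw>expanded|conserved|all|true)
      | any_deg\s*(?P<anyop>>=|<=|==|>|<)\s*(?P<anyval>\d+)
      | total\s*(?P<totop>>=|<=|==|>|<)\s*(?P<totval>\d+)
      | (?P<fn>deg|count)\[(?P<sp>[^\]]+)\]\s*(?P<op>>=|<=|==|>|<)\s*(?P<val>\d+)
    )$""",
    re.VERBOSE,
)

_OPS: dict[str, Callable[[int, int], bool]] = {
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
}


@dataclass(frozen=True)
class SetPredicate:
    """A conjunction of atoms over OG summary rows.

    Atoms: ``expanded``, ``conserved``, ``all``/``true``,
    ``any_deg>=m`` (max per-species DEG count), ``total>=c`` (total genes),
    ``deg[Species]>=m`` and ``count[Species]>=c`` (operators ``>= <= == > <``).
    Atoms are joined with ``&``.
    """

    expression: str

    @staticmethod
    def parse(expression: str) -> "SetPredicate":
        pred = SetPredicate(expression)
        pred._compile()  # validate eagerly
        return pred

    def _compile(self) -> list[Callable[[OGSummaryRow], bool]]:
        atoms: list[Callable[[OGSummaryRow], bool]] = []
        text = self.expression.strip()
        if not text:
            return atoms
        for raw in text.split("&"):
            atom = raw.strip()
            m = _ATOM_RE.match(atom)
            if m is None:
                raise ValueError(f"cannot parse predicate atom {atom!r}")
            if m.group("kw") in ("all", "true"):
                continue
            if m.group("kw") == "expanded":
                atoms.append(lambda r: r.expanded)
            elif m.group("kw") == "conserved":
                atoms.append(lambda r: r.conserved)
            elif m.group("anyop"):
                op, val = _OPS[m.group("anyop")], int(m.group("anyval"))
                atoms.append(
                    lambda r, op=op, val=val: op(
                        max(r.deg_counts.values(), default=0), val
                    )
                )
            elif m.group("totop"):
                op, val = _OPS[m.group("totop")], int(m.group("totval"))
                atoms.append(lambda r, op=op, val=val: op(r.total_genes, val))
            else:
                fn, sp = m.group("fn"), m.group("sp").strip()
                op, val = _OPS[m.group("op")], int(m.group("val"))
                src = (lambda r, sp=sp: r.deg_counts.get(sp, 0)) if fn == "deg" \
                    else (lambda r, sp=sp: r.counts.get(sp, 0))
                atoms.append(lambda r, src=src, op=op, val=val: op(src(r), val))
        return atoms

    def __call__(self, row: OGSummaryRow) -> bool:
        return all(atom(row) for atom in self._compile())

    def filter(self, rows: Iterable[OGSummaryRow]) -> list[OGSummaryRow]:
        atoms = self._compile()
        return [r for r in rows if all(a(r) for a in atoms)]


@dataclass
class SetTestResult:
    urn: UrnSpec
    p: float
    fold_enrichment: float | None
    #: ring counts for the urn plot: background, success-in-background,
    #: sample, success-in-sample
    rings: dict[str, int] | None = None


def overrepresentation(
    sample: SetPredicate,
    success: SetPredicate,
    background: SetPredicate,
    rows: Sequence[OGSummaryRow],
) -> SetTestResult:
    """Test whether ``success`` OGs are over-represented in the ``sample``
    relative to the ``background``.

    The sample is intersected with the background before counting. Returns
    the urn, the one-sided p and the fold enrichment ``(k/n) / (K/N)``
    (missing when undefined).
    """
    bg = background.filter(rows)
    if not bg:
        raise ValueError("background predicate selects no OGs")
    bg_ids = {r.og_id for r in bg}
    samp = [r for r in sample.filter(rows) if r.og_id in bg_ids]
    succ_ids = {r.og_id for r in success.filter(rows) if r.og_id in bg_ids}
    N, n = len(bg), len(samp)
    K = len(succ_ids)
    k = sum(1 for r in samp if r.og_id in succ_ids)
    urn = UrnSpec(N=N, K=K, n=n, k=k)
    if n == 0:
        return SetTestResult(urn=urn, p=1.0, fold_enrichment=None,
                             rings={"N": N, "K": K, "n": n, "k": k})
    p = hypergeom_sf(urn)
    fold = None
    if K > 0:
        fold = (k / n) / (K / N)
    return SetTestResult(urn=urn, p=p, fold_enrichment=fold,
                         rings={"N": N, "K": K, "n": n, "k": k})
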