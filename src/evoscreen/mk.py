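"""McDonald-Kreitman test.

Assembles the 2x2 polymorphism/divergence contingency table (Pn/Ps within
species, Dn/Ds fixed between species), evaluates it with an in-house
two-sided Fisher's exact test computed in log space, and reports the
neutrality index NI = (Pn/Ps)/(Dn/Ds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy.special import gammaln

from .codonseq import CodonCounts

# relative tolerance on the "point probability <= observed" comparison,
# guarding against ties broken by floating-point noise
_PMF_RTOL = 1e-7


@dataclass(frozen=True)
class MKTable:
    """Counts: rows = within-species variation / fixed differences,
    columns = nonsynonymous / synonymous."""

    pn: int
    ps: int
    dn: int
    ds: int

    def __post_init__(self):
        for name in ("pn", "ps", "dn", "ds"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.pn + self.ps + self.dn + self.ds


@dataclass(frozen=True)
class FETResult:
    p_two_sided: float
    odds_ratio: float
    degenerate: bool = False  # a zero margin: p = 1 by convention


@dataclass(frozen=True)
class MKResult:
    table: MKTable
    fet: FETResult
    neutrality_index: Optional[float]  # None when undefined (zero in a ratio term)
    significant: bool
    alpha: float
    dn_raw: Optional[float] = None  # fractional divergence before rounding
    ds_raw: Optional[float] = None


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(X = a) for X ~ Hypergeom with margins (r1, r2) x (c1, c2)."""
    n = r1 + r2
    b = r1 - a
    c = c1 - a
    d = r2 - c
    return (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(b + 1)
        + gammaln(r2 + 1)
        - gammaln(c + 1)
        - gammaln(d + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_two_sided(table: MKTable) -> FETResult:
    """Exact two-sided Fisher test by the point-probability rule.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one
    (within relative tolerance), all in log space via log-gamma.
    A zero margin yields p = 1, flagged degenerate.
    """
    a, b, c, d = table.pn, table.ps, table.dn, table.ds
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table: every margin is zero")

    # odds ratio ad/bc with the usual infinity convention
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)

    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return FETResult(p_two_sided=1.0, odds_ratio=odds, degenerate=True)

    lp_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    cutoff = lp_obs + math.log1p(_PMF_RTOL)
    logs = [
        lp
        for k in range(lo, hi + 1)
        if (lp := _log_hypergeom_pmf(k, r1, r2, c1)) <= cutoff
    ]
    m = max(logs)
    p = math.exp(m) * sum(math.exp(lp - m) for lp in logs)
    return FETResult(p_two_sided=min(p, 1.0), odds_ratio=odds)


def neutrality_index(table: MKTable) -> Optional[float]:
    """NI = (Pn/Ps)/(Dn/Ds); None when any denominator term is zero."""
    if table.ps == 0 or table.ds == 0 or table.dn == 0:
        return None
    return (table.pn / table.ps) / (table.dn / table.ds)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mk_test(
    polymorphisms: tuple,
    divergence,
    alpha: float = 0.05,
) -> MKResult:
    """Run the MK test from polymorphism tallies and divergence counts.

    ``polymorphisms`` is (Pn, Ps) from validated within-species variants.
    ``divergence`` is either a :class:`~evoscreen.codonseq.CodonCounts`
    (fractional pathway-averaged differences, rounded half-up to integers
    for the table; raw values retained in the result) or a (Dn, Ds) tuple
    of integers.
    """
    pn, ps = polymorphisms
    if isinstance(divergence, CodonCounts):
        dn_raw, ds_raw = divergence.n_diff, divergence.s_diff
        dn, ds = _round_half_up(dn_raw), _round_half_up(ds_raw)
    else:
        dn, ds = divergence
        dn_raw = ds_raw = None
    table = MKTable(pn=pn, ps=ps, dn=dn, ds=ds)
    fet = fisher_exact_two_sided(table)
    return MKResult(
        table=table,
        fet=fet,
        neutrality_index=neutrality_index(table),
        significant=fet.p_two_sided < alpha,
        alpha=alpha,
        dn_raw=dn_raw,
        ds_raw=ds_raw,
    )


def read_mk_tables(path) -> dict:
    """Read per-gene MK count tables from TSV (gene, Pn, Ps, Dn, Ds)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "Pn", "Ps", "Dn", "Ds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {
        str(row.gene): MKTable(pn=int(row.Pn), ps=int(row.Ps), dn=int(row.Dn), ds=int(row.Ds))
        for row in df.itertuples(index=False)
    }


def mk_results_frame(results: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Tabulate per-gene MK results (gene -> MKResult) for TSV/JSON output."""
    rows = []
    for gene, r in sorted(results.items()):
        rows.append(
            {
                "gene": gene,
                "Pn": r.table.pn,
                "Ps": r.table.ps,
                "Dn": r.table.dn,
                "Ds": r.table.ds,
                "p_two_sided": r.fet.p_two_sided,
                "odds_ratio": r.fet.odds_ratio,
                "neutrality_index": (
                    r.neutrality_index if r.neutrality_index is not None else float("nan")
                ),
                "NI_defined": r.neutrality_index is not None,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
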