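"""Expression-screen triage of differential-expression result tables.

Consumes limma/GEO2R-style per-dataset tables (probe, gene symbol, raw and
adjusted p, log fold change), applies Benjamini-Hochberg adjustment where
needed, converts raw p-values to inverse-normal Z-scores, selects candidate
genes by a raw-p gate plus a |z| threshold, and finds genes significant in
two or more datasets.

The Z-score is the standard-normal quantile of the *raw* p-value (the
familiar spreadsheet NORMSINV); the adjusted p is carried through for
reporting only. An optional flag signs z by the fold-change direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("probe_id", "gene_symbol", "p_raw", "p_adj", "log_fc")

DEFAULT_P_CUTOFF = 1e-3
DEFAULT_Z_CUTOFF = 5.5


def bh_adjust(p_values: Sequence) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adj_(i) = min over j >= i of (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    bad = np.where((p <= 0) | (p > 1) | ~np.isfinite(p))[0]
    if bad.size:
        raise ValueError(f"p-value out of (0, 1] at index {int(bad[0])}: {p[bad[0]]}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def z_from_p(p_raw, log_fc=None, sign_by_direction: bool = False):
    """Inverse-normal Z-score of a raw p-value (NORMSINV convention).

    z = Phi^-1(p_raw), negative for p < 0.5. With ``sign_by_direction``,
    |z| is given the sign of ``log_fc`` instead.
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p-values must lie strictly inside (0, 1) for a finite quantile")
    z = norm.ppf(p)
    if sign_by_direction:
        if log_fc is None:
            raise ValueError("sign_by_direction requires log_fc")
        z = np.abs(z) * np.sign(np.asarray(log_fc, dtype=float))
    return z if z.shape else float(z)


@dataclass
class DatasetScreen:
    """One dataset's screen: the annotated table plus its significant subset."""

    dataset_id: str
    records: pd.DataFrame
    significant_ids: list = field(default_factory=list)


def load_screen_table(path, dataset_id: str) -> DatasetScreen:
    """Read a per-dataset TSV (header required: probe_id, gene_symbol,
    p_raw, p_adj, log_fc) and attach Z-scores."""
    df = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return annotate_screen(df, dataset_id)


def annotate_screen(
    records: pd.DataFrame, dataset_id: str, sign_by_direction: bool = False
) -> DatasetScreen:
    """Attach (or recompute) the z column from raw p-values."""
    df = records.copy()
    df["z"] = z_from_p(
        df["p_raw"].to_numpy(),
        df["log_fc"].to_numpy(),
        sign_by_direction=sign_by_direction,
    )
    return DatasetScreen(dataset_id=dataset_id, records=df)


def select_candidates(
    screen: DatasetScreen,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> list:
    """Keep probes with p_raw <= p_cutoff AND |z| >= z_cutoff (both inclusive)."""
    df = screen.records
    mask = (df["p_raw"] <= p_cutoff) & (df["z"].abs() >= z_cutoff)
    ids = df.loc[mask, "probe_id"].tolist()
    screen.significant_ids = ids
    return ids


def cross_dataset_overlap(screens: Iterable[DatasetScreen]) -> dict:
    """Genes significant in >= 2 distinct datasets.

    Gene symbols are harmonized case-insensitively; duplicate probes for a
    gene within one dataset are deduplicated keeping the smallest adjusted
    p (logged). Returns gene -> list of (dataset_id, probe_id, p_adj)
    evidence rows.
    """
    evidence: dict = {}
    for screen in screens:
        df = screen.records
        sig = df[df["probe_id"].isin(set(screen.significant_ids))]
        best: dict = {}
        for row in sig.itertuples(index=False):
            key = str(row.gene_symbol).upper()
            if key in best and best[key][2] <= row.p_adj:
                logger.info(
                    "dataset %s: duplicate probes for gene %s; keeping smallest p",
                    screen.dataset_id,
                    row.gene_symbol,
                )
                continue
            best[key] = (screen.dataset_id, row.probe_id, float(row.p_adj))
        for key, row in best.items():
            evidence.setdefault(key, []).append(row)
    return {
        gene: rows
        for gene, rows in evidence.items()
        if len({ds for ds, _, _ in rows}) >= 2
    }


def overlap_frame(overlap: dict) -> pd.DataFrame:
    """Flatten the overlap map into a tidy evidence table."""
    rows = [
        {"gene_symbol": gene, "dataset_id": ds, "probe_id": probe, "p_adj": p}
        for gene in sorted(overlap)
        for ds, probe, p in overlap[gene]
    ]
    return pd.DataFrame(rows, columns=["gene_symbol", "dataset_id", "probe_id", "p_adj"])
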