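"""Running per-residue dN/dS with peptide-region annotation and variant overlay.

Pools NG86 per-codon counts in a rectangular window around each residue
(edge windows shrink), forms a pseudocounted omega, summarizes named
peptide regions against the gene-wide average, and flags variants that
fall in locally fast-evolving (omega > 1) stretches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .codonseq import CodonCounts

DEFAULT_WINDOW = 10  # half-width in residues
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class PeptideRegion:
    """A named peptide interval in 1-based inclusive residue coordinates.

    Regions may overlap and nest (a short bioactive peptide inside its
    parent peptide, for instance).
    """

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad region {self.name}: {self.start}..{self.end}")

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass
class DnDsTrack:
    """Per-residue omega values; NaN marks residues where omega is undefined."""

    values: np.ndarray
    window: int
    pseudocount: float

    @property
    def length(self) -> int:
        return len(self.values)

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def running_dnds(
    per_codon_counts: Sequence,
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DnDsTrack:
    """Sliding-window omega along the protein.

    At residue i, counts are pooled over residues [i - window, i + window]
    clipped to the protein, and omega_i = ((N_diff + c) / N_sites) /
    ((S_diff + c) / S_sites) with pseudocount c. Windows whose pooled
    S_sites (or N_sites) is zero yield NaN, never a silent 0. Entries of
    ``per_codon_counts`` may be None (uncomparable codons); they contribute
    nothing to the pool.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    n = len(per_codon_counts)
    s_sites = np.zeros(n)
    n_sites = np.zeros(n)
    s_diff = np.zeros(n)
    n_diff = np.zeros(n)
    for i, c in enumerate(per_codon_counts):
        if c is None:
            continue
        s_sites[i], n_sites[i] = c.s_sites, c.n_sites
        s_diff[i], n_diff[i] = c.s_diff, c.n_diff
    cs_ss = np.concatenate([[0.0], np.cumsum(s_sites)])
    cs_ns = np.concatenate([[0.0], np.cumsum(n_sites)])
    cs_sd = np.concatenate([[0.0], np.cumsum(s_diff)])
    cs_nd = np.concatenate([[0.0], np.cumsum(n_diff)])
    values = np.full(n, np.nan)
    for i in range(n):
        lo = max(0, i - window)
        hi = min(n, i + window + 1)
        ss = cs_ss[hi] - cs_ss[lo]
        ns = cs_ns[hi] - cs_ns[lo]
        sd = cs_sd[hi] - cs_sd[lo]
        nd = cs_nd[hi] - cs_nd[lo]
        if ss <= 0 or ns <= 0:
            continue
        ds = (sd + pseudocount) / ss
        dn = (nd + pseudocount) / ns
        if ds > 0:
            values[i] = dn / ds
    return DnDsTrack(values=values, window=window, pseudocount=pseudocount)


@dataclass(frozen=True)
class RegionSummary:
    name: str
    start: int
    end: int
    mean_omega: float  # NaN when the region is fully undefined
    n_defined: int
    conserved: bool  # mean omega below the gene-wide average
    fully_undefined: bool


def summarize_regions(
    track: DnDsTrack, regions: Sequence, global_omega: float
) -> List[RegionSummary]:
    """Mean omega per peptide region with a conservation flag.

    The mean is taken over defined residues only; a region whose residues
    are all undefined is flagged rather than silently averaged.
    """
    out = []
    for r in regions:
        if r.end > track.length:
            raise ValueError(
                f"region {r.name} ({r.start}..{r.end}) exceeds track length "
                f"{track.length}"
            )
        vals = track.values[r.start - 1 : r.end]
        defined = vals[np.isfinite(vals)]
        if defined.size == 0:
            out.append(
                RegionSummary(r.name, r.start, r.end, float("nan"), 0, False, True)
            )
            continue
        mean = float(defined.mean())
        out.append(
            RegionSummary(
                r.name, r.start, r.end, mean, int(defined.size),
                conserved=mean < global_omega, fully_undefined=False,
            )
        )
    return out


@dataclass(frozen=True)
class OverlayEntry:
    residue_position: int
    variant_id: str
    tolerance_call: str
    in_regions: tuple
    high_omega: bool  # local track omega > 1.0 at the variant's residue


@dataclass
class VariantOverlay:
    entries: List[OverlayEntry] = field(default_factory=list)
    rejected: List[str] = field(default_factory=list)  # out-of-range variants


def overlay_variants(
    track: DnDsTrack, regions: Sequence, variants: Iterable
) -> VariantOverlay:
    """Annotate variants with containing regions and the high-omega flag.

    ``variants`` are records with ``residue_position``, ``variant_id`` and
    an optional tolerance/consensus call. A variant sitting where the local
    omega exceeds 1.0 is flagged high_omega (the fast-region display rule).
    Out-of-range positions are rejected with a report; the run continues.
    """
    overlay = VariantOverlay()
    for v in variants:
        pos = v.residue_position
        vid = getattr(v, "variant_id", "") or f"pos{pos}"
        if not (1 <= pos <= track.length):
            overlay.rejected.append(
                f"{vid}: residue {pos} outside protein of length {track.length}"
            )
            continue
        value = track.values[pos - 1]
        call = getattr(v, "tolerance_call", None) or getattr(v, "effect", None)
        overlay.entries.append(
            OverlayEntry(
                residue_position=pos,
                variant_id=vid,
                tolerance_call=str(call) if call is not None else "",
                in_regions=tuple(r.name for r in regions if r.contains(pos)),
                high_omega=bool(np.isfinite(value) and value > 1.0),
            )
        )
    return overlay


# ---------------------------------------------------------------------------
# plain-text I/O


def read_regions(path) -> List[PeptideRegion]:
    """BED-like region file: gene, start, end, name (TSV, 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "start", "end", "name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PeptideRegion(name=str(r.name), start=int(r.start), end=int(r.end))
        for r in df.itertuples(index=False)
    ]


def track_frame(track: DnDsTrack) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue": np.arange(1, track.length + 1),
            "omega": track.values,
            "defined": track.defined(),
        }
    )


def overlay_frame(overlay: VariantOverlay) -> pd.DataFrame:
    rows = [
        {
            "residue": e.residue_position,
            "variant_id": e.variant_id,
            "tolerance_call": e.tolerance_call,
            "in_regions": ",".join(e.in_regions),
            "high_omega": e.high_omega,
        }
        for e in overlay.entries
    ]
    return pd.DataFrame(
        rows, columns=["residue", "variant_id", "tolerance_call", "in_regions", "high_omega"]
    )
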