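"""Coding-variant effect classification and tolerance triage.

Classifies single-base coding changes (synonymous / missense / nonsense),
applies SIFT and PolyPhen-2 tolerance thresholds (SIFT damaging iff score
<= 0.05; PolyPhen benign / possibly_damaging / probably_damaging with a
confidence flag), consolidates the two predictors into a consensus call,
and summarizes per-gene tolerated fractions. SIFT and PolyPhen are always
consumed as scored inputs, never invoked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .codonseq import GeneticCode, STANDARD_CODE, STOP, translate
from .mk import MKTable, fisher_exact_two_sided

SIFT_DAMAGING_CUTOFF = 0.05

POLYPHEN_CALLS = ("benign", "possibly_damaging", "probably_damaging")


class Effect(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"


class Consensus(str, Enum):
    TOLERATED = "tolerated_consensus"
    DAMAGING = "damaging_consensus"
    DISCORDANT = "discordant"


@dataclass
class VariantRecord:
    gene: str
    cds_position: int  # 1-based nucleotide offset within the CDS
    ref_base: str
    alt_base: str
    residue_position: int = 0
    ref_aa: str = ""
    alt_aa: str = ""
    effect: Optional[Effect] = None
    sift_score: Optional[float] = None
    polyphen_call: Optional[str] = None
    polyphen_high_confidence: bool = True
    validated: bool = False
    variant_id: str = ""


def classify_coding_change(
    cds: str, cds_position: int, ref_base: str, alt_base: str,
    code: GeneticCode = STANDARD_CODE,
) -> Effect:
    """Substitute one base in the CDS, translate the affected codon, compare.

    Raises if the stated reference base disagrees with the CDS at that
    position (1-based) or the CDS frame is broken.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    if not (1 <= cds_position <= len(cds)):
        raise ValueError(f"cds_position {cds_position} outside CDS of length {len(cds)}")
    idx = cds_position - 1
    if cds[idx] != ref_base.upper():
        raise ValueError(
            f"reference mismatch at CDS position {cds_position}: "
            f"CDS has {cds[idx]}, variant says {ref_base}"
        )
    codon_start = 3 * (idx // 3)
    ref_codon = cds[codon_start : codon_start + 3]
    offset = idx - codon_start
    alt_codon = ref_codon[:offset] + alt_base.upper() + ref_codon[offset + 1 :]
    ref_aa = translate(ref_codon, code)
    alt_aa = translate(alt_codon, code)
    if alt_aa == STOP and ref_aa != STOP:
        return Effect.NONSENSE
    if alt_aa == ref_aa:
        return Effect.SYNONYMOUS
    return Effect.MISSENSE


def annotate_variant(
    variant: VariantRecord, cds: str, code: GeneticCode = STANDARD_CODE
) -> VariantRecord:
    """Fill effect, residue position, and ref/alt amino acids in place."""
    variant.effect = classify_coding_change(
        cds, variant.cds_position, variant.ref_base, variant.alt_base, code
    )
    idx = variant.cds_position - 1
    variant.residue_position = idx // 3 + 1
    start = 3 * (idx // 3)
    ref_codon = cds.upper()[start : start + 3]
    offset = idx - start
    variant.ref_aa = translate(ref_codon, code)
    variant.alt_aa = translate(
        ref_codon[:offset] + variant.alt_base.upper() + ref_codon[offset + 1 :], code
    )
    return variant


def sift_call(score: float) -> str:
    """SIFT tolerance call: 'damaging' iff score <= 0.05 (boundary inclusive)."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"SIFT score must be in [0, 1], got {score}")
    return "damaging" if score <= SIFT_DAMAGING_CUTOFF else "tolerated"


def consensus_tolerance(variant: VariantRecord) -> Consensus:
    """Consolidate SIFT and PolyPhen-2 into one call.

    tolerated_consensus:  SIFT tolerated AND PolyPhen benign.
    damaging_consensus:   SIFT damaging AND PolyPhen probably_damaging at
                          high confidence (low-confidence probably_damaging
                          is excluded from the damaging consensus).
    Anything else is discordant.
    """
    if variant.sift_score is None or variant.polyphen_call is None:
        raise ValueError("both SIFT and PolyPhen predictions are required")
    if variant.polyphen_call not in POLYPHEN_CALLS:
        raise ValueError(f"unknown PolyPhen call {variant.polyphen_call!r}")
    sift = sift_call(variant.sift_score)
    if sift == "tolerated" and variant.polyphen_call == "benign":
        return Consensus.TOLERATED
    if (
        sift == "damaging"
        and variant.polyphen_call == "probably_damaging"
        and variant.polyphen_high_confidence
    ):
        return Consensus.DAMAGING
    return Consensus.DISCORDANT


@dataclass
class ToleranceSummary:
    gene: str
    n_variants: int
    n_tolerated_consensus: int
    n_damaging_consensus: int
    n_discordant: int
    n_missing_prediction: int

    @property
    def fraction_tolerated(self) -> float:
        scored = self.n_tolerated_consensus + self.n_damaging_consensus + self.n_discordant
        return self.n_tolerated_consensus / scored if scored else float("nan")


def summarize_tolerance(gene: str, variants: Iterable[VariantRecord]) -> ToleranceSummary:
    """Tally consensus categories over one gene's variants.

    Variants missing either prediction are excluded from consensus counts
    and tallied separately.
    """
    tol = dam = dis = missing = total = 0
    for v in variants:
        total += 1
        if v.sift_score is None or v.polyphen_call is None:
            missing += 1
            continue
        c = consensus_tolerance(v)
        if c is Consensus.TOLERATED:
            tol += 1
        elif c is Consensus.DAMAGING:
            dam += 1
        else:
            dis += 1
    return ToleranceSummary(
        gene=gene,
        n_variants=total,
        n_tolerated_consensus=tol,
        n_damaging_consensus=dam,
        n_discordant=dis,
        n_missing_prediction=missing,
    )


def compare_gene_tolerance(summaries: Sequence) -> pd.DataFrame:
    """Pairwise Fisher exact tests on (damaging, tolerated) consensus counts.

    Each gene pair forms a 2x2 table of consensus-damaging vs
    consensus-tolerated counts; p-values come from the same exact test used
    by the MK module. Degenerate (zero-margin) tables are flagged.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two genes to compare tolerance")
    rows = []
    for i in range(len(summaries)):
        for j in range(i + 1, len(summaries)):
            a, b = summaries[i], summaries[j]
            t = MKTable(
                pn=a.n_damaging_consensus,
                ps=a.n_tolerated_consensus,
                dn=b.n_damaging_consensus,
                ds=b.n_tolerated_consensus,
            )
            fet = fisher_exact_two_sided(t)
            rows.append(
                {
                    "gene_a": a.gene,
                    "gene_b": b.gene,
                    "p_two_sided": fet.p_two_sided,
                    "odds_ratio": fet.odds_ratio,
                    "degenerate": fet.degenerate,
                }
            )
    return pd.DataFrame(rows)


def mk_polymorphism_counts(
    variants: Iterable[VariantRecord],
    require_validated: bool = True,
    include_nonsense: bool = False,
) -> tuple:
    """(Pn, Ps) tallies feeding the MK test.

    By default only variants validated by a polymorphism project count, and
    nonsense variants are excluded from the nonsynonymous tally.
    """
    pn = ps = 0
    for v in variants:
        if require_validated and not v.validated:
            continue
        if v.effect is Effect.SYNONYMOUS:
            ps += 1
        elif v.effect is Effect.MISSENSE:
            pn += 1
        elif v.effect is Effect.NONSENSE and include_nonsense:
            pn += 1
    return pn, ps


VARIANT_COLUMNS = (
    "gene", "cds_position", "ref", "alt", "sift_score",
    "polyphen_call", "polyphen_confidence", "validated",
)


def read_variant_table(path) -> list:
    """Read a variant TSV (columns per VARIANT_COLUMNS; empty = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        sift = row["sift_score"]
        poly = row["polyphen_call"]
        out.append(
            VariantRecord(
                gene=row["gene"],
                cds_position=int(row["cds_position"]),
                ref_base=row["ref"],
                alt_base=row["alt"],
                sift_score=None if pd.isna(sift) else float(sift),
                polyphen_call=None if pd.isna(poly) else str(poly),
                polyphen_high_confidence=str(row["polyphen_confidence"]) == "high",
                validated=bool(row["validated"]),
                variant_id=str(row.get("variant_id", f"var{i + 1}")),
            )
        )
    return out


def tolerance_frame(summaries: Sequence) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene,
            "n_variants": s.n_variants,
            "n_tolerated_consensus": s.n_tolerated_consensus,
            "n_damaging_consensus": s.n_damaging_consensus,
            "n_discordant": s.n_discordant,
            "n_missing_prediction": s.n_missing_prediction,
            "fraction_tolerated": s.fraction_tolerated,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
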