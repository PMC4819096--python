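"""Synthetic-data generators with known ground truth.

Every pipeline input can be generated here so each stage is testable
without any external download: codon alignments evolved under chosen
omega site classes on a given tree, MK contingency tables with a chosen
neutrality index, dbSNP-style variant tables with SIFT/PolyPhen scores,
and limma-style differential-expression tables with a spiked-in
significant gene set.

All generators are pure functions of (spec, seed). The random stream is
partitioned per output kind (independent child seeds), so adding one
generator call does not perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .codonseq import CodonAlignment, GeneticCode, STANDARD_CODE, STOP
from .codon_models import (
    N_SENSE,
    PhyloTree,
    SENSE_CODONS,
    _reassemble,
    _symmetric_eig,
    _unnormalized_generator,
    mean_rate,
)
from .expression_screen import bh_adjust
from .mk import MKTable
from .variant_effects import VariantRecord, annotate_variant

# stream labels hashed into per-kind child seeds
_STREAMS = {"alignment": 1, "mk": 2, "expression": 3, "snp": 4}


def _stream_rng(seed: int, kind: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[kind]]))


@dataclass
class SimulationSpec:
    """Conditions of a synthetic study; every output records the seed."""

    seed: int = 0
    tree_newick: Optional[str] = None
    n_codons: int = 300
    kappa: float = 2.0
    pi: "str | np.ndarray" = "uniform"
    # list of (proportion, omega) classes, or an explicit per-column omega vector
    site_class_profile: Sequence = ((1.0, 0.2),)
    per_column_omega: Optional[np.ndarray] = None
    # expected (Pn, Ps, Dn, Ds) Poisson rates
    mk_rates: Tuple[float, float, float, float] = (20.0, 20.0, 100.0, 100.0)
    # expression screen
    n_genes: int = 5000
    n_datasets: int = 1
    spike_genes: Sequence = ()
    spike_p_scale: float = 1e-10

    def resolve_pi(self) -> np.ndarray:
        if isinstance(self.pi, str):
            if self.pi != "uniform":
                raise ValueError(f"unknown pi spec {self.pi!r}")
            return np.full(N_SENSE, 1.0 / N_SENSE)
        pi = np.asarray(self.pi, float)
        if pi.shape != (N_SENSE,) or not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("pi must be 61 frequencies summing to 1")
        return pi


def balanced_tree_newick(n_taxa: int, branch_length: float = 0.1) -> str:
    """A simple balanced (caterpillar-free) tree for simulation studies."""
    labels = [f"t{i + 1}" for i in range(n_taxa)]

    def build(ls):
        if len(ls) == 1:
            return f"{ls[0]}:{branch_length}"
        mid = len(ls) // 2
        return f"({build(ls[:mid])},{build(ls[mid:])}):{branch_length}"

    inner = build(labels)
    return f"{inner};" if inner.startswith("(") else f"({inner});"


def simulate_codon_alignment(spec: SimulationSpec):
    """Evolve codon sequences down the tree under per-column omega classes.

    Root codons are drawn from pi; each branch applies exp(Q_omega * t)
    with the column's omega, the mixture normalized to one expected
    substitution per codon per unit branch length. Returns the alignment
    and the true per-column class labels.
    """
    if spec.tree_newick is None:
        raise ValueError("spec.tree_newick is required")
    tree = PhyloTree.from_newick(spec.tree_newick)
    pi = spec.resolve_pi()
    rng = _stream_rng(spec.seed, "alignment")

    if spec.per_column_omega is not None:
        col_omega = np.asarray(spec.per_column_omega, float)
        if len(col_omega) != spec.n_codons:
            raise ValueError("per_column_omega length must equal n_codons")
        distinct = sorted(set(col_omega.tolist()))
        labels = np.array([distinct.index(w) for w in col_omega])
        class_omegas = distinct
        class_weights = [float(np.mean(col_omega == w)) for w in distinct]
    else:
        props = np.array([p for p, _ in spec.site_class_profile], float)
        if not math.isclose(props.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("site-class proportions must sum to 1")
        class_omegas = [w for _, w in spec.site_class_profile]
        class_weights = props.tolist()
        labels = rng.choice(len(class_omegas), size=spec.n_codons, p=props)
        col_omega = np.array([class_omegas[k] for k in labels])

    gens = [_unnormalized_generator(w, spec.kappa, pi) for w in class_omegas]
    rate = sum(wt * mean_rate(Q, pi) for wt, Q in zip(class_weights, gens))
    if rate <= 0:
        raise ValueError("degenerate profile: zero expected substitution rate")
    eigs = [_symmetric_eig(Q / rate, pi) for Q in gens]

    node_table = tree.arrays()
    n_nodes = len(node_table)
    children_of = [children for _, children, _ in node_table]
    root_idx = n_nodes - 1  # postorder: root last
    states = np.empty((n_nodes, spec.n_codons), dtype=np.int64)
    states[root_idx] = rng.choice(N_SENSE, size=spec.n_codons, p=pi)

    # preorder traversal from the root, sampling each child from exp(Q t)
    stack = [root_idx]
    order = []
    while stack:
        idx = stack.pop()
        order.append(idx)
        stack.extend(children_of[idx])
    for idx in order:
        for child in children_of[idx]:
            t = node_table[child][2]
            child_states = np.empty(spec.n_codons, dtype=np.int64)
            for k, (w, V, d) in enumerate(eigs):
                cols = np.where(labels == k)[0]
                if cols.size == 0:
                    continue
                P = _reassemble(w, V, d, t)
                P = P / P.sum(axis=1, keepdims=True)
                for j in cols:
                    child_states[j] = rng.choice(N_SENSE, p=P[states[idx, j]])
            states[child] = child_states

    taxa, rows = [], []
    for i, (label, children, _t) in enumerate(node_table):
        if not children:
            taxa.append(label)
            rows.append([SENSE_CODONS[s] for s in states[i]])
    aln = CodonAlignment(taxa=taxa, codons=rows)
    return aln, labels, col_omega


def simulate_mk_data(spec: SimulationSpec, n_replicates: int = 1) -> List[MKTable]:
    """Independent-Poisson MK tables with expectation ``spec.mk_rates``.

    The neutrality index of the expectation equals the targeted NI. A
    Poisson count model is the simplest one consistent with independent
    substitution counts; it is a stand-in for real polymorphism data.
    """
    rates = np.asarray(spec.mk_rates, float)
    if np.any(rates < 0):
        raise ValueError("mk rates must be >= 0")
    if rates.sum() == 0:
        raise ValueError("all-zero expectation: degenerate MK simulation")
    rng = _stream_rng(spec.seed, "mk")
    draws = rng.poisson(rates, size=(n_replicates, 4))
    return [MKTable(pn=int(a), ps=int(b), dn=int(c), ds=int(d)) for a, b, c, d in draws]


def simulate_expression_tables(spec: SimulationSpec) -> List[pd.DataFrame]:
    """limma/GEO2R-style result tables with a known spiked-in gene set.

    Null genes draw raw p ~ Uniform(0, 1); spiked genes draw raw p ~
    Uniform(0.1, 1) * spike_p_scale (default scale 1e-10, far below the
    |z| >= 5.5 boundary of ~1.9e-8). Fold-change signs are random and a
    BH-adjusted column is included. One table per dataset.
    """
    if not (0 < spec.spike_p_scale <= 1):
        raise ValueError("spike_p_scale must be in (0, 1]")
    genes = [f"GENE{i + 1:04d}" for i in range(spec.n_genes)]
    universe = set(genes)
    for g in spec.spike_genes:
        if g not in universe:
            raise ValueError(f"spike gene {g} not in the simulated gene universe")
    rng = _stream_rng(spec.seed, "expression")
    spiked = set(spec.spike_genes)
    tables = []
    for _ in range(spec.n_datasets):
        p_raw = rng.uniform(np.nextafter(0.0, 1.0), 1.0, size=spec.n_genes)
        for i, g in enumerate(genes):
            if g in spiked:
                p_raw[i] = rng.uniform(0.1, 1.0) * spec.spike_p_scale
        log_fc = rng.normal(0.0, 1.5, size=spec.n_genes) + np.where(
            [g in spiked for g in genes], 0.0, 0.0
        )
        tables.append(
            pd.DataFrame(
                {
                    "probe_id": [f"probe_{g}" for g in genes],
                    "gene_symbol": genes,
                    "p_raw": p_raw,
                    "p_adj": bh_adjust(p_raw),
                    "log_fc": log_fc,
                }
            )
        )
    return tables


_POLYPHEN_LEVELS = ("benign", "possibly_damaging", "probably_damaging")


def random_cds(
    n_codons: int, seed: int = 0, code: GeneticCode = STANDARD_CODE
) -> str:
    """A random stop-free CDS (start codon first, no terminal stop)."""
    rng = np.random.default_rng(seed)
    sense = [c for c in SENSE_CODONS if c != "ATG"]
    return "ATG" + "".join(rng.choice(sense, size=n_codons - 1))


def simulate_snp_table(
    cds: str,
    n_variants: int,
    seed: int = 0,
    effect_mix: Optional[str] = None,
    sift_sampler=None,
    polyphen_sampler=None,
    p_validated: float = 0.7,
    gene: str = "GENE",
    code: GeneticCode = STANDARD_CODE,
) -> List[VariantRecord]:
    """dbSNP-style variant rows over a CDS with configured score distributions.

    Positions are uniform over the CDS, alt bases uniform over the
    non-reference bases; effects are annotated by local classification.
    ``effect_mix='synonymous'``/'missense' restricts emitted rows by
    rejection sampling. ``sift_sampler(rng)``/``polyphen_sampler(rng)``
    customize score draws (defaults: SIFT ~ Uniform(0,1), PolyPhen uniform
    over categories with high confidence).
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if n_variants > 3 * len(cds):
        raise ValueError("more variants requested than distinct single-base changes")
    rng = _stream_rng(seed, "snp")
    variants: List[VariantRecord] = []
    attempts = 0
    while len(variants) < n_variants:
        attempts += 1
        if attempts > 1000 * n_variants:
            raise RuntimeError("rejection sampling failed to satisfy the effect mix")
        pos = int(rng.integers(1, len(cds) + 1))
        ref = cds[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        sift = float(sift_sampler(rng)) if sift_sampler else float(rng.uniform())
        poly = (
            polyphen_sampler(rng)
            if polyphen_sampler
            else (str(rng.choice(_POLYPHEN_LEVELS)), True)
        )
        v = VariantRecord(
            gene=gene,
            cds_position=pos,
            ref_base=ref,
            alt_base=alt,
            sift_score=sift,
            polyphen_call=poly[0],
            polyphen_high_confidence=bool(poly[1]),
            validated=bool(rng.uniform() < p_validated),
            variant_id=f"rs_sim_{len(variants) + 1}",
        )
        annotate_variant(v, cds, code)
        if effect_mix is not None and v.effect.value != effect_mix:
            continue
        variants.append(v)
    return variants


def variants_to_frame(variants: Sequence) -> pd.DataFrame:
    """Serialize variant records into the TSV dialect the readers accept."""
    return pd.DataFrame(
        {
            "gene": [v.gene for v in variants],
            "cds_position": [v.cds_position for v in variants],
            "ref": [v.ref_base for v in variants],
            "alt": [v.alt_base for v in variants],
            "sift_score": [v.sift_score for v in variants],
            "polyphen_call": [v.polyphen_call for v in variants],
            "polyphen_confidence": [
                "high" if v.polyphen_high_confidence else "low" for v in variants
            ],
            "validated": [v.validated for v in variants],
            "variant_id": [v.variant_id for v in variants],
        }
    )
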