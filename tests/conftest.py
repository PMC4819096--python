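"""Shared fixtures: small codon alignments and a complete synthetic study.

Everything is generated programmatically at test time; nothing is
downloaded and no binary fixtures exist.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from evoscreen import (
    CodonAlignment,
    PhyloTree,
    RunConfig,
    SimulationSpec,
    balanced_tree_newick,
    run_pipeline,
    simulate_codon_alignment,
)
from evoscreen.synthetic_data import simulate_snp_table, variants_to_frame


@pytest.fixture(scope="session")
def m0_alignment():
    """An 8-taxon, 500-codon alignment simulated under a single omega = 0.2."""
    spec = SimulationSpec(
        seed=11,
        tree_newick=balanced_tree_newick(8, 0.2),
        n_codons=500,
        kappa=2.0,
        site_class_profile=((1.0, 0.2),),
    )
    aln, labels, col_omega = simulate_codon_alignment(spec)
    return aln, PhyloTree.from_newick(spec.tree_newick), spec


@pytest.fixture(scope="session")
def tiny_alignment():
    """A 3-taxon, 2-codon toy alignment for exhaustive-oracle checks."""
    return CodonAlignment.from_sequences(
        ["A", "B", "C"], ["ATGAAA", "ATGAAG", "ATAAAA"]
    )


def _write_expression_tables(path, rng):
    genes = ["CAND", "NEUT1", "NEUT2"] + [f"NULL{i:03d}" for i in range(120)]
    for ds in ("SETA", "SETB", "SETC"):
        p_raw = rng.uniform(0.01, 1.0, size=len(genes))
        if ds in ("SETA", "SETB"):
            p_raw[0] = 1e-12  # planted candidate significant in two datasets
        df = pd.DataFrame(
            {
                "probe_id": [f"{ds}_{g}" for g in genes],
                "gene_symbol": genes,
                "p_raw": p_raw,
                "p_adj": np.minimum(p_raw * len(genes), 1.0),
                "log_fc": rng.normal(0, 1, size=len(genes)),
            }
        )
        df.to_csv(path / f"{ds}.tsv", sep="\t", index=False)


@pytest.fixture(scope="session")
def synthetic_study(tmp_path_factory):
    """A full synthetic study: expression tables, alignments, tree, variants,
    MK tables and peptide regions for three genes, with gene CAND planted as
    the strongest candidate (significant screen + MK + damaging variants)."""
    root = tmp_path_factory.mktemp("study")
    rng = np.random.default_rng(2024)
    (root / "expression").mkdir()
    _write_expression_tables(root / "expression", rng)

    tree_newick = "((human:0.12,mouse:0.12):0.06,(taxC:0.12,taxD:0.12):0.06);"
    (root / "tree.nwk").write_text(tree_newick + "\n")
    (root / "alignments").mkdir()
    variant_frames = []
    mk_rows = []
    for gene, seed, mk_counts, sift in [
        ("CAND", 101, (27, 16, 79, 146), 0.01),
        ("NEUT1", 102, (10, 10, 50, 50), 0.60),
        ("NEUT2", 103, (5, 5, 30, 30), 0.70),
    ]:
        spec = SimulationSpec(
            seed=seed,
            tree_newick=tree_newick,
            n_codons=60,
            kappa=2.0,
            site_class_profile=((1.0, 0.3),),
        )
        aln, *_ = simulate_codon_alignment(spec)
        aln.write_fasta(root / "alignments" / f"{gene}.fasta")
        cds = "".join(aln.row("human"))
        damaging = sift <= 0.05
        variants = simulate_snp_table(
            cds,
            n_variants=12,
            seed=seed,
            sift_sampler=lambda r, s=sift: s,
            polyphen_sampler=lambda r, d=damaging: (
                ("probably_damaging", True) if d else ("benign", True)
            ),
            gene=gene,
        )
        variant_frames.append(variants_to_frame(variants))
        mk_rows.append(
            {
                "gene": gene,
                "Pn": mk_counts[0],
                "Ps": mk_counts[1],
                "Dn": mk_counts[2],
                "Ds": mk_counts[3],
            }
        )
    pd.concat(variant_frames).to_csv(root / "variants.tsv", sep="\t", index=False)
    pd.DataFrame(mk_rows).to_csv(root / "mk_tables.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene": g, "start": 5, "end": 20, "name": "pep-long"}
            for g in ("CAND", "NEUT1", "NEUT2")
        ]
        + [
            {"gene": g, "start": 8, "end": 14, "name": "pep-short"}
            for g in ("CAND", "NEUT1", "NEUT2")
        ]
    ).to_csv(root / "regions.tsv", sep="\t", index=False)
    return root


def make_study_config(study_root, out_dir, **overrides) -> RunConfig:
    defaults = dict(
        expression_dir=str(study_root / "expression"),
        alignment_dir=str(study_root / "alignments"),
        tree_path=str(study_root / "tree.nwk"),
        variants_path=str(study_root / "variants.tsv"),
        regions_path=str(study_root / "regions.tsv"),
        mk_table_path=str(study_root / "mk_tables.tsv"),
        reference_taxon="human",
        comparison_taxon="mouse",
        model_pair=("M1a", "M2a"),
        seed=1,
        out_dir=str(out_dir),
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def study_runs(synthetic_study, tmp_path_factory):
    """The synthetic study executed twice with identical config (different
    output directories), for ranking and byte-reproducibility checks."""
    out1 = tmp_path_factory.mktemp("run1")
    out2 = tmp_path_factory.mktemp("run2")
    r1 = run_pipeline(make_study_config(synthetic_study, out1))
    r2 = run_pipeline(make_study_config(synthetic_study, out2))
    return (r1, out1), (r2, out2)
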