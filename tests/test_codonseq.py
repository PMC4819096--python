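"""Codon handling: translation, NG86 sites/differences, coverage filter, I/O."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from evoscreen.codonseq import (
    CodonAlignment,
    GAP_CODON,
    GeneticCode,
    STANDARD_CODE,
    STOP,
    StopCodonError,
    UntranslatableCodonError,
    count_codon_differences,
    count_sites,
    filter_columns_by_coverage,
    pairwise_counts,
    per_codon_counts,
    translate,
)

SENSE = [c for c, aa in STANDARD_CODE.table.items() if aa != STOP]


# ---------------------------------------------------------------------------
# genetic code and translation


def test_standard_code_structure():
    assert len(STANDARD_CODE.table) == 64
    assert STANDARD_CODE.stop_codons == {"TAA", "TAG", "TGA"}
    assert len({aa for aa in STANDARD_CODE.table.values() if aa != STOP}) == 20


@pytest.mark.parametrize(
    "codon,expected", [("ATG", "M"), ("TAA", STOP), ("TTT", "F"), ("tgg", "W")]
)
def test_translate_standard(codon, expected):
    assert translate(codon) == expected


@pytest.mark.parametrize("codon", ["---", "ATN", "A-G", "AT"])
def test_translate_rejects_gap_and_ambiguity(codon):
    with pytest.raises(UntranslatableCodonError):
        translate(codon)


def test_code_override_file(tmp_path):
    path = tmp_path / "code.tsv"
    lines = [f"{c}\t{aa}" for c, aa in STANDARD_CODE.table.items()]
    path.write_text("# comment\n" + "\n".join(lines) + "\n")
    code = GeneticCode.from_file(path)
    assert code.table == STANDARD_CODE.table


# ---------------------------------------------------------------------------
# NG86 sites


@pytest.mark.parametrize(
    "codon,s,n",
    [
        ("ATG", 0.0, 3.0),  # Met: single-codon amino acid
        ("TGG", 0.0, 3.0),  # Trp: stop mutants excluded from denominators
        ("TTT", 1 / 3, 8 / 3),  # only TTC among 9 mutants is synonymous
    ],
)
def test_count_sites_examples(codon, s, n):
    sites = count_sites(codon)
    assert sites.s_sites == pytest.approx(s)
    assert sites.n_sites == pytest.approx(n)


def test_count_sites_rejects_stop():
    with pytest.raises(StopCodonError):
        count_sites("TAA")


def test_site_conservation_all_sense_codons():
    """S + N = 3 exactly for every sense codon."""
    for codon in SENSE:
        sites = count_sites(codon)
        assert sites.s_sites + sites.n_sites == pytest.approx(3.0, abs=1e-12)
        assert sites.s_sites >= 0


# ---------------------------------------------------------------------------
# pathway-averaged differences


def _oracle_paths(a, b):
    """Independent exhaustive pathway enumerator: builds every full codon
    path recursively, discards those crossing a stop, classifies steps."""
    table = STANDARD_CODE.table

    def extend(path):
        cur = path[-1]
        if cur == b:
            yield path
            return
        for pos in range(3):
            if cur[pos] != b[pos]:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                yield from extend(path + [nxt])

    results = []
    for path in extend([a]):
        if any(table[c] == STOP for c in path[1:-1]):
            continue
        s = sum(1 for x, y in zip(path, path[1:]) if table[x] == table[y])
        results.append((s, len(path) - 1 - s))
    return results


@pytest.mark.parametrize(
    "a,b,s,n",
    [
        ("TTT", "TTC", 1.0, 0.0),
        ("AAA", "AAA", 0.0, 0.0),
        ("TTT", "GTA", 0.5, 1.5),  # mean of (1,1) and (0,2) pathways
    ],
)
def test_count_differences_examples(a, b, s, n):
    d = count_codon_differences(a, b)
    assert (d.s_diff, d.n_diff) == (pytest.approx(s), pytest.approx(n))
    assert d.countable


def test_pathway_counts_match_exhaustive_oracle_all_pairs():
    """Pathway-averaged counts equal the independent enumerator for every
    sense-codon pair, and conserve the positional Hamming distance."""
    for a, b in itertools.product(SENSE, repeat=2):
        d = count_codon_differences(a, b)
        oracle = _oracle_paths(a, b)
        hamming = sum(x != y for x, y in zip(a, b))
        if not oracle:
            assert not d.countable and d.s_diff == d.n_diff == 0.0
            continue
        es = sum(s for s, _ in oracle) / len(oracle)
        en = sum(n for _, n in oracle) / len(oracle)
        assert d.s_diff == pytest.approx(es, abs=1e-12)
        assert d.n_diff == pytest.approx(en, abs=1e-12)
        assert d.s_diff + d.n_diff == pytest.approx(hamming)


@given(
    a=st.sampled_from(SENSE),
    b=st.sampled_from(SENSE),
)
@settings(max_examples=200, deadline=None)
def test_difference_symmetry(a, b):
    assert count_codon_differences(a, b) == count_codon_differences(b, a)


# ---------------------------------------------------------------------------
# pairwise counts


def test_pairwise_identity():
    row = ["ATG", "TTT", "GGC", "AAA", "CCC", "GAT", "TGC", "CAT", "AGA", "TTG"]
    c = pairwise_counts(row, row)
    assert c.s_diff == c.n_diff == 0.0
    assert c.s_sites + c.n_sites == pytest.approx(30.0)
    assert c.codons_compared == 10


def test_pairwise_single_synonymous_change():
    c = pairwise_counts(["TTT", "ATG"], ["TTC", "ATG"])
    assert c.s_diff == pytest.approx(1.0)
    assert c.n_diff == pytest.approx(0.0)


def test_pairwise_matches_per_codon_sum():
    a = ["TTT", "ATG", "GGC", "AAA", "CAT"]
    b = ["GTA", "ATG", "GGT", "AGA", "CAT"]
    total = pairwise_counts(a, b)
    s = n = 0.0
    for ca, cb in zip(a, b):
        d = count_codon_differences(ca, cb)
        s += d.s_diff
        n += d.n_diff
    assert total.s_diff == pytest.approx(s)
    assert total.n_diff == pytest.approx(n)
    # symmetry in sequence arguments
    rev = pairwise_counts(b, a)
    assert rev.s_diff == pytest.approx(total.s_diff)
    assert rev.s_sites == pytest.approx(total.s_sites)


def test_pairwise_skips_gaps_and_stops():
    c = pairwise_counts(["ATG", "---", "TAA", "TTT"], ["ATG", "AAA", "AAA", "TTC"])
    assert c.codons_compared == 2
    assert c.codons_skipped == 2


def test_pairwise_requires_comparable_codons():
    with pytest.raises(ValueError):
        pairwise_counts(["---"], ["AAA"])


# ---------------------------------------------------------------------------
# alignment container and coverage filter


def test_alignment_rejects_frame_breaking_gap():
    with pytest.raises(ValueError, match="frame-breaking"):
        CodonAlignment.from_sequences(["a", "b"], ["ATGA--", "ATGAAA"])


def test_alignment_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        CodonAlignment.from_sequences(["a", "b"], ["ATG", "ATGAAA"])


def test_coverage_filter():
    # 10 taxa, 4 columns at coverages 1.0, 0.5, 0.3, 0.2
    cols = [10, 5, 3, 2]
    codons = [
        ["AAA" if i < k else GAP_CODON for k in cols] for i in range(10)
    ]
    aln = CodonAlignment(taxa=[f"t{i}" for i in range(10)], codons=codons)
    kept = filter_columns_by_coverage(aln, 0.35)
    assert kept.n_codons == 2
    # fully ungapped alignment is unchanged at any threshold
    full = CodonAlignment.from_sequences(["a", "b"], ["ATGAAA", "ATGAAA"])
    assert filter_columns_by_coverage(full, 1.0).codons == full.codons
    with pytest.raises(ValueError, match="every column"):
        filter_columns_by_coverage(
            CodonAlignment(taxa=["x", "y"], codons=[[GAP_CODON], [GAP_CODON]]), 0.35
        )


def test_all_gap_column_removed():
    aln = CodonAlignment(
        taxa=["a", "b"], codons=[[GAP_CODON, "AAA"], [GAP_CODON, "AAC"]]
    )
    assert filter_columns_by_coverage(aln, 0.35).n_codons == 1


def test_fasta_round_trip(tmp_path):
    aln = CodonAlignment.from_sequences(
        ["human", "mouse"], ["ATGAAATTTGGG" * 10, "ATGAAGTTTGGA" * 10]
    )
    path = tmp_path / "aln.fasta"
    aln.write_fasta(path)
    text = path.read_text()
    assert max(len(l) for l in text.splitlines()) <= 60
    back = CodonAlignment.read_fasta(path)
    assert back.taxa == aln.taxa
    assert back.codons == aln.codons
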