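"""Codon-aware sequence handling.

Genetic code, translation, codon alignment I/O, coverage-based column
filtering, and Nei-Gojobori (NG86) counting of synonymous/nonsynonymous
sites and differences with mutational-pathway averaging.

Coordinates are 1-based inclusive throughout (codon and residue positions).
Only whole-codon gaps ("---") are supported; frame-breaking gaps are
rejected at parse time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
GAP_CODON = "---"
STOP = "*"


class UntranslatableCodonError(ValueError):
    """Raised for gap or ambiguous codons that carry no amino acid."""


class StopCodonError(ValueError):
    """Raised when a stop codon appears where a sense codon is required."""


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon -> amino-acid map; stop codons map to ``*``."""

    name: str
    table: dict  # codon -> one-letter amino acid or "*"

    def __post_init__(self):
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 entries, got {len(self.table)}")
        for codon in self.table:
            if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
                raise ValueError(f"invalid codon key {codon!r}")

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.table.items() if aa == STOP)

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon) == STOP

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear code (NCBI translation table 1)."""
        t = CodonTable.unambiguous_dna_by_id[1]
        table = dict(t.forward_table)
        for stop in t.stop_codons:
            table[stop] = STOP
        return cls(name="standard", table=table)

    @classmethod
    def from_file(cls, path) -> "GeneticCode":
        """Read a plain-text code table: one ``CODON<TAB>AA`` line per codon."""
        table = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'CODON<TAB>AA'")
            table[parts[0].upper()] = parts[1].strip()
        return cls(name=str(path), table=table)


STANDARD_CODE = GeneticCode.standard()


def translate(codon: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate one ungapped codon; returns ``*`` for stops.

    Raises :class:`UntranslatableCodonError` for gapped or ambiguous codons
    rather than silently skipping them.
    """
    codon = codon.upper()
    if codon not in code.table:
        raise UntranslatableCodonError(f"cannot translate codon {codon!r}")
    return code.table[codon]


@dataclass
class CodonAlignment:
    """Taxa x codon-column matrix; substrate for counting and likelihood.

    ``codons[i][j]`` is the j-th codon of taxon i, either a fully ungapped
    ACGT triplet or the whole-codon gap ``---``.
    """

    taxa: list
    codons: list  # list of per-taxon lists of codon strings

    def __post_init__(self):
        if len(self.taxa) != len(self.codons):
            raise ValueError("taxa and codon rows differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(row) for row in self.codons}
        if len(lengths) > 1:
            raise ValueError(f"rows differ in codon length: {sorted(lengths)}")
        for label, row in zip(self.taxa, self.codons):
            for j, codon in enumerate(row):
                if codon == GAP_CODON:
                    continue
                if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
                    raise ValueError(
                        f"taxon {label!r}, codon {j + 1}: {codon!r} is neither an "
                        "ACGT triplet nor a whole-codon gap (frame-breaking gaps "
                        "are not supported)"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    @property
    def length_nt(self) -> int:
        return 3 * self.n_codons

    def row(self, taxon: str) -> list:
        return self.codons[self.taxa.index(taxon)]

    def column(self, j: int) -> list:
        """Codon column ``j`` (0-based internal index)."""
        return [row[j] for row in self.codons]

    @classmethod
    def from_sequences(cls, taxa: Sequence, seqs: Sequence) -> "CodonAlignment":
        """Build from equal-length nucleotide strings (length divisible by 3)."""
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError("sequences differ in length; alignment required")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        codons = [
            [str(s[i : i + 3]).upper() for i in range(0, len(s), 3)] for s in seqs
        ]
        return cls(taxa=list(taxa), codons=codons)

    @classmethod
    def read_fasta(cls, path) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences([r.id for r in records], [str(r.seq) for r in records])

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq("".join(row)), id=label, description="")
            for label, row in zip(self.taxa, self.codons)
        ]
        SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


class SiteCounts(NamedTuple):
    """NG86 fractional synonymous/nonsynonymous sites of one codon."""

    s_sites: float
    n_sites: float


class DiffCounts(NamedTuple):
    """Pathway-averaged differences for one codon pair.

    ``countable`` is False when every minimal mutational pathway passes
    through a stop codon (the counts are then 0, 0).
    """

    s_diff: float
    n_diff: float
    countable: bool


@lru_cache(maxsize=None)
def _count_sites_cached(codon: str, code_key: tuple) -> SiteCounts:
    table = dict(code_key)
    s_total = 0.0
    for pos in range(3):
        syn = 0
        denom = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if table[mutant] == STOP:
                continue  # stop mutants excluded from denominators
            denom += 1
            if table[mutant] == table[codon]:
                syn += 1
        if denom:
            s_total += syn / denom
    return SiteCounts(s_sites=s_total, n_sites=3.0 - s_total)


def count_sites(codon: str, code: GeneticCode = STANDARD_CODE) -> SiteCounts:
    """NG86 site decomposition of one sense codon.

    Per position, the synonymous fraction is (# synonymous non-stop
    single-base mutants) / (# non-stop single-base mutants); S is the sum
    over positions and N = 3 - S.
    """
    codon = codon.upper()
    aa = translate(codon, code)
    if aa == STOP:
        raise StopCodonError(f"stop codon {codon} carries no sites")
    return _count_sites_cached(codon, tuple(sorted(code.table.items())))


@lru_cache(maxsize=None)
def _count_diffs_cached(a: str, b: str, code_key: tuple) -> DiffCounts:
    table = dict(code_key)
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return DiffCounts(0.0, 0.0, True)
    s_sum = n_sum = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        current = a
        s = n = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if table[nxt] == STOP and nxt != b:
                ok = False
                break
            if table[nxt] == table[current]:
                s += 1
            else:
                n += 1
            current = nxt
        if ok:
            s_sum += s
            n_sum += n
            n_paths += 1
    if n_paths == 0:
        return DiffCounts(0.0, 0.0, False)
    return DiffCounts(s_sum / n_paths, n_sum / n_paths, True)


def count_codon_differences(
    codon_a: str, codon_b: str, code: GeneticCode = STANDARD_CODE
) -> DiffCounts:
    """Average synonymous/nonsynonymous steps over minimal mutational pathways.

    Enumerates all orderings of the differing positions, discards pathways
    passing through a stop codon, classifies each single-base step, and
    returns the mean per class over retained pathways (NG86).
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if translate(c, code) == STOP:
            raise StopCodonError(f"stop codon {c} in difference counting")
    return _count_diffs_cached(a, b, tuple(sorted(code.table.items())))


@dataclass
class CodonCounts:
    """Summed NG86 counts for one sequence pair (Table-5-style divergence input)."""

    s_sites: float
    n_sites: float
    s_diff: float
    n_diff: float
    codons_compared: int
    codons_skipped: int = 0  # gap- or stop-containing codon pairs
    codons_uncountable: int = 0  # all pathways pass through stops

    @property
    def dn(self) -> float:
        return self.n_diff / self.n_sites if self.n_sites else float("nan")

    @property
    def ds(self) -> float:
        return self.s_diff / self.s_sites if self.s_sites else float("nan")

    @property
    def omega(self) -> float:
        """Global dN/dS of the pair; nan when dS = 0."""
        ds = self.ds
        return self.dn / ds if ds else float("nan")


def per_codon_counts(
    seq_a: Sequence, seq_b: Sequence, code: GeneticCode = STANDARD_CODE
) -> list:
    """Per-codon-pair counts; ``None`` where a pair is not comparable.

    Sites per pair are the mean of the two codons' NG86 sites; differences
    are pathway-averaged. Uncountable pairs (all pathways through stops)
    contribute sites but zero differences, flagged via DiffCounts.countable.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in codon length")
    out = []
    for ca, cb in zip(seq_a, seq_b):
        ca, cb = ca.upper(), cb.upper()
        if ca == GAP_CODON or cb == GAP_CODON:
            out.append(None)
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            out.append(None)
            continue
        sa = count_sites(ca, code)
        sb = count_sites(cb, code)
        diffs = count_codon_differences(ca, cb, code)
        counts = CodonCounts(
            s_sites=(sa.s_sites + sb.s_sites) / 2.0,
            n_sites=(sa.n_sites + sb.n_sites) / 2.0,
            s_diff=diffs.s_diff,
            n_diff=diffs.n_diff,
            codons_compared=1,
            codons_uncountable=0 if diffs.countable else 1,
        )
        out.append(counts)
    return out


def pairwise_counts(
    seq_a: Sequence, seq_b: Sequence, code: GeneticCode = STANDARD_CODE
) -> CodonCounts:
    """Summed NG86 counts between two aligned codon sequences.

    Codon pairs containing a gap or stop are skipped and tallied in
    ``codons_skipped``; pairs whose every pathway crosses a stop are
    tallied in ``codons_uncountable`` (they still contribute sites).
    """
    per_codon = per_codon_counts(seq_a, seq_b, code)
    total = CodonCounts(0.0, 0.0, 0.0, 0.0, codons_compared=0)
    for c in per_codon:
        if c is None:
            total.codons_skipped += 1
            continue
        total.s_sites += c.s_sites
        total.n_sites += c.n_sites
        total.s_diff += c.s_diff
        total.n_diff += c.n_diff
        total.codons_compared += 1
        total.codons_uncountable += c.codons_uncountable
    if total.codons_compared == 0:
        raise ValueError("no comparable codons between the two sequences")
    return total


def filter_columns_by_coverage(
    aln: CodonAlignment, min_coverage: float
) -> CodonAlignment:
    """Drop codon columns whose ungapped fraction is below ``min_coverage``.

    Mirrors the usual positions-with-low-site-coverage elimination applied
    before phylogenetic analysis; order of retained columns is preserved.
    """
    if not (0.0 < min_coverage <= 1.0):
        raise ValueError("min_coverage must be in (0, 1]")
    n = aln.n_taxa
    keep = [
        j
        for j in range(aln.n_codons)
        if sum(1 for c in aln.column(j) if c != GAP_CODON) / n >= min_coverage
    ]
    if not keep:
        raise ValueError("coverage filter removed every column")
    return CodonAlignment(
        taxa=list(aln.taxa),
        codons=[[row[j] for j in keep] for row in aln.codons],
    )
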