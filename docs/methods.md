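# Methods

This note documents the models, conventions, defaults, and numerical
choices behind each module, what the synthetic generators do and do not
emulate, and the known limitations.

## Codon handling and NG86 counting (`codonseq`)

The genetic code is the standard nuclear code (translation table 1) —
appropriate for eutherian nuclear mRNAs, which are this package's use
case; a plain-text override file (codon TAB amino-acid, 64 lines) swaps in
any other code. Only whole-codon gaps (`---`) are supported; frame-breaking
gaps are rejected at parse time, and ambiguity codes are rejected rather
than guessed.

Synonymous/nonsynonymous **sites** per codon follow Nei–Gojobori (1986):
at each codon position the synonymous fraction is the number of synonymous
single-base mutants divided by the number of non-stop single-base mutants;
mutants that create stops are excluded from the denominator. S + N = 3
exactly for every sense codon.

**Differences** between two codons are averaged over all minimal
mutational pathways (orderings of the differing positions). Pathways that
pass through a stop codon are discarded; if every pathway does, the pair
is counted as (0, 0) and flagged uncountable rather than silently skipped.
Sites for a sequence pair are the mean of the two sequences' per-codon
sites. Pathway averaging is one of several defensible conventions for
between-species counts; it is the package's chosen one and is pinned by an
exhaustive-enumeration oracle test over all 61×61 codon pairs.

The coverage filter removes alignment columns whose ungapped fraction
falls below a threshold (default 0.35, i.e. columns with more than 65%
gaps are dropped), the usual pre-filter before phylogenetic analysis.
Codon and residue coordinates are 1-based inclusive everywhere.

## McDonald–Kreitman test (`mk`)

The 2×2 table crosses within-species variation (Pn, Ps) against fixed
between-species differences (Dn, Ds). The Fisher exact test is computed
in-house in log space via log-gamma: the two-sided *p* is the sum of
hypergeometric probabilities of all tables with the observed margins whose
point probability is ≤ the observed one, with a relative tolerance of 1e-7
on that comparison to absorb floating-point ties. This point-probability
rule is the dominant two-sidedness convention and reproduces the reference
tables' published *p*-values, which pins the convention empirically. A
zero margin returns *p* = 1 flagged degenerate.

Fractional pathway-averaged divergence counts are rounded half-up to
integers for the table (fixed differences are integers in published
tables); the raw fractional values are retained in the result. The
neutrality index NI = (Pn/Ps)/(Dn/Ds) is reported as undefined — never as
0 or ∞ — when Ps, Dn, or Ds is zero. α defaults to 0.05.

Out of scope: polarized (outgroup-based) MK variants, asymptotic-MK α
estimation, and multiple-hit corrections of divergence.

## Codon site models (`codon_models`)

The rate matrix is Goldman–Yang-style over the 61 sense codons:
single-base changes only, factor κ for transitions, factor ω for
nonsynonymous changes, target-codon frequency π_j from F3x4
(position-specific nucleotide frequencies multiplied, stops removed,
renormalized; a nucleotide absent at some position gets a small
configurable pseudo-frequency, with a warning). The generator satisfies
detailed balance; matrix exponentials use eigendecomposition in the
π-symmetrized basis. The mixture generator is normalized so the
proportion-weighted mean rate is one substitution per codon, making branch
lengths expected substitutions per codon.

Site-class mixtures: M0 (one ratio), M1a (ω0 ≤ 1 plus ω = 1), M2a (M1a
plus ω2 ≥ 1), M3 (three free classes), M7 (beta-distributed ω ≤ 1), M8
(M7 plus a free ω ≥ 1 class, boundary allowed). The beta is discretized
into K equal-probability categories represented by conditional means
(default K = 10, the conventional choice); category means are validated
against numerical quadrature.

Likelihood: Felsenstein pruning over unique site patterns with per-node
rescaling; column log-likelihoods are mixed over classes with logsumexp.
The likelihood is invariant to re-rooting (reversibility) and to leaf
order, and is checked against exhaustive ancestral-state enumeration on
small trees.

Fitting: κ is free (estimated by ML); branch lengths come from the input
tree with one optional global scale factor co-estimated — full per-branch
optimization is deliberately out of scope for tractability. The optimizer
is bounded L-BFGS-B from three documented starts per model (optionally
jittered with a fixed seed), proportions via stick-breaking, beta shapes
in log space, relative ftol 1e-10 (≈1e-6 absolute on lnL of magnitude
1e4). Non-convergence is flagged and the best-so-far returned. Alternative
models in a nested pair (M1a→M2a, M7→M8, M0→M3) additionally start at the
exact embedding of the fitted null, which guarantees lnL(alt) ≥ lnL(null).

LRT: statistic max(0, 2ΔlnL) against χ²(df); df = 2 for both standard
pairs, critical value 5.991 at α = 0.05. Site identification is naive
empirical Bayes: per-column class posteriors with fitted parameters
plugged in; columns whose posterior mass on ω > 1 classes reaches the
threshold (default 0.95) are reported 1-based. Bayes empirical Bayes
(integrating over parameter uncertainty) is not implemented; NEB is known
to be anticonservative at small sample sizes, which is why the LRT — not
the site list — is the significance gate.

## Running dN/dS (`sitewise`)

At residue *i*, NG86 per-codon counts are pooled over the window
[*i* − w, *i* + w] clipped to the protein (edge windows shrink), and
ω_i = ((N_d + c)/N_s) / ((S_d + c)/S_s) with pseudocount c. Defaults
w = 10 residues and c = 0.5: the window is wide enough to accumulate
synonymous events at mammalian divergence levels yet narrow enough to
resolve peptide-sized features, and the half-count pseudocount keeps ω
defined in windows with no observed change. Neither value is canonical;
both are config-exposed and echoed in output metadata. Windows with zero
synonymous (or nonsynonymous) sites yield an explicit undefined marker.
With c = 0 and a window covering the whole protein, the track reproduces
the global pairwise ω exactly (tested).

Per-codon counts default to the reference-vs-comparison pairwise
comparison (human vs mouse in the pipeline). A site-model-based
alternative (NEB posterior-weighted ω per column) can be fed in as the
counts source; the package asserts neither as *the* canonical source.
Peptide-region coordinates are user configuration; the test fixtures'
coordinates are synthetic and non-authoritative. Variants are flagged
high-omega when the local track value exceeds 1.0.

## Variant tolerance (`variant_effects`)

Effects are classified locally (substitute, translate, compare; stop-gain
is nonsense) and validated against a full-CDS-translation oracle in tests.
SIFT: damaging iff score ≤ 0.05 (boundary damaging). Consensus:
tolerated iff SIFT-tolerated AND PolyPhen-benign; damaging iff
SIFT-damaging AND high-confidence probably-damaging (low-confidence
probably-damaging never contributes to the damaging consensus); all else
discordant. Variants missing a prediction are tallied separately. SIFT and
PolyPhen are consumed as scored inputs only — rerunning them is
network-dependent and out of scope.

MK polymorphism tallies take validated variants only by default
(mirroring the restriction to 1000-Genomes-validated SNPs), and exclude
nonsense variants from Pn (convention; both switches exposed). Cross-gene
tolerance comparison applies the same exact Fisher test to each gene
pair's (damaging, tolerated) counts — offered as a reasonable realization
of "is this gene's excess of poorly tolerated variation significant?",
not as a canonical test.

## Synthetic data (`synthetic_data`)

Generators are pure functions of (spec, seed); the stream is partitioned
per output kind via child seeds so adding one call does not perturb
another's draws.

* **Alignments**: root codons from π, evolved down the given tree by
  sampling exp(Qt) per branch with per-column ω (explicit class profile or
  per-column vector). True class labels are returned. No indels, no
  rate variation beyond ω classes, no CpG or context effects.
* **MK tables**: independent Poisson counts at specified expected
  (Pn, Ps, Dn, Ds) — the simplest model consistent with independent
  substitution counts, a stand-in rather than a claim about real
  polymorphism data (no linkage, no frequency spectrum).
* **Expression tables**: null genes draw raw p ~ U(0,1); spiked genes draw
  p ~ U(0.1, 1)·10⁻¹⁰ by default, far below the |z| ≥ 5.5 boundary
  (Φ(−5.5) ≈ 1.9e-8), so planted candidates are recovered exactly. Real
  microarray p-values are correlated across probes; the generator's
  independence means passing tests demonstrate threshold logic, not
  robustness to correlation.
* **SNP tables**: uniform positions, uniform non-reference alt bases,
  configurable SIFT/PolyPhen samplers, effects annotated by the local
  classifier.

## Pipeline (`pipeline`, `cli`)

Stages run in dependency order; a failing gene is isolated (logged,
flagged in the report) while the others complete. Candidates are ranked by
a documented lexicographic artifact convention — MK significance, then LRT
significance, then consensus-damaging fraction, then name — because the
original analysis style ranks narratively and some rule must be fixed.
Reports are deterministic and byte-reproducible under a fixed seed:
`report.tsv`/`report.json` carry no timestamps; the config echo, its hash,
and the seed go to `run_metadata.json`.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own trade-off between statistical resolution and
a quick default run: one-ratio recovery at 8 taxa × 500 codons × 10
replicates (tests) and 8 × 400 × 3 (acceptance script); the M7-null /
M8-alternative false-positive calibration scaled down to 5 taxa ×
150 codons × K = 5 × 20 replicates; screen simulations at 5 000 genes with
20 spikes; the end-to-end study at 3 genes × 60 codons × 4 taxa plus 120
null genes in 3 datasets.

## Known limitations

* Branch lengths are rescaled globally, not re-optimized per branch;
  lnL values are therefore not directly comparable to a full-ML program's
  on real data, though LRTs between models sharing the constraint remain
  internally consistent.
* NEB only (no BEB); F3x4 only (no F61/F1x4); no branch or branch-site
  models; no tree search.
* The one-dataset-per-table screen consumes limma/GEO2R output; it does
  not refit differential expression.
* Gene-symbol harmonization is case-insensitive string matching; no alias
  databases.
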