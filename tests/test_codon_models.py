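"""Codon site models: F3x4, beta discretization, pruning likelihood,
nested fits, LRT, NEB posteriors."""

import math

import dendropy
import numpy as np
import pytest
import scipy.linalg
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from evoscreen.codon_models import (
    CODON_INDEX,
    N_SENSE,
    OptimizerConfig,
    PhyloTree,
    SENSE_CODONS,
    SiteClassModel,
    _unnormalized_generator,
    build_generator,
    chi2_critical,
    discretize_beta,
    f3x4_frequencies,
    fit_model,
    fit_nested_pair,
    log_likelihood,
    lrt,
    lrt_from_statistic,
    mean_rate,
    neb_site_classes,
    transition_matrix,
)
from evoscreen.codonseq import CodonAlignment
from evoscreen.synthetic_data import (
    SimulationSpec,
    balanced_tree_newick,
    simulate_codon_alignment,
)

# ---------------------------------------------------------------------------
# F3x4


def test_f3x4_uniform_positions_give_equal_frequencies():
    # one sequence whose every codon position uses A/C/G/T equally
    aln = CodonAlignment.from_sequences(["x"], ["AAACCCGGGTTT"])
    pi = f3x4_frequencies(aln)
    np.testing.assert_allclose(pi, np.full(N_SENSE, 1 / N_SENSE), rtol=1e-12)


def test_f3x4_matches_hand_calculation():
    aln = CodonAlignment.from_sequences(["a", "b"], ["ATGGCT", "ATGGCC"])
    with pytest.warns(UserWarning):  # some nucleotides absent at a position
        pi = f3x4_frequencies(aln, pseudo_frequency=0.0)
    # position freqs: pos1 A=G=1/2; pos2 T=C=1/2; pos3 G=T=C... per codon column
    # hand: pos1 {A:0.5,G:0.5}; pos2 {T:0.5,C:0.5}; pos3 {G:0.5,T:0.25,C:0.25}
    raw = {}
    f1 = {"A": 0.5, "G": 0.5}
    f2 = {"T": 0.5, "C": 0.5}
    f3 = {"G": 0.5, "T": 0.25, "C": 0.25}
    for c in SENSE_CODONS:
        raw[c] = f1.get(c[0], 0) * f2.get(c[1], 0) * f3.get(c[2], 0)
    total = sum(raw.values())
    for c, v in raw.items():
        assert pi[CODON_INDEX[c]] == pytest.approx(v / total, abs=1e-12)


def test_f3x4_normalized(m0_alignment):
    aln, _, _ = m0_alignment
    assert f3x4_frequencies(aln).sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# beta discretization


def test_discretize_uniform_beta():
    np.testing.assert_allclose(
        discretize_beta(1.0, 1.0, 10), np.arange(0.05, 1.0, 0.1), atol=1e-12
    )


@pytest.mark.parametrize("p,q", [(1.0, 1.0), (0.843, 2.462), (2.0, 5.0), (0.3, 0.3)])
def test_discretized_mean_preserved(p, q):
    means = discretize_beta(p, q, 10)
    assert means.mean() == pytest.approx(p / (p + q), abs=1e-6)


def test_discretize_matches_quadrature():
    p, q, K = 0.843, 2.462, 10
    means = discretize_beta(p, q, K)
    edges = beta_dist.ppf(np.linspace(0, 1, K + 1), p, q)
    for i in range(K):
        num, _ = quad(lambda x: x * beta_dist.pdf(x, p, q), edges[i], edges[i + 1])
        assert means[i] == pytest.approx(num * K, abs=1e-6)


def test_discretize_rejects_bad_shapes():
    with pytest.raises(ValueError):
        discretize_beta(float("nan"), 1.0, 10)
    with pytest.raises(ValueError):
        discretize_beta(-1.0, 1.0, 10)


# ---------------------------------------------------------------------------
# generator and transition matrices


@pytest.fixture(scope="module")
def pi61(m0_alignment):
    aln, _, _ = m0_alignment
    return f3x4_frequencies(aln)


def test_generator_rows_sum_to_zero(pi61):
    Q = build_generator(0.3, 2.0, pi61)
    np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)


def test_generator_detailed_balance(pi61):
    Q = build_generator(0.3, 2.0, pi61)
    flux = pi61[:, None] * Q
    np.testing.assert_allclose(flux, flux.T, atol=1e-15)


def test_transition_matrix_stochastic_and_stationary(pi61):
    Q = build_generator(0.5, 3.0, pi61)
    for t in (0.01, 0.5, 5.0):
        P = transition_matrix(Q, pi61, t)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(pi61 @ P, pi61, atol=1e-8)
        np.testing.assert_allclose(P, scipy.linalg.expm(Q * t), atol=1e-9)


def test_normalized_generator_unit_rate(pi61):
    Q = build_generator(0.7, 2.0, pi61)
    assert mean_rate(Q, pi61) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# likelihood


def test_zero_branch_identical_sequences():
    aln = CodonAlignment.from_sequences(["A", "B"], ["ATG", "ATG"])
    tree = PhyloTree.from_newick("(A:0,B:0);")
    pi = np.full(N_SENSE, 1 / N_SENSE)
    model = SiteClassModel("M0", proportions=(1.0,), omegas=(0.5,))
    lnl = log_likelihood(aln, tree, model, 2.0, pi)
    assert lnl == pytest.approx(math.log(pi[CODON_INDEX["ATG"]]), abs=1e-10)


def _oracle_lnl(aln, tree_newick, props, omegas, kappa, pi):
    """Exhaustive ancestral-state summation (scipy expm, explicit loops)."""
    tree = PhyloTree.from_newick(tree_newick)
    table = tree.arrays()
    internal = [i for i, (_, ch, _) in enumerate(table) if ch]
    gens = [_unnormalized_generator(w, kappa, pi) for w in omegas]
    rate = sum(p * mean_rate(Q, pi) for p, Q in zip(props, gens))
    row = {lab: aln.row(lab) for lab, ch, _ in table if not ch}
    total = 0.0
    for j in range(aln.n_codons):
        col = 0.0
        for k, Q in enumerate(gens):
            P = [scipy.linalg.expm((Q / rate) * t) for (_, _, t) in table]
            import itertools

            class_lik = 0.0
            for assign in itertools.product(range(N_SENSE), repeat=len(internal)):
                state = {}
                for idx, (lab, ch, _) in enumerate(table):
                    if ch:
                        state[idx] = assign[internal.index(idx)]
                    else:
                        state[idx] = CODON_INDEX[row[lab][j]]
                prob = pi[state[len(table) - 1]]
                for idx, (_, ch, t) in enumerate(table):
                    if idx == len(table) - 1:
                        continue
                    parent = next(
                        i for i, (_, c, _) in enumerate(table) if idx in c
                    )
                    prob *= P[idx][state[parent], state[idx]]
                class_lik += prob
            col += props[k] * class_lik
        total += math.log(col)
    return total


@pytest.mark.parametrize(
    "newick,props,omegas",
    [
        ("(A:0.3,B:0.2,C:0.4);", (1.0,), (0.4,)),  # star, one internal node
        ("((A:0.1,B:0.2):0.15,C:0.3);", (1.0,), (0.4,)),  # two internal nodes
        ("((A:0.1,B:0.2):0.15,C:0.3);", (0.7, 0.3), (0.1, 2.0)),  # mixture
    ],
)
def test_pruning_matches_exhaustive_enumeration(tiny_alignment, newick, props, omegas):
    aln = tiny_alignment
    pi = f3x4_frequencies(aln)
    model = (
        SiteClassModel("M0", proportions=(1.0,), omegas=omegas)
        if len(omegas) == 1
        else SiteClassModel("M3", proportions=props, omegas=omegas, K=len(omegas))
    )
    lnl = log_likelihood(aln, PhyloTree.from_newick(newick), model, 2.0, pi)
    oracle = _oracle_lnl(aln, newick, props, omegas, 2.0, pi)
    assert lnl == pytest.approx(oracle, abs=1e-9)


def test_likelihood_invariant_to_rerooting(tiny_alignment):
    aln = tiny_alignment
    pi = f3x4_frequencies(aln)
    model = SiteClassModel("M0", proportions=(1.0,), omegas=(0.3,))
    t1 = PhyloTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3);")
    lnl1 = log_likelihood(aln, t1, model, 2.0, pi)
    dt = dendropy.Tree.get(data="((A:0.1,B:0.2):0.15,C:0.3);", schema="newick")
    leaf_a = dt.find_node_with_taxon_label("A")
    dt.reroot_at_edge(leaf_a.edge, length1=0.05, length2=0.05)
    lnl2 = log_likelihood(aln, PhyloTree(dt), model, 2.0, pi)
    assert lnl2 == pytest.approx(lnl1, abs=1e-8)


def test_likelihood_invariant_to_leaf_reordering(tiny_alignment):
    aln = tiny_alignment
    perm = CodonAlignment(
        taxa=[aln.taxa[i] for i in (2, 0, 1)],
        codons=[aln.codons[i] for i in (2, 0, 1)],
    )
    tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3);")
    pi = f3x4_frequencies(aln)
    model = SiteClassModel("M0", proportions=(1.0,), omegas=(0.3,))
    assert log_likelihood(perm, tree, model, 2.0, pi) == pytest.approx(
        log_likelihood(aln, tree, model, 2.0, pi), abs=1e-10
    )


def test_likelihood_rejects_mismatched_taxa(tiny_alignment):
    tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.15,D:0.3);")
    pi = np.full(N_SENSE, 1 / N_SENSE)
    model = SiteClassModel("M0", proportions=(1.0,), omegas=(0.3,))
    with pytest.raises(ValueError, match="taxa"):
        log_likelihood(tiny_alignment, tree, model, 2.0, pi)


def test_alignment_with_stop_codon_rejected():
    aln = CodonAlignment.from_sequences(["A", "B"], ["TAAAAA", "ATGAAA"])
    tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
    pi = np.full(N_SENSE, 1 / N_SENSE)
    model = SiteClassModel("M0", proportions=(1.0,), omegas=(0.3,))
    with pytest.raises(ValueError, match="column 1"):
        log_likelihood(aln, tree, model, 2.0, pi)


# ---------------------------------------------------------------------------
# model container constraints


def test_model_constraint_validation():
    with pytest.raises(ValueError):
        SiteClassModel("M1a", proportions=(0.5, 0.5), omegas=(0.2, 0.9))
    with pytest.raises(ValueError):
        SiteClassModel("M2a", proportions=(0.5, 0.3, 0.2), omegas=(0.2, 1.0, 0.5))
    with pytest.raises(ValueError):
        SiteClassModel("M0", proportions=(0.9,), omegas=(0.2,))
    with pytest.raises(ValueError):
        SiteClassModel("M8", proportions=(0.9, 0.1), beta_p=1, beta_q=1, omega_s=0.5)


def test_m8_site_classes_layout():
    m = SiteClassModel("M8", proportions=(0.9, 0.1), beta_p=1.0, beta_q=1.0,
                       omega_s=2.0, K=5)
    props, omegas = m.site_classes()
    assert props.sum() == pytest.approx(1.0)
    assert props[:5] == pytest.approx(np.full(5, 0.18))
    assert omegas[-1] == 2.0 and np.all(omegas[:-1] <= 1.0)


# ---------------------------------------------------------------------------
# fitting, nesting, LRT


@pytest.fixture(scope="module")
def small_mixture_data():
    col_omega = np.array([0.1] * 90 + [4.0] * 10)
    spec = SimulationSpec(
        seed=21,
        tree_newick=balanced_tree_newick(8, 0.3),
        n_codons=100,
        kappa=2.0,
        per_column_omega=col_omega,
    )
    aln, labels, _ = simulate_codon_alignment(spec)
    return aln, PhyloTree.from_newick(spec.tree_newick)


def test_nested_fits_never_lose_likelihood(small_mixture_data):
    """lnL(alt) >= lnL(null) for M1a/M2a and M7/M8 (alt started at the
    null optimum's embedding)."""
    aln, tree = small_mixture_data
    cfg = OptimizerConfig(n_starts=1)
    n1, a1, _ = fit_nested_pair(aln, tree, "M1a", "M2a", optimizer=cfg)
    assert a1.lnL >= n1.lnL - 1e-6
    n2, a2, _ = fit_nested_pair(aln, tree, "M7", "M8", K=5, optimizer=cfg)
    assert a2.lnL >= n2.lnL - 1e-6


def test_neb_detects_planted_positive_sites(small_mixture_data):
    """Sites simulated at omega = 4 among omega = 0.1 background are the
    ones NEB flags under the selection model."""
    aln, tree = small_mixture_data
    cfg = OptimizerConfig(n_starts=1)
    _, alt, lr = fit_nested_pair(aln, tree, "M1a", "M2a", optimizer=cfg)
    assert lr.significant  # strong planted signal
    neb = neb_site_classes(alt, positive_threshold=0.90)
    sites = [s for s, _ in neb.positive_sites]
    assert len(sites) >= 3
    in_block = sum(1 for s in sites if 91 <= s <= 100)
    assert in_block / len(sites) >= 0.8
    # posteriors are proper per-column distributions
    np.testing.assert_allclose(alt.site_posteriors.sum(axis=1), 1.0, atol=1e-9)


def test_m0_fit_has_single_class_posteriors(small_mixture_data):
    aln, tree = small_mixture_data
    fit = fit_model(aln, tree, "M0", optimizer=OptimizerConfig(n_starts=1))
    np.testing.assert_allclose(fit.site_posteriors, 1.0, atol=1e-12)
    neb = neb_site_classes(fit)
    assert not neb.has_positive_class and neb.positive_sites == []


def test_chi2_critical_value():
    assert chi2_critical(2, 0.05) == pytest.approx(5.991, abs=5e-4)


def test_lrt_equal_likelihoods_not_significant():
    res = lrt(-1000.0, -1000.0, df=2)
    assert res.statistic == 0.0 and not res.significant


def test_lrt_marginal_statistic_below_threshold():
    res = lrt_from_statistic(5.573, df=2, alpha=0.05)
    assert not res.significant
    assert res.p_value == pytest.approx(0.0616, abs=5e-4)


def test_lrt_rejects_inverted_fits():
    with pytest.raises(ValueError, match="optimization failure"):
        lrt(-1000.0, -1000.1, df=2)
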