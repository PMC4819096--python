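"""Maximum-likelihood codon substitution models on a fixed tree.

Goldman-Yang-style codon rate matrices (omega, kappa, F3x4 equilibrium
frequencies over the 61 sense codons), site-class mixture models
M0 / M1a / M2a / M3 / M7 / M8, likelihood computation by Felsenstein
pruning with per-pattern rescaling, likelihood-ratio tests between nested
fits, and naive empirical Bayes (NEB) identification of positively
selected sites.

Conventions:
  * branch lengths are expected substitutions per codon; the mixture
    generator is normalized so the proportion-weighted mean rate is 1;
  * kappa is a free parameter estimated by ML; an optional single global
    branch-scale factor is co-estimated (per-branch optimization is out
    of scope);
  * the beta distribution of M7/M8 is discretized into K equal-probability
    categories represented by their conditional means (K = 10 default);
  * matrix exponentials use eigendecomposition of the reversible generator
    in the pi-symmetrized basis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import betainc, betaincinv, logsumexp
from scipy.stats import chi2

from .codonseq import CodonAlignment, GAP_CODON, GeneticCode, STANDARD_CODE, STOP

# ---------------------------------------------------------------------------
# codon state space

SENSE_CODONS = tuple(
    c
    for c in (a + b + d for a in "TCAG" for b in "TCAG" for d in "TCAG")
    if STANDARD_CODE.table[c] != STOP
)
N_SENSE = len(SENSE_CODONS)  # 61 under the standard code
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_PURINES = {"A", "G"}


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES) == (y in _PURINES)


# ---------------------------------------------------------------------------
# trees


class PhyloTree:
    """A fixed tree with branch lengths in expected substitutions per codon."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("every branch must carry a length")
            if not math.isfinite(edge.length) or edge.length < 0:
                raise ValueError(f"invalid branch length {edge.length}")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    @property
    def leaf_labels(self) -> list:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def arrays(self):
        """Postorder node table: (taxon_label|None, child indices, edge length)."""
        nodes = list(self._tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        table = []
        for n in nodes:
            label = n.taxon.label if n.taxon is not None else None
            children = [index[id(c)] for c in n.child_nodes()]
            length = 0.0 if n is self._tree.seed_node else float(n.edge.length)
            table.append((label, children, length))
        return table


# ---------------------------------------------------------------------------
# frequencies and rate matrices


def f3x4_frequencies(
    aln: CodonAlignment, pseudo_frequency: float = 1e-6
) -> np.ndarray:
    """F3x4 codon frequencies: per-codon-position nucleotide frequencies
    multiplied, stop codons removed, renormalized over the 61 sense codons.

    A nucleotide entirely absent at some position would zero out sense
    codons; such positions get a configurable pseudo-frequency (with a
    warning) so the likelihood stays well-defined.
    """
    if aln.n_codons == 0:
        raise ValueError("empty alignment")
    counts = np.zeros((3, 4))
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for row in aln.codons:
        for codon in row:
            if codon == GAP_CODON:
                continue
            for pos, base in enumerate(codon):
                counts[pos, nt_index[base]] += 1
    if np.any(counts == 0):
        warnings.warn(
            "a nucleotide is absent at some codon position; "
            f"adding pseudo-frequency {pseudo_frequency}",
            stacklevel=2,
        )
        counts = counts + pseudo_frequency * counts.sum(axis=1, keepdims=True)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


@dataclass(frozen=True)
class CodonRateMatrix:
    """GY94-style reversible generator over the 61 sense codons."""

    omega: float
    kappa: float
    pi: np.ndarray

    def generator(self, normalize: bool = True) -> np.ndarray:
        """Rate matrix Q; rows sum to zero. With ``normalize`` the expected
        rate -sum_i pi_i Q_ii is scaled to 1 substitution per codon."""
        return build_generator(self.omega, self.kappa, self.pi, normalize=normalize)


def build_generator(
    omega: float, kappa: float, pi: np.ndarray, normalize: bool = True
) -> np.ndarray:
    Q = _unnormalized_generator(omega, kappa, pi)
    if normalize:
        rate = -float(np.dot(pi, np.diag(Q)))
        if rate > 0:
            Q = Q / rate
    return Q


def _unnormalized_generator(omega: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    Q = np.zeros((N_SENSE, N_SENSE))
    for i, ci in enumerate(SENSE_CODONS):
        aa_i = STANDARD_CODE.table[ci]
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            rate = pi[j]
            if _is_transition(ci[p], cj[p]):
                rate *= kappa
            if STANDARD_CODE.table[cj] != aa_i:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def mean_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    return -float(np.dot(pi, np.diag(Q)))


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t) via eigendecomposition in the pi-symmetrized basis."""
    w, V, d = _symmetric_eig(Q, pi)
    return _reassemble(w, V, d, t)


def _symmetric_eig(Q: np.ndarray, pi: np.ndarray):
    d = np.sqrt(pi)
    B = Q * d[:, None] / d[None, :]
    B = (B + B.T) / 2.0  # symmetrize away roundoff
    w, V = np.linalg.eigh(B)
    return w, V, d


def _reassemble(w, V, d, t: float) -> np.ndarray:
    M = (V * np.exp(w * t)) @ V.T
    P = M / d[:, None] * d[None, :]
    np.clip(P, 0.0, None, out=P)
    return P


# ---------------------------------------------------------------------------
# site-class models

MODEL_IDS = ("M0", "M1a", "M2a", "M3", "M7", "M8")


@dataclass(frozen=True)
class SiteClassModel:
    """Parameterization of a site-class omega mixture.

    ``proportions``/``omegas`` hold explicit classes (M0/M1a/M2a/M3);
    ``beta_p``/``beta_q`` the beta shapes (M7/M8); ``omega_s`` the extra
    selection-class omega of M8 (bounded below by 1, boundary allowed);
    ``K`` the number of equal-probability beta categories.
    """

    model_id: str
    proportions: Optional[tuple] = None
    omegas: Optional[tuple] = None
    beta_p: Optional[float] = None
    beta_q: Optional[float] = None
    omega_s: Optional[float] = None
    K: int = 10

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id}")
        if self.proportions is not None:
            s = sum(self.proportions)
            if not math.isclose(s, 1.0, abs_tol=1e-8):
                raise ValueError(f"class proportions sum to {s}, not 1")
            if any(p < -1e-12 or p > 1 + 1e-12 for p in self.proportions):
                raise ValueError("proportions must lie in [0, 1]")
        if self.omegas is not None and any(w < 0 for w in self.omegas):
            raise ValueError("omega must be >= 0")
        if self.model_id == "M1a" and self.omegas is not None and self.omegas[1] != 1.0:
            raise ValueError("M1a fixes omega1 = 1")
        if self.model_id == "M7" and self.omegas is not None and any(
            w > 1 for w in self.omegas
        ):
            raise ValueError("M7 constrains omega <= 1")
        if self.model_id in ("M2a", "M8"):
            extra = self.omegas[-1] if self.model_id == "M2a" and self.omegas else self.omega_s
            if extra is not None and extra < 1.0 - 1e-9:
                raise ValueError(f"{self.model_id} selection-class omega must be >= 1")

    def site_classes(self) -> tuple:
        """(proportions, omegas) arrays of the discrete mixture."""
        mid = self.model_id
        if mid in ("M0", "M1a", "M2a", "M3"):
            return np.asarray(self.proportions, float), np.asarray(self.omegas, float)
        cats = discretize_beta(self.beta_p, self.beta_q, self.K)
        if mid == "M7":
            return np.full(self.K, 1.0 / self.K), cats
        # M8: beta categories carry p0 in total, plus one omega_s class
        p0 = self.proportions[0]
        props = np.append(np.full(self.K, p0 / self.K), 1.0 - p0)
        return props, np.append(cats, self.omega_s)

    @property
    def n_free_parameters(self) -> int:
        return {"M0": 1, "M1a": 2, "M2a": 4, "M3": 5, "M7": 2, "M8": 4}[self.model_id]


def discretize_beta(beta_p: float, beta_q: float, K: int) -> np.ndarray:
    """Means of K equal-probability slices of Beta(beta_p, beta_q).

    Category i's value is the conditional mean of the beta distribution on
    its i-th probability-1/K slice: K * mean_total * (I(b_i; p+1, q) -
    I(a_i; p+1, q)) with I the regularized incomplete beta.
    """
    if not (math.isfinite(beta_p) and math.isfinite(beta_q)):
        raise ValueError("beta shapes must be finite")
    if beta_p <= 0 or beta_q <= 0 or K < 1:
        raise ValueError("beta shapes must be positive and K >= 1")
    edges = betaincinv(beta_p, beta_q, np.linspace(0.0, 1.0, K + 1))
    cdf1 = betainc(beta_p + 1.0, beta_q, edges)
    total_mean = beta_p / (beta_p + beta_q)
    means = K * total_mean * np.diff(cdf1)
    return np.clip(means, 0.0, 1.0)


# ---------------------------------------------------------------------------
# likelihood by pruning


def encode_alignment(aln: CodonAlignment) -> np.ndarray:
    """(n_taxa, n_codons) integer codes; -1 marks a whole-codon gap.

    Stop codons are rejected with the offending column named.
    """
    codes = np.empty((aln.n_taxa, aln.n_codons), dtype=np.int64)
    for i, row in enumerate(aln.codons):
        for j, codon in enumerate(row):
            if codon == GAP_CODON:
                codes[i, j] = -1
            elif codon in CODON_INDEX:
                codes[i, j] = CODON_INDEX[codon]
            else:
                raise ValueError(
                    f"taxon {aln.taxa[i]!r}, codon column {j + 1}: {codon!r} "
                    "is a stop or invalid codon; sense codons only"
                )
    return codes


def _compress_patterns(codes: np.ndarray):
    patterns, inverse, counts = np.unique(
        codes, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, inverse.ravel(), counts.astype(float)


def _class_column_loglikes(
    patterns: np.ndarray,
    node_table: list,
    taxon_row: dict,
    P_per_branch: list,
    pi: np.ndarray,
) -> np.ndarray:
    """Pruning for one rate class: log-likelihood per site pattern."""
    npat = patterns.shape[1]
    partials = [None] * len(node_table)
    logscale = np.zeros(npat)
    for idx, (label, children, _t) in enumerate(node_table):
        if not children:  # leaf
            states = patterns[taxon_row[label]]
            L = np.zeros((npat, N_SENSE))
            observed = states >= 0
            L[observed, states[observed]] = 1.0
            L[~observed, :] = 1.0  # gap = missing data
            partials[idx] = L
        else:
            L = np.ones((npat, N_SENSE))
            for c in children:
                L *= partials[c] @ P_per_branch[c].T
                partials[c] = None
            scale = L.max(axis=1)
            if np.any(scale <= 0):
                bad = int(np.argmax(scale <= 0))
                raise FloatingPointError(
                    f"zero partial likelihood at site pattern {bad}"
                )
            L /= scale[:, None]
            logscale += np.log(scale)
            partials[idx] = L
    root = partials[-1]
    return np.log(root @ pi) + logscale


def _mixture_loglikes(
    patterns, node_table, taxon_row, props, omegas, kappa, pi, scale=1.0
):
    """Per-pattern per-class log-likelihoods under the normalized mixture."""
    # joint normalization: mean rate over the mixture is 1 sub/codon
    gens = [_unnormalized_generator(w, kappa, pi) for w in omegas]
    rate = sum(p * mean_rate(Q, pi) for p, Q in zip(props, gens))
    if rate <= 0:
        raise FloatingPointError("degenerate mixture: zero expected rate")
    per_class = np.empty((len(omegas), patterns.shape[1]))
    for k, Q in enumerate(gens):
        w, V, d = _symmetric_eig(Q / rate, pi)
        P_per_branch = [
            _reassemble(w, V, d, t * scale) for (_, _, t) in node_table
        ]
        per_class[k] = _class_column_loglikes(
            patterns, node_table, taxon_row, P_per_branch, pi
        )
    return per_class


def log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: SiteClassModel,
    kappa: float,
    pi: np.ndarray,
    branch_scale: float = 1.0,
) -> float:
    """Total log-likelihood of the alignment under a site-class mixture."""
    props, omegas = model.site_classes()
    codes = encode_alignment(aln)
    patterns, _inv, weights = _compress_patterns(codes)
    node_table, taxon_row = _prepare_tree(tree, aln)
    per_class = _mixture_loglikes(
        patterns, node_table, taxon_row, props, omegas, kappa, pi, branch_scale
    )
    col_log = _mix_columns(per_class, props)
    lnL = float(np.dot(col_log, weights))
    if not math.isfinite(lnL):
        bad = int(np.argmax(~np.isfinite(col_log)))
        raise FloatingPointError(f"non-finite likelihood at site pattern {bad}")
    return lnL


def _mix_columns(per_class: np.ndarray, props: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logw = np.log(props)
    return logsumexp(per_class + logw[:, None], axis=0)


def _prepare_tree(tree: PhyloTree, aln: CodonAlignment):
    node_table = tree.arrays()
    leaf_set = {lab for lab, ch, _ in node_table if not ch}
    if leaf_set != set(aln.taxa):
        raise ValueError(
            f"tree leaves {sorted(leaf_set)} do not match alignment taxa "
            f"{sorted(aln.taxa)}"
        )
    taxon_row = {label: i for i, label in enumerate(aln.taxa)}
    return node_table, taxon_row


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    model: SiteClassModel
    lnL: float
    kappa_hat: float
    branch_scale_hat: float
    site_posteriors: np.ndarray  # (n_codons, n_classes), rows sum to 1
    class_omegas: np.ndarray
    class_proportions: np.ndarray
    converged: bool
    n_evaluations: int
    message: str = ""


# documented multi-start omega / shape seeds per model
_BASE_STARTS = {
    "M0": [{"omega": 0.2}, {"omega": 0.05}, {"omega": 1.5}],
    "M1a": [
        {"p0": 0.8, "omega0": 0.2},
        {"p0": 0.5, "omega0": 0.05},
        {"p0": 0.95, "omega0": 0.5},
    ],
    "M2a": [
        {"a1": 0.8, "a2": 0.7, "omega0": 0.2, "omega2": 2.0},
        {"a1": 0.5, "a2": 0.9, "omega0": 0.05, "omega2": 4.0},
        {"a1": 0.9, "a2": 0.5, "omega0": 0.5, "omega2": 1.5},
    ],
    "M3": [
        {"a1": 0.4, "a2": 0.6, "w0": 0.05, "w1": 0.3, "w2": 1.2},
        {"a1": 0.3, "a2": 0.5, "w0": 0.01, "w1": 0.2, "w2": 0.8},
        {"a1": 0.6, "a2": 0.5, "w0": 0.1, "w1": 0.5, "w2": 2.0},
    ],
    "M7": [
        {"beta_p": 0.8, "beta_q": 2.5},
        {"beta_p": 0.3, "beta_q": 1.0},
        {"beta_p": 2.0, "beta_q": 2.0},
    ],
    "M8": [
        {"p0": 0.95, "beta_p": 0.8, "beta_q": 2.5, "omega_s": 1.5},
        {"p0": 0.8, "beta_p": 0.3, "beta_q": 1.0, "omega_s": 3.0},
        {"p0": 0.99, "beta_p": 2.0, "beta_q": 2.0, "omega_s": 1.1},
    ],
}

_W_MAX = 50.0
_SHAPE_BOUNDS = (math.log(0.02), math.log(50.0))


def _model_layout(model_id: str, K: int):
    """Vector layout (names, bounds) of the free parameters, excluding the
    shared tail (kappa, log branch scale)."""
    if model_id == "M0":
        return ["omega"], [(1e-6, _W_MAX)]
    if model_id == "M1a":
        return ["p0", "omega0"], [(0.0, 1.0), (1e-6, 1.0)]
    if model_id == "M2a":
        return (
            ["a1", "a2", "omega0", "omega2"],
            [(0.0, 1.0), (0.0, 1.0), (1e-6, 1.0), (1.0, _W_MAX)],
        )
    if model_id == "M3":
        return (
            ["a1", "a2", "w0", "w1", "w2"],
            [(0.0, 1.0), (0.0, 1.0), (1e-6, _W_MAX), (1e-6, _W_MAX), (1e-6, _W_MAX)],
        )
    if model_id == "M7":
        return ["log_bp", "log_bq"], [_SHAPE_BOUNDS, _SHAPE_BOUNDS]
    if model_id == "M8":
        return (
            ["p0", "log_bp", "log_bq", "omega_s"],
            [(0.0, 1.0), _SHAPE_BOUNDS, _SHAPE_BOUNDS, (1.0, _W_MAX)],
        )
    raise ValueError(model_id)


def _params_to_model(model_id: str, values: dict, K: int) -> SiteClassModel:
    if model_id == "M0":
        return SiteClassModel("M0", proportions=(1.0,), omegas=(values["omega"],), K=K)
    if model_id == "M1a":
        p0 = values["p0"]
        return SiteClassModel(
            "M1a", proportions=(p0, 1.0 - p0), omegas=(values["omega0"], 1.0), K=K
        )
    if model_id == "M2a":
        a1, a2 = values["a1"], values["a2"]
        p0, p1 = a1, (1.0 - a1) * a2
        p2 = max(0.0, 1.0 - p0 - p1)
        return SiteClassModel(
            "M2a",
            proportions=(p0, p1, p2),
            omegas=(values["omega0"], 1.0, values["omega2"]),
            K=K,
        )
    if model_id == "M3":
        a1, a2 = values["a1"], values["a2"]
        p0, p1 = a1, (1.0 - a1) * a2
        p2 = max(0.0, 1.0 - p0 - p1)
        return SiteClassModel(
            "M3",
            proportions=(p0, p1, p2),
            omegas=(values["w0"], values["w1"], values["w2"]),
            K=K,
        )
    if model_id == "M7":
        return SiteClassModel(
            "M7",
            beta_p=math.exp(values["log_bp"]),
            beta_q=math.exp(values["log_bq"]),
            K=K,
        )
    if model_id == "M8":
        return SiteClassModel(
            "M8",
            proportions=(values["p0"], 1.0 - values["p0"]),
            beta_p=math.exp(values["log_bp"]),
            beta_q=math.exp(values["log_bq"]),
            omega_s=values["omega_s"],
            K=K,
        )
    raise ValueError(model_id)


def _start_to_vector(model_id: str, start: dict, names) -> list:
    s = dict(start)
    if "beta_p" in s:
        s["log_bp"] = math.log(s.pop("beta_p"))
    if "beta_q" in s:
        s["log_bq"] = math.log(s.pop("beta_q"))
    return [s[name] for name in names]


def embedded_start(null_fit: "FitResult", alt_id: str) -> dict:
    """Parameters of the alternative model equal (in likelihood) to a fitted
    null: guarantees lnL(alt) >= lnL(null) when used as an extra start."""
    null_model = null_fit.model
    if null_model.model_id == "M7" and alt_id == "M8":
        return {
            "p0": 1.0,
            "beta_p": null_model.beta_p,
            "beta_q": null_model.beta_q,
            "omega_s": 1.0,
            "kappa": null_fit.kappa_hat,
            "branch_scale": null_fit.branch_scale_hat,
        }
    if null_model.model_id == "M1a" and alt_id == "M2a":
        p0 = null_model.proportions[0]
        return {
            "a1": p0,
            "a2": 1.0,
            "omega0": null_model.omegas[0],
            "omega2": 1.0,
            "kappa": null_fit.kappa_hat,
            "branch_scale": null_fit.branch_scale_hat,
        }
    if null_model.model_id == "M0" and alt_id == "M3":
        return {
            "a1": 1.0,
            "a2": 0.5,
            "w0": null_model.omegas[0],
            "w1": null_model.omegas[0],
            "w2": null_model.omegas[0],
            "kappa": null_fit.kappa_hat,
            "branch_scale": null_fit.branch_scale_hat,
        }
    raise ValueError(f"no embedding from {null_model.model_id} into {alt_id}")


@dataclass
class OptimizerConfig:
    n_starts: int = 3  # documented multi-starts drawn from _BASE_STARTS
    jitter: float = 0.0  # relative jitter on starts (seeded)
    seed: int = 0
    maxiter: int = 300
    ftol: float = 1e-10  # relative; ~1e-6 absolute on lnL of magnitude 1e4
    kappa_bounds: tuple = (0.2, 25.0)
    log_scale_bounds: tuple = (math.log(0.02), math.log(50.0))
    optimize_branch_scale: bool = True


def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model_id: str,
    K: int = 10,
    optimizer: Optional[OptimizerConfig] = None,
    pi: Optional[np.ndarray] = None,
    extra_starts: Optional[Sequence] = None,
    kappa_start: float = 2.0,
) -> FitResult:
    """Maximize lnL over the model's free parameters plus kappa (and an
    optional global branch-scale factor), from documented multi-starts.

    Non-convergence is flagged in the result; the best parameters seen are
    always returned. ``extra_starts`` accepts parameter dicts (e.g. from
    :func:`embedded_start`) prepended to the start list.
    """
    cfg = optimizer or OptimizerConfig()
    if pi is None:
        pi = f3x4_frequencies(aln)
    codes = encode_alignment(aln)
    patterns, inverse, weights = _compress_patterns(codes)
    node_table, taxon_row = _prepare_tree(tree, aln)
    names, bounds = _model_layout(model_id, K)
    all_names = names + ["kappa", "log_scale"]
    all_bounds = bounds + [cfg.kappa_bounds, cfg.log_scale_bounds]
    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        values = dict(zip(names, x[: len(names)]))
        kappa = x[-2]
        scale = math.exp(x[-1]) if cfg.optimize_branch_scale else 1.0
        model = _params_to_model(model_id, values, K)
        props, omegas = model.site_classes()
        try:
            per_class = _mixture_loglikes(
                patterns, node_table, taxon_row, props, omegas, kappa, pi, scale
            )
            col_log = _mix_columns(per_class, props)
            lnL = float(np.dot(col_log, weights))
        except FloatingPointError:
            return 1e12
        if not math.isfinite(lnL):
            return 1e12
        return -lnL

    starts = []
    for s in extra_starts or []:
        starts.append(dict(s))
    for s in _BASE_STARTS[model_id][: cfg.n_starts]:
        starts.append(dict(s))

    rng = np.random.default_rng(cfg.seed)
    best = None
    for start in starts:
        kappa0 = start.pop("kappa", kappa_start)
        scale0 = start.pop("branch_scale", 1.0)
        x0 = _start_to_vector(model_id, start, names) + [kappa0, math.log(scale0)]
        if cfg.jitter > 0:
            x0 = [
                v + rng.normal(0.0, cfg.jitter * max(abs(v), 0.1)) for v in x0
            ]
        x0 = [min(max(v, lo), hi) for v, (lo, hi) in zip(x0, all_bounds)]
        res = minimize(
            objective,
            np.asarray(x0, float),
            method="L-BFGS-B",
            bounds=all_bounds,
            options={"maxiter": cfg.maxiter, "ftol": cfg.ftol},
        )
        if best is None or res.fun < best.fun:
            best = res

    values = dict(zip(names, best.x[: len(names)]))
    kappa_hat = float(best.x[-2])
    scale_hat = math.exp(float(best.x[-1])) if cfg.optimize_branch_scale else 1.0
    model = _params_to_model(model_id, values, K)
    props, omegas = model.site_classes()
    per_class = _mixture_loglikes(
        patterns, node_table, taxon_row, props, omegas, kappa_hat, pi, scale_hat
    )
    col_log = _mix_columns(per_class, props)
    lnL = float(np.dot(col_log, weights))
    # NEB plug-in posteriors, expanded from patterns to columns
    with np.errstate(divide="ignore"):
        logw = np.log(props)
    log_post = per_class + logw[:, None] - col_log[None, :]
    posteriors_pat = np.exp(log_post).T  # (npat, nclasses)
    posteriors = posteriors_pat[inverse]
    return FitResult(
        model=model,
        lnL=lnL,
        kappa_hat=kappa_hat,
        branch_scale_hat=scale_hat,
        site_posteriors=posteriors,
        class_omegas=omegas,
        class_proportions=props,
        converged=bool(best.success),
        n_evaluations=n_eval,
        message=str(best.message),
    )


_NESTED_PAIRS = {("M7", "M8"): 2, ("M1a", "M2a"): 2, ("M0", "M3"): 4}


def fit_nested_pair(
    aln: CodonAlignment,
    tree: PhyloTree,
    null_id: str,
    alt_id: str,
    K: int = 10,
    optimizer: Optional[OptimizerConfig] = None,
    pi: Optional[np.ndarray] = None,
    alpha: float = 0.05,
):
    """Fit a nested null/alternative pair and run the LRT.

    The alternative fit includes a start at the null optimum's embedding,
    guaranteeing lnL(alt) >= lnL(null).
    """
    if (null_id, alt_id) not in _NESTED_PAIRS:
        raise ValueError(f"unsupported nested pair {null_id} vs {alt_id}")
    null_fit = fit_model(aln, tree, null_id, K=K, optimizer=optimizer, pi=pi)
    alt_fit = fit_model(
        aln,
        tree,
        alt_id,
        K=K,
        optimizer=optimizer,
        pi=pi,
        extra_starts=[embedded_start(null_fit, alt_id)],
    )
    df = _NESTED_PAIRS[(null_id, alt_id)]
    return null_fit, alt_fit, lrt(null_fit, alt_fit, df=df, alpha=alpha)


# ---------------------------------------------------------------------------
# likelihood-ratio test and NEB


@dataclass(frozen=True)
class LRTResult:
    statistic: float  # 2 * (lnL_alt - lnL_null), clamped at 0
    df: int
    p_value: float
    critical_value: float
    alpha: float
    significant: bool


def chi2_critical(df: int, alpha: float = 0.05) -> float:
    """Chi-squared (1 - alpha) quantile, e.g. 5.991 at df = 2, alpha = 0.05."""
    return float(chi2.ppf(1.0 - alpha, df))


def lrt(null_fit, alt_fit, df: int, alpha: float = 0.05) -> LRTResult:
    """LRT of nested fits: statistic 2*delta-lnL against chi-squared(df)."""
    lnl_null = null_fit.lnL if hasattr(null_fit, "lnL") else float(null_fit)
    lnl_alt = alt_fit.lnL if hasattr(alt_fit, "lnL") else float(alt_fit)
    delta = lnl_alt - lnl_null
    if delta < -1e-6:
        raise ValueError(
            f"alternative lnL {lnl_alt} below null {lnl_null}: "
            "optimization failure upstream"
        )
    stat = max(0.0, 2.0 * delta)
    return lrt_from_statistic(stat, df, alpha)


def lrt_from_statistic(statistic: float, df: int, alpha: float = 0.05) -> LRTResult:
    crit = chi2_critical(df, alpha)
    return LRTResult(
        statistic=statistic,
        df=df,
        p_value=float(chi2.sf(statistic, df)),
        critical_value=crit,
        alpha=alpha,
        significant=statistic > crit,
    )


@dataclass
class NEBResult:
    positive_sites: list  # (1-based column, posterior P(omega-class > 1))
    has_positive_class: bool
    threshold: float
    note: str = ""


def neb_site_classes(fit: FitResult, positive_threshold: float = 0.95) -> NEBResult:
    """Columns whose NEB posterior mass on omega > 1 classes reaches the
    threshold (plug-in posteriors with fitted parameters; 1-based sites)."""
    positive = fit.class_omegas > 1.0
    if not positive.any():
        return NEBResult(
            positive_sites=[],
            has_positive_class=False,
            threshold=positive_threshold,
            note=f"model {fit.model.model_id} has no class with omega > 1",
        )
    mass = fit.site_posteriors[:, positive].sum(axis=1)
    sites = [
        (i + 1, float(mass[i])) for i in range(len(mass)) if mass[i] >= positive_threshold
    ]
    return NEBResult(
        positive_sites=sites, has_positive_class=True, threshold=positive_threshold
    )
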