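"""Codon site-class substitution models, ML fitting, LRTs, and NEB posteriors.

The substitution process is the 61-state reversible codon model with a
transition/transversion ratio kappa, codon frequencies pi, and a
nonsynonymous/synonymous rate ratio omega:

    q_ij = pi_j * kappa^{transition} * omega^{nonsynonymous}

for codon pairs differing at one nucleotide (zero otherwise), scaled so the
expected number of substitutions per codon per unit time is one. Site-class
mixtures implement the standard model families:

    M0   one ratio                       M3   K discrete classes
    M1a  nearly neutral (w0<1, w1=1)     M7   beta(p, q), 10 categories
    M2a  M1a + positive class (w2>1)     M8   M7 + positive class (w10>=1)

plus the fixed-sites pair A/B in which a designated column partition (the
key binding-cavity positions) receives its own omega. Likelihoods are
computed by Felsenstein pruning with gaps as missing data; per-site
posteriors over classes (naive empirical Bayes at the MLEs) give the
posterior probability of positive selection and the posterior-mean omega
per alignment column.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._codons import (
    N_CODONS,
    SENSE_CODONS,
    SINGLE_STEP,
    SYNONYMOUS,
    TRANSITION,
)
from .phylogeny import Tree

MODEL_IDS = ("M0", "M1a", "M2a", "M3", "M7", "M8")


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


# ---------------------------------------------------------------------------
# rate matrix and transition probabilities

_TS_MASK = SINGLE_STEP & TRANSITION
_TV_MASK = SINGLE_STEP & ~TRANSITION
_NONSYN_MASK = SINGLE_STEP & ~SYNONYMOUS


def equal_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(int_matrix: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies.

    Counts nucleotides at the three codon positions over all non-missing
    cells, forms the product for each sense codon, and renormalizes. A small
    floor keeps every sense codon attainable (zero frequencies would break
    the reversible eigendecomposition).
    """
    counts = np.zeros((3, 4))  # positions x TCAG
    nuc_index = {"T": 0, "C": 1, "A": 2, "G": 3}
    for state in np.unique(int_matrix):
        if state < 0:
            continue
        codon = SENSE_CODONS[state]
        weight = np.sum(int_matrix == state)
        for pos in range(3):
            counts[pos, nuc_index[codon[pos]]] += weight
    counts += 1.0  # Laplace smoothing against absent nucleotides
    nf = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            nf[0, nuc_index[c[0]]] * nf[1, nuc_index[c[1]]] * nf[2, nuc_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    pi = np.maximum(pi, floor * pi.max())
    return pi / pi.sum()


def f1x4_frequencies(int_matrix: np.ndarray) -> np.ndarray:
    """Codon frequencies from overall nucleotide frequencies."""
    counts = np.ones(4)
    nuc_index = {"T": 0, "C": 1, "A": 2, "G": 3}
    for state in np.unique(int_matrix):
        if state < 0:
            continue
        codon = SENSE_CODONS[state]
        weight = np.sum(int_matrix == state)
        for ch in codon:
            counts[nuc_index[ch]] += weight
    nf = counts / counts.sum()
    pi = np.array(
        [nf[nuc_index[c[0]]] * nf[nuc_index[c[1]]] * nf[nuc_index[c[2]]] for c in SENSE_CODONS]
    )
    return pi / pi.sum()


def f61_frequencies(int_matrix: np.ndarray) -> np.ndarray:
    """Empirical codon frequencies with a single pseudocount."""
    counts = np.ones(N_CODONS)
    states, freq = np.unique(int_matrix[int_matrix >= 0], return_counts=True)
    counts[states] += freq
    return counts / counts.sum()


def codon_frequencies(int_matrix: np.ndarray, scheme: str = "F3x4") -> np.ndarray:
    fns = {
        "equal": lambda m: equal_frequencies(),
        "F1x4": f1x4_frequencies,
        "F3x4": f3x4_frequencies,
        "F61": f61_frequencies,
    }
    if scheme not in fns:
        raise ModelError(f"unknown codon frequency scheme {scheme!r}")
    return fns[scheme](int_matrix)


def raw_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unscaled generator q_ij = pi_j * kappa^{ts} * omega^{nonsyn}."""
    if kappa <= 0 or omega < 0:
        raise ModelError("kappa must be > 0 and omega >= 0")
    if omega == 0:
        omega = 1e-8  # keep the chain irreducible
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[SINGLE_STEP] = 1.0
    Q[_TS_MASK] *= kappa
    Q[_NONSYN_MASK] *= omega
    Q *= pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Scaled 61x61 generator of the codon model.

    Rows sum to zero; -sum_i pi_i q_ii = 1 so branch lengths are expected
    substitutions per codon.
    """
    Q = raw_rate_matrix(kappa, omega, pi)
    mu = -np.sum(pi * np.diag(Q))
    return Q / mu


def mixture_rate_matrices(
    kappa: float, omegas: np.ndarray, props: np.ndarray, pi: np.ndarray
) -> list[np.ndarray]:
    """Per-class generators under shared mixture scaling.

    All classes are divided by the same factor, chosen so the expected
    substitution rate averaged over site classes is one: sites in classes
    with larger omega evolve proportionally faster, as in the standard
    site-model convention. Branch lengths are then expected substitutions
    per codon averaged over the site distribution.
    """
    raws = [raw_rate_matrix(kappa, w, pi) for w in omegas]
    mus = np.array([-np.sum(pi * np.diag(Q)) for Q in raws])
    c = float(np.dot(props, mus))
    if c <= 0:
        raise ModelError("degenerate mixture rate")
    return [Q / c for Q in raws]


class SpectralQ:
    """Eigendecomposition of a reversible generator for fast P(t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        sym = (Q * d[:, None]) / d[None, :]
        sym = 0.5 * (sym + sym.T)
        eigval, eigvec = np.linalg.eigh(sym)
        self.eigval = eigval
        self.right = eigvec / d[:, None]
        self.left = eigvec.T * d[None, :]
        self.pi = pi

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ModelError("branch length must be >= 0")
        P = (self.right * np.exp(self.eigval * t)[None, :]) @ self.left
        np.clip(P, 0.0, None, out=P)
        rows = P.sum(axis=1, keepdims=True)
        return P / rows


def transition_probabilities(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """Stochastic matrix P(t) = exp(Qt) via the reversible symmetrization."""
    if pi is None:
        # stationary distribution from the generator's left null vector
        eigval, eigvec = np.linalg.eig(Q.T)
        k = int(np.argmin(np.abs(eigval)))
        pi = np.real(eigvec[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
    return SpectralQ(Q, pi).transition(t)


# ---------------------------------------------------------------------------
# beta discretization (M7/M8)


def discretize_beta(p: float, q: float, K: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """K equal-probability categories of Beta(p, q); each omega is the mean
    of the density over its quantile slice (incomplete-beta differences)."""
    if p <= 0 or q <= 0:
        raise ModelError("beta parameters must be positive")
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, K + 1), p, q)
    upper = stats.beta.cdf(edges, p + 1, q)
    mean = p / (p + q)
    omegas = mean * (upper[1:] - upper[:-1]) * K
    omegas = np.clip(omegas, 1e-12, 1.0 - 1e-12)
    props = np.full(K, 1.0 / K)
    return props, omegas


# ---------------------------------------------------------------------------
# pruning engine


class PruningEngine:
    """Felsenstein pruning over compressed site patterns.

    Columns are compressed to unique leaf-state patterns; gaps are missing
    data (all-ones partial vectors). Likelihoods are returned per pattern
    and per site class, with per-pattern log scaling to avoid underflow.
    """

    def __init__(self, int_matrix: np.ndarray, labels: list[str], tree: Tree):
        leaf_names = tree.leaf_names()
        if set(leaf_names) != set(labels):
            raise ModelError("tree leaves do not match alignment labels")
        order = [labels.index(name) for name in leaf_names]
        data = int_matrix[order]  # rows in tree-leaf order
        patterns, inverse, weights = np.unique(
            data.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (M, S)
        self.pattern_index = inverse  # (L,)
        self.weights = weights.astype(float)
        self.n_columns = int_matrix.shape[1]
        self.tree = tree
        self._nodes = tree.postorder()
        self._leaf_counter = 0
        # map leaves (in postorder) to pattern rows
        self._leaf_slot = {}
        k = 0
        for node in self._nodes:
            if node.is_leaf:
                self._leaf_slot[id(node)] = k
                k += 1

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def pattern_likelihoods(
        self, spectral: SpectralQ, branch_lengths: dict[int, float]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(likelihood, log_scale) per pattern for one site class."""
        M = self.n_patterns
        P_cache: dict[int, np.ndarray] = {
            nid: spectral.transition(t) for nid, t in branch_lengths.items()
        }
        partial: dict[int, np.ndarray] = {}
        scale = np.zeros(M)
        for node in self._nodes:
            if node.is_leaf:
                continue
            F = np.ones((M, N_CODONS))
            for child in node.children:
                P = P_cache[id(child)]
                if child.is_leaf:
                    states = self.patterns[:, self._leaf_slot[id(child)]]
                    contrib = np.ones((M, N_CODONS))
                    seen = states >= 0
                    contrib[seen] = P[:, states[seen]].T
                else:
                    contrib = partial.pop(id(child)) @ P.T
                F *= contrib
            mx = F.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            F /= mx[:, None]
            scale += np.log(mx)
            partial[id(node)] = F
        root = partial[id(self.tree.root)]
        like = root @ spectral.pi
        return like, scale

    def class_log_likelihoods(
        self,
        kappa: float,
        omegas: np.ndarray,
        pi: np.ndarray,
        branch_lengths: dict[int, float],
        props: np.ndarray | None = None,
    ) -> np.ndarray:
        """(K, M) matrix of per-pattern log-likelihoods, one row per class.

        With ``props`` given, the class generators share the mixture scaling
        (the standard convention: omega > 1 classes evolve faster); without
        it each class is scaled to unit rate on its own.
        """
        if props is not None:
            Qs = mixture_rate_matrices(kappa, omegas, props, pi)
        else:
            Qs = [build_rate_matrix(kappa, w, pi) for w in omegas]
        out = np.empty((len(omegas), self.n_patterns))
        for k, Q in enumerate(Qs):
            spectral = SpectralQ(Q, pi)
            like, scale = self.pattern_likelihoods(spectral, branch_lengths)
            out[k] = np.log(np.maximum(like, 1e-300)) + scale
        return out

    def mixture_lnl(self, props: np.ndarray, class_loglik: np.ndarray) -> float:
        """Total alignment log-likelihood of the site-class mixture."""
        m = class_loglik.max(axis=0)
        mix = np.log(np.maximum(props @ np.exp(class_loglik - m[None, :]), 1e-300)) + m
        return float(np.dot(self.weights, mix))

    def posterior(self, props: np.ndarray, class_loglik: np.ndarray) -> np.ndarray:
        """NEB per-column posterior over classes, expanded to columns: (L, K)."""
        m = class_loglik.max(axis=0)
        w = props[:, None] * np.exp(class_loglik - m[None, :])
        post = (w / w.sum(axis=0, keepdims=True)).T  # (M, K)
        return post[self.pattern_index]


# ---------------------------------------------------------------------------
# model parameterizations (transformed, unconstrained-with-bounds)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p: float) -> float:
    p = min(max(p, 1e-8), 1 - 1e-8)
    return float(np.log(p / (1 - p)))


def _stick_break(raw: np.ndarray) -> np.ndarray:
    """K-1 unconstrained values -> K proportions summing to one."""
    props = []
    rest = 1.0
    for x in raw:
        frac = _sigmoid(x)
        props.append(rest * frac)
        rest *= 1.0 - frac
    props.append(rest)
    return np.array(props)


class _ModelFamily:
    """Transformation between the optimizer vector and (props, omegas)."""

    def __init__(self, model_id: str, n_classes_m3: int = 3):
        self.model_id = model_id
        self.K3 = n_classes_m3

    @property
    def n_params(self) -> int:
        return {
            "M0": 1,
            "M1a": 2,
            "M2a": 4,
            "M3": 2 * self.K3 - 1,
            "M7": 2,
            "M8": 4,
        }[self.model_id]

    def bounds(self) -> list[tuple[float, float]]:
        L = (-15.0, 15.0)
        W = (np.log(1e-4), np.log(50.0))
        PQ = (np.log(5e-3), np.log(100.0))
        WPOS = (np.log(1e-6), np.log(50.0))  # log(w - 1)
        return {
            "M0": [W],
            "M1a": [L, L],
            "M2a": [L, L, L, WPOS],
            "M3": [L] * (self.K3 - 1) + [W] * self.K3,
            "M7": [PQ, PQ],
            "M8": [PQ, PQ, L, WPOS],
        }[self.model_id]

    def default_init(self) -> np.ndarray:
        return {
            "M0": np.array([np.log(0.4)]),
            "M1a": np.array([_logit(0.7), _logit(0.2)]),
            "M2a": np.array([_logit(0.65), _logit(0.85), _logit(0.2), np.log(1.0)]),
            "M3": np.concatenate(
                [
                    np.zeros(self.K3 - 1),
                    np.log(np.linspace(0.05, 0.8, self.K3)),
                ]
            ),
            "M7": np.array([np.log(0.6), np.log(1.5)]),
            "M8": np.array([np.log(0.6), np.log(1.5), _logit(0.9), np.log(1.0)]),
        }[self.model_id]

    def classes(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
        """-> (proportions, omegas, named parameter dict)."""
        mid = self.model_id
        if mid == "M0":
            w = float(np.exp(theta[0]))
            return np.array([1.0]), np.array([w]), {"omega": w}
        if mid == "M1a":
            p0 = float(_sigmoid(theta[0]))
            w0 = float(_sigmoid(theta[1]))
            return (
                np.array([p0, 1.0 - p0]),
                np.array([w0, 1.0]),
                {"p0": p0, "omega0": w0},
            )
        if mid == "M2a":
            props = _stick_break(theta[:2])
            w0 = float(_sigmoid(theta[2]))
            w2 = 1.0 + float(np.exp(theta[3]))
            return (
                props,
                np.array([w0, 1.0, w2]),
                {
                    "p0": float(props[0]),
                    "p1": float(props[1]),
                    "p2": float(props[2]),
                    "omega0": w0,
                    "omega2": w2,
                },
            )
        if mid == "M3":
            props = _stick_break(theta[: self.K3 - 1])
            omegas = np.exp(theta[self.K3 - 1 :])
            return props, omegas, {
                **{f"p{k}": float(props[k]) for k in range(self.K3)},
                **{f"omega{k}": float(omegas[k]) for k in range(self.K3)},
            }
        if mid == "M7":
            p, q = np.exp(theta[:2])
            props, omegas = discretize_beta(float(p), float(q))
            return props, omegas, {"p": float(p), "q": float(q)}
        if mid == "M8":
            p, q = np.exp(theta[:2])
            p0 = float(_sigmoid(theta[2]))
            w10 = 1.0 + float(np.exp(theta[3]))
            props, omegas = discretize_beta(float(p), float(q))
            props = np.append(props * p0, 1.0 - p0)
            omegas = np.append(omegas, w10)
            return props, omegas, {
                "p": float(p),
                "q": float(q),
                "p0": p0,
                "p10": 1.0 - p0,
                "omega10": w10,
            }
        raise ModelError(f"unknown model {mid!r}")


# ---------------------------------------------------------------------------
# fit containers


@dataclass
class SiteModelFit:
    """Maximized site-class model: MLEs, lnL, and per-site NEB posteriors."""

    model_id: str
    lnl: float
    kappa: float
    parameters: dict
    proportions: np.ndarray
    omegas: np.ndarray
    branch_lengths: list[float]
    tree_newick: str
    pi: np.ndarray
    posteriors: np.ndarray  # (columns, classes)
    neb_omega: np.ndarray  # (columns,)
    freq_scheme: str = "F3x4"
    converged: bool = True
    n_restarts: int = 0
    seed: int | None = None
    partition_omegas: dict | None = None  # fixed-sites models only

    def posterior_positive(self) -> np.ndarray:
        """P(omega > 1 | column) per alignment column."""
        mask = self.omegas > 1.0
        return self.posteriors[:, mask].sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "lnl": self.lnl,
            "kappa": self.kappa,
            "parameters": self.parameters,
            "proportions": self.proportions.tolist(),
            "omegas": self.omegas.tolist(),
            "branch_lengths": list(self.branch_lengths),
            "tree": self.tree_newick,
            "freq_scheme": self.freq_scheme,
            "converged": self.converged,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
        }


@dataclass
class LRTResult:
    """Likelihood ratio test between nested fits: LR = 2(lnL_alt - lnL_null)."""

    delta: float
    lr: float
    df: int
    p_value: float
    alpha: float
    null_model: str
    alt_model: str

    @property
    def tenable_model(self) -> str:
        return self.alt_model if self.p_value < self.alpha else self.null_model

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "LR": self.lr,
            "df": self.df,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "null_model": self.null_model,
            "alt_model": self.alt_model,
            "tenable_model": self.tenable_model,
        }


def likelihood_ratio_test(
    fit_null: SiteModelFit | float,
    fit_alt: SiteModelFit | float,
    df: int,
    alpha: float = 0.05,
    null_model: str | None = None,
    alt_model: str | None = None,
) -> LRTResult:
    """Chi-square LRT; accepts fits or raw log-likelihoods."""
    lnl0 = fit_null.lnl if isinstance(fit_null, SiteModelFit) else float(fit_null)
    lnl1 = fit_alt.lnl if isinstance(fit_alt, SiteModelFit) else float(fit_alt)
    if df < 1:
        raise ModelError("df must be >= 1")
    delta = lnl1 - lnl0
    if delta < -1e-4:
        raise ConvergenceError(
            f"alternative lnL {lnl1:.6f} below null {lnl0:.6f}; optimizer failure"
        )
    delta = max(delta, 0.0)
    lr = 2.0 * delta
    p = float(stats.chi2.sf(lr, df))
    return LRTResult(
        delta=delta,
        lr=lr,
        df=df,
        p_value=p,
        alpha=alpha,
        null_model=null_model
        or (fit_null.model_id if isinstance(fit_null, SiteModelFit) else "null"),
        alt_model=alt_model
        or (fit_alt.model_id if isinstance(fit_alt, SiteModelFit) else "alt"),
    )


# ---------------------------------------------------------------------------
# fitting


_BL_BOUNDS = (np.log(1e-6), np.log(25.0))
_KAPPA_BOUNDS = (np.log(0.05), np.log(50.0))


def _initial_branch_lengths(tree: Tree) -> np.ndarray:
    return np.array([max(e.length, 1e-3) for e in tree.edges()])


def fit_model(
    alignment,
    tree: Tree,
    model_id: str = "M0",
    freq_scheme: str = "F3x4",
    branch_mode: str = "optimize",
    n_restarts: int = 3,
    seed: int = 0,
    n_classes_m3: int = 3,
    init_theta: np.ndarray | None = None,
    tol: float = 1e-8,
) -> SiteModelFit:
    """Maximum-likelihood fit of one site-class model.

    Optimizes kappa, branch lengths (unless ``branch_mode="fixed"``, which
    keeps the input tree's lengths — e.g. lengths pre-estimated under M0),
    and the model's class parameters by bounded quasi-Newton on transformed
    parameters, with ``n_restarts`` jittered restarts (seeded, recorded).
    Requires an admitted subgroup alignment of at least 3 sequences.
    """
    if alignment.n_sequences < 3:
        raise ModelError("model fitting requires >= 3 sequences")
    if model_id not in MODEL_IDS:
        raise ModelError(f"unknown model {model_id!r}")
    family = _ModelFamily(model_id, n_classes_m3)
    int_matrix = alignment.integer_matrix()
    pi = codon_frequencies(int_matrix, freq_scheme)
    work_tree = tree.copy()
    engine = PruningEngine(int_matrix, list(alignment.labels), work_tree)
    edges = work_tree.edges()
    n_edges = len(edges)
    optimize_bl = branch_mode == "optimize"
    fixed_bl = _initial_branch_lengths(work_tree)

    def unpack(x: np.ndarray):
        kappa = float(np.exp(x[0]))
        if optimize_bl:
            bl = np.exp(x[1 : 1 + n_edges])
            theta = x[1 + n_edges :]
        else:
            bl = fixed_bl
            theta = x[1:]
        return kappa, bl, theta

    def neg_lnl(x: np.ndarray) -> float:
        kappa, bl, theta = unpack(x)
        props, omegas, _ = family.classes(theta)
        lengths = {id(e): t for e, t in zip(edges, bl)}
        class_ll = engine.class_log_likelihoods(kappa, omegas, pi, lengths, props)
        return -engine.mixture_lnl(props, class_ll)

    base = [np.log(2.0)]
    bounds = [_KAPPA_BOUNDS]
    if optimize_bl:
        base += list(np.log(fixed_bl))
        bounds += [_BL_BOUNDS] * n_edges
    theta0 = family.default_init() if init_theta is None else np.asarray(init_theta, float)
    base = np.concatenate([base, theta0])
    bounds += family.bounds()
    base = np.clip(base, [b[0] for b in bounds], [b[1] for b in bounds])

    rng = np.random.default_rng(seed)
    best = None
    starts = max(1, n_restarts)
    for r in range(starts):
        x0 = base if r == 0 else np.clip(
            base + rng.normal(0.0, 0.5, size=base.shape),
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        res = optimize.minimize(
            neg_lnl,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res

    kappa, bl, theta = unpack(best.x)
    props, omegas, named = family.classes(theta)
    lengths = {id(e): t for e, t in zip(edges, bl)}
    class_ll = engine.class_log_likelihoods(kappa, omegas, pi, lengths, props)
    lnl = engine.mixture_lnl(props, class_ll)
    post = engine.posterior(props, class_ll)
    neb = post @ omegas
    for e, t in zip(edges, bl):
        e.length = float(t)
    return SiteModelFit(
        model_id=model_id,
        lnl=lnl,
        kappa=kappa,
        parameters=named,
        proportions=props,
        omegas=omegas,
        branch_lengths=[float(t) for t in bl],
        tree_newick=work_tree.to_newick(),
        pi=pi,
        posteriors=post,
        neb_omega=neb,
        freq_scheme=freq_scheme,
        converged=bool(best.success),
        n_restarts=starts,
        seed=seed,
    )


_NESTED_INIT = {
    ("M1a", "M2a"): lambda f: np.array(
        [
            _logit(f.parameters["p0"] * (1 - 1e-4)),
            _logit(1.0 - 1e-4),  # p2 ~ 0
            _logit(f.parameters["omega0"]),
            np.log(1.0),
        ]
    ),
    ("M7", "M8"): lambda f: np.array(
        [
            np.log(f.parameters["p"]),
            np.log(f.parameters["q"]),
            _logit(1.0 - 1e-4),  # p10 ~ 0
            np.log(1.0),
        ]
    ),
    ("M0", "M3"): lambda f: np.concatenate(
        [
            np.zeros(2),
            np.log(
                np.maximum(
                    np.array([0.5, 1.0, 2.0]) * f.parameters["omega"], 1e-4
                )
            ),
        ]
    ),
}


def fit_nested_pair(
    alignment,
    tree: Tree,
    null_id: str,
    alt_id: str,
    df: int,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[SiteModelFit, SiteModelFit, LRTResult]:
    """Fit a nested model pair and run the LRT.

    The alternative is additionally started from the null's MLE (embedded in
    the larger family), which guarantees lnL_alt >= lnL_null up to optimizer
    tolerance.
    """
    null_fit = fit_model(alignment, tree, null_id, **fit_kwargs)
    alt_fit = fit_model(alignment, tree, alt_id, **fit_kwargs)
    embed = _NESTED_INIT.get((null_id, alt_id))
    if embed is not None:
        seeded = fit_model(
            alignment,
            tree,
            alt_id,
            **{**fit_kwargs, "n_restarts": 1, "init_theta": embed(null_fit)},
        )
        if seeded.lnl > alt_fit.lnl:
            alt_fit = seeded
    if alt_fit.lnl < null_fit.lnl - 1e-4 and embed is not None:
        # optimizer failure on the larger family: restart from the embedded
        # null MLE at tighter tolerance
        retry = fit_model(
            alignment,
            tree,
            alt_id,
            **{
                **fit_kwargs,
                "n_restarts": 1,
                "init_theta": embed(null_fit),
                "tol": 1e-10,
            },
        )
        if retry.lnl > alt_fit.lnl:
            alt_fit = retry
    # nested models: the alternative can always reproduce the null, so any
    # residual deficit is optimizer noise and the LRT statistic floors at 0
    lnl_alt = max(alt_fit.lnl, null_fit.lnl)
    lrt = likelihood_ratio_test(
        null_fit.lnl, lnl_alt, df=df, alpha=alpha, null_model=null_id, alt_model=alt_id
    )
    return null_fit, alt_fit, lrt


def fixed_sites_fit(
    alignment,
    tree: Tree,
    key_columns: list[int],
    freq_scheme: str = "F3x4",
    branch_mode: str = "optimize",
    df: int = 1,
    alpha: float = 0.05,
    n_restarts: int = 2,
    seed: int = 0,
) -> tuple[SiteModelFit, SiteModelFit, LRTResult]:
    """Fixed-sites models A (one omega) and B (partition-specific omega).

    The partition is key columns (1-based) vs the rest; kappa and branch
    lengths are shared between partitions. Model A is the M0 fit; model B
    gives each partition its own omega. df defaults to 1 (one extra omega).
    """
    if not key_columns:
        raise ModelError("empty key partition")
    L = alignment.column_count
    key_idx = sorted(set(int(c) - 1 for c in key_columns))
    if any(i < 0 or i >= L for i in key_idx):
        raise ModelError("key columns outside alignment")
    rest_idx = [j for j in range(L) if j not in set(key_idx)]
    if not rest_idx:
        raise ModelError("empty non-key partition")

    fit_a = fit_model(
        alignment,
        tree,
        "M0",
        freq_scheme=freq_scheme,
        branch_mode=branch_mode,
        n_restarts=n_restarts,
        seed=seed,
    )

    int_matrix = alignment.integer_matrix()
    pi = codon_frequencies(int_matrix, freq_scheme)
    work_tree = tree.copy()
    engine = PruningEngine(int_matrix, list(alignment.labels), work_tree)
    edges = work_tree.edges()
    n_edges = len(edges)
    optimize_bl = branch_mode == "optimize"
    fixed_bl = _initial_branch_lengths(work_tree)
    key_cols = np.zeros(L, dtype=bool)
    key_cols[key_idx] = True
    pattern_key_weight = np.zeros(engine.n_patterns)
    pattern_rest_weight = np.zeros(engine.n_patterns)
    for col, pat in enumerate(engine.pattern_index):
        if key_cols[col]:
            pattern_key_weight[pat] += 1.0
        else:
            pattern_rest_weight[pat] += 1.0

    def unpack(x):
        kappa = float(np.exp(x[0]))
        if optimize_bl:
            bl = np.exp(x[1 : 1 + n_edges])
            wk, wr = np.exp(x[1 + n_edges :])
        else:
            bl = fixed_bl
            wk, wr = np.exp(x[1:])
        return kappa, bl, wk, wr

    part_props = np.array([len(key_idx) / L, len(rest_idx) / L])

    def neg_lnl(x):
        kappa, bl, wk, wr = unpack(x)
        lengths = {id(e): t for e, t in zip(edges, bl)}
        ll = engine.class_log_likelihoods(
            kappa, np.array([wk, wr]), pi, lengths, part_props
        )
        return -float(pattern_key_weight @ ll[0] + pattern_rest_weight @ ll[1])

    w0 = max(fit_a.parameters["omega"], 1e-3)
    base = [np.log(fit_a.kappa)]
    bounds = [_KAPPA_BOUNDS]
    if optimize_bl:
        base += [np.log(max(t, 1e-5)) for t in fit_a.branch_lengths]
        bounds += [_BL_BOUNDS] * n_edges
    base += [np.log(w0), np.log(w0)]
    bounds += [(np.log(1e-4), np.log(50.0))] * 2
    base = np.clip(np.array(base), [b[0] for b in bounds], [b[1] for b in bounds])

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        x0 = base if r == 0 else np.clip(
            base + rng.normal(0, 0.4, size=base.shape),
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        res = optimize.minimize(
            neg_lnl, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 500}
        )
        if best is None or res.fun < best.fun:
            best = res

    kappa, bl, wk, wr = unpack(best.x)
    lnl_b = -best.fun
    lengths = {id(e): t for e, t in zip(edges, bl)}
    ll = engine.class_log_likelihoods(kappa, np.array([wk, wr]), pi, lengths, part_props)
    # per-column "posterior" is degenerate: the partition assignment is fixed
    post = np.zeros((L, 2))
    post[key_cols, 0] = 1.0
    post[~key_cols, 1] = 1.0
    neb = np.where(key_cols, wk, wr)
    for e, t in zip(edges, bl):
        e.length = float(t)
    fit_b = SiteModelFit(
        model_id="FS-B",
        lnl=lnl_b,
        kappa=kappa,
        parameters={"omega_key": float(wk), "omega_rest": float(wr)},
        proportions=np.array(
            [len(key_idx) / L, len(rest_idx) / L]
        ),
        omegas=np.array([wk, wr]),
        branch_lengths=[float(t) for t in bl],
        tree_newick=work_tree.to_newick(),
        pi=pi,
        posteriors=post,
        neb_omega=neb,
        freq_scheme=freq_scheme,
        converged=bool(best.success),
        n_restarts=max(1, n_restarts),
        seed=seed,
        partition_omegas={"key": float(wk), "rest": float(wr)},
    )
    lnl_b_adj = max(lnl_b, fit_a.lnl)
    lrt = likelihood_ratio_test(
        fit_a.lnl, lnl_b_adj, df=df, alpha=alpha, null_model="FS-A", alt_model="FS-B"
    )
    fit_a.model_id = "FS-A"
    return fit_a, fit_b, lrt


# ---------------------------------------------------------------------------
# NEB reporting


def neb_site_report(
    fit: SiteModelFit,
    position_map=None,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Per-column NEB table: P(omega > 1), posterior-mean omega, and call.

    Standard per-site report layout (MSA index, BW index, key
    flag, posterior probability of positive selection, NEB omega); columns
    whose P(omega > 1) exceeds ``threshold`` are called "Positive".
    """
    p_pos = fit.posterior_positive()
    L = len(fit.neb_omega)
    rows = []
    key_set = set(position_map.key_columns) if position_map is not None else set()
    for col in range(1, L + 1):
        bw = position_map.bw_label(col) if position_map is not None else None
        call = "Positive" if p_pos[col - 1] > threshold else "-"
        rows.append(
            {
                "column_index": col,
                "bw_index": bw if bw else "",
                "is_key": col in key_set,
                "p_positive": float(p_pos[col - 1]),
                "neb_omega": float(fit.neb_omega[col - 1]),
                "call": call,
            }
        )
    return pd.DataFrame(rows)
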