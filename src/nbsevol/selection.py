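"""Codon site models of positive selection: M0 (one omega), M7 (beta) and
M8 (beta & omega), the M7-vs-M8 likelihood-ratio test, and empirical-Bayes
identification of positively selected sites.

The substitution process is a GY94-style Markov model over the 61 sense
codons (transition/transversion ratio kappa, nonsynonymous/synonymous rate
ratio omega, stationary codon frequencies pi).  Site likelihoods come from
Felsenstein pruning with per-node numerical rescaling; site-class models
average the site likelihood over K = 10 equal-probability beta categories
(category medians, plus the extra omega_s >= 1 class for M8).

Fitting holds branch lengths fixed at their M0 estimates (a standard
runtime approximation to joint optimization) and maximizes the model
parameters by bounded derivative-free search with seeded random restarts.
Site posteriors are NEB — posteriors at the MLEs, without integrating over
parameter uncertainty.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from ._codon import (
    N_CODONS,
    decompose_rate_matrix,
    encode_codons,
    f3x4_frequencies,
    probabilities_from_decomposition,
    rate_matrix,
    uniform_codon_frequencies,
)
from .phylo import Node, PhyloTree

K_CATEGORIES = 10


@dataclass
class CodonModelParams:
    """Parameters of one site model.

    M0: ``omega``.  M7: beta shapes ``p, q`` (omega in (0,1)).  M8: beta
    shapes plus ``p0`` (beta-class weight) and ``omega_s >= 1``.
    """

    model: str                         # "M0" | "M7" | "M8"
    kappa: float
    pi: np.ndarray
    omega: float | None = None         # M0
    p: float | None = None             # M7/M8 beta shape
    q: float | None = None
    p0: float | None = None            # M8 weight of the beta component
    omega_s: float | None = None       # M8 positive-selection omega
    k_categories: int = K_CATEGORIES

    def site_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(omega values, weights) of the discretized site classes."""
        if self.model == "M0":
            return np.array([self.omega]), np.array([1.0])
        quantiles = (np.arange(self.k_categories) + 0.5) / self.k_categories
        betas = stats.beta.ppf(quantiles, self.p, self.q)
        betas = np.clip(betas, 1e-8, 1.0 - 1e-8)
        if self.model == "M7":
            w = np.full(self.k_categories, 1.0 / self.k_categories)
            return betas, w
        if self.model == "M8":
            w = np.full(self.k_categories, self.p0 / self.k_categories)
            return (np.append(betas, self.omega_s),
                    np.append(w, 1.0 - self.p0))
        raise ValueError(f"unknown model {self.model!r}")


@dataclass
class SiteModelFit:
    model: str
    params: CodonModelParams
    lnl: float
    site_lnl: np.ndarray
    branch_lengths: dict[str, float]
    converged: bool
    data_fingerprint: str
    # per-site, per-class likelihoods at the MLEs (classes x sites), plus
    # class weights — retained for empirical-Bayes posteriors
    class_site_likelihood: np.ndarray | None = None
    class_weights: np.ndarray | None = None


@dataclass
class LRTResult:
    """Likelihood-ratio test of M8 against M7 (df = 2)."""

    two_delta_lnl: float
    df: int
    significance: str          # "ns" | "*" | "**"
    crit_05: float
    crit_01: float


@dataclass
class SiteClassPosterior:
    """Per-site posterior that omega > 1 under the fitted M8 model."""

    prob_positive: np.ndarray
    class_posteriors: np.ndarray       # sites x classes
    flags: list[str]                   # "" | "*" (>= 0.95) | "**" (>= 0.99)


def chi2_critical(alpha: float, df: int = 2) -> float:
    """Upper-tail chi-square critical value (for df=2 this is -2 ln alpha)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.chi2.isf(alpha, df))


# --- alignment/tree plumbing --------------------------------------------------

def _prepare_alignment(ids: Sequence[str], rows: Sequence[str]) -> np.ndarray:
    """Codon-index matrix (taxa x sites) after dropping gapped codon columns."""
    ncol = len(rows[0]) // 3
    cols = []
    encoded = []
    for row in rows:
        if len(row) != len(rows[0]):
            raise ValueError("alignment rows differ in length")
    for c in range(ncol):
        codons = [row[3 * c:3 * c + 3] for row in rows]
        if any("-" in cd for cd in codons):
            continue
        cols.append([encode_codons(cd)[0] for cd in codons])
    if not cols:
        raise ValueError("no gap-free codon columns to analyze")
    return np.array(cols, dtype=np.int64).T


def _tree_edges(tree: PhyloTree) -> tuple[list[tuple[int, int, str | None]], int, dict[str, int]]:
    """Post-order edge list (child_idx, parent_idx, leaf_label)."""
    nodes: list[Node] = []

    def collect(node: Node) -> int:
        for c in node.children:
            collect(c)
        nodes.append(node)
        return len(nodes) - 1

    collect(tree.root)
    index = {id(n): i for i, n in enumerate(nodes)}
    edges = []
    leaf_index: dict[str, int] = {}
    for n in nodes:
        i = index[id(n)]
        if n.is_leaf:
            leaf_index[n.label] = i
        for c in n.children:
            edges.append((index[id(c)], i, c.label if c.is_leaf else None))
    # order edges child-first (post-order by child index)
    edges.sort(key=lambda e: e[0])
    return edges, index[id(tree.root)], leaf_index


class _Pruner:
    """Felsenstein pruning over 61 codon states with per-node rescaling."""

    def __init__(self, tree: PhyloTree, data: np.ndarray, ids: Sequence[str],
                 pi: np.ndarray):
        self.edges, self.root, leaf_index = _tree_edges(tree)
        self.n_nodes = max(max(c, p) for c, p, _ in self.edges) + 1
        self.pi = pi
        self.n_sites = data.shape[1]
        missing = [i for i in ids if i not in leaf_index]
        if missing:
            raise ValueError(f"tree lacks leaves for: {missing}")
        self.leaf_states = {leaf_index[gid]: data[k] for k, gid in enumerate(ids)}
        self.children: dict[int, list[int]] = {}
        self.parent_of: dict[int, int] = {}
        for child, parent, _ in self.edges:
            self.children.setdefault(parent, []).append(child)
            self.parent_of[child] = parent

    def site_likelihoods(self, pmats: Mapping[int, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """(site likelihoods, log scale factors) for one set of edge P(t)."""
        partial = np.empty((self.n_nodes, N_CODONS, self.n_sites))
        log_scale = np.zeros(self.n_sites)
        order = sorted(self.children)  # parents appear after children (post-order ids)
        for node in range(self.n_nodes):
            if node in self.leaf_states:
                part = np.zeros((N_CODONS, self.n_sites))
                part[self.leaf_states[node], np.arange(self.n_sites)] = 1.0
                partial[node] = part
        for parent in order:
            acc = np.ones((N_CODONS, self.n_sites))
            for child in self.children[parent]:
                acc *= pmats[child] @ partial[child]
            mx = acc.max(axis=0)
            mx = np.where(mx > 0, mx, 1.0)
            log_scale += np.log(mx)
            partial[parent] = acc / mx
        site_l = self.pi @ partial[self.root]
        return site_l, log_scale


def _branch_vector(tree: PhyloTree) -> list[tuple[int, float]]:
    edges, _, _ = _tree_edges(tree)
    nodes: list[Node] = []

    def collect(node: Node) -> None:
        for c in node.children:
            collect(c)
        nodes.append(node)

    collect(tree.root)
    return [(i, nodes[i].length) for i, _, _ in edges]


def _fingerprint(ids: Sequence[str], data: np.ndarray, tree_newick: str) -> str:
    h = hashlib.sha256()
    h.update("|".join(ids).encode())
    h.update(data.tobytes())
    h.update(tree_newick.encode())
    return h.hexdigest()[:16]


# --- likelihood -------------------------------------------------------------

def _class_site_likelihoods(pruner: _Pruner, params: CodonModelParams,
                            branch_lengths: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class site likelihoods with a shared log-scale per class."""
    omegas, weights = params.site_classes()
    per_class = np.empty((len(omegas), pruner.n_sites))
    scales = np.empty((len(omegas), pruner.n_sites))
    for k, w in enumerate(omegas):
        q = rate_matrix(params.kappa, float(w), params.pi)
        evals, u, uinv = decompose_rate_matrix(q, params.pi)
        pmats = {child: probabilities_from_decomposition(evals, u, uinv, branch_lengths[child])
                 for child, _, _ in pruner.edges}
        site_l, log_scale = pruner.site_likelihoods(pmats)
        per_class[k] = site_l
        scales[k] = log_scale
    return per_class, scales, weights


def _total_lnl(per_class: np.ndarray, scales: np.ndarray, weights: np.ndarray) -> tuple[float, np.ndarray]:
    # log sum_k w_k * L_k * exp(scale_k), stably per site
    with np.errstate(divide="ignore"):
        log_terms = np.log(np.maximum(per_class, 1e-300)) + scales + \
            np.log(weights[:, None])
    mx = log_terms.max(axis=0)
    site_lnl = mx + np.log(np.exp(log_terms - mx).sum(axis=0))
    return float(site_lnl.sum()), site_lnl


def site_likelihood(alignment: tuple[Sequence[str], Sequence[str]], tree: PhyloTree,
                    params: CodonModelParams,
                    branch_lengths: Mapping[str, float] | None = None) -> tuple[float, np.ndarray]:
    """Total and per-site log-likelihood of a codon alignment on a tree.

    ``alignment`` is (ids, aligned codon rows); gapped codon columns are
    dropped.  Branch lengths default to those stored on the tree; an explicit
    mapping (by edge child index) overrides them.
    """
    ids, rows = alignment
    data = _prepare_alignment(ids, rows)
    pruner = _Pruner(tree, data, ids, params.pi)
    if branch_lengths is None:
        bl = dict(_branch_vector(tree))
    else:
        bl = dict(branch_lengths)
    per_class, scales, weights = _class_site_likelihoods(pruner, params, bl)
    return _total_lnl(per_class, scales, weights)


# --- fitting ------------------------------------------------------------------

_BOUNDS = {
    "kappa": (0.2, 20.0),
    "omega": (1e-4, 10.0),
    "p": (0.05, 50.0),
    "q": (0.05, 50.0),
    "p0": (1e-6, 1.0),
    "omega_s": (1.0, 20.0),
    "branch": (1e-8, 30.0),
}


def _fit_m0(pruner: _Pruner, pi: np.ndarray, init_bl: Sequence[tuple[int, float]],
            seed: int) -> tuple[float, float, float, dict[int, float], bool]:
    """Joint M0 fit of kappa, omega and branch lengths."""
    edge_ids = [e for e, _ in init_bl]
    x0 = np.array([2.0, 0.3] + [max(l, 0.01) for _, l in init_bl])
    lb = np.array([_BOUNDS["kappa"][0], _BOUNDS["omega"][0]] +
                  [_BOUNDS["branch"][0]] * len(edge_ids))
    ub = np.array([_BOUNDS["kappa"][1], _BOUNDS["omega"][1]] +
                  [_BOUNDS["branch"][1]] * len(edge_ids))

    def neg(x: np.ndarray) -> float:
        kappa, omega = x[0], x[1]
        bl = dict(zip(edge_ids, x[2:]))
        params = CodonModelParams(model="M0", kappa=kappa, omega=omega, pi=pi)
        per_class, scales, weights = _class_site_likelihoods(pruner, params, bl)
        lnl, _ = _total_lnl(per_class, scales, weights)
        return -lnl

    res = optimize.minimize(neg, x0, method="Powell",
                            bounds=list(zip(lb, ub)),
                            options={"ftol": 1e-6, "maxiter": 20000})
    kappa, omega = float(res.x[0]), float(res.x[1])
    bl = {e: float(v) for e, v in zip(edge_ids, res.x[2:])}
    return kappa, omega, -float(res.fun), bl, bool(res.success)


def _nj_codon_start(tree: PhyloTree) -> list[tuple[int, float]]:
    bl = _branch_vector(tree)
    return [(e, max(l, 0.01)) for e, l in bl]


def fit_model(alignment: tuple[Sequence[str], Sequence[str]], tree: PhyloTree,
              model: str, *, seed: int = 0, restarts: int = 3,
              k_categories: int = K_CATEGORIES,
              frequencies: str = "f3x4",
              m0_fit: SiteModelFit | None = None,
              init: Mapping[str, float] | None = None) -> SiteModelFit:
    """Fit a codon site model (M0, M7 or M8) to a family alignment.

    Branch lengths and kappa are estimated under M0 and held fixed for the
    site-class models; M7/M8 parameters are maximized by bounded Powell
    search from ``restarts`` seeded random starting points (convergence
    tolerance 1e-6 in lnL).  ``init`` adds one extra starting point — used
    to seed M8 from a fitted M7 so the nesting lnL(M8) >= lnL(M7) holds by
    construction.
    """
    ids, rows = alignment
    if len(ids) < 3:
        raise ValueError("site-model fitting requires at least 3 sequences")
    data = _prepare_alignment(ids, rows)
    if frequencies == "f3x4":
        counts = np.bincount(data.ravel(), minlength=N_CODONS).astype(float)
        pi = f3x4_frequencies(counts)
    elif frequencies == "equal":
        pi = uniform_codon_frequencies()
    else:
        raise ValueError(f"unknown frequency model {frequencies!r}")
    pruner = _Pruner(tree, data, ids, pi)
    fingerprint = _fingerprint(ids, data, tree.newick(with_support=False))
    identical = bool((data == data[0]).all())

    if m0_fit is not None and m0_fit.model == "M0":
        kappa = m0_fit.params.kappa
        branch_lengths = {int(k): v for k, v in m0_fit.branch_lengths.items()}
        m0 = m0_fit
    else:
        kappa, omega0, lnl0, branch_lengths, ok = _fit_m0(
            pruner, pi, _nj_codon_start(tree), seed)
        params0 = CodonModelParams(model="M0", kappa=kappa, omega=omega0, pi=pi)
        per_class, scales, weights = _class_site_likelihoods(pruner, params0, branch_lengths)
        lnl0, site_lnl0 = _total_lnl(per_class, scales, weights)
        m0 = SiteModelFit(model="M0", params=params0, lnl=lnl0, site_lnl=site_lnl0,
                          branch_lengths={str(k): v for k, v in branch_lengths.items()},
                          converged=ok and not identical, data_fingerprint=fingerprint,
                          class_site_likelihood=per_class, class_weights=weights)
    if model == "M0":
        return m0

    rng = np.random.default_rng(seed)
    if model == "M7":
        names = ["p", "q"]
    elif model == "M8":
        names = ["p", "q", "p0", "omega_s"]
    else:
        raise ValueError(f"unknown model {model!r}")
    bounds = [_BOUNDS[n] for n in names]

    def neg(x: np.ndarray) -> float:
        kw = dict(zip(names, x))
        params = CodonModelParams(model=model, kappa=kappa, pi=pi,
                                  k_categories=k_categories, **kw)
        per_class, scales, weights = _class_site_likelihoods(
            pruner, params, branch_lengths)
        lnl, _ = _total_lnl(per_class, scales, weights)
        return -lnl

    starts = []
    if init is not None:
        starts.append(np.array([init[n] for n in names]))
    base = {"p": 0.5, "q": 1.5, "p0": 0.9, "omega_s": 2.0}
    starts.append(np.array([base[n] for n in names]))
    while len(starts) < restarts + (init is not None):
        starts.append(np.array([
            rng.uniform(max(lo, 0.1), min(hi, 5.0)) for (lo, hi) in bounds]))

    # bounded Powell is not strictly monotone: its final point can be a hair
    # worse than the start, so every start is also kept as a candidate —
    # this preserves lnL(M8) >= lnL(M7) exactly when seeded at the embedding
    best_x, best_fun, success = None, np.inf, False
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        f0 = neg(x0)
        if f0 < best_fun:
            best_x, best_fun = x0, f0
        res = optimize.minimize(neg, x0, method="Powell", bounds=bounds,
                                options={"ftol": 1e-6, "maxiter": 20000})
        if res.fun < best_fun:
            best_x, best_fun = res.x, res.fun
        success = success or bool(res.success)
    kw = dict(zip(names, (float(v) for v in best_x)))
    params = CodonModelParams(model=model, kappa=kappa, pi=pi,
                              k_categories=k_categories, **kw)
    per_class, scales, weights = _class_site_likelihoods(pruner, params, branch_lengths)
    lnl, site_lnl = _total_lnl(per_class, scales, weights)
    # keep scaled class likelihoods for NEB posteriors
    log_class = np.log(np.maximum(per_class, 1e-300)) + scales
    return SiteModelFit(model=model, params=params, lnl=lnl, site_lnl=site_lnl,
                        branch_lengths={str(k): v for k, v in branch_lengths.items()},
                        converged=success and not identical,
                        data_fingerprint=fingerprint,
                        class_site_likelihood=log_class, class_weights=weights)


def lrt_m7_m8(fit7: SiteModelFit, fit8: SiteModelFit, tolerance: float = 1e-4) -> LRTResult:
    """2(lnL_M8 - lnL_M7) against chi-square critical values (df = 2)."""
    if fit7.model != "M7" or fit8.model != "M8":
        raise ValueError("expected an M7 fit and an M8 fit")
    if fit7.data_fingerprint != fit8.data_fingerprint:
        raise ValueError("fits come from different data or trees")
    two_delta = 2.0 * (fit8.lnl - fit7.lnl)
    if two_delta < -tolerance:
        raise ValueError(f"lnL(M8) < lnL(M7) by more than tolerance: {two_delta}")
    two_delta = max(two_delta, 0.0)
    crit_05 = chi2_critical(0.05, 2)
    crit_01 = chi2_critical(0.01, 2)
    if two_delta > crit_01:
        sig = "**"
    elif two_delta > crit_05:
        sig = "*"
    else:
        sig = "ns"
    return LRTResult(two_delta_lnl=two_delta, df=2, significance=sig,
                     crit_05=crit_05, crit_01=crit_01)


def positive_sites(fit8: SiteModelFit) -> SiteClassPosterior:
    """Empirical-Bayes site posteriors of the positive-selection class.

    P(class k | site) is proportional to weight_k * L(site | omega_k) at the
    M8 MLEs; P(omega > 1) is the posterior mass of the omega_s class.  Flags:
    '*' at >= 0.95, '**' at >= 0.99.
    """
    if fit8.model != "M8":
        raise ValueError("positive_sites requires an M8 fit")
    log_class = fit8.class_site_likelihood          # classes x sites (log)
    weights = fit8.class_weights
    log_post = log_class + np.log(np.maximum(weights, 1e-300))[:, None]
    mx = log_post.max(axis=0)
    post = np.exp(log_post - mx)
    post /= post.sum(axis=0)
    omegas, _ = fit8.params.site_classes()
    positive_mass = post[omegas > 1.0 - 1e-12].sum(axis=0)
    flags = ["**" if p >= 0.99 else "*" if p >= 0.95 else "" for p in positive_mass]
    return SiteClassPosterior(prob_positive=positive_mass,
                              class_posteriors=post.T, flags=flags)
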