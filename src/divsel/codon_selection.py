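"""Branch-site codon models with population-specific foreground branches.

The selection machinery at the heart of the package. A Goldman-Yang style
codon substitution process over the 61 sense codons is combined into the
branch-site mixture ("modified model A"): four site classes

* class 0  (weight p0):            omega0 <= 1 on every branch,
* class 1  (weight p1):            omega1 = 1 on every branch,
* class 2a (weight p2*p0/(p0+p1)): omega0 on background, omega2 on foreground,
* class 2b (weight p2*p1/(p0+p1)): omega1 on background, omega2 on foreground,

with p2 = 1 - p0 - p1. Foreground branches are defined by sampling
population: every terminal branch leading to an allele from the focal
population, plus every internal branch whose descendant tips all come from
that population. The test of positive selection compares the alternative
model (omega2 estimated, >= 1) against the null (omega2 = 1) with a
chi-square(1) likelihood-ratio test; positively selected codons are then
located with a Bayes-empirical-Bayes average of site-class posteriors over a
grid prior on (p0, p1, omega0, omega2).

Codons with a gap or N at a tip are treated as fully missing at that tip
(all-ones partial likelihood), so indel-adjacent codons still contribute
signal from the alleles that carry them -- the likelihood-level analogue of
pairwise deletion.

Likelihoods use Felsenstein pruning over the 61-state space with per-node
rescaling; transition matrices come from a spectral decomposition of the
reversible generator, so P(t) for all branches of a class costs one
symmetric eigendecomposition plus cheap per-branch reconstructions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2 as chi2_dist

from .alleles_qc import BASES

# ---------------------------------------------------------------------------
# Genetic code machinery (standard nuclear code, 61 sense codons)
# ---------------------------------------------------------------------------

def _standard_code() -> tuple[list[str], dict[str, str], set[str]]:
    from Bio.Data.CodonTable import standard_dna_table as t

    stops = set(t.stop_codons)
    codons = sorted(c for c in t.forward_table)
    return codons, dict(t.forward_table), stops


CODONS, _AA_OF, STOP_CODONS = _standard_code()
N_STATES = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO_ACIDS = np.array([_AA_OF[c] for c in CODONS])

_NUC_INDEX = {b: i for i, b in enumerate(BASES)}
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


def _pair_structure():
    """Arrays describing single-nucleotide codon pairs (i, j, ts?, syn?)."""
    ii, jj, ts, syn = [], [], [], []
    for i, a in enumerate(CODONS):
        for j, b in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            x, y = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append(frozenset((x, y)) in _TRANSITION_PAIRS)
            syn.append(AMINO_ACIDS[i] == AMINO_ACIDS[j])
    return (np.array(ii), np.array(jj), np.array(ts, bool), np.array(syn, bool))


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_SYN = _pair_structure()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CodonModelParams:
    kappa: float
    codon_freqs: np.ndarray
    p0: float
    p1: float
    omega0: float
    omega2: float = 1.0  # fixed to 1 in the null model

    def validate(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if abs(float(np.sum(self.codon_freqs)) - 1.0) > 1e-8:
            raise ValueError("codon frequencies must sum to 1")
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1 and self.p0 + self.p1 <= 1 + 1e-12):
            raise ValueError("invalid site-class proportions")
        if not (0 < self.omega0 <= 1):
            raise ValueError("omega0 must be in (0, 1]")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")

    @property
    def p2(self) -> float:
        return max(0.0, 1.0 - self.p0 - self.p1)

    def class_weights(self) -> np.ndarray:
        """Weights of classes (0, 1, 2a, 2b); p2 split in ratio p0:p1."""
        p01 = self.p0 + self.p1
        if p01 <= 0:
            return np.array([0.0, 0.0, 0.5 * self.p2, 0.5 * self.p2])
        return np.array(
            [
                self.p0,
                self.p1,
                self.p2 * self.p0 / p01,
                self.p2 * self.p1 / p01,
            ]
        )


@dataclass
class LrtResult:
    two_delta_lnl: float
    df: int
    p_value: float


@dataclass
class BranchSiteFit:
    params: CodonModelParams
    lnL: float
    n_restarts: int
    converged: bool
    site_posteriors: np.ndarray | None  # naive EB P(class in {2a,2b}) per codon
    model: str  # "null" or "alt"
    scale: float = 1.0
    restart_lnls: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def build_codon_rate_matrix(
    kappa: float,
    omega: float,
    codon_freqs: np.ndarray,
    normalization: Literal["neutral", "self"] = "neutral",
) -> np.ndarray:
    """Goldman-Yang generator on 61 sense codons.

    q_ij for single-nucleotide codon pairs is pi_j times kappa for a
    transition and times omega for a nonsynonymous change; rows sum to zero.

    ``normalization="neutral"`` (default) divides by the stationary rate of
    the neutral (omega = 1) matrix with the same kappa and frequencies, so
    the *relative* rates of site classes with different omega are preserved
    -- a class with omega > 1 really does accumulate more substitutions per
    unit branch length. Branch lengths are then expected substitutions per
    codon for a neutral site (any constant factor is absorbed by the joint
    branch-length scale). ``"self"`` normalizes each matrix to unit rate at
    its own omega, which equalizes rates across classes and leaves only the
    synonymous/nonsynonymous composition as signal.
    """
    pi = np.asarray(codon_freqs, float)
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("codon frequencies must sum to 1 (tol 1e-8)")
    q = np.zeros((N_STATES, N_STATES))
    ts_fac = np.where(_PAIR_TS, kappa, 1.0)
    rates = pi[_PAIR_J] * ts_fac * np.where(_PAIR_SYN, 1.0, omega)
    q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalization == "self":
        mean_rate = -float(pi @ np.diag(q))
    else:
        # stationary rate of the omega = 1 matrix: sum_i pi_i sum_{j!=i} q1_ij
        mean_rate = float((pi[_PAIR_I] * pi[_PAIR_J] * ts_fac).sum())
    if mean_rate > 0:
        q /= mean_rate
    return q


def transition_probs(q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a generator matrix; rows sum to 1."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return expm(q * t)


class _SpectralModel:
    """Reversible codon model with eigendecomposition-based P(t)."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        self.pi = np.asarray(pi, float)
        q = build_codon_rate_matrix(kappa, omega, self.pi)
        d = np.sqrt(self.pi)
        sym = (q * d[:, None]) / d[None, :]
        sym = 0.5 * (sym + sym.T)  # enforce exact symmetry
        lam, v = np.linalg.eigh(sym)
        self.lam = lam
        self._left = v / d[:, None]       # D^-1 V
        self._right = (v * d[:, None]).T  # V^T D

    def p_matrix(self, t: float) -> np.ndarray:
        p = (self._left * np.exp(self.lam * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        return p

    def p_matrices(self, ts: np.ndarray) -> np.ndarray:
        e = np.exp(np.outer(ts, self.lam))  # (B, 61)
        # (B, 61, 61) scaled eigenvectors, folded into one (B*61, 61) GEMM
        scaled = self._left[None, :, :] * e[:, None, :]
        p = scaled.reshape(-1, e.shape[1]) @ self._right
        p = p.reshape(len(ts), e.shape[1], e.shape[1])
        np.clip(p, 0.0, None, out=p)
        return p


def f3x4_frequencies(seqs: Iterable[str], floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies from positional nucleotide counts.

    Counts nucleotides by codon position over codons free of gaps and Ns,
    floors each positional frequency, and renormalizes the resulting product
    over the 61 sense codons.
    """
    counts = np.zeros((3, 4))
    for s in seqs:
        for k in range(0, len(s) - 2, 3):
            codon = s[k : k + 3]
            if all(c in BASES for c in codon):
                for pos, c in enumerate(codon):
                    counts[pos, _NUC_INDEX[c]] += 1
    if counts.sum() == 0:
        pos_freqs = np.full((3, 4), 0.25)
    else:
        pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    pos_freqs = np.maximum(pos_freqs, floor)
    pos_freqs /= pos_freqs.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freqs[0, _NUC_INDEX[c[0]]]
            * pos_freqs[1, _NUC_INDEX[c[1]]]
            * pos_freqs[2, _NUC_INDEX[c[2]]]
            for c in CODONS
        ]
    )
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Foreground labeling
# ---------------------------------------------------------------------------

@dataclass
class LabeledTree:
    """Rooted gene tree with per-branch foreground flags.

    Arrays are laid out for pruning: tips get indices 0..n_tips-1 in
    ``tip_names`` order, internal nodes follow in postorder (root last).
    ``children[k]`` lists (child_index, branch_length, is_foreground) for
    internal node ``n_tips + k``.
    """

    tip_names: list[str]
    children: list[list[tuple[int, float, bool]]]
    population: str
    tree: dendropy.Tree | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_branches(self) -> int:
        return sum(len(c) for c in self.children)

    def branch_list(self) -> list[tuple[int, float, bool]]:
        return [b for group in self.children for b in group]

    def total_length(self) -> float:
        return sum(t for _, t, _ in self.branch_list())

    def foreground_fraction(self) -> float:
        tot = self.total_length()
        fg = sum(t for _, t, f in self.branch_list() if f)
        return fg / tot if tot else 0.0


def label_foreground(
    tree: dendropy.Tree,
    meta: dict[str, tuple[str, str]],
    population: str,
) -> LabeledTree:
    """Flag foreground branches for a focal population.

    A branch is foreground iff it is a terminal branch to a tip sampled from
    the focal population, or an internal branch whose descendant tips all
    come from that population. The root has no branch and is never flagged.
    """
    tree = tree.clone(depth=1)
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else None
        if name is None or name not in meta:
            raise ValueError(f"tip {name!r} has no population metadata")

    tip_names: list[str] = []
    index_of: dict[int, int] = {}
    focal_only: dict[int, bool] = {}
    children: list[list[tuple[int, float, bool]]] = []

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            index_of[id(node)] = len(tip_names)
            focal_only[id(node)] = meta[name][1] == population
            tip_names.append(name)
    n_tips = len(tip_names)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        kids = []
        all_focal = True
        for child in node.child_nodes():
            fg = focal_only[id(child)]
            all_focal = all_focal and fg
            length = child.edge.length or 0.0
            if length < 0:
                raise ValueError("negative branch length")
            kids.append((index_of[id(child)], float(length), fg))
        index_of[id(node)] = n_tips + len(children)
        focal_only[id(node)] = all_focal
        children.append(kids)
    return LabeledTree(tip_names, children, population, tree)


def prune_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Drop an outgroup tip (used for rooting) before model fitting."""
    tree = tree.clone(depth=1)
    taxa = [t for t in tree.taxon_namespace if t.label == outgroup]
    if not taxa:
        raise ValueError(f"outgroup {outgroup!r} not found in tree")
    tree.prune_taxa(taxa)
    return tree


# ---------------------------------------------------------------------------
# Pruning likelihood engine
# ---------------------------------------------------------------------------

CLASS_NAMES = ("0", "1", "2a", "2b")


class BranchSitePruner:
    """Felsenstein pruning for the branch-site mixture on one alignment+tree.

    Site patterns are compressed; per-tip codons with any gap/N are fully
    missing. A fixed stop codon at an ungapped tip raises with the 1-based
    codon site index.
    """

    def __init__(
        self,
        seqs: dict[str, str],
        ltree: LabeledTree,
        codon_freqs: np.ndarray | None = None,
    ):
        tipset = set(ltree.tip_names)
        seqset = set(seqs)
        if tipset != seqset:
            missing = sorted(tipset - seqset)
            extra = sorted(seqset - tipset)
            raise ValueError(
                f"tree/alignment tip mismatch: missing from alignment {missing}, "
                f"not in tree {extra}"
            )
        length = len(next(iter(seqs.values())))
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} not divisible by 3")
        self.ltree = ltree
        self.n_sites = length // 3

        n_tips = ltree.n_tips
        codes = np.full((n_tips, self.n_sites), -1, dtype=np.int16)
        for ti, name in enumerate(ltree.tip_names):
            s = seqs[name].upper()
            for k in range(self.n_sites):
                codon = s[3 * k : 3 * k + 3]
                if all(c in BASES for c in codon):
                    if codon in STOP_CODONS:
                        raise ValueError(
                            f"stop codon {codon} at codon site {k + 1} in {name}"
                        )
                    codes[ti, k] = CODON_INDEX[codon]
        self.tip_codes = codes
        patterns, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_tips, S)
        self.pattern_of_site = inverse
        self.counts = counts.astype(float)
        self.S = patterns.shape[1]

        if codon_freqs is None:
            codon_freqs = f3x4_frequencies(seqs.values())
        self.pi = np.asarray(codon_freqs, float)

        self._tip_valid = [self.patterns[i] >= 0 for i in range(ltree.n_tips)]
        self._branches = ltree.branch_list()
        self._lens = np.array([t for _, t, _ in self._branches])
        self._fg = np.array([f for _, _, f in self._branches], bool)
        self._model_cache: dict[tuple[float, float], _SpectralModel] = {}
        self._class_cache: dict[tuple, np.ndarray] = {}

    # -- internals ----------------------------------------------------------

    def _model(self, kappa: float, omega: float) -> _SpectralModel:
        key = (round(kappa, 12), round(omega, 12))
        if key not in self._model_cache:
            if len(self._model_cache) > 64:
                self._model_cache.clear()
            self._model_cache[key] = _SpectralModel(kappa, omega, self.pi)
        return self._model_cache[key]

    def _branch_p(self, kappa: float, omega: float, scale: float) -> np.ndarray:
        return self._model(kappa, omega).p_matrices(self._lens * scale)

    def _prune(self, p_by_branch: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihood given one P matrix per branch."""
        S = self.S
        n_tips = self.ltree.n_tips
        partial: list[np.ndarray | None] = [None] * (n_tips + len(self.ltree.children))
        logscale = np.zeros(S)
        b = 0  # branch cursor, matches branch_list order
        node_idx = n_tips
        for kids in self.ltree.children:
            m: np.ndarray | None = None
            for child_idx, _t, _fg in kids:
                p = p_by_branch[b]
                b += 1
                if child_idx < n_tips:
                    idx = self.patterns[child_idx]
                    valid = self._tip_valid[child_idx]
                    if m is None:
                        m = np.ones((S, N_STATES))
                        if valid.any():
                            m[valid] = p[:, idx[valid]].T
                    elif valid.all():
                        m *= p[:, idx].T
                    elif valid.any():
                        m[valid] *= p[:, idx[valid]].T
                else:
                    contrib = partial[child_idx] @ p.T
                    if m is None:
                        m = contrib
                    else:
                        m *= contrib
            mx = m.max(axis=1)
            mx[mx == 0] = 1.0
            m /= mx[:, None]
            logscale += np.log(mx)
            partial[node_idx] = m
            node_idx += 1
        root = partial[node_idx - 1]
        lik = root @ self.pi
        return np.log(lik) + logscale

    def class_logliks(
        self, kappa: float, omega0: float, omega2: float, scale: float = 1.0
    ) -> np.ndarray:
        """Log per-pattern likelihood for classes (0, 1, 2a, 2b): (4, S).

        Results are memoized per class configuration: finite-difference
        gradient steps perturb one parameter at a time, so the classes a
        perturbation does not touch are served from cache.
        """
        key_base = (round(kappa, 12), round(scale, 12))
        p_cache: dict[float, np.ndarray] = {}

        def branch_p(omega: float) -> np.ndarray:
            if omega not in p_cache:
                p_cache[omega] = self._branch_p(kappa, omega, scale)
            return p_cache[omega]

        fg = self._fg[:, None, None]
        out = np.empty((4, self.S))
        specs = [
            (omega0, omega0),
            (1.0, 1.0),
            (omega0, omega2),
            (1.0, omega2),
        ]
        seen: dict[tuple[float, float], int] = {}
        for c, (w_bg, w_fg) in enumerate(specs):
            prev = seen.get((w_bg, w_fg))
            if prev is not None:
                out[c] = out[prev]
                continue
            seen[(w_bg, w_fg)] = c
            key = key_base + (round(w_bg, 12), round(w_fg, 12))
            hit = self._class_cache.get(key)
            if hit is None:
                if w_bg == w_fg:
                    p = branch_p(w_bg)
                else:
                    p = np.where(fg, branch_p(w_fg), branch_p(w_bg))
                hit = self._prune(p)
                if len(self._class_cache) > 256:
                    self._class_cache.clear()
                self._class_cache[key] = hit
            out[c] = hit
        return out

    # -- public -------------------------------------------------------------

    def site_log_likelihoods(self, params: CodonModelParams, scale: float = 1.0) -> np.ndarray:
        """Mixture per-codon lnL contributions in original site order."""
        params.validate()
        logf = self.class_logliks(params.kappa, params.omega0, params.omega2, scale)
        w = params.class_weights()
        per_pattern = logsumexp(logf, axis=0, b=w[:, None])
        return per_pattern[self.pattern_of_site]

    def log_likelihood(self, params: CodonModelParams, scale: float = 1.0) -> float:
        params.validate()
        logf = self.class_logliks(params.kappa, params.omega0, params.omega2, scale)
        w = params.class_weights()
        return float(self.counts @ logsumexp(logf, axis=0, b=w[:, None]))

    def class_posteriors(self, params: CodonModelParams, scale: float = 1.0) -> np.ndarray:
        """Posterior P(class | site) for the 4 classes, per codon site."""
        logf = self.class_logliks(params.kappa, params.omega0, params.omega2, scale)
        w = params.class_weights()
        logw = np.log(np.maximum(w, 1e-300))[:, None]
        lognum = logw + logf
        logden = logsumexp(lognum, axis=0)
        post = np.exp(lognum - logden)
        return post[:, self.pattern_of_site]


def site_log_likelihoods(
    seqs: dict[str, str],
    ltree: LabeledTree,
    params: CodonModelParams,
    scale: float = 1.0,
) -> np.ndarray:
    """Convenience wrapper: per-codon lnL contributions for one alignment."""
    return BranchSitePruner(seqs, ltree, params.codon_freqs).site_log_likelihoods(
        params, scale
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    n_starts: int = 3
    optimize_scale: bool = True
    maxiter: int = 60
    ftol: float = 1e-8  # L-BFGS-B relative tolerance on the outer objective
    fd_step: float = 1e-4  # finite-difference step for the outer gradient
    converge_tol: float = 0.01  # lnL agreement defining convergence
    confirm_restart: bool = True  # extra jittered restart from the best optimum
    codon_freqs: np.ndarray | None = None


_LOG = np.log


def _optimize_weights(logf: np.ndarray, counts: np.ndarray, _x0=None):
    """Profile (p0, p1) for fixed class log-likelihoods by EM.

    The class weights factor as an outer product: with a = (p0+p1, p2) the
    probability of a site being unselected vs selected, and b = (r, 1-r)
    with r = p0/(p0+p1) the mix between the omega0 and omega1 regimes, the
    weights of classes (0, 1, 2a, 2b) are (a0*b0, a0*b1, a1*b0, a1*b1).
    Both factors have closed-form EM updates, so the profile is exact and
    deterministic. Returns (lnL, p0, p1, (a, b)).
    """
    m = logf.max(axis=0)
    g = np.exp(logf - m)  # (4, S)
    cm = float(counts @ m)
    n_tot = float(counts.sum())

    def run(a0: float, b0: float) -> tuple[float, float, float]:
        a1, b1 = 1.0 - a0, 1.0 - b0
        lnl = -np.inf
        for it in range(600):
            w = np.array([a0 * b0, a0 * b1, a1 * b0, a1 * b1])
            lik = np.maximum(w @ g, 1e-300)  # (S,)
            # nk_k = sum_s counts_s * w_k g_ks / lik_s, via one matvec
            nk = w * (g @ (counts / lik))
            a0 = min(max((nk[0] + nk[1]) / n_tot, 1e-12), 1.0 - 1e-12)
            a1 = 1.0 - a0
            b0 = min(max((nk[0] + nk[2]) / n_tot, 1e-12), 1.0 - 1e-12)
            b1 = 1.0 - b0
            if it % 4 == 3 or it == 599:
                new_lnl = cm + float(counts @ np.log(lik))
                if new_lnl - lnl < 1e-8:
                    lnl = max(lnl, new_lnl)
                    break
                lnl = new_lnl
        else:
            lnl = cm + float(counts @ np.log(lik))
        return lnl, a0, b0

    starts = [(0.9, 0.78), (0.6, 0.4)]
    best = max(run(*s) for s in starts)
    lnl, a0, b0 = best
    p0 = a0 * b0
    p1 = a0 * (1.0 - b0)
    return lnl, p0, p1, (a0, b0)


def fit_branch_site(
    seqs: dict[str, str],
    ltree: LabeledTree,
    model: Literal["null", "alt"] = "alt",
    opts: FitOptions | None = None,
) -> BranchSiteFit:
    """Maximum-likelihood branch-site fit (null: omega2=1; alt: omega2 free).

    Optimizes (kappa, p0, p1, omega0[, omega2][, branch-length scale]) by
    profiling the class proportions inside an outer quasi-Newton search over
    the rate parameters, from several dispersed starting points. The fit is
    flagged converged when the two best restarts agree within
    ``converge_tol`` log-likelihood units.
    """
    opts = opts or FitOptions()
    pruner = BranchSitePruner(seqs, ltree, opts.codon_freqs)
    return _fit_with_pruner(pruner, model, opts)


def _fit_with_pruner(
    pruner: BranchSitePruner,
    model: str,
    opts: FitOptions,
    warm: BranchSiteFit | None = None,
) -> BranchSiteFit:
    counts = pruner.counts
    is_alt = model == "alt"
    # transformed parameters: log kappa, log omega0, [log(omega2-1)], [log scale]
    bounds = [(np.log(0.1), np.log(50.0)), (np.log(1e-6), 0.0)]
    if is_alt:
        bounds.append((np.log(1e-6), np.log(998.0)))
    if opts.optimize_scale:
        bounds.append((np.log(0.02), np.log(50.0)))

    weight_x0 = {"x": None}

    def unpack(x):
        kappa = float(np.exp(x[0]))
        omega0 = float(np.exp(x[1]))
        k = 2
        omega2 = 1.0
        if is_alt:
            omega2 = 1.0 + float(np.exp(x[k]))
            k += 1
        scale = float(np.exp(x[k])) if opts.optimize_scale else 1.0
        return kappa, omega0, omega2, scale

    def neg_lnl(x):
        kappa, omega0, omega2, scale = unpack(x)
        logf = pruner.class_logliks(kappa, omega0, omega2, scale)
        lnl, _p0, _p1, wx = _optimize_weights(logf, counts, weight_x0["x"])
        weight_x0["x"] = wx
        return -lnl

    starts = []
    base = [(2.0, 0.1, 2.0, 1.0), (1.0, 0.5, 5.0, 1.0), (5.0, 0.03, 1.3, 0.5)]
    if warm is not None:
        # warm restarts from the null solution: one probing omega2 > 1, one
        # starting at the nested boundary (omega2 -> 1) so the alternative
        # can never undercut the null
        base = [(warm.params.kappa, warm.params.omega0, 2.5, warm.scale)] + base
    for kappa, w0, w2, sc in base[: max(opts.n_starts, 3)]:
        x = [np.log(kappa), np.log(w0)]
        if is_alt:
            x.append(np.log(w2 - 1.0))
        if opts.optimize_scale:
            x.append(np.log(sc))
        starts.append(np.array(x))

    results = []
    for x0 in starts:
        weight_x0["x"] = None
        r = minimize(
            neg_lnl,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.maxiter, "ftol": opts.ftol, "eps": opts.fd_step},
        )
        results.append(r)
    results.sort(key=lambda r: r.fun)
    if opts.confirm_restart:
        # confirmation restart: jitter the best solution and re-optimize;
        # landing back within tolerance demonstrates a reproducible optimum
        jitter = np.array([0.05 * (-1) ** k for k in range(len(results[0].x))])
        x_conf = np.clip(
            results[0].x + jitter, [b[0] for b in bounds], [b[1] for b in bounds]
        )
        results.append(
            minimize(
                neg_lnl,
                x_conf,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": opts.maxiter, "ftol": opts.ftol, "eps": opts.fd_step},
            )
        )
        results.sort(key=lambda r: r.fun)
    best = results[0]
    lnls = sorted((-r.fun for r in results), reverse=True)
    converged = len(lnls) >= 2 and (lnls[0] - lnls[1]) < opts.converge_tol

    kappa, omega0, omega2, scale = unpack(best.x)
    logf = pruner.class_logliks(kappa, omega0, omega2, scale)
    lnl, p0, p1, _ = _optimize_weights(logf, counts)
    if warm is not None and is_alt and lnl < warm.lnL:
        # nested models: the null solution (omega2 = 1) is in the alt space
        kappa, omega0, scale = warm.params.kappa, warm.params.omega0, warm.scale
        omega2 = 1.0
        p0, p1 = warm.params.p0, warm.params.p1
        lnl = warm.lnL
    params = CodonModelParams(
        kappa=kappa,
        codon_freqs=pruner.pi,
        p0=p0,
        p1=p1,
        omega0=omega0,
        omega2=omega2,
    )
    post = pruner.class_posteriors(params, scale)
    site_post = post[2] + post[3]
    return BranchSiteFit(
        params=params,
        lnL=float(lnl),
        n_restarts=len(starts),
        converged=bool(converged),
        site_posteriors=site_post,
        model=model,
        scale=scale,
        restart_lnls=lnls,
    )


def fit_null_and_alt(
    seqs: dict[str, str], ltree: LabeledTree, opts: FitOptions | None = None
) -> tuple[BranchSiteFit, BranchSiteFit]:
    """Fit the null first, then the alternative warm-started from it."""
    opts = opts or FitOptions()
    pruner = BranchSitePruner(seqs, ltree, opts.codon_freqs)
    fit_null = _fit_with_pruner(pruner, "null", opts)
    fit_alt = _fit_with_pruner(pruner, "alt", opts, warm=fit_null)
    return fit_null, fit_alt


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------

def lrt(fit_alt: BranchSiteFit, fit_null: BranchSiteFit, tol: float = 0.05) -> LrtResult:
    """Chi-square(1) LRT of the selection model against the omega2=1 null."""
    delta = 2.0 * (fit_alt.lnL - fit_null.lnL)
    if delta < -tol:
        raise ValueError(
            f"lnL(alt)={fit_alt.lnL:.4f} < lnL(null)={fit_null.lnL:.4f}: optimizer failure"
        )
    delta = max(delta, 0.0)
    return LrtResult(delta, 1, float(chi2_dist.sf(delta, 1)))


# ---------------------------------------------------------------------------
# Bayes empirical Bayes site identification
# ---------------------------------------------------------------------------

def beb_site_posteriors(
    seqs: dict[str, str],
    ltree: LabeledTree,
    fit_alt: BranchSiteFit,
    n_bins: int = 10,
    mode: Literal["beb", "neb"] = "beb",
    allow_unconverged: bool = False,
) -> np.ndarray:
    """Per-codon posterior probability of the positively selected classes.

    BEB averages the site-class posterior over a grid prior: (p0, p1)
    uniform on the simplex (n_bins x n_bins midpoint grid, points with
    p0+p1 <= 1), omega0 on n_bins midpoints of (0, 1) and omega2 on n_bins
    midpoints of (1, 11); kappa, branch-length scale and codon frequencies
    stay at their MLEs. ``neb`` evaluates the posterior at the MLEs only.
    """
    if fit_alt.model != "alt":
        raise ValueError("BEB requires an alternative-model fit")
    if not fit_alt.converged and not allow_unconverged:
        raise ValueError("refusing BEB on an unconverged fit")
    pruner = BranchSitePruner(seqs, ltree, fit_alt.params.codon_freqs)
    if mode == "neb":
        post = pruner.class_posteriors(fit_alt.params, fit_alt.scale)
        return post[2] + post[3]

    kappa = fit_alt.params.kappa
    scale = fit_alt.scale
    counts = pruner.counts
    S = pruner.S

    w0_grid = (np.arange(n_bins) + 0.5) / n_bins
    w2_grid = 1.0 + (np.arange(n_bins) + 0.5) * (10.0 / n_bins)
    # class log-likelihood caches
    logf1 = pruner._prune(pruner._branch_p(kappa, 1.0, scale))
    logf0 = np.empty((n_bins, S))
    logf2b = np.empty((n_bins, S))
    logf2a = np.empty((n_bins, n_bins, S))
    fg = pruner._fg[:, None, None]
    p1m = pruner._branch_p(kappa, 1.0, scale)
    for a, w0 in enumerate(w0_grid):
        p0m = pruner._branch_p(kappa, w0, scale)
        logf0[a] = pruner._prune(p0m)
        for b, w2 in enumerate(w2_grid):
            p2m = pruner._branch_p(kappa, w2, scale)
            logf2a[a, b] = pruner._prune(np.where(fg, p2m, p0m))
    for b, w2 in enumerate(w2_grid):
        p2m = pruner._branch_p(kappa, w2, scale)
        logf2b[b] = pruner._prune(np.where(fg, p2m, p1m))

    # triangle of (p0, p1) midpoints
    tri = [
        ((i + 0.5) / n_bins, (j + 0.5) / n_bins)
        for i in range(n_bins)
        for j in range(n_bins)
        if (i + 0.5) / n_bins + (j + 0.5) / n_bins <= 1.0 + 1e-12
    ]
    weight_rows = []
    for p0, p1 in tri:
        p2 = max(0.0, 1.0 - p0 - p1)
        p01 = p0 + p1
        weight_rows.append([p0, p1, p2 * p0 / p01, p2 * p1 / p01])
    w_tri = np.array(weight_rows)  # (T, 4)

    total_lnl = []
    sel_post = []
    for a in range(n_bins):
        for b in range(n_bins):
            logf = np.stack([logf0[a], logf1, logf2a[a, b], logf2b[b]])  # (4, S)
            m = logf.max(axis=0)
            g = np.exp(logf - m)  # (4, S)
            lik = w_tri @ g  # (T, S)
            lik = np.maximum(lik, 1e-300)
            total_lnl.append((m + np.log(lik)) @ counts)  # (T,)
            sel = (w_tri[:, 2:4] @ g[2:4]) / lik  # (T, S)
            sel_post.append(sel)
    total_lnl = np.concatenate(total_lnl)  # (G,)
    sel_post = np.concatenate(sel_post, axis=0)  # (G, S)
    logw = total_lnl - logsumexp(total_lnl)
    grid_post = np.exp(logw)
    per_pattern = grid_post @ sel_post
    return per_pattern[pruner.pattern_of_site]


# ---------------------------------------------------------------------------
# Robustness across candidate gene trees
# ---------------------------------------------------------------------------

def multi_tree_robustness(
    seqs: dict[str, str],
    trees: Sequence[dendropy.Tree],
    meta: dict[str, tuple[str, str]],
    population: str,
    opts: FitOptions | None = None,
    alpha: float = 0.05,
    beb_threshold: float = 0.95,
) -> tuple[pd.DataFrame, dict]:
    """Repeat the null/alt fits and site identification over candidate trees.

    Returns a per-tree table (lnL_null, lnL_alt, 2*delta, p, flagged sites)
    and a summary with the fraction of significant trees and per-site flag
    frequencies.
    """
    if len(trees) < 2:
        raise ValueError("need at least two candidate trees")
    rows = []
    flag_freq: dict[int, int] = {}
    for k, tree in enumerate(trees):
        ltree = label_foreground(tree, meta, population)
        if set(ltree.tip_names) != set(seqs):
            missing = sorted(set(ltree.tip_names) ^ set(seqs))
            raise ValueError(f"tree {k} tip set differs from alignment: {missing}")
        fit_null, fit_alt = fit_null_and_alt(seqs, ltree, opts)
        res = lrt(fit_alt, fit_null)
        post = beb_site_posteriors(seqs, ltree, fit_alt, allow_unconverged=True)
        flagged = sorted(int(i) + 1 for i in np.where(post > beb_threshold)[0])
        for s in flagged:
            flag_freq[s] = flag_freq.get(s, 0) + 1
        rows.append(
            {
                "tree": k,
                "lnL_null": fit_null.lnL,
                "lnL_alt": fit_alt.lnL,
                "two_delta_lnl": res.two_delta_lnl,
                "p_value": res.p_value,
                "significant": res.p_value < alpha,
                "flagged_sites": flagged,
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "fraction_significant": float(table["significant"].mean()),
        "site_flag_frequency": {
            s: c / len(trees) for s, c in sorted(flag_freq.items())
        },
    }
    return table, summary


def paml_foreground_newick(ltree: LabeledTree) -> str:
    """Export the labeled tree with #1 marks on foreground branches."""
    tree = ltree.tree.clone(depth=1)
    # annotate by matching the foreground rule again on the clone
    focal: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            focal[id(node)] = node.taxon.label in {
                ltree.tip_names[i]
                for i in range(ltree.n_tips)
            } and _tip_is_foreground(ltree, node.taxon.label)
        else:
            focal[id(node)] = all(focal[id(c)] for c in node.child_nodes())
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        if focal[id(node)]:
            if node.is_leaf():
                node.taxon.label = f"{node.taxon.label} #1"
            else:
                node.label = "#1"
    out = tree.as_string(schema="newick", suppress_rooting=True).strip()
    # dendropy renders the space before the mark as an underscore
    return out.replace("_#1", " #1").replace("'", "")


def _tip_is_foreground(ltree: LabeledTree, name: str) -> bool:
    for kids in ltree.children:
        for idx, _t, fg in kids:
            if idx < ltree.n_tips and ltree.tip_names[idx] == name:
                return fg
    return False
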