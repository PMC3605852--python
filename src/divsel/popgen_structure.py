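"""Population structure from pairwise haplotype distances.

Distance-based (AMOVA) fixation index Phi_ST between two populations of
haplotypes, a label-permutation test of Phi_ST = 0, and the standardized
index Phi'_ST = Phi_ST / Phi_ST_max, where Phi_ST_max is obtained by setting
every between-population distance to the maximum attainable distance and
recomputing Phi_ST.

Distances default to Kimura two-parameter with the alignment gap treated as a
fifth character state: base-vs-gap mismatches enter the transversion class
(a gap is maximally unlike both transition partners), gap-vs-gap counts as
identity, and columns with N in either sequence are excluded (pairwise
deletion). If the K2P logarithm argument is non-positive (saturation) the
raw mismatch proportion is returned and flagged.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, NamedTuple

import numpy as np

from .alleles_qc import BASES, MISSING, PopAlignment

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

# Largest finite K2P distance: P = 0, Q at the largest value keeping the log
# argument positive given double-precision resolution (the formula diverges
# at Q = 1/2, so this is a cap, not a limit).
_Q_CAP = 0.5 * (1.0 - math.sqrt(np.finfo(float).eps))
K2P_SATURATION_CAP = -0.5 * math.log((1.0 - _Q_CAP) * math.sqrt(1.0 - 2.0 * _Q_CAP))


class K2PResult(NamedTuple):
    distance: float
    p_transition: float
    q_transversion: float
    n_sites: int
    saturated: bool


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, substitutions/site

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")

    def index(self, name: str) -> int:
        return self.ids.index(name)


@dataclass
class StructureResult:
    phi_st: float
    perm_p: float
    n_perm: int
    phi_prime_maxdist: float
    phi_prime_fraglen: float


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def k2p_components(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance with gap-as-fifth-state semantics, with components."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences have unequal lengths")
    n = ts = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == MISSING or b == MISSING:
            continue
        n += 1
        if a == b:
            continue
        if a in BASES and b in BASES:
            if (a in PURINES) == (b in PURINES):
                ts += 1
            else:
                tv += 1
        else:
            # base-vs-gap: counted in the transversion class
            tv += 1
    if n == 0:
        raise ValueError("no comparable (non-N) columns")
    p = ts / n
    q = tv / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return K2PResult((ts + tv) / n, p, q, n, True)
    d = -0.5 * math.log(arg1 * math.sqrt(arg2))
    return K2PResult(d, p, q, n, False)


def k2p_gap_distance(seq_a: str, seq_b: str) -> float:
    """K2P distance (substitutions/site) treating the gap as a fifth state."""
    return k2p_components(seq_a, seq_b).distance


def p_distance(seq_a: str, seq_b: str) -> float:
    """Mismatch proportion with the same fifth-state/pairwise-deletion rules."""
    r = k2p_components(seq_a, seq_b)
    return r.p_transition + r.q_transversion


def distance_matrix(
    seqs: dict[str, str],
    model: Literal["k2p_gap", "p"] = "k2p_gap",
) -> DistanceMatrix:
    fn: Callable[[str, str], float] = k2p_gap_distance if model == "k2p_gap" else p_distance
    ids = list(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(seqs[ids[i]], seqs[ids[j]])
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# AMOVA Phi_ST
# ---------------------------------------------------------------------------

def _group_indices(dm: DistanceMatrix, groups: dict[str, str]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i, name in enumerate(dm.ids):
        if name not in groups:
            raise ValueError(f"allele {name} has no group assignment")
        out.setdefault(groups[name], []).append(i)
    return out


def _phi_from_d2(d2: np.ndarray, members: list[np.ndarray]) -> float:
    """Phi_ST from a squared-distance matrix and group index arrays.

    Standard two-level distance AMOVA: within-group sums of squares are
    1/n_g times the within-group pairwise sums, the total is 1/N times the
    overall sum; variance components follow from the expected mean squares
    with unequal group sizes.
    """
    sizes = np.array([len(m) for m in members])
    n_tot = int(sizes.sum())
    n_groups = len(members)
    iu = np.triu_indices(d2.shape[0], 1)
    ss_total = d2[iu].sum() / n_tot
    ss_within = 0.0
    for m in members:
        sub = d2[np.ix_(m, m)]
        ss_within += sub[np.triu_indices(len(m), 1)].sum() / len(m)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n_tot - n_groups
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n_prime = (n_tot - (sizes**2).sum() / n_tot) / df_among
    sigma_a = (ms_among - ms_within) / n_prime
    sigma_w = ms_within
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def phi_st(dm: DistanceMatrix, groups: dict[str, str]) -> float:
    """AMOVA fixation index Phi_ST from pairwise distances (may be < 0)."""
    by_group = _group_indices(dm, groups)
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    for g, m in by_group.items():
        if len(m) < 2:
            raise ValueError(f"group {g} has fewer than 2 members")
    members = [np.array(m) for m in by_group.values()]
    return _phi_from_d2(dm.d**2, members)


def phi_st_permutation(
    dm: DistanceMatrix,
    groups: dict[str, str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for Phi_ST = 0, permuting allele labels.

    p = (1 + #{permuted Phi_ST >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    observed = phi_st(dm, groups)
    by_group = _group_indices(dm, groups)
    sizes = [len(m) for m in by_group.values()]
    all_idx = np.concatenate([np.array(m) for m in by_group.values()])
    d2 = dm.d**2
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        members = []
        pos = 0
        for s in sizes:
            members.append(perm[pos : pos + s])
            pos += s
        if _phi_from_d2(d2, members) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Standardized Phi'_ST
# ---------------------------------------------------------------------------

def phi_prime(
    phi: float,
    dm: DistanceMatrix,
    groups: dict[str, str],
    method: Literal["max_observed", "fragment_length"] = "max_observed",
    fragment_length: int | None = None,
    dmax_model: Literal["mismatch", "k2p_saturation"] = "mismatch",
) -> float:
    """Standardized fixation index Phi'_ST = Phi_ST / Phi_ST_max.

    Phi_ST_max is the Phi_ST of a matrix in which every between-group
    distance is replaced by the maximum attainable distance D_max:

    * ``max_observed``: D_max is the largest entry of ``dm``.
    * ``fragment_length``: D_max is the distance of two sequences differing
      at every site of the fragment. Under the mismatch-proportion cap
      (default) this is 1.0 substitutions/site; under ``k2p_saturation`` it
      is the largest finite K2P value (the K2P formula diverges at full
      saturation, so the cap sits just inside the domain of the logarithm).
    """
    by_group = _group_indices(dm, groups)
    if method == "max_observed":
        d_max = float(dm.d.max())
    elif method == "fragment_length":
        if fragment_length is None or fragment_length <= 0:
            raise ValueError("fragment_length must be positive for this method")
        d_max = 1.0 if dmax_model == "mismatch" else K2P_SATURATION_CAP
    else:
        raise ValueError(f"unknown method {method!r}")

    d = dm.d.copy()
    labels = np.array([groups[name] for name in dm.ids])
    between = labels[:, None] != labels[None, :]
    d[between] = d_max
    members = [np.array(m) for m in by_group.values()]
    phi_max = _phi_from_d2(d**2, members)
    if phi_max == 0:
        raise ValueError("Phi_ST_max is zero; standardization undefined")
    return float(phi / phi_max)


# ---------------------------------------------------------------------------
# Locus-level driver
# ---------------------------------------------------------------------------

def analyze_locus(
    aln: PopAlignment,
    populations: tuple[str, str],
    n_perm: int = 10_000,
    seed: int | None = None,
    span: tuple[int, int] | None = None,
    model: Literal["k2p_gap", "p"] = "k2p_gap",
) -> StructureResult:
    """Full structure analysis of one locus between two populations."""
    pops = aln.populations()
    keep = {a for p in populations for a in pops.get(p, [])}
    seqs = {a: s for a, s in aln.alleles.items() if a in keep}
    if span is not None:
        lo, hi = span
        seqs = {a: s[lo - 1 : hi] for a, s in seqs.items()}
    groups = {a: aln.meta[a][1] for a in seqs}
    dm = distance_matrix(seqs, model=model)
    phi = phi_st(dm, groups)
    p = phi_st_permutation(dm, groups, n_perm=n_perm, seed=seed)
    frag = len(next(iter(seqs.values())))
    pp_max = phi_prime(phi, dm, groups, method="max_observed")
    pp_frag = phi_prime(
        phi, dm, groups, method="fragment_length", fragment_length=frag
    )
    return StructureResult(phi, p, n_perm, pp_max, pp_frag)
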