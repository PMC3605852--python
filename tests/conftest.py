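import os

# small-matrix BLAS work gains nothing from threading; spinning worker
# threads actively hurt on a single-CPU host
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

from divsel.alleles_qc import PopAlignment
from divsel.popgen_structure import DistanceMatrix


def make_aln(seqs, pops=None, regions=(), breakpoint=None):
    """PopAlignment from {id: seq}; populations default to 'A' for all."""
    if pops is None:
        pops = {name: "A" for name in seqs}
    meta = {name: (f"ind_{name}", pops[name]) for name in seqs}
    return PopAlignment(dict(seqs), meta, list(regions), breakpoint)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_labeled_tree(rng, n_tips, fg_prob=0.4, t_range=(0.02, 0.5)):
    """Random rooted binary tree in the pruning array layout.

    Internal nodes are created in postorder by sequential joining, so the
    children list is valid for LabeledTree directly.
    """
    from divsel.codon_selection import LabeledTree

    tip_names = [f"t{i}" for i in range(n_tips)]
    subtrees = list(range(n_tips))
    children = []
    next_idx = n_tips
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        kids = [
            (a, float(rng.uniform(*t_range)), bool(rng.random() < fg_prob)),
            (b, float(rng.uniform(*t_range)), bool(rng.random() < fg_prob)),
        ]
        children.append(kids)
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(next_idx)
        next_idx += 1
    return LabeledTree(tip_names, children, "A", None)


def enumeration_site_likelihood(ltree, tip_codons, p_of_branch, pi):
    """Site likelihood by exhaustive summation over ancestral codon states.

    Independent oracle for the pruning algorithm: loops over every
    assignment of the non-root internal nodes (vectorizing only the root
    state) and multiplies per-branch transition probabilities explicitly.
    """
    from itertools import product

    n_tips = ltree.n_tips
    n_internal = len(ltree.children)
    total = 0.0
    for assign in product(range(len(pi)), repeat=n_internal - 1):
        val = 1.0
        root_vec = np.ones(len(pi))
        b = 0
        for k, kids in enumerate(ltree.children):
            parent_state = None if k == n_internal - 1 else assign[k]
            for child_idx, _t, _fg in kids:
                p = p_of_branch[b]
                b += 1
                if child_idx < n_tips:
                    s = tip_codons[child_idx]
                    col = np.ones(len(pi)) if s < 0 else p[:, s]
                else:
                    col = p[:, assign[child_idx - n_tips]]
                if parent_state is None:
                    root_vec = root_vec * col
                else:
                    val *= col[parent_state]
        total += val * float(root_vec @ pi)
    return total


def amova_phi_oracle(d, groups):
    """Phi_ST from first principles: explicit pair loops over the AMOVA
    sums of squares and the expected-mean-square solution for unequal
    group sizes. Deliberately unvectorized and independent of the
    implementation under test."""
    ids = list(range(len(d)))
    n = len(ids)
    labels = sorted(set(groups.values()))
    ss_total = 0.0
    for i in ids:
        for j in ids:
            if i < j:
                ss_total += d[i][j] ** 2
    ss_total /= n
    ss_within = 0.0
    sizes = []
    for g in labels:
        members = [i for i in ids if groups[i] == g]
        sizes.append(len(members))
        acc = 0.0
        for i in members:
            for j in members:
                if i < j:
                    acc += d[i][j] ** 2
        ss_within += acc / len(members)
    ss_among = ss_total - ss_within
    df_a = len(labels) - 1
    df_w = n - len(labels)
    ms_a = ss_among / df_a
    ms_w = ss_within / df_w
    n_prime = (n - sum(s * s for s in sizes) / n) / df_a
    sigma_a = (ms_a - ms_w) / n_prime
    sigma_w = ms_w
    if sigma_a + sigma_w == 0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)


def random_additive_tree(rng, n):
    """Random binary tree and its exact leaf-to-leaf path distances."""
    labels = [f"x{i}" for i in range(n)]
    idx = {lab: k for k, lab in enumerate(labels)}
    d = np.zeros((n, n))
    # each live subtree: {leaf: distance to subtree junction}
    subtrees = [{lab: 0.0} for lab in labels]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        for ka, va in a.items():
            for kb, vb in b.items():
                dist = va + la + vb + lb
                d[idx[ka], idx[kb]] = d[idx[kb], idx[ka]] = dist
        merged = {k: v + la for k, v in a.items()}
        merged.update({k: v + lb for k, v in b.items()})
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(merged)
    return DistanceMatrix(labels, d)
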