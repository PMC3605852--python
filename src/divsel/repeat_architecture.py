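"""Repeat-domain architecture: copy extraction, paralog trees, conversion.

Repetitive gamete-recognition loci often carry tandem arrays (here a
collagen-like repeat and a longer tandem repeat) whose copies can be gained,
lost, or overwritten by gene conversion. Given fixed per-copy spans in
alignment coordinates, this module extracts the copy sequences per allele,
counts copies (an all-gap span is an absent copy), builds neighbor-joining
trees of repeat paralogs, screens for conversion events (whole-copy and
phase-shifted), and tests whether copy-number variation covaries between two
domains.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.stats import chi2 as chi2_dist

from .alleles_qc import GAP, PopAlignment
from .popgen_structure import DistanceMatrix, distance_matrix


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RepeatCopy:
    allele_id: str
    domain: str
    copy_index: int
    span: tuple[int, int]  # 1-based inclusive alignment columns
    sequence: str


@dataclass
class RepeatAnnotation:
    domains: dict[str, list[RepeatCopy]]
    copy_number: dict[tuple[str, str], int]  # (allele_id, domain) -> count

    def copies_of(self, domain: str, allele_id: str) -> list[RepeatCopy]:
        return [c for c in self.domains.get(domain, []) if c.allele_id == allele_id]

    def alleles(self) -> list[str]:
        return sorted({a for a, _ in self.copy_number})


@dataclass
class ConversionEvent:
    allele_id: str
    domain: str
    copy_index: int
    donor_copy_index: int
    span: tuple[int, int]
    identity: float
    kind: str  # "whole_copy" or "phase_shift"


# ---------------------------------------------------------------------------
# Copy extraction
# ---------------------------------------------------------------------------

def extract_repeat_copies(
    aln: PopAlignment,
    domain_spans: list[tuple[str, int, int, int]],
) -> RepeatAnnotation:
    """Extract per-allele repeat-copy sequences from configured spans.

    ``domain_spans`` rows are (domain, copy_index, start, end). Spans within
    a domain must not overlap. For each allele, a copy whose span is all
    gaps is recorded as absent; copy_number counts the present copies.
    """
    by_domain: dict[str, list[tuple[int, int, int]]] = {}
    for domain, idx, start, end in domain_spans:
        if start < 1 or end < start or end > aln.length:
            raise ValueError(f"span ({start},{end}) out of bounds for {domain}")
        by_domain.setdefault(domain, []).append((idx, start, end))
    for domain, spans in by_domain.items():
        ordered = sorted(spans, key=lambda s: s[1])
        for (_, s1, e1), (_, s2, _e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping spans in domain {domain}")

    domains: dict[str, list[RepeatCopy]] = {d: [] for d in by_domain}
    copy_number: dict[tuple[str, str], int] = {}
    for allele, seq in aln.alleles.items():
        for domain, spans in by_domain.items():
            n = 0
            for idx, start, end in sorted(spans, key=lambda s: s[0]):
                sub = seq[start - 1 : end]
                if set(sub) <= {GAP}:
                    continue
                n += 1
                domains[domain].append(
                    RepeatCopy(allele, domain, idx, (start, end), sub)
                )
            copy_number[(allele, domain)] = n
    return RepeatAnnotation(domains, copy_number)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by id order; negative branch lengths
    are clamped to zero with the deficit moved to the sister branch so the
    pair still spans d_ij. Returns an unrooted tree (trifurcating base).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 items")
    d = dm.d.astype(float).copy()
    taxon_ns = dendropy.TaxonNamespace(dm.ids)
    nodes: list[dendropy.Node] = []
    for name in dm.ids:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(name))
        nodes.append(node)
    labels = list(dm.ids)  # sort keys for tie-breaking
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break: smallest (label_i, label_j)
        cand = np.argwhere(q <= qmin + 1e-12)
        best = min(
            ((labels[active[i]], labels[active[j]], i, j) for i, j in cand if i < j),
        )
        ai, aj = best[2], best[3]
        i_glob, j_glob = active[ai], active[aj]
        dij = sub[ai, aj]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += -vi
            vi = 0.0
        if vj < 0:
            vi += -vj
            vj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i_glob])
        nodes[i_glob].edge.length = float(vi)
        parent.add_child(nodes[j_glob])
        nodes[j_glob].edge.length = float(vj)
        # distances from the new node
        new_row = np.zeros(d.shape[0] + 1)
        for k_local, k_glob in enumerate(active):
            if k_glob in (i_glob, j_glob):
                continue
            new_row[k_glob] = 0.5 * (sub[ai, k_local] + sub[aj, k_local] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        labels.append(min(labels[i_glob], labels[j_glob]))
        active = [k for k in active if k not in (i_glob, j_glob)] + [d.shape[0] - 1]

    # final three nodes: closed-form star
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    root = dendropy.Node()
    for k, v in ((a, va), (b, vb), (c, vc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = float(max(v, 0.0))
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def repeat_copy_tree(
    annotation: RepeatAnnotation,
    domain: str,
    model: str = "k2p_gap",
) -> dendropy.Tree:
    """NJ tree of all copies of a domain across alleles."""
    copies = annotation.domains.get(domain, [])
    if len(copies) < 3:
        raise ValueError(f"domain {domain} has fewer than 3 copies")
    seqs = {f"{c.allele_id}|{c.copy_index}": c.sequence for c in copies}
    widths = {len(s) for s in seqs.values()}
    if len(widths) != 1:
        raise ValueError("repeat copies must share alignment width")
    return nj_tree(distance_matrix(seqs, model=model))


# ---------------------------------------------------------------------------
# Gene conversion
# ---------------------------------------------------------------------------

def _identity(a: str, b: str) -> float:
    comp = match = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        comp += 1
        if x == y:
            match += 1
    return match / comp if comp else 0.0


def _paralog_consensus(copies: list[RepeatCopy]) -> str:
    cols = zip(*(c.sequence for c in copies))
    out = []
    for col in cols:
        counts = Counter(col)
        top = max(counts.values())
        out.append(sorted(s for s, c in counts.items() if c == top)[0])
    return "".join(out)


def detect_gene_conversion(
    annotation: RepeatAnnotation,
    min_window: int = 30,
    min_identity: float = 1.0,
) -> list[ConversionEvent]:
    """Screen repeat copies for gene conversion.

    Whole-copy events: a copy whose nearest paralog consensus (p-distance)
    is a *different* paralog, at identity >= min_identity, while the same
    copy index in most other alleles is nearest its own paralog consensus.

    Phase-shifted events: a window (>= min_window columns) crossing a copy
    boundary that is identical (>= min_identity) to the window offset by a
    whole number of copies (offsets up to +/-2), in an allele where that
    offset-similarity is not the rule across the sample.
    """
    events: list[ConversionEvent] = []
    for domain, copies in annotation.domains.items():
        widths = {len(c.sequence) for c in copies}
        if len(widths) != 1:
            raise ValueError(f"copies of domain {domain} differ in width")
        width = widths.pop()
        by_index: dict[int, list[RepeatCopy]] = {}
        for c in copies:
            by_index.setdefault(c.copy_index, []).append(c)
        if len(by_index) < 2:
            continue
        consensus = {k: _paralog_consensus(v) for k, v in by_index.items()}

        # (a) whole-copy conversion
        nearest: dict[tuple[str, int], int] = {}
        for c in copies:
            ids = {k: _identity(c.sequence, cons) for k, cons in consensus.items()}
            nearest[(c.allele_id, c.copy_index)] = max(
                sorted(ids), key=lambda k: (ids[k], k == c.copy_index)
            )
        for c in copies:
            best = nearest[(c.allele_id, c.copy_index)]
            if best == c.copy_index:
                continue
            if _identity(c.sequence, consensus[best]) < min_identity:
                continue
            peers = [
                p for p in by_index[c.copy_index] if p.allele_id != c.allele_id
            ]
            if peers:
                own = sum(
                    1
                    for p in peers
                    if nearest[(p.allele_id, p.copy_index)] == p.copy_index
                )
                if own <= len(peers) / 2:
                    continue  # paralog itself is degenerate, not a conversion
            events.append(
                ConversionEvent(
                    c.allele_id,
                    domain,
                    c.copy_index,
                    best,
                    c.span,
                    _identity(c.sequence, consensus[best]),
                    "whole_copy",
                )
            )

        # (b) phase-shifted conversion across copy boundaries
        events.extend(
            _phase_shift_events(annotation, domain, width, min_window, min_identity)
        )
    return events


def _phase_shift_events(
    annotation: RepeatAnnotation,
    domain: str,
    width: int,
    min_window: int,
    min_identity: float,
) -> list[ConversionEvent]:
    if min_window > 2 * width:
        return []
    events: list[ConversionEvent] = []
    alleles = annotation.alleles()
    concat: dict[str, tuple[str, list[int]]] = {}
    for a in alleles:
        copies = sorted(annotation.copies_of(domain, a), key=lambda c: c.copy_index)
        if len(copies) < 2:
            continue
        concat[a] = ("".join(c.sequence for c in copies), [c.copy_index for c in copies])

    # a window is anchored at a boundary between consecutive copies and
    # compared to the same window offset by +/-1 or +/-2 copy widths
    half = max(min_window // 2, 1)
    for a, (seq, indices) in concat.items():
        n_copies = len(indices)
        found: set[tuple[int, int]] = set()
        for b in range(1, n_copies):  # boundary between copy b-1 and b
            lo = b * width - half
            hi = b * width + (min_window - half)
            if lo < 0 or hi > len(seq):
                continue
            window = seq[lo:hi]
            # positive offsets only: a match at +k from boundary b equals a
            # match at -k from boundary b+k, so one orientation suffices
            for off in (1, 2):
                if (b + off) < 1 or (b + off) >= n_copies:
                    continue
                shift = off * width
                wlo, whi = lo + shift, hi + shift
                if wlo < 0 or whi > len(seq):
                    continue
                ident = _identity(window, seq[wlo:whi])
                if ident >= min_identity and (indices[b - 1], off) not in found:
                    found.add((indices[b - 1], off))
                    events.append(
                        ConversionEvent(
                            a,
                            domain,
                            indices[b - 1],
                            indices[min(b - 1 + off, n_copies - 1)],
                            (lo + 1, hi),
                            ident,
                            "phase_shift",
                        )
                    )
    return events


# ---------------------------------------------------------------------------
# Copy-number covariation
# ---------------------------------------------------------------------------

def yates_chi2_2x2(table: np.ndarray, clamp: bool = True) -> tuple[float, float]:
    """Yates-corrected chi-square for a 2x2 table (df = 1).

    With ``clamp`` (default) each |O-E|-0.5 is floored at 0, so the
    correction can never overshoot; without it the classical formula is
    used (scipy's behaviour).
    """
    obs = np.asarray(table, float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / n
    if np.any(exp == 0):
        raise ValueError("expected cell count of zero")
    adj = np.abs(obs - exp) - 0.5
    if clamp:
        adj = np.maximum(adj, 0.0)
    stat = float(((adj**2) / exp).sum())
    return stat, float(chi2_dist.sf(stat, 1))


def copy_number_covariation(
    annotation: RepeatAnnotation,
    domain_a: str,
    domain_b: str,
    modal_a: int | None = None,
    modal_b: int | None = None,
    clamp: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Test independence of copy-number variation between two domains.

    Alleles are classified as varying from the modal copy number (supplied
    or empirical mode) in each domain; the resulting 2x2 table (varies x
    varies) is tested with a Yates-corrected chi-square, df = 1.
    """
    alleles = annotation.alleles()
    counts_a = {a: annotation.copy_number.get((a, domain_a)) for a in alleles}
    counts_b = {a: annotation.copy_number.get((a, domain_b)) for a in alleles}
    if any(v is None for v in counts_a.values()) or any(
        v is None for v in counts_b.values()
    ):
        raise ValueError("copy numbers missing for some alleles")
    if modal_a is None:
        modal_a = Counter(counts_a.values()).most_common(1)[0][0]
    if modal_b is None:
        modal_b = Counter(counts_b.values()).most_common(1)[0][0]
    both = a_only = b_only = neither = 0
    for a in alleles:
        va = counts_a[a] != modal_a
        vb = counts_b[a] != modal_b
        if va and vb:
            both += 1
        elif va:
            a_only += 1
        elif vb:
            b_only += 1
        else:
            neither += 1
    table = np.array([[both, a_only], [b_only, neither]], float)
    stat, p = yates_chi2_2x2(table, clamp=clamp)
    return stat, p, table
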