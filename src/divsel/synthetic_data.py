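"""Synthetic two-population datasets with the structure the pipeline assumes.

Emulates the study design the package is built for: two populations of 20
diploid individuals each (one with the larger effective size and most of the
diversity), separated by an old split with low migration; a long coding
region containing a collagen-like repeat domain and a tandem-repeat domain
whose copy numbers vary mostly in the focal population; an intron evolving
neutrally with rare indels; a minority of codon sites under positive
selection (omega2 > 1) on the branches of one population only; and clone
sequencing with a small per-base error rate.

Every generator takes its randomness from the config seed and is
reproducible bit-for-bit. The emitted FASTA/TSV/newick/JSON are exactly the
input dialects of the analysis modules, and a TruthTable records what was
planted so downstream recovery can be scored without re-simulation.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import dendropy
import msprime
import numpy as np

from .alleles_qc import CloneSet, PopAlignment, Region
from .codon_selection import (
    CODONS,
    N_STATES,
    LabeledTree,
    _SpectralModel,
    label_foreground,
)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generator settings; defaults mirror the study conditions."""

    seed: int
    n_individuals: tuple[int, int] = (20, 20)
    pop_names: tuple[str, str] = ("bamfield", "sandspit")
    focal_population: str = "bamfield"

    # demography (natural units; converted to branch lengths below)
    ne_focal: float = 30_000.0
    ne_other: float = 5_000.0
    split_generations: float = 50_000.0  # ~200 kyr at ~4 yr/generation
    migration_rate: float = 1e-5

    # sequence layout
    n_codons: int = 950
    intron_length: int = 1285

    # codon model
    kappa: float = 2.0
    omega0: float = 0.1
    p0: float = 0.7
    p1: float = 0.2
    omega2: float = 4.0

    # branch-length scaling: expected substitutions per codon per generation,
    # or a target total tree length (substitutions/codon) that overrides it
    subs_per_generation: float = 2e-8
    target_tree_length: float | None = 3.0

    # repeat domains (lengths in nucleotides, multiples of 3)
    collagen_copies: int = 4
    collagen_copy_len: int = 36
    tandem_copies: int = 9
    tandem_copy_len: int = 96
    collagen_probs_focal: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.20, 3: 0.65, 4: 0.10}
    )
    collagen_probs_other: dict[int, float] = field(default_factory=lambda: {3: 1.0})
    tandem_probs_focal: dict[int, float] = field(
        default_factory=lambda: {5: 0.05, 6: 0.10, 7: 0.15, 8: 0.55, 9: 0.15}
    )
    tandem_probs_other: dict[int, float] = field(
        default_factory=lambda: {7: 0.15, 8: 0.75, 9: 0.10}
    )

    # other indels
    n_coding_point_indels: int = 3
    coding_point_indel_focal_bias: float = 0.8
    n_intron_indels: int = 2

    # planted gene conversion
    n_whole_copy_conversions: int = 0
    n_phase_shift_conversions: int = 0
    conversion_window: int = 30

    # clone sequencing
    clone_error_rate: float = 0.00128
    clones_min: int = 6
    clones_max: int = 10

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_individuals) < 1:
            raise ValueError("need at least one individual per population")
        for name, probs in (
            ("collagen_probs_focal", self.collagen_probs_focal),
            ("collagen_probs_other", self.collagen_probs_other),
            ("tandem_probs_focal", self.tandem_probs_focal),
            ("tandem_probs_other", self.tandem_probs_other),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.collagen_copy_len % 3 or self.tandem_copy_len % 3:
            raise ValueError("repeat copy lengths must be codon multiples")
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1 and self.p0 + self.p1 <= 1):
            raise ValueError("invalid site-class proportions")


@dataclass
class TruthTable:
    tree_newick: str
    site_classes: list[int]  # per codon: 0, 1, 2 (=2a), 3 (=2b)
    selected_sites: list[int]  # 1-based codon indices in classes 2a/2b
    coding_indel_types: list[tuple[int, int]]
    intron_indel_types: list[tuple[int, int]]
    copy_numbers: dict[str, dict[str, int]]  # allele -> domain -> count
    conversion_events: list[dict]
    clone_error_rate: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TruthTable":
        d = json.loads(s)
        d["coding_indel_types"] = [tuple(x) for x in d["coding_indel_types"]]
        d["intron_indel_types"] = [tuple(x) for x in d["intron_indel_types"]]
        return cls(**d)


@dataclass
class SyntheticDataset:
    aln: PopAlignment
    tree: dendropy.Tree
    ltree: LabeledTree
    truth: TruthTable
    domain_spans: list[tuple[str, int, int, int]]
    clone_sets: list[CloneSet]
    config: SimConfig


# ---------------------------------------------------------------------------
# Genealogy
# ---------------------------------------------------------------------------

def simulate_genealogy(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dendropy.Tree, dict[str, tuple[str, str]]]:
    """Two-population structured-coalescent gene tree with labeled tips.

    Branch lengths are expected substitutions per codon: generation-scaled
    msprime times multiplied by ``subs_per_generation``, then (optionally)
    rescaled so the total tree length equals ``target_tree_length``.
    Returns the rooted tree and the allele -> (individual, population) map.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    focal, other = config.focal_population, [
        p for p in config.pop_names if p != config.focal_population
    ][0]
    n_focal = config.n_individuals[config.pop_names.index(focal)]
    n_other = config.n_individuals[config.pop_names.index(other)]

    dem = msprime.Demography()
    dem.add_population(name="focal", initial_size=config.ne_focal)
    dem.add_population(name="other", initial_size=config.ne_other)
    dem.add_population(
        name="anc", initial_size=0.5 * (config.ne_focal + config.ne_other)
    )
    if config.migration_rate > 0:
        dem.set_symmetric_migration_rate(["focal", "other"], config.migration_rate)
    dem.add_population_split(
        time=config.split_generations, derived=["focal", "other"], ancestral="anc"
    )
    ts = msprime.sim_ancestry(
        samples={"focal": n_focal, "other": n_other},
        demography=dem,
        ploidy=2,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    tree = ts.first()

    # name sample nodes: two alleles per diploid individual
    names: dict[int, str] = {}
    meta: dict[str, tuple[str, str]] = {}
    counters = {focal: 0, other: 0}
    pop_of = {0: focal, 1: other}
    seen_ind: dict[int, tuple[str, int]] = {}
    for node_id in ts.samples():
        node = ts.node(node_id)
        pop = pop_of[node.population]
        ind = node.individual
        if ind not in seen_ind:
            counters[pop] += 1
            seen_ind[ind] = (f"{pop}_{counters[pop]:02d}", 0)
        ind_name, k = seen_ind[ind]
        seen_ind[ind] = (ind_name, k + 1)
        allele = f"{ind_name}_a{k + 1}"
        names[node_id] = allele
        meta[allele] = (ind_name, pop)

    # convert to dendropy with scaled branch lengths
    factor = config.subs_per_generation
    if config.target_tree_length is not None:
        total_gen = sum(
            tree.branch_length(u) for u in tree.nodes() if u != tree.root
        )
        factor = config.target_tree_length / total_gen
    taxa = dendropy.TaxonNamespace(sorted(meta))
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(u: int) -> dendropy.Node:
        node = dendropy.Node()
        kids = tree.children(u)
        if not kids:
            node.taxon = taxa.get_taxon(names[u])
        for v in kids:
            child = build(v)
            child.edge.length = tree.branch_length(v) * factor
            node.add_child(child)
        return node

    dtree.seed_node = build(tree.root)
    dtree.is_rooted = True
    return dtree, meta


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

def _preorder_edges(ltree: LabeledTree):
    """Edges as (parent_idx, child_idx, length, foreground), root first."""
    n_tips = ltree.n_tips
    edges = []
    for k, kids in enumerate(ltree.children):
        parent = n_tips + k
        for child, t, fg in kids:
            edges.append((parent, child, t, fg))
    edges.sort(key=lambda e: -e[0])  # parents created later come first (root last index)
    return edges


def simulate_codon_alignment(
    ltree: LabeledTree,
    config: SimConfig,
    rng: np.random.Generator,
    codon_freqs: np.ndarray | None = None,
) -> tuple[dict[str, str], np.ndarray]:
    """Evolve codon sites along the labeled tree under the branch-site mix.

    Site classes are drawn from (p0, p1, p2a, p2b); classes 2a/2b switch to
    omega2 on foreground branches. Uses the same generators as the
    inference code, so no stop codons are ever emitted. Returns tip
    sequences (nucleotide strings) and the per-site true class (0,1,2,3).
    """
    pi = (
        np.full(N_STATES, 1.0 / N_STATES)
        if codon_freqs is None
        else np.asarray(codon_freqs, float)
    )
    n = config.n_codons
    p2 = 1.0 - config.p0 - config.p1
    p01 = config.p0 + config.p1
    w = np.array(
        [config.p0, config.p1, p2 * config.p0 / p01, p2 * config.p1 / p01]
    )
    classes = rng.choice(4, size=n, p=w)

    omega_of = {
        (0, False): config.omega0,
        (0, True): config.omega0,
        (1, False): 1.0,
        (1, True): 1.0,
        (2, False): config.omega0,
        (2, True): config.omega2,
        (3, False): 1.0,
        (3, True): config.omega2,
    }
    models: dict[float, _SpectralModel] = {}

    def model(omega: float) -> _SpectralModel:
        if omega not in models:
            models[omega] = _SpectralModel(config.kappa, omega, pi)
        return models[omega]

    n_nodes = ltree.n_tips + len(ltree.children)
    states = np.empty((n_nodes, n), dtype=np.int64)
    root = n_nodes - 1
    states[root] = rng.choice(N_STATES, size=n, p=pi)

    edges = _preorder_edges(ltree)
    for parent, child, t, fg in edges:
        child_states = np.empty(n, dtype=np.int64)
        for cls in np.unique(classes):
            mask = classes == cls
            omega = omega_of[(int(cls), bool(fg))]
            p = model(omega).p_matrix(t)
            p = p / p.sum(axis=1, keepdims=True)
            rows = p[states[parent][mask]]
            u = rng.random(mask.sum())
            child_states[mask] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
        states[child] = np.minimum(child_states, N_STATES - 1)

    seqs = {
        name: "".join(CODONS[s] for s in states[i])
        for i, name in enumerate(ltree.tip_names)
    }
    return seqs, classes


# ---------------------------------------------------------------------------
# Intron (HKY) simulation
# ---------------------------------------------------------------------------

def _hky_p(kappa: float, t: float) -> np.ndarray:
    """HKY transition matrix with uniform base frequencies, unit rate."""
    q = np.full((4, 4), 1.0)
    # order A C G T; transitions A<->G (0,2) and C<->T (1,3)
    q[0, 2] = q[2, 0] = kappa
    q[1, 3] = q[3, 1] = kappa
    np.fill_diagonal(q, 0.0)
    q *= 0.25
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -0.25 * np.trace(q)
    q /= rate
    from scipy.linalg import expm

    return expm(q * t)


def simulate_nucleotide_alignment(
    ltree: LabeledTree, length: int, kappa: float, rng: np.random.Generator
) -> dict[str, str]:
    """Neutral HKY sequences along the tree (branch lengths per codon / 3)."""
    n_nodes = ltree.n_tips + len(ltree.children)
    states = np.empty((n_nodes, length), dtype=np.int64)
    root = n_nodes - 1
    states[root] = rng.integers(0, 4, size=length)
    for parent, child, t, _fg in _preorder_edges(ltree):
        p = _hky_p(kappa, t / 3.0)
        rows = p[states[parent]]
        u = rng.random(length)
        states[child] = np.minimum((rows.cumsum(axis=1) < u[:, None]).sum(axis=1), 3)
    return {
        name: "".join(BASES[s] for s in states[i])
        for i, name in enumerate(ltree.tip_names)
    }


# ---------------------------------------------------------------------------
# Structural variation
# ---------------------------------------------------------------------------

def _sample_from(probs: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(probs)
    return int(rng.choice(keys, p=[probs[k] for k in keys]))


def inject_structural_variation(
    coding: dict[str, str],
    meta: dict[str, tuple[str, str]],
    config: SimConfig,
    rng: np.random.Generator,
    ltree: LabeledTree | None = None,
) -> tuple[dict[str, str], list[Region], list[tuple[str, int, int, int]], dict]:
    """Overlay repeat copy-number indels, small indels and the intron.

    The coding alignment is laid out as
    [nonrepeat | collagen copies | nonrepeat | tandem copies | nonrepeat];
    per-allele copy counts are drawn from per-population distributions and
    realized as gap runs over the last deleted copy spans (indels aligned
    to copy boundaries). A neutral intron (HKY) is appended, with a small
    number of planted intron deletion types. Returns the full alignment,
    region map, domain-span table, and a truth dict.
    """
    n_nt = 3 * config.n_codons
    col_len = config.collagen_copies * config.collagen_copy_len
    tan_len = config.tandem_copies * config.tandem_copy_len
    nonrep = n_nt - col_len - tan_len
    if nonrep < 90:
        raise ValueError("n_codons too small for the configured repeat domains")
    pre = (nonrep // 3) - ((nonrep // 3) % 3)
    mid = pre
    col_start = pre + 1
    tan_start = pre + col_len + mid + 1
    domain_spans = []
    for k in range(config.collagen_copies):
        s = col_start + k * config.collagen_copy_len
        domain_spans.append(("collagen", k + 1, s, s + config.collagen_copy_len - 1))
    for k in range(config.tandem_copies):
        s = tan_start + k * config.tandem_copy_len
        domain_spans.append(("tandem", k + 1, s, s + config.tandem_copy_len - 1))

    focal = config.focal_population
    rows = {a: list(seq) for a, seq in coding.items()}
    copy_numbers: dict[str, dict[str, int]] = {}
    coding_types: set[tuple[int, int]] = set()
    alleles = list(rows)

    for a in alleles:
        pop = meta[a][1]
        is_focal = pop == focal
        n_col = _sample_from(
            config.collagen_probs_focal if is_focal else config.collagen_probs_other,
            rng,
        )
        n_tan = _sample_from(
            config.tandem_probs_focal if is_focal else config.tandem_probs_other, rng
        )
        n_col = min(n_col, config.collagen_copies)
        n_tan = min(n_tan, config.tandem_copies)
        copy_numbers[a] = {"collagen": n_col, "tandem": n_tan}
        if n_col < config.collagen_copies:
            s = col_start + n_col * config.collagen_copy_len
            e = col_start + col_len - 1
            for i in range(s - 1, e):
                rows[a][i] = "-"
            coding_types.add((s, e))
        if n_tan < config.tandem_copies:
            s = tan_start + n_tan * config.tandem_copy_len
            e = tan_start + tan_len - 1
            for i in range(s - 1, e):
                rows[a][i] = "-"
            coding_types.add((s, e))

    # small coding indels in the nonrepeat tail, concentrated in the focal pop
    tail_start = tan_start + tan_len
    tail_end = n_nt
    focal_alleles = [a for a in alleles if meta[a][1] == focal]
    other_alleles = [a for a in alleles if meta[a][1] != focal]
    point_positions = []
    pos = tail_start + 15
    for _ in range(config.n_coding_point_indels):
        length = int(rng.integers(1, 4)) * 3
        if pos + length > tail_end - 6:
            break
        point_positions.append((pos, pos + length - 1))
        pos += length + 30
    for s, e in point_positions:
        n_car = int(rng.integers(1, 6))
        pool = (
            focal_alleles
            if rng.random() < config.coding_point_indel_focal_bias
            else other_alleles
        ) or alleles
        for a in rng.choice(pool, size=min(n_car, len(pool)), replace=False):
            for i in range(s - 1, e):
                rows[a][i] = "-"
        coding_types.add((s, e))

    # intron
    intron_types: set[tuple[int, int]] = set()
    if config.intron_length > 0:
        if ltree is None:
            raise ValueError("ltree is required to simulate the intron")
        intron = simulate_nucleotide_alignment(
            ltree, config.intron_length, config.kappa, rng
        )
        for a in alleles:
            rows[a].extend(intron[a])
        pos = n_nt + 40
        for _ in range(config.n_intron_indels):
            length = int(rng.integers(2, 12))
            if pos + length > n_nt + config.intron_length - 10:
                break
            s, e = pos, pos + length - 1
            n_car = int(rng.integers(1, 5))
            for a in rng.choice(alleles, size=min(n_car, len(alleles)), replace=False):
                for i in range(s - 1, e):
                    rows[a][i] = "-"
            intron_types.add((s, e))
            pos += length + 60

    # planted gene conversion (after all indels, on alleles with full copies)
    conversions: list[dict] = []
    full = [a for a in alleles if copy_numbers[a]["tandem"] == config.tandem_copies]
    for _ in range(config.n_whole_copy_conversions):
        if not full:
            break
        a = str(rng.choice(sorted(full)))
        recipient, donor = 1, 3
        # overwrite with the donor-paralog consensus (same majority rule and
        # tie-break as the conversion detector) across alleles carrying it
        d_s = tan_start + (donor - 1) * config.tandem_copy_len
        d_e = d_s + config.tandem_copy_len - 1
        donors = [
            x
            for x in alleles
            if copy_numbers[x]["tandem"] >= donor
            and "-" not in rows[x][d_s - 1 : d_e]
        ]
        cols = []
        for j in range(config.tandem_copy_len):
            states = [rows[x][d_s - 1 + j] for x in donors]
            counts = {s: states.count(s) for s in set(states)}
            top = max(counts.values())
            cols.append(sorted(s for s, c in counts.items() if c == top)[0])
        r_s = tan_start + (recipient - 1) * config.tandem_copy_len
        for j, c in enumerate(cols):
            rows[a][r_s - 1 + j] = c
        conversions.append(
            {
                "allele_id": a,
                "domain": "tandem",
                "copy_index": recipient,
                "donor_copy_index": donor,
                "kind": "whole_copy",
            }
        )
        full = [x for x in full if x != a]
    for _ in range(config.n_phase_shift_conversions):
        if not full:
            break
        a = str(rng.choice(sorted(full)))
        b = config.tandem_copies - 2  # boundary between copies b and b+1
        w = config.conversion_window
        half = w // 2
        src = tan_start + b * config.tandem_copy_len - half + config.tandem_copy_len
        dst = tan_start + b * config.tandem_copy_len - half
        for j in range(w):
            rows[a][dst - 1 + j] = rows[a][src - 1 + j]
        conversions.append(
            {
                "allele_id": a,
                "domain": "tandem",
                "copy_index": b,
                "donor_copy_index": b + 1,
                "kind": "phase_shift",
            }
        )
        full = [x for x in full if x != a]

    full_len = n_nt + config.intron_length
    regions = [Region("coding", 1, n_nt, "coding")]
    if config.intron_length > 0:
        regions.append(Region("intron", n_nt + 1, full_len, "intron"))
    seqs = {a: "".join(r) for a, r in rows.items()}
    truth = {
        "coding_indel_types": sorted(coding_types),
        "intron_indel_types": sorted(intron_types),
        "copy_numbers": copy_numbers,
        "conversions": conversions,
    }
    return seqs, regions, domain_spans, truth


# ---------------------------------------------------------------------------
# Clone reads
# ---------------------------------------------------------------------------

def simulate_clone_reads(
    alleles: dict[str, str],
    meta: dict[str, tuple[str, str]],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[CloneSet]:
    """Clone sets per individual: 6-10 clones split between its alleles,
    with iid per-base errors at the configured rate (gaps are never hit)."""
    by_ind: dict[str, list[str]] = {}
    for a, (ind, _pop) in meta.items():
        if a in alleles:
            by_ind.setdefault(ind, []).append(a)
    out = []
    for ind in sorted(by_ind):
        allele_ids = sorted(by_ind[ind])
        n_clones = int(rng.integers(config.clones_min, config.clones_max + 1))
        assignment: dict[str, int] = {}
        clones: list[tuple[str, str]] = []
        counts = [n_clones // 2, n_clones - n_clones // 2] if len(allele_ids) == 2 else [
            n_clones
        ]
        cid = 0
        for k, (aid, cnt) in enumerate(zip(allele_ids, counts), start=1):
            template = alleles[aid]
            arr = np.frombuffer(template.encode(), dtype="S1")
            base_pos = np.where(np.isin(arr, [b"A", b"C", b"G", b"T"]))[0]
            for _ in range(cnt):
                cid += 1
                clone = list(template)
                if config.clone_error_rate > 0 and len(base_pos):
                    hits = base_pos[
                        rng.random(len(base_pos)) < config.clone_error_rate
                    ]
                    for h in hits:
                        alts = [b for b in BASES if b != clone[h]]
                        clone[h] = alts[int(rng.integers(0, 3))]
                name = f"{ind}_c{cid}"
                clones.append((name, "".join(clone)))
                assignment[name] = k
        out.append(CloneSet(ind, clones, assignment))
    return out


# ---------------------------------------------------------------------------
# End-to-end dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig, with_clones: bool = False) -> SyntheticDataset:
    """Full synthetic dataset: genealogy, coding + intron alignment with
    structural variation, region/domain maps, truth table and (optionally)
    clone reads."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree, meta = simulate_genealogy(config, rng)
    ltree = label_foreground(tree, meta, config.focal_population)
    coding, classes = simulate_codon_alignment(ltree, config, rng)
    seqs, regions, domain_spans, struct = inject_structural_variation(
        coding, meta, config, rng, ltree=ltree
    )
    aln = PopAlignment(seqs, meta, regions, breakpoint=None)
    truth = TruthTable(
        tree_newick=tree.as_string(schema="newick").strip(),
        site_classes=[int(c) for c in classes],
        selected_sites=[int(i) + 1 for i in np.where(classes >= 2)[0]],
        coding_indel_types=struct["coding_indel_types"],
        intron_indel_types=struct["intron_indel_types"],
        copy_numbers=struct["copy_numbers"],
        conversion_events=struct["conversions"],
        clone_error_rate=config.clone_error_rate,
    )
    clone_sets = (
        simulate_clone_reads(aln.alleles, meta, config, rng) if with_clones else []
    )
    return SyntheticDataset(aln, tree, ltree, truth, domain_spans, clone_sets, config)


# ---------------------------------------------------------------------------
# In-study worked-example fixtures
# ---------------------------------------------------------------------------

def worked_example_fixtures() -> dict:
    """Published worked-example inputs as plain data.

    These are the study's printed numbers used as *inputs* by acceptance
    checks: the indel-density counts and lengths, the positively selected
    codon table, modal repeat copy numbers, the copy-number covariation
    marginals, and headline polymorphism/structure statistics.
    """
    table1 = [
        # (codon, flagged_populations, P_sandspit, P_bamfield)
        (124, ["bamfield"], 0.006, 1.0),
        (175, ["bamfield"], 0.019, 1.0),
        (176, ["bamfield"], 0.006, 0.997),
        (365, ["bamfield"], 0.693, 0.995),
        (631, ["bamfield"], 0.076, 0.998),
        (653, ["bamfield"], 0.024, 0.972),
        (805, ["bamfield"], 0.025, 0.973),
        (842, ["bamfield", "sandspit"], 0.999, 0.999),
        (461, ["sandspit"], 0.988, 0.001),
        (493, ["sandspit"], 0.999, 0.001),
        (640, ["sandspit"], 0.994, 0.056),
    ]
    return {
        "indel_density": {
            "n_coding": 22,
            "len_coding": 2850,
            "n_intron": 2,
            "len_intron": 1285,
            "reported_chi2": 4.76,
        },
        "selected_sites_table": [
            {
                "codon": c,
                "populations": pops,
                "p_sandspit": ps,
                "p_bamfield": pb,
            }
            for c, pops, ps, pb in table1
        ],
        "reported_site_counts": {"bamfield": 9, "sandspit": 4, "total": 11},
        "repeat_copy_numbers": {
            "collagen": {"min": 1, "max": 4, "mode": 3},
            "tandem": {"min": 3, "max": 9, "mode": 8},
        },
        "copy_number_covariation": {
            "n_alleles": 80,
            "collagen_variants": 15,
            "tandem_variants": 10,
            "both": 2,
            "reported_chi2": 0.1382,
        },
        "structure": {
            "phi_st": 0.220,
            "phi_prime_maxdist": 0.462,
            "phi_prime_fraglen": 0.454,
        },
        "polymorphism": {
            "alignment_length": 4134,
            "n_variable_sites": 196,
            "n_unique_alleles": 68,
            "n_sequences": 88,
            "coding_length": 2853,
            "coding_variable_sites": 70,
            "aa_polymorphisms": 46,
            "clone_error_rate": 0.00128,
        },
    }


def fixtures_roundtrip(fixtures: dict) -> dict:
    """Serialize fixtures to JSON and back (lossless by construction)."""
    return json.loads(json.dumps(fixtures))
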