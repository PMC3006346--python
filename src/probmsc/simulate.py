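"""Multispecies-coalescent simulator for the five-taxon elephantid design.

Generates unlinked multilocus data under the fixed species topology
(((F,S),(A,M)),O) with instantaneous splits and constant population sizes
per interval — the demographic model whose parameters the inference module
estimates.  Everything is internally in mutation units: split times tau
(split time x mutation rate) and scaled sizes theta (4 N mu g, the expected
heterozygosity of two chromosomes from that interval).  Within an interval
each pair of lineages coalesces at rate 2/theta, so k lineages wait an
exponential time with rate k(k-1)/theta between coalescences.  Conversions
to years and diploid sizes happen only at reporting time, through the
generation time (31 y) and a user-supplied mutation rate.

The default parameter values are the study's fitted point estimates; the
remaining knobs emulate the real data's design: 375 unlinked loci of mean
length 106 bp (minimum 50), two chromosomes per elephantid taxon, a single
haploid mastodon, and an ancient-DNA damage channel that flips mastodon
C->T and G->A to mimic cytosine-deamination errors in the 1-fold shotgun
mastodon consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .alignments import LocusAlignment
from .taxa import Taxon

#: Leaf order of every simulated genealogy (bit i of a node's leaf mask).
LEAF_LABELS = ("F1", "F2", "S1", "S2", "A1", "A2", "M1", "M2", "O")
LEAF_TAXON = {
    "F1": Taxon.FOREST, "F2": Taxon.FOREST,
    "S1": Taxon.SAVANNA, "S2": Taxon.SAVANNA,
    "A1": Taxon.ASIAN, "A2": Taxon.ASIAN,
    "M1": Taxon.MAMMOTH, "M2": Taxon.MAMMOTH,
    "O": Taxon.MASTODON,
}

BASES = "ACGT"


@dataclass(frozen=True)
class SpeciesTreeModel:
    """Fixed-topology species tree with interval split times and sizes.

    Defaults are the study's fitted point estimates (mutation units).  The
    root interval (elephantid-mastodon) is poorly constrained by data of
    this design; its defaults place the split at ~27 Mya under the reference
    mutation rate implied by calibrating the African-Eurasian split to
    6.6 Mya.
    """

    tau_fs: float = 0.00135
    tau_am: float = 0.00131
    tau_loxeur: float = 0.00220
    tau_root: float = 0.009
    theta_f: float = 0.00238
    theta_s: float = 0.00068
    theta_a: float = 0.00113
    theta_m: float = 0.00093
    theta_fs: float = 0.00263
    theta_am: float = 0.00181
    theta_loxeur: float = 0.00259
    theta_root: float = 0.00259
    generation_years: float = 31.0
    mu_per_year: float = 3.33e-10

    def __post_init__(self) -> None:
        if not (0 < self.tau_fs < self.tau_loxeur < self.tau_root):
            raise ValueError("need 0 < tau_fs < tau_loxeur < tau_root")
        if not (0 < self.tau_am < self.tau_loxeur):
            raise ValueError("need 0 < tau_am < tau_loxeur")
        for name in ("theta_f", "theta_s", "theta_a", "theta_m",
                     "theta_fs", "theta_am", "theta_loxeur", "theta_root"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def theta_of(self, pop: str) -> float:
        return getattr(self, f"theta_{pop}")

    def split_time_mya(self, tau: float) -> float:
        """Convert a tau to Mya under the model's reference mutation rate."""
        return tau / self.mu_per_year / 1e6

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "tau_fs", "tau_am", "tau_loxeur", "tau_root",
            "theta_f", "theta_s", "theta_a", "theta_m",
            "theta_fs", "theta_am", "theta_loxeur", "theta_root",
            "generation_years", "mu_per_year")}


def _pair_intervals(model: SpeciesTreeModel, x: Taxon, y: Taxon
                    ) -> tuple[float, list[tuple[float, float]]]:
    """(merge time, [(theta, interval width), ...]) for a chromosome pair;
    the last interval is unbounded."""
    m = model
    d_lox = m.tau_root - m.tau_loxeur
    if x == y:
        start = 0.0
        chain = {
            Taxon.FOREST: [(m.theta_f, m.tau_fs), (m.theta_fs, m.tau_loxeur - m.tau_fs)],
            Taxon.SAVANNA: [(m.theta_s, m.tau_fs), (m.theta_fs, m.tau_loxeur - m.tau_fs)],
            Taxon.ASIAN: [(m.theta_a, m.tau_am), (m.theta_am, m.tau_loxeur - m.tau_am)],
            Taxon.MAMMOTH: [(m.theta_m, m.tau_am), (m.theta_am, m.tau_loxeur - m.tau_am)],
        }[x]
    elif Taxon.MASTODON in (x, y):
        return m.tau_root, [(m.theta_root, math.inf)]
    else:
        pair = frozenset((x, y))
        if pair == frozenset((Taxon.FOREST, Taxon.SAVANNA)):
            start = m.tau_fs
            chain = [(m.theta_fs, m.tau_loxeur - m.tau_fs)]
        elif pair == frozenset((Taxon.ASIAN, Taxon.MAMMOTH)):
            start = m.tau_am
            chain = [(m.theta_am, m.tau_loxeur - m.tau_am)]
        else:
            start = m.tau_loxeur
            chain = []
    chain = chain + [(m.theta_loxeur, d_lox), (m.theta_root, math.inf)]
    return start, chain


def expected_pairwise_divergence(model: SpeciesTreeModel, x: Taxon | str,
                                 y: Taxon | str) -> float:
    """Closed-form expected per-site divergence of one chromosome from each
    taxon (x == y gives expected per-site heterozygosity).

    The pair merges into a common population at the split time tau and then
    coalesces through successive intervals: within an interval of width d
    and size theta it coalesces at rate 2/theta, contributing
    E[min(T, d)] = (theta/2)(1 - exp(-2 d / theta)) of expected extra time
    and escaping with probability exp(-2 d / theta).  Divergence is twice
    the expected coalescence time.
    """
    x, y = Taxon(x), Taxon(y)
    start, chain = _pair_intervals(model, x, y)
    extra = 0.0
    reach = 1.0
    for theta, width in chain:
        if math.isinf(width):
            extra += reach * theta / 2.0
            break
        esc = math.exp(-2.0 * width / theta)
        # E[min(T, width)] = (theta/2)(1 - esc) already includes the
        # width * esc plateau of escaping pairs
        extra += reach * (theta / 2.0) * (1.0 - esc)
        reach *= esc
    return 2.0 * (start + extra)


class GeneTree:
    """Coalescent genealogy: node times (mutation units), children, leaf masks."""

    __slots__ = ("time", "children", "parent", "mask", "n_leaves")

    def __init__(self, n_leaves: int) -> None:
        self.n_leaves = n_leaves
        self.time: list[float] = [0.0] * n_leaves
        self.children: list[tuple[int, int] | None] = [None] * n_leaves
        self.parent: list[int] = [-1] * n_leaves
        self.mask: list[int] = [1 << i for i in range(n_leaves)]

    def add_node(self, time: float, a: int, b: int) -> int:
        idx = len(self.time)
        self.time.append(time)
        self.children.append((a, b))
        self.parent.append(-1)
        self.parent[a] = idx
        self.parent[b] = idx
        self.mask.append(self.mask[a] | self.mask[b])
        return idx

    @property
    def root(self) -> int:
        return len(self.time) - 1

    def branches(self) -> list[tuple[int, float]]:
        """(node, length-to-parent) for every non-root node."""
        return [(i, self.time[self.parent[i]] - self.time[i])
                for i in range(len(self.time)) if self.parent[i] != -1]

    def leaf_names(self, node: int) -> frozenset[str]:
        m = self.mask[node]
        return frozenset(LEAF_LABELS[i] for i in range(self.n_leaves) if m >> i & 1)

    def tmrca(self) -> float:
        return self.time[self.root]

    def pair_tmrca(self, i: int, j: int) -> float:
        """Time of the most recent common ancestor of two leaves."""
        want = (1 << i) | (1 << j)
        best = math.inf
        for k in range(self.n_leaves, len(self.time)):
            if self.mask[k] & want == want:
                best = min(best, self.time[k])
        return best


def _coalesce_interval(
    lineages: list[int],
    theta: float,
    t_start: float,
    t_end: float,
    tree: GeneTree,
    rng: np.random.Generator,
) -> list[int]:
    """Run the coalescent among ``lineages`` over [t_start, t_end).

    k lineages coalesce pairwise at total rate k(k-1)/theta per mutation
    unit; t_end = inf runs to the interval MRCA.
    """
    t = t_start
    lineages = list(lineages)
    while len(lineages) >= 2:
        k = len(lineages)
        t += rng.exponential(theta / (k * (k - 1)))
        if t >= t_end:
            break
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        node = tree.add_node(t, a, b)
        lineages = [l for l in lineages if l not in (a, b)] + [node]
    return lineages


def simulate_gene_tree(model: SpeciesTreeModel, rng: np.random.Generator) -> GeneTree:
    """One genealogy for 2 chromosomes per elephantid plus the mastodon."""
    tree = GeneTree(len(LEAF_LABELS))
    f, s, a, m, o = [0, 1], [2, 3], [4, 5], [6, 7], [8]
    f = _coalesce_interval(f, model.theta_f, 0.0, model.tau_fs, tree, rng)
    s = _coalesce_interval(s, model.theta_s, 0.0, model.tau_fs, tree, rng)
    a = _coalesce_interval(a, model.theta_a, 0.0, model.tau_am, tree, rng)
    m = _coalesce_interval(m, model.theta_m, 0.0, model.tau_am, tree, rng)
    fs = _coalesce_interval(f + s, model.theta_fs, model.tau_fs, model.tau_loxeur, tree, rng)
    am = _coalesce_interval(a + m, model.theta_am, model.tau_am, model.tau_loxeur, tree, rng)
    lox = _coalesce_interval(fs + am, model.theta_loxeur, model.tau_loxeur,
                             model.tau_root, tree, rng)
    root = _coalesce_interval(lox + o, model.theta_root, model.tau_root, math.inf, tree, rng)
    assert len(root) == 1
    return tree


def drop_mutations(
    tree: GeneTree,
    length: int,
    mode: Literal["infinite_sites", "jc69"],
    rng: np.random.Generator,
    locus_id: str = "L001",
) -> tuple[LocusAlignment, pd.DataFrame]:
    """Place mutations on a genealogy and emit sequences plus a ledger.

    Expected mutations on a branch are branch length (mutation units) times
    the locus length.  ``infinite_sites`` gives every mutation a fresh
    column; ``jc69`` evolves each column independently with equal exchange
    rates (allowing recurrent/back mutation).  The ledger records every
    mutation event: position, derived-carrying leaf set, from/to bases.
    """
    n_leaves = tree.n_leaves
    seqs = [[None] * length for _ in range(n_leaves)]
    ledger_rows: list[dict] = []
    if mode == "infinite_sites":
        ancestral = rng.integers(0, 4, size=length)
        derived_state = [None] * length
        branches = tree.branches()
        counts = rng.poisson([max(bl, 0.0) * length for _, bl in branches])
        total = int(counts.sum())
        if total > length:
            raise ValueError(
                f"locus {locus_id}: {total} mutations exceed {length} columns; "
                "infinite-sites assumption broken (branch lengths too long)")
        cols = rng.choice(length, size=total, replace=False)
        ci = 0
        for (node, _bl), nmut in zip(branches, counts):
            for _ in range(int(nmut)):
                col = int(cols[ci]); ci += 1
                anc = BASES[ancestral[col]]
                der = BASES[(ancestral[col] + int(rng.integers(1, 4))) % 4]
                derived_state[col] = (tree.mask[node], der)
                ledger_rows.append({"locus_id": locus_id, "pos": col + 1,
                                    "leaves": ",".join(sorted(tree.leaf_names(node))),
                                    "anc": anc, "der": der})
        for leaf in range(n_leaves):
            bit = 1 << leaf
            row = seqs[leaf]
            for col in range(length):
                ds = derived_state[col]
                if ds is not None and ds[0] & bit:
                    row[col] = ds[1]
                else:
                    row[col] = BASES[ancestral[col]]
    elif mode == "jc69":
        order = _preorder(tree)
        root_states = rng.integers(0, 4, size=length)
        states = {tree.root: root_states}
        for node in order:
            parent = tree.parent[node]
            if parent == -1:
                continue
            bl = max(tree.time[parent] - tree.time[node], 0.0)
            cur = states[parent].copy()
            nmut = rng.poisson(bl, size=length)
            for col in np.nonzero(nmut)[0]:
                base = int(cur[col])
                for _ in range(int(nmut[col])):
                    new = (base + int(rng.integers(1, 4))) % 4
                    ledger_rows.append({
                        "locus_id": locus_id, "pos": int(col) + 1,
                        "leaves": ",".join(sorted(tree.leaf_names(node))),
                        "anc": BASES[base], "der": BASES[new]})
                    base = new
                cur[col] = base
            states[node] = cur
        for leaf in range(n_leaves):
            seqs[leaf] = [BASES[b] for b in states[leaf]]
    else:
        raise ValueError(f"unknown mutation mode {mode!r}")
    sequences = {LEAF_LABELS[i]: "".join(seqs[i]) for i in range(n_leaves)}
    ledger = pd.DataFrame(ledger_rows, columns=["locus_id", "pos", "leaves", "anc", "der"])
    aln = LocusAlignment(locus_id, sequences, dict(LEAF_TAXON), length)
    return aln, ledger


def _preorder(tree: GeneTree) -> list[int]:
    order: list[int] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        order.append(node)
        ch = tree.children[node]
        if ch is not None:
            stack.extend(ch)
    return order


def apply_damage(
    alignment: LocusAlignment,
    rate: float,
    rng: np.random.Generator,
    taxon: Taxon = Taxon.MASTODON,
) -> LocusAlignment:
    """Ancient-DNA damage: flip C->T and G->A independently at ``rate`` in
    the (haploid shotgun) sequences of ``taxon``; other taxa untouched."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("damage rate must be in [0, 1]")
    new_seqs = dict(alignment.sequences)
    for label in alignment.samples_for(taxon):
        seq = list(new_seqs[label])
        hits = rng.random(len(seq)) < rate
        for i in np.nonzero(hits)[0]:
            if seq[i] == "C":
                seq[i] = "T"
            elif seq[i] == "G":
                seq[i] = "A"
        new_seqs[label] = "".join(seq)
    return LocusAlignment(alignment.locus_id, new_seqs,
                          dict(alignment.sample_to_taxon), alignment.length)


@dataclass
class SimulatedDataset:
    """Loci plus full generating truth (genealogies, mutation ledger, model)."""

    loci: list[LocusAlignment]
    gene_trees: list[GeneTree]
    ledger: pd.DataFrame
    model: SpeciesTreeModel
    seed: int
    damage_rate: float = 0.0

    @property
    def total_bp(self) -> int:
        return sum(l.length for l in self.loci)


def simulate_dataset(
    model: SpeciesTreeModel | None = None,
    n_loci: int = 375,
    mean_length: float = 106.0,
    min_length: int = 50,
    mode: Literal["infinite_sites", "jc69"] = "infinite_sites",
    damage_rate: float = 0.05,
    seed: int = 0,
    lengths: Iterable[int] | None = None,
) -> SimulatedDataset:
    """Simulate a full multilocus study: genealogies, mutations, damage.

    Locus lengths are ``min_length + Poisson(mean_length - min_length)``
    unless an explicit length list is given.  Each locus runs on its own
    substream spawned from ``seed``, so outputs are reproducible and
    insensitive to generation order.
    """
    model = model or SpeciesTreeModel()
    root_ss = np.random.SeedSequence(seed)
    streams = root_ss.spawn(n_loci + 1)
    len_rng = np.random.default_rng(streams[-1])
    if lengths is None:
        lens = (min_length + len_rng.poisson(mean_length - min_length, size=n_loci)).astype(int)
    else:
        lens = np.asarray(list(lengths), dtype=int)
        if len(lens) != n_loci:
            raise ValueError("length list must match n_loci")
    loci: list[LocusAlignment] = []
    trees: list[GeneTree] = []
    ledgers: list[pd.DataFrame] = []
    for i in range(n_loci):
        rng = np.random.default_rng(streams[i])
        locus_id = f"L{i + 1:03d}"
        tree = simulate_gene_tree(model, rng)
        aln, ledger = drop_mutations(tree, int(lens[i]), mode, rng, locus_id=locus_id)
        if damage_rate > 0:
            aln = apply_damage(aln, damage_rate, rng)
        loci.append(aln)
        trees.append(tree)
        ledgers.append(ledger)
    ledger = (pd.concat(ledgers, ignore_index=True) if ledgers
              else pd.DataFrame(columns=["locus_id", "pos", "leaves", "anc", "der"]))
    return SimulatedDataset(loci=loci, gene_trees=trees, ledger=ledger,
                            model=model, seed=seed, damage_rate=damage_rate)
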