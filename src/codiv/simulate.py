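"""Synthetic co-diversification scenarios with known ground truth.

A scenario couples a host tree (Yule process, rescaled to a chosen
root-to-tip depth in substitutions/site) with a parasite tree that starts
as an exact copy — perfect co-divergence — and is then perturbed by a
chosen number of host shifts, each modeled as a subtree-prune-and-regraft
move of a single parasite tip onto a random branch (re-attached so the
tree stays ultrametric). Sequences evolve along both trees under TN93, and
parasite sequences are truncated to a mixture of 5'-anchored fragment
lengths emulating nested sequencing fragments sharing one forward primer.

Host and parasite tips carry the same names (t01, t02, ...): the true
association links one parasite tip to its namesake host tip, and the tips
moved by SPR are the planted host-shift links whose Procrustes residuals
the pipeline should flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .io import PAD, PartialAlignment, write_fasta_alignment, write_links

__all__ = [
    "Tn93Params",
    "Node",
    "Tree",
    "CoPhyloScenario",
    "DEFAULT_FRAGMENT_MIX",
    "sample_host_tree",
    "derive_parasite_tree",
    "evolve_sequences",
    "truncate_fragments",
    "simulate_scenario",
    "emit_scenario",
    "scenario_distances",
]

#: Fragment-length mixture: (length or None for full-length, probability).
#: Defaults emulate nested fragments of ~350 and ~530 bp among mostly
#: full-length sequences.
DEFAULT_FRAGMENT_MIX: tuple[tuple[Optional[int], float], ...] = (
    (350, 0.17),
    (530, 0.17),
    (None, 0.66),
)


@dataclass(frozen=True)
class Tn93Params:
    """TN93 substitution process: two transition rates (A<->G, C<->T), one
    transversion rate, and equilibrium base frequencies (A, C, G, T).
    The rate matrix is normalized to one expected substitution per unit
    branch length, so branch lengths are in substitutions/site.

    Defaults give a transition/transversion rate ratio of 4, typical for
    ribosomal markers.
    """

    rate_ag: float = 4.0
    rate_ct: float = 4.0
    rate_tv: float = 1.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if min(self.rate_ag, self.rate_ct, self.rate_tv) <= 0:
            raise ValueError("substitution rates must be positive")
        if len(self.freqs) != 4 or min(self.freqs) <= 0:
            raise ValueError("base frequencies must be four positive numbers")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")

    def rate_matrix(self) -> np.ndarray:
        """Normalized TN93 rate matrix, state order A, C, G, T."""
        pi = np.asarray(self.freqs, dtype=float)
        r = np.full((4, 4), self.rate_tv, dtype=float)
        r[0, 2] = r[2, 0] = self.rate_ag
        r[1, 3] = r[3, 1] = self.rate_ct
        q = r * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diagonal(q)))
        return q / mu

    def transition_matrix(self, t: float) -> np.ndarray:
        """Site transition probabilities P(t) = exp(Q t)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if t == 0.0:
            return np.eye(4)
        p = expm(self.rate_matrix() * t)
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Minimal rooted tree


@dataclass
class Node:
    name: Optional[str] = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(
            self.name, self.length, [c.copy() for c in self.children]
        )


@dataclass
class Tree:
    """Rooted tree with branch lengths in substitutions/site."""

    root: Node

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def nodes(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def tips(self) -> list[Node]:
        return [n for n in self.nodes() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def parent_map(self) -> dict[int, Node]:
        parents: dict[int, Node] = {}
        for n in self.nodes():
            for c in n.children:
                parents[id(c)] = n
        return parents

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths."""
        depth: dict[int, float] = {id(self.root): self.root.length}
        stack = [self.root]
        while stack:
            n = stack.pop()
            for c in n.children:
                depth[id(c)] = depth[id(n)] + c.length
                stack.append(c)
        return depth

    def scale(self, factor: float) -> None:
        for n in self.nodes():
            n.length *= factor

    def newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.10g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = n.name or ""
            return f"({inner}){label}:{n.length:.10g}"

        return fmt(self.root) + ";"


def sample_host_tree(n_tips: int, seed: int, depth: float = 0.15) -> Tree:
    """Yule (pure-birth) tree rescaled so every root-to-tip path equals
    ``depth`` substitutions/site. Tips are named t01, t02, ... left to right.
    """
    if n_tips < 4:
        raise ValueError("need at least 4 tips for a meaningful host tree")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(seed)
    root = Node(length=0.0)
    birth: dict[int, float] = {}
    active: list[Node] = []
    for _ in range(2):
        c = Node()
        root.children.append(c)
        birth[id(c)] = 0.0
        active.append(c)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        parent = active.pop(i)
        parent.length = t - birth[id(parent)]
        for _ in range(2):
            c = Node()
            parent.children.append(c)
            birth[id(c)] = t
            active.append(c)
    total = t + rng.exponential(1.0 / n_tips)
    for leaf in active:
        leaf.length = total - birth[id(leaf)]
    tree = Tree(root)
    if total > 0:
        tree.scale(depth / total)
        tree.root.length = 0.0
    else:  # pragma: no cover - exponential draws are a.s. positive
        tree.scale(0.0)
    if depth == 0:
        for n in tree.nodes():
            n.length = 0.0
    for i, leaf in enumerate(tree.tips()):
        leaf.name = f"t{i + 1:02d}"
    return tree


def _prune_tip(tree: Tree, tip: Node) -> Node:
    """Detach a tip, splicing out its parent. Returns the former sibling
    (whose edge must not receive the re-attachment: that would rebuild the
    original topology)."""
    parents = tree.parent_map()
    parent = parents.get(id(tip))
    if parent is None:
        raise ValueError("cannot prune the root")
    siblings = [c for c in parent.children if c is not tip]
    if len(siblings) != 1:
        raise ValueError("tip SPR requires a binary tree")
    sibling = siblings[0]
    grand = parents.get(id(parent))
    if grand is None:
        sibling.length = 0.0
        tree.root = sibling
    else:
        sibling.length += parent.length
        grand.children[grand.children.index(parent)] = sibling
    return sibling


def _regraft_tip(
    tree: Tree, tip: Node, exclude: Node, total_depth: float,
    rng: np.random.Generator,
) -> None:
    parents = tree.parent_map()
    candidates = [
        n for n in tree.nodes()
        if id(n) in parents and n is not exclude
    ]
    if not candidates:
        raise ValueError(
            "no branch available for re-attachment; use a larger tree or "
            "another seed"
        )
    target = candidates[int(rng.integers(len(candidates)))]
    u = float(rng.uniform())
    parent = parents[id(target)]
    depths = tree.depths()
    attach_depth = depths[id(target)] - (1.0 - u) * target.length
    mid = Node(length=u * target.length)
    target.length *= 1.0 - u
    parent.children[parent.children.index(target)] = mid
    mid.children = [target, tip]
    tip.length = max(total_depth - attach_depth, 0.0)


def derive_parasite_tree(
    host_tree: Tree, n_shifts: int, seed: int, rate_ratio: float = 1.0
) -> tuple[Tree, frozenset[str]]:
    """Parasite tree: a copy of the host tree perturbed by tip-SPR moves.

    Each of the ``n_shifts`` moves prunes a distinct random tip and
    regrafts it onto a random branch outside its former sibling's edge, so
    every move changes the topology; the moved tips are the planted host
    shifts. Branch lengths are first multiplied by ``rate_ratio``
    (parasite/host substitution rate) and the tree stays ultrametric.
    """
    n_tips = len(host_tree.tips())
    if not 0 <= n_shifts <= n_tips - 2:
        raise ValueError(f"n_shifts must be in [0, {n_tips - 2}]")
    if rate_ratio <= 0:
        raise ValueError("rate_ratio must be positive")
    tree = host_tree.copy()
    tree.scale(rate_ratio)
    rng = np.random.default_rng(seed)
    names = tree.tip_names()
    shifted = [names[i] for i in rng.choice(len(names), size=n_shifts, replace=False)]
    total_depth = max(tree.depths()[id(t)] for t in tree.tips())
    for name in shifted:
        tip = next(t for t in tree.tips() if t.name == name)
        sibling = _prune_tip(tree, tip)
        _regraft_tip(tree, tip, sibling, total_depth, rng)
    return tree, frozenset(shifted)


def evolve_sequences(
    tree: Tree, length: int, params: Tn93Params | None = None, seed: int = 0
) -> PartialAlignment:
    """Evolve sequences down a tree: root drawn from the equilibrium
    frequencies, each branch applying site-independent TN93 transition
    probabilities. Returns a full-coverage alignment, one record per tip.
    """
    if length < 100:
        raise ValueError("sequence length must be at least 100")
    params = params or Tn93Params()
    rng = np.random.default_rng(seed)
    pi = np.asarray(params.freqs)
    pmat_cache: dict[float, np.ndarray] = {}

    def pmat(t: float) -> np.ndarray:
        key = round(t, 12)
        if key not in pmat_cache:
            pmat_cache[key] = params.transition_matrix(t)
        return pmat_cache[key]

    def mutate(seq: np.ndarray, t: float) -> np.ndarray:
        if t == 0.0:
            return seq.copy()
        p = pmat(t)
        out = np.empty_like(seq)
        for s in range(4):
            idx = np.flatnonzero(seq == s)
            if idx.size:
                out[idx] = rng.choice(4, size=idx.size, p=p[s])
        return out

    root_seq = rng.choice(4, size=length, p=pi)
    tip_seqs: list[tuple[str, np.ndarray]] = []

    def walk(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf:
            tip_seqs.append((node.name, seq))
            return
        for child in node.children:
            walk(child, mutate(seq, child.length))

    walk(tree.root, mutate(root_seq, tree.root.length))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return PartialAlignment.from_sequences(
        (name, bases[seq].tobytes().decode("ascii")) for name, seq in tip_seqs
    )


def truncate_fragments(
    aln: PartialAlignment,
    length_mix: Sequence[tuple[Optional[int], float]] = DEFAULT_FRAGMENT_MIX,
    seed: int = 0,
) -> PartialAlignment:
    """Truncate sequences to 5'-anchored fragments drawn from a mixture.

    Each entry of ``length_mix`` is (fragment length, probability); a
    length of None keeps the sequence full. Coverage becomes [0, length)
    with the remainder padded — emulating nested sequencing fragments that
    all share the forward primer.
    """
    lengths = [l for l, _ in length_mix]
    probs = np.asarray([p for _, p in length_mix], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("fragment mixture probabilities must sum to 1")
    for l in lengths:
        if l is not None and l > aln.columns:
            raise ValueError(
                f"fragment length {l} exceeds alignment length {aln.columns}"
            )
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(lengths), size=len(aln), p=probs)
    pairs = []
    for label, seq, k in zip(aln.labels, aln.residues, draws):
        cut = lengths[k]
        if cut is None:
            pairs.append((label, seq))
        else:
            pairs.append((label, seq[:cut] + PAD * (aln.columns - cut)))
    return PartialAlignment.from_sequences(pairs)


@dataclass(frozen=True)
class CoPhyloScenario:
    """A complete synthetic co-diversification scenario with ground truth."""

    host_tree: Tree
    parasite_tree: Tree
    true_links: tuple[tuple[str, str], ...]
    shifted_links: tuple[tuple[str, str], ...]
    host_seqs: PartialAlignment
    parasite_seqs: PartialAlignment
    params: dict

    def __post_init__(self) -> None:
        if not set(self.shifted_links) <= set(self.true_links):
            raise ValueError("shifted links must be a subset of true links")


def simulate_scenario(
    n_tips: int = 16,
    n_shifts: int = 0,
    seed: int = 0,
    depth: float = 0.15,
    rate_ratio: float = 1.0,
    seq_length: int = 800,
    fragment_mix: Sequence[tuple[Optional[int], float]] = DEFAULT_FRAGMENT_MIX,
    tn93: Tn93Params | None = None,
) -> CoPhyloScenario:
    """Generate one scenario: trees, sequences, true and shifted links.

    All randomness derives from ``seed`` through fixed sub-streams, so the
    whole scenario is reproducible bit for bit. Hosts keep full-length
    sequences; parasites get the fragment-length mixture.
    """
    tn93 = tn93 or Tn93Params()
    subs = np.random.SeedSequence(seed).generate_state(5) % (2**31)
    host_tree = sample_host_tree(n_tips, seed=int(subs[0]), depth=depth)
    parasite_tree, shifted = derive_parasite_tree(
        host_tree, n_shifts, seed=int(subs[1]), rate_ratio=rate_ratio
    )
    host_seqs = evolve_sequences(host_tree, seq_length, tn93, seed=int(subs[2]))
    para_full = evolve_sequences(parasite_tree, seq_length, tn93, seed=int(subs[3]))
    parasite_seqs = truncate_fragments(para_full, fragment_mix, seed=int(subs[4]))
    names = host_tree.tip_names()
    true_links = tuple((n, n) for n in names)
    shifted_links = tuple((n, n) for n in names if n in shifted)
    params = {
        "n_tips": n_tips,
        "n_shifts": n_shifts,
        "seed": seed,
        "depth": depth,
        "rate_ratio": rate_ratio,
        "seq_length": seq_length,
        "fragment_mix": [[l, p] for l, p in fragment_mix],
        "tn93": {
            "rate_ag": tn93.rate_ag,
            "rate_ct": tn93.rate_ct,
            "rate_tv": tn93.rate_tv,
            "freqs": list(tn93.freqs),
        },
    }
    return CoPhyloScenario(
        host_tree=host_tree,
        parasite_tree=parasite_tree,
        true_links=true_links,
        shifted_links=shifted_links,
        host_seqs=host_seqs,
        parasite_seqs=parasite_seqs,
        params=params,
    )


def scenario_distances(scenario: CoPhyloScenario):
    """TN93 distance matrices (host, parasite) estimated from the scenario's
    sequences through the standard pipeline."""
    from .distances import distance_matrix

    return (
        distance_matrix(scenario.host_seqs),
        distance_matrix(scenario.parasite_seqs),
    )


def emit_scenario(scenario: CoPhyloScenario, outdir: str | Path) -> dict[str, Path]:
    """Write a scenario to disk: FASTA alignments, Newick trees, link TSVs
    and the parameter record. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "host_fasta": outdir / "host.fasta",
        "parasite_fasta": outdir / "parasites.fasta",
        "host_tree": outdir / "host.nwk",
        "parasite_tree": outdir / "parasite.nwk",
        "links": outdir / "links.tsv",
        "shifted_links": outdir / "shifted_links.tsv",
        "params": outdir / "params.json",
    }
    write_fasta_alignment(scenario.host_seqs, paths["host_fasta"])
    write_fasta_alignment(scenario.parasite_seqs, paths["parasite_fasta"])
    paths["host_tree"].write_text(scenario.host_tree.newick() + "\n")
    paths["parasite_tree"].write_text(scenario.parasite_tree.newick() + "\n")
    write_links(scenario.true_links, paths["links"])
    write_links(scenario.shifted_links, paths["shifted_links"])
    paths["params"].write_text(json.dumps(scenario.params, indent=2) + "\n")
    return paths
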