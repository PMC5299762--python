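"""mtDNA haplogroup assignment from haploid variant profiles.

A :class:`HaplogroupTree` is a rooted tree of haplogroup labels (L0, L1, M,
N, R, H, ...) in which each edge carries a set of defining variants
``(position, derived allele)``.  A sample's haplotype — the set of derived
variants it carries — is scored against the cumulative defining-variant set
of every node (union of the defining variants on the root→node path) and the
best-matching node is reported as the haplogroup call.

Scoring is the unweighted Kulczynski similarity

    score(N) = 1/2 * ( |O ∩ E| / |E|  +  |O ∩ E| / |O| )

where ``O`` is the observed variant set and ``E`` the expected (cumulative
defining) set of node ``N``.  The first term rewards completeness of the
expected path, the second penalises unexplained (private) variants.  The
root has an empty expected set; its E-term is defined as 1 so that an empty
observed profile deterministically calls the root ("reference", rCRS-like).
Phylogenetic variant weighting (as used by production haplogroup callers)
is deliberately not modelled; back-mutations simply reduce the E-term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Variant",
    "HaplogroupTree",
    "HaplotypeCall",
    "assign_haplogroup",
    "macro_and_origin",
    "haplogroup_path_distance",
]

#: A derived variant: (1-based position, derived allele).
Variant = tuple[int, str]


@dataclass(frozen=True)
class HaplogroupTree:
    """Rooted haplogroup tree with per-edge defining variants.

    Parameters
    ----------
    root
        Label of the root node (conventionally ``"reference"``).
    parent
        Mapping child label → parent label (the root is absent).
    edge_variants
        Mapping child label → set of defining variants on the edge from its
        parent.  The root maps to an empty set.
    macro_map
        Node label → macro-haplogroup label (deep clade: L0..L5, M, N, R).
    origin_map
        Node label → continental origin group.
    """

    root: str
    parent: dict[str, str]
    edge_variants: dict[str, frozenset[Variant]]
    macro_map: dict[str, str]
    origin_map: dict[str, str]

    def __post_init__(self) -> None:
        labels = self.labels()
        if self.root in self.parent:
            raise ValueError(f"root {self.root!r} must not have a parent")
        for child, par in self.parent.items():
            if par not in labels:
                raise ValueError(f"orphan node {child!r}: parent {par!r} unknown")
        # cycle / connectivity check: every node must reach the root
        for node in labels:
            seen = set()
            cur = node
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle detected through {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]
        for node in labels:
            if node not in self.macro_map:
                raise ValueError(f"node {node!r} has no macro-haplogroup entry")
            if node not in self.origin_map:
                raise ValueError(f"node {node!r} has no origin entry")
        # defining-variant positions must be unique along any root→node path
        for node in labels:
            positions: set[int] = set()
            for pos, _ in self.cumulative_variants(node):
                if pos in positions:
                    raise ValueError(
                        f"position {pos} occurs twice on the root→{node} path"
                    )
                positions.add(pos)

    def labels(self) -> set[str]:
        return {self.root} | set(self.parent)

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == node)

    def path_to_root(self, node: str) -> list[str]:
        """Labels on the node→root path, inclusive of both endpoints."""
        if node not in self.labels():
            raise KeyError(f"unknown haplogroup label {node!r}")
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def depth(self, node: str) -> int:
        return len(self.path_to_root(node)) - 1

    def cumulative_variants(self, node: str) -> frozenset[Variant]:
        """Union of defining variants on the root→node path (E(node))."""
        out: set[Variant] = set()
        for label in self.path_to_root(node):
            out |= self.edge_variants.get(label, frozenset())
        return frozenset(out)

    def all_positions(self) -> frozenset[int]:
        """Every position used by some edge of the tree."""
        return frozenset(
            pos for vs in self.edge_variants.values() for pos, _ in vs
        )


@dataclass
class HaplotypeCall:
    """Result of scoring one sample's variant profile against the tree."""

    sample: str
    haplogroup: str
    score: float
    runners_up: list[tuple[str, float]] = field(default_factory=list)
    n_private: int = 0

    def __post_init__(self) -> None:
        if any(s > self.score + 1e-12 for _, s in self.runners_up):
            raise ValueError("runner-up score exceeds best score")


def _kulczynski(observed: frozenset[Variant], expected: frozenset[Variant]) -> float:
    inter = len(observed & expected)
    e_term = inter / len(expected) if expected else 1.0
    o_term = inter / len(observed) if observed else 1.0
    return 0.5 * (e_term + o_term)


def assign_haplogroup(
    variants: set[Variant] | frozenset[Variant],
    tree: HaplogroupTree,
    sample: str = "",
    n_runners_up: int = 3,
) -> HaplotypeCall:
    """Call the best-matching haplogroup for one derived-variant set.

    Ties on score are broken by greater node depth (more derived call),
    then lexicographically by label.  Variants at positions outside the
    tree's coordinate universe count as private (unexplained).
    """
    labels = tree.labels()
    if not labels:
        raise ValueError("empty haplogroup tree")
    observed = frozenset(variants)
    scored: list[tuple[float, int, str]] = []
    for node in labels:
        s = _kulczynski(observed, tree.cumulative_variants(node))
        scored.append((s, tree.depth(node), node))
    # best: highest score, then deepest, then lexicographically first label
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best_score, _, best = scored[0]
    n_private = len(observed - tree.cumulative_variants(best))
    runners = [(lab, s) for s, _, lab in scored[1 : 1 + n_runners_up]]
    return HaplotypeCall(
        sample=sample,
        haplogroup=best,
        score=best_score,
        runners_up=runners,
        n_private=n_private,
    )


def macro_and_origin(call: HaplotypeCall, tree: HaplogroupTree) -> tuple[str, str]:
    """Map a call to its (macro-haplogroup, continental origin group)."""
    label = call.haplogroup
    if label not in tree.macro_map or label not in tree.origin_map:
        raise KeyError(f"haplogroup {label!r} has no macro/origin mapping")
    return tree.macro_map[label], tree.origin_map[label]


def haplogroup_path_distance(tree: HaplogroupTree, h1: str, h2: str) -> int:
    """Number of edges on the unique tree path between two haplogroups."""
    for h in (h1, h2):
        if h not in tree.labels():
            raise KeyError(f"unknown haplogroup label {h!r}")
    # depths along root paths; walk up from the deeper node to the LCA
    p1 = tree.path_to_root(h1)
    p2 = tree.path_to_root(h2)
    anc1 = {lab: i for i, lab in enumerate(p1)}
    for j, lab in enumerate(p2):
        if lab in anc1:
            return anc1[lab] + j
    raise AssertionError("rooted tree must share the root")  # pragma: no cover
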