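"""Genealogies with two branch lengths: total generations and asexual generations.

A sampled genealogy from a sexual-asexual complex is a rooted tree whose
tips sit at time 0 (generations before present) and whose root is the most
recent common ancestor, always a sexual individual.  Every branch records
both the total number of generations it spans and the number of those
generations its lineage spent inside an (unfounded) clone.  The asexual
portion of the tree is what the "pruned" mutation overlay and the empirical
pruning procedures aim to isolate.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "GNode",
    "GBranch",
    "Genealogy",
    "GenealogyError",
]


class GenealogyError(ValueError):
    """Structural problem with a genealogy (empty, cyclic, bad branch)."""


@dataclass
class GNode:
    id: str
    time: float  # generations before present, tips at 0
    is_sexual: bool = False
    group: str | None = None  # deme or clone identifier


@dataclass
class GBranch:
    parent: str
    child: str
    total_gens: float
    asexual_gens: float

    def __post_init__(self) -> None:
        if self.total_gens < 0:
            raise GenealogyError(
                f"branch {self.parent}->{self.child}: negative total_gens"
            )
        if not (-1e-9 <= self.asexual_gens <= self.total_gens + 1e-9):
            raise GenealogyError(
                f"branch {self.parent}->{self.child}: asexual_gens "
                f"{self.asexual_gens} outside [0, {self.total_gens}]"
            )
        self.asexual_gens = min(max(self.asexual_gens, 0.0), self.total_gens)


@dataclass
class Genealogy:
    """Rooted tree over sampled individuals with dual branch durations."""

    nodes: dict[str, GNode] = field(default_factory=dict)
    branches: dict[str, GBranch] = field(default_factory=dict)  # keyed by child id
    samples: list[str] = field(default_factory=list)
    root: str | None = None

    # ------------------------------------------------------------------ build
    def add_node(
        self,
        node_id: str,
        time: float,
        is_sexual: bool = False,
        group: str | None = None,
    ) -> str:
        if node_id in self.nodes:
            raise GenealogyError(f"duplicate node id {node_id!r}")
        self.nodes[node_id] = GNode(node_id, float(time), is_sexual, group)
        return node_id

    def add_branch(self, parent: str, child: str, asexual_gens: float = 0.0) -> None:
        if child in self.branches:
            raise GenealogyError(f"node {child!r} already has a parent")
        total = self.nodes[parent].time - self.nodes[child].time
        if total < -1e-9:
            raise GenealogyError(
                f"parent {parent!r} is younger than child {child!r}"
            )
        self.branches[child] = GBranch(parent, child, max(total, 0.0), asexual_gens)

    # -------------------------------------------------------------- structure
    def children_of(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for br in self.branches.values():
            out[br.parent].append(br.child)
        return out

    def validate(self) -> None:
        if not self.nodes:
            raise GenealogyError("empty genealogy")
        roots = [nid for nid in self.nodes if nid not in self.branches]
        if len(roots) != 1:
            raise GenealogyError(f"expected a single root, found {len(roots)}")
        if self.root is None:
            self.root = roots[0]
        elif self.root != roots[0]:
            raise GenealogyError("declared root is not the parentless node")
        # reachability + acyclicity via one traversal
        children = self.children_of()
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise GenealogyError("cycle detected")
            seen.add(nid)
            stack.extend(children[nid])
        if seen != set(self.nodes):
            raise GenealogyError("nodes unreachable from root")
        for tip in self.samples:
            if tip not in self.nodes:
                raise GenealogyError(f"sample {tip!r} is not a node")
            if abs(self.nodes[tip].time) > 1e-9:
                raise GenealogyError(f"tip {tip!r} not at time 0")

    def tips(self) -> list[str]:
        children = self.children_of()
        return [nid for nid in self.nodes if not children[nid]]

    # ------------------------------------------------------------- summaries
    def summarize(self) -> dict[str, float]:
        """Tree height and the two total branch lengths, in generations."""
        self.validate()
        total = sum(br.total_gens for br in self.branches.values())
        asex = sum(br.asexual_gens for br in self.branches.values())
        return {
            "tmrca": self.nodes[self.root].time,
            "total_length": total,
            "asexual_length": asex,
        }

    def asexual_fraction(self) -> float:
        """Fraction of the genealogy's length spent in the asexual state."""
        s = self.summarize()
        if s["total_length"] <= 0:
            raise GenealogyError("asexual_fraction undefined: zero total length")
        return s["asexual_length"] / s["total_length"]

    def descendant_tips(self) -> dict[str, frozenset[str]]:
        """Tip set below every node (tips map to themselves)."""
        children = self.children_of()
        out: dict[str, frozenset[str]] = {}

        order: list[str] = []
        stack = [self.root if self.root is not None else self._find_root()]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(children[nid])
        for nid in reversed(order):
            kids = children[nid]
            if not kids:
                out[nid] = frozenset([nid])
            else:
                acc: frozenset[str] = frozenset()
                for k in kids:
                    acc = acc | out[k]
                out[nid] = acc
        return out

    def _find_root(self) -> str:
        roots = [nid for nid in self.nodes if nid not in self.branches]
        if len(roots) != 1:
            raise GenealogyError("no unique root")
        return roots[0]

    # ----------------------------------------------------------------- I/O
    def to_newick(self) -> str:
        """Serialize with total_gens as branch length and the asexual
        duration in a bracketed ``[&asex=...]`` comment tag per branch.

        Children are ordered by their smallest descendant tip label so the
        output is canonical for a given topology.
        """
        self.validate()
        children = self.children_of()
        desc = self.descendant_tips()

        def fmt(x: float) -> str:
            return repr(float(x))

        def rec(nid: str) -> str:
            kids = sorted(children[nid], key=lambda c: min(desc[c]))
            if kids:
                inner = "(" + ",".join(rec(k) for k in kids) + ")"
            else:
                inner = nid
            br = self.branches.get(nid)
            if br is None:
                return inner + ";"
            return f"{inner}:{fmt(br.total_gens)}[&asex={fmt(br.asexual_gens)}]"

        return rec(self.root)

    @classmethod
    def from_newick(cls, text: str) -> "Genealogy":
        """Parse a newick string with optional ``[&asex=...]`` branch tags.

        Trees without asexual tags parse with ``asexual_gens = 0`` and a
        warning.  Node times are reconstructed from branch lengths assuming
        tips at time 0; an internally inconsistent (non-ultrametric) tree is
        rejected.
        """
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                extract_comment_metadata=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise GenealogyError(f"malformed newick: {exc}") from exc

        g = cls()
        missing_tags = False
        counter = [0]

        # depth of each node from the root, in branch-length units
        def name_for(nd: dendropy.Node) -> str:
            if nd.taxon is not None and nd.taxon.label:
                return nd.taxon.label
            if nd.label:
                return nd.label
            counter[0] += 1
            return f"_n{counter[0]}"

        depths: dict[int, float] = {}
        names: dict[int, str] = {}
        root = tree.seed_node
        depths[id(root)] = 0.0
        for nd in tree.preorder_node_iter():
            if nd is not root:
                depths[id(nd)] = depths[id(nd.parent_node)] + (nd.edge.length or 0.0)
            names[id(nd)] = name_for(nd)
        height = max(depths[id(lf)] for lf in tree.leaf_node_iter())
        for lf in tree.leaf_node_iter():
            if abs(depths[id(lf)] - height) > 1e-6 * max(height, 1.0):
                raise GenealogyError(
                    "tips are not contemporaneous; not a sampled genealogy"
                )

        for nd in tree.preorder_node_iter():
            g.add_node(names[id(nd)], height - depths[id(nd)])
        for nd in tree.preorder_node_iter():
            if nd is root:
                continue
            ann = {a.name: a.value for a in nd.annotations}
            if "asex" in ann:
                asex = float(ann["asex"])
            else:
                asex = 0.0
                missing_tags = True
            g.add_branch(names[id(nd.parent_node)], names[id(nd)], asex)
        g.root = names[id(root)]
        g.samples = sorted(
            names[id(lf)] for lf in tree.leaf_node_iter()
        )
        if missing_tags:
            warnings.warn(
                "newick tree lacks [&asex=...] tags; asexual_gens set to 0",
                stacklevel=2,
            )
        g.validate()
        return g

    def to_branch_table(self) -> str:
        """TSV of per-branch records: parent, child, total_gens, asexual_gens."""
        buf = io.StringIO()
        buf.write("parent\tchild\ttotal_gens\tasexual_gens\n")
        for child in sorted(self.branches):
            br = self.branches[child]
            buf.write(
                f"{br.parent}\t{br.child}\t{br.total_gens!r}\t{br.asexual_gens!r}\n"
            )
        return buf.getvalue()


def merge_all(
    g: Genealogy,
    children: list[str],
    time: float,
    prefix: str,
    is_sexual: bool,
    group: str | None,
    asexual_gens_per_child: list[float] | None = None,
) -> str:
    """Merge several lineages at one time point into a single ancestor.

    Simultaneous multi-way coalescence is represented as a chain of
    zero-length binary branches so the tree stays binary.  Returns the id of
    the final ancestor node.
    """
    if not children:
        raise GenealogyError("merge_all needs at least one child")
    if asexual_gens_per_child is None:
        asexual_gens_per_child = [
            time - g.nodes[c].time for c in children
        ]
    current = children[0]
    current_asex = asexual_gens_per_child[0]
    for i, (child, asex) in enumerate(
        zip(children[1:], asexual_gens_per_child[1:]), start=1
    ):
        nid = g.add_node(f"{prefix}_{i}", time, is_sexual, group)
        g.add_branch(nid, current, current_asex)
        g.add_branch(nid, child, asex)
        current = nid
        current_asex = 0.0  # zero-length chain links
    if len(children) == 1:
        # single lineage: create the ancestor node explicitly
        nid = g.add_node(f"{prefix}_0", time, is_sexual, group)
        g.add_branch(nid, current, current_asex)
        current = nid
    return current
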