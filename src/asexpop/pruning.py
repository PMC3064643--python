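"""Isolating post-formational polymorphism in sexual-asexual alignments.

Sequence variability of an asexual population mixes polymorphisms
inherited from the sexual ancestor ("frozen" standing variation) with
mutations acquired after the transitions to asexuality.  Two pruning
procedures separate the two components in an aligned dataset that contains
both sexual and asexual individuals:

* **site pruning** (:func:`prune_by_sites`): every alignment column that
  segregates among the sexual sequences is deleted, and the sexual rows
  are then dropped; what remains are polymorphic sites never observed
  segregating in the sexual ancestor;

* **tree pruning** (:func:`map_transitions` + :func:`binarize_pruned`):
  reproduction mode is optimised on a rooted haplotype tree under the
  constraint that only sexual-to-asexual transitions are possible,
  per-site changes are mapped onto branches by Fitch parsimony, and only
  mutations on branches leading to asexual nodes (i.e. those defining the
  relationships among asexual haplotypes and their connections to the
  closest sexual nodes) are retained and binarised.

A small maximum-parsimony tree search (:func:`build_small_mp_tree`) is
provided for datasets without a published tree; an externally supplied
tree is preferred when available.  :func:`four_x_rule` implements the
species-delimitation screen that flags reciprocally monophyletic clusters
as distinct species when between-cluster divergence exceeds four times the
largest within-cluster diversity.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .overlay import HaplotypeMatrix

__all__ = [
    "LabeledAlignment",
    "TransitionMap",
    "PruneReport",
    "prune_by_sites",
    "build_small_mp_tree",
    "map_transitions",
    "binarize_pruned",
    "four_x_rule",
]

_BASES = {"A": 1, "C": 2, "G": 4, "T": 8}
_GAPLIKE = set("-N?X.")


@dataclass
class LabeledAlignment:
    """Equal-length nucleotide sequences labelled sexual/asexual."""

    ids: list[str]
    seqs: list[str]
    labels: dict[str, str]                  # id -> 'sexual' | 'asexual'
    complex_id: str = "complex"
    clusters: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        self.seqs = [s.upper() for s in self.seqs]
        for i in self.ids:
            if self.labels.get(i) not in ("sexual", "asexual"):
                raise ValueError(f"sequence {i!r} lacks a sexual/asexual label")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def subset(self, keep: list[str]) -> "LabeledAlignment":
        idx = {i: s for i, s in zip(self.ids, self.seqs)}
        return LabeledAlignment(
            list(keep),
            [idx[i] for i in keep],
            {i: self.labels[i] for i in keep},
            self.complex_id,
            {i: c for i, c in self.clusters.items() if i in keep},
        )

    def by_label(self, label: str) -> list[str]:
        return [i for i in self.ids if self.labels[i] == label]

    @classmethod
    def from_fasta(
        cls, fasta: str | io.TextIOBase, sample_sheet: str, complex_id: str = "complex"
    ) -> "LabeledAlignment":
        """Build from FASTA text/handle and a sample-sheet TSV.

        The sheet has columns ``id``, ``role`` (sexual/asexual) and
        optionally ``cluster``.
        """
        from Bio import SeqIO

        handle = io.StringIO(fasta) if isinstance(fasta, str) else fasta
        ids, seqs = [], []
        for rec in SeqIO.parse(handle, "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        labels, clusters = {}, {}
        lines = sample_sheet.strip().splitlines()
        header = lines[0].split("\t")
        for ln in lines[1:]:
            row = dict(zip(header, ln.split("\t")))
            labels[row["id"]] = row["role"]
            if row.get("cluster"):
                clusters[row["id"]] = row["cluster"]
        return cls(ids, seqs, labels, complex_id, clusters)

    def columns(self) -> np.ndarray:
        """Character matrix, shape (n, L)."""
        return np.array([list(s) for s in self.seqs])


def _valid_columns(mat: np.ndarray) -> np.ndarray:
    """Columns free of gaps/ambiguity codes (conservative site handling)."""
    bad = np.zeros(mat.shape[1], dtype=bool)
    for ch in _GAPLIKE:
        bad |= (mat == ch).any(axis=0)
    return ~bad


def segregating_columns(a: LabeledAlignment, among: list[str] | None = None) -> np.ndarray:
    """Indices of columns polymorphic among the given sequences.

    Columns containing gaps or N anywhere in the alignment are excluded
    from consideration.
    """
    mat = a.columns()
    valid = _valid_columns(mat)
    if among is not None:
        rows = [a.ids.index(i) for i in among]
        mat = mat[rows]
    poly = np.array(
        [len(set(mat[:, j])) > 1 if valid[j] else False for j in range(mat.shape[1])]
    )
    return np.nonzero(poly)[0]


@dataclass
class PruneReport:
    S_total: int        # segregating among asexuals before pruning
    S_pruned: int       # segregating among asexuals after pruning
    removed_columns: list[int]


def prune_by_sites(a: LabeledAlignment) -> tuple[LabeledAlignment, PruneReport]:
    """Delete every column segregating in the sexual progenitors, then drop
    the sexual rows.  Returns the pruned asexual alignment and a report."""
    sexuals = a.by_label("sexual")
    asexuals = a.by_label("asexual")
    if not asexuals:
        raise ValueError("alignment has no asexual sequences")
    if len(sexuals) < 2:
        warnings.warn(
            "fewer than 2 sexual sequences: no site can be called segregating "
            "in sexuals; pruning removes rows only",
            stacklevel=2,
        )
    S_total = len(segregating_columns(a, asexuals))
    removed = set(segregating_columns(a, sexuals).tolist()) if len(sexuals) >= 2 else set()
    keep_cols = [j for j in range(a.length) if j not in removed]
    idx = {i: s for i, s in zip(a.ids, a.seqs)}
    new_seqs = ["".join(idx[i][j] for j in keep_cols) for i in asexuals]
    pruned = LabeledAlignment(
        list(asexuals),
        new_seqs,
        {i: "asexual" for i in asexuals},
        a.complex_id,
        {i: c for i, c in a.clusters.items() if i in asexuals},
    )
    S_pruned = len(segregating_columns(pruned, asexuals))
    return pruned, PruneReport(S_total, S_pruned, sorted(removed))


# ------------------------------------------------------------ MP tree search


def _encode(a: LabeledAlignment, ids: list[str]) -> np.ndarray:
    """Bitmask-encoded states, shape (len(ids), L); gap/N columns dropped."""
    mat = a.columns()
    valid = _valid_columns(mat)
    rows = [a.ids.index(i) for i in ids]
    sub = mat[np.ix_(rows, np.nonzero(valid)[0])]
    enc = np.zeros(sub.shape, dtype=np.uint8)
    for b, v in _BASES.items():
        enc[sub == b] = v
    return enc


def _fitch_len(tree, enc: np.ndarray) -> int:
    """Parsimony length of a nested-tuple tree (leaves are row indices)."""

    def rec(t) -> tuple[np.ndarray, int]:
        if isinstance(t, int):
            return enc[t], 0
        (sa, ca), (sb, cb) = rec(t[0]), rec(t[1])
        inter = sa & sb
        miss = inter == 0
        return np.where(miss, sa | sb, inter), ca + cb + int(miss.sum())

    states, changes = rec(tree)
    return changes


def _insertions(t, leaf):
    yield (t, leaf)
    if isinstance(t, tuple):
        a, b = t
        for na in _insertions(a, leaf):
            yield (na, b)
        for nb in _insertions(b, leaf):
            yield (a, nb)


def _canon(t):
    if isinstance(t, int):
        return t, t
    (ca, ma), (cb, mb) = _canon(t[0]), _canon(t[1])
    if ma <= mb:
        return (ca, cb), ma
    return (cb, ca), mb


def _tuple_to_dendropy(tree, labels: list[str], root_label: str) -> dendropy.Tree:
    """Convert ((...)-tuple over row indices, rooted above row 0) to a
    dendropy tree re-rooted on the pendant edge of ``root_label``."""

    def newick(t) -> str:
        if isinstance(t, int):
            return labels[t]
        return f"({newick(t[0])},{newick(t[1])})"

    nwk = f"({labels[0]},{newick(tree)});"
    dt = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    leaf = next(
        lf for lf in dt.leaf_node_iter() if lf.taxon.label == root_label
    )
    dt.reroot_at_edge(leaf.edge, update_bipartitions=False)
    return dt


_EXACT_LIMIT = 9  # exhaustive topology enumeration up to this many haplotypes


def build_small_mp_tree(
    a: LabeledAlignment, rng: np.random.Generator | None = None, restarts: int = 10
) -> dendropy.Tree:
    """Maximum-parsimony tree over the distinct haplotypes of an alignment.

    Exhaustive search over unrooted topologies for up to 9 distinct
    haplotypes; beyond that, random-order stepwise addition with
    re-insertion hill climbing and ``restarts`` restarts.  Ties are broken
    by canonical (lexicographically smallest) topology, so the result is
    deterministic for a fixed seed.  The tree is rooted on the pendant
    edge of a sexual haplotype and its tips are labelled by representative
    sequence ids; identical sequences are collapsed to one tip.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    # collapse identical sequences; a haplotype is sexual if any carrier is
    hap_of: dict[str, list[str]] = {}
    for i, s in zip(a.ids, a.seqs):
        hap_of.setdefault(s, []).append(i)
    reps = []
    for s, carriers in hap_of.items():
        sex = [c for c in carriers if a.labels[c] == "sexual"]
        reps.append(sex[0] if sex else carriers[0])
    reps.sort()
    sex_reps = [r for r in reps if a.labels[r] == "sexual"]
    if not sex_reps:
        raise ValueError("cannot root: no sexual haplotype present")
    root_label = sex_reps[0]
    h = len(reps)
    enc = _encode(a, reps)
    if h == 1:
        raise ValueError("all sequences identical; no tree to build")
    if h == 2:
        dt = dendropy.Tree.get(data=f"({reps[0]},{reps[1]});", schema="newick", preserve_underscores=True)
        return dt
    if np.all(enc.min(axis=0) == enc.max(axis=0)):
        warnings.warn("all haplotypes identical at valid sites: star tree")
    if h == 3:
        tree = (1, 2)  # single unrooted topology
        return _tuple_to_dendropy(tree, reps, root_label)

    def score(t) -> int:
        return _fitch_len((0, t), enc)

    if h <= _EXACT_LIMIT:
        best, best_len = None, None
        trees = [(1, 2)]
        for leaf in range(3, h):
            trees = [nt for t in trees for nt in _insertions(t, leaf)]
        for t in trees:
            ln = score(t)
            ct = _canon(t)[0]
            if best_len is None or ln < best_len or (ln == best_len and repr(ct) < repr(best)):
                best, best_len = ct, ln
        return _tuple_to_dendropy(best, reps, root_label)

    best, best_len = None, None
    for r in range(restarts):
        order = list(rng.permutation(np.arange(1, h)))
        t = (int(order[0]), int(order[1]))
        for leaf in order[2:]:
            t = min(
                _insertions(t, int(leaf)),
                key=lambda cand: (score(cand), repr(_canon(cand)[0])),
            )
        # hill climb: remove each leaf and re-insert at the best edge
        improved = True
        while improved:
            improved = False
            cur = score(t)
            for leaf in range(1, h):
                pruned_t = _remove_leaf(t, leaf)
                if pruned_t is None:
                    continue
                cand = min(
                    _insertions(pruned_t, leaf),
                    key=lambda c: (score(c), repr(_canon(c)[0])),
                )
                if score(cand) < cur:
                    t, cur, improved = cand, score(cand), True
        ln = score(t)
        ct = _canon(t)[0]
        if best_len is None or ln < best_len or (ln == best_len and repr(ct) < repr(best)):
            best, best_len = ct, ln
    return _tuple_to_dendropy(best, reps, root_label)


def _remove_leaf(t, leaf):
    """Tree with ``leaf`` removed, or None if removal empties the tree."""
    if isinstance(t, int):
        return None if t == leaf else t
    a, b = _remove_leaf(t[0], leaf), _remove_leaf(t[1], leaf)
    if a is None:
        return b
    if b is None:
        return a
    return (a, b)


# --------------------------------------------------- transition mapping


@dataclass
class TransitionMap:
    tree: dendropy.Tree
    modes: dict[int, str]            # id(node) -> 'sexual' | 'asexual'
    transitions: int                 # number of sex->asex branches
    mutations: list[dict]            # all mapped mutations
    retained: list[dict]             # mutations on asexual-leading branches
    tip_members: dict[str, list[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)


def map_transitions(a: LabeledAlignment, tree: dendropy.Tree) -> TransitionMap:
    """Optimise the reproduction-mode character and map site changes.

    Mode optimisation uses asymmetric parsimony (sexual-to-asexual costs
    one step, the reverse is forbidden), whose unique optimum labels a
    node asexual exactly when every tip below it is asexual.  Site changes
    are assigned to branches by Fitch optimisation with a deterministic
    downward pass (ambiguities resolved toward the alphabetically first
    base).  A mutation is retained when its branch leads to an asexual
    node, i.e. it lies within an asexual clade or on the stem connecting
    the clade to its closest sexual ancestor node.
    """
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    unknown = [t for t in tips if t not in a.ids]
    if unknown:
        raise ValueError(f"tree tips not in alignment: {unknown}")
    # map every alignment sequence to its tree tip (identical sequences may
    # be collapsed to one representative tip)
    seq_of = dict(zip(a.ids, a.seqs))
    tip_members: dict[str, list[str]] = {t: [t] for t in tips}
    for i in a.ids:
        if i in tip_members:
            continue
        match = [t for t in tips if seq_of[t] == seq_of[i]]
        if not match:
            raise ValueError(f"sequence {i!r} matches no tree tip haplotype")
        tip_members[match[0]].append(i)

    # ---- mode character: node is asexual iff all tips below are asexual
    modes: dict[int, str] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            members = tip_members[nd.taxon.label]
            labs = {a.labels[m] for m in members}
            if labs == {"asexual"}:
                modes[id(nd)] = "asexual"
            elif labs == {"sexual"}:
                modes[id(nd)] = "sexual"
            else:
                # identical haplotype shared by sexual and asexual carriers:
                # the tip itself is treated as sexual (standing variation)
                modes[id(nd)] = "sexual"
        else:
            kids = [modes[id(c)] for c in nd.child_nodes()]
            modes[id(nd)] = "asexual" if set(kids) == {"asexual"} else "sexual"
    root = tree.seed_node
    if modes[id(root)] == "asexual":
        raise ValueError("root resolves as asexual; cannot polarise transitions")
    transitions = 0
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        pm, cm = modes[id(nd.parent_node)], modes[id(nd)]
        assert not (pm == "asexual" and cm == "sexual"), "asex->sex change emitted"
        if pm == "sexual" and cm == "asexual":
            transitions += 1

    # ---- Fitch mapping of site changes
    mat = a.columns()
    valid_idx = np.nonzero(_valid_columns(mat))[0]
    enc_by_tip = {}
    row = {i: r for r, i in enumerate(a.ids)}
    for t in tips:
        chars = mat[row[t]][valid_idx]
        enc = np.zeros(len(valid_idx), dtype=np.uint8)
        for b, v in _BASES.items():
            enc[chars == b] = v
        enc_by_tip[t] = enc

    down: dict[int, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            down[id(nd)] = enc_by_tip[nd.taxon.label]
        else:
            kids = nd.child_nodes()
            st = down[id(kids[0])]
            for c in kids[1:]:
                inter = st & down[id(c)]
                st = np.where(inter == 0, st | down[id(c)], inter)
            down[id(nd)] = st

    inv = {v: b for b, v in _BASES.items()}

    def first_base(mask: int) -> int:
        for v in (1, 2, 4, 8):
            if mask & v:
                return v
        raise ValueError("empty state set")

    assigned: dict[int, np.ndarray] = {}
    mutations: list[dict] = []
    retained: list[dict] = []
    for nd in tree.preorder_node_iter():
        st = down[id(nd)]
        if nd is root:
            assigned[id(nd)] = np.array([first_base(int(m)) for m in st], dtype=np.uint8)
            continue
        par = assigned[id(nd.parent_node)]
        keep = (st & par) != 0
        out = np.where(keep, par, 0).astype(np.uint8)
        for j in np.nonzero(~keep)[0]:
            out[j] = first_base(int(st[j]))
        assigned[id(nd)] = out
        changed = np.nonzero(out != par)[0]
        for j in changed:
            mut = {
                "site": int(valid_idx[j]),
                "from": inv[int(par[j])],
                "to": inv[int(out[j])],
                "edge_child": nd,
                "child_mode": modes[id(nd)],
            }
            mutations.append(mut)
            if modes[id(nd)] == "asexual":
                retained.append(mut)
    return TransitionMap(
        tree, modes, transitions, mutations, retained, tip_members, dict(a.labels)
    )


def binarize_pruned(tm: TransitionMap, locus_length: int) -> HaplotypeMatrix:
    """One binary column per retained segregating mutation, rows = asexual tips.

    Mutations fixed among the asexual individuals (e.g. on the stem of a
    single monophyletic asexual clade) carry no frequency information and
    are dropped.  Raises if more retained mutations than ``locus_length``.
    """
    if len(tm.retained) > locus_length:
        raise ValueError(
            f"{len(tm.retained)} retained mutations exceed locus length "
            f"{locus_length}"
        )
    # rows are asexual individuals: collapsed haplotype tips expand to
    # their carriers
    tip_of: dict[str, str] = {}
    rows: list[str] = []
    for lf in tm.tree.leaf_node_iter():
        if tm.modes[id(lf)] != "asexual":
            continue
        for member in tm.tip_members.get(lf.taxon.label, [lf.taxon.label]):
            tip_of[member] = lf.taxon.label
            rows.append(member)
    idx = {m: i for i, m in enumerate(rows)}
    cols = []
    for mut in tm.retained:
        below_tips = {lf.taxon.label for lf in mut["edge_child"].leaf_iter()}
        col = np.zeros(len(rows), dtype=np.uint8)
        for member, tip in tip_of.items():
            if tip in below_tips:
                col[idx[member]] = 1
        if 0 < col.sum() < len(rows):
            cols.append(col)
    data = (
        np.stack(cols, axis=1) if cols else np.zeros((len(rows), 0), dtype=np.uint8)
    )
    return HaplotypeMatrix(rows, data, locus_length)


# ----------------------------------------------------------------- 4X rule


def four_x_rule(
    a: LabeledAlignment, clusters: dict[str, str] | None = None
) -> list[dict]:
    """Species-delimitation screen for reciprocally monophyletic clusters.

    For every cluster pair, computes the mean between-cluster per-site
    divergence d and each cluster's per-site mean pairwise diversity
    (theta_pi); the pair is flagged as distinct species when d exceeds
    four times the larger of the two diversities.  Pairs involving a
    singleton cluster are skipped with a warning (theta_pi undefined).
    """
    clusters = clusters if clusters is not None else a.clusters
    if not clusters:
        raise ValueError("no cluster assignment provided")
    groups: dict[str, list[str]] = {}
    for i in a.ids:
        if i in clusters:
            groups.setdefault(clusters[i], []).append(i)
    if len(groups) < 2:
        raise ValueError("need at least two clusters")
    mat = a.columns()
    valid = _valid_columns(mat)
    L = int(valid.sum())
    row = {i: r for r, i in enumerate(a.ids)}

    def pdiff(x: str, y: str) -> float:
        rx, ry = mat[row[x]][valid], mat[row[y]][valid]
        return float(np.mean(rx != ry))

    def theta_pi_per_site(members: list[str]) -> float:
        pairs = list(itertools.combinations(members, 2))
        return float(np.mean([pdiff(x, y) for x, y in pairs]))

    tpi = {}
    for name, members in groups.items():
        if len(members) >= 2:
            tpi[name] = theta_pi_per_site(members)
    out = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        if ga not in tpi or gb not in tpi:
            warnings.warn(
                f"cluster pair ({ga}, {gb}) skipped: singleton cluster",
                stacklevel=2,
            )
            continue
        d = float(
            np.mean([pdiff(x, y) for x in groups[ga] for y in groups[gb]])
        )
        ref = max(tpi[ga], tpi[gb])
        out.append(
            {
                "cluster_a": ga,
                "cluster_b": gb,
                "divergence": d,
                "max_theta_pi": ref,
                "distinct_species": bool(d > 4.0 * ref),
            }
        )
    return out
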