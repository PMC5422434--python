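"""Family alignment, gene-tree inference, and duplication/loss reconciliation.

Alignment and tree inference have two engines each: a deterministic internal
one (centre-star progressive alignment; neighbour joining on p-distances with
a nonparametric bootstrap) and adapters around external ``mafft`` and RAxML
executables preserving those tools' published defaults.  Reconciliation maps
each gene-tree node to the LCA of its leaf species in the species tree; a
node is a duplication when it maps to the same species-tree node as one of
its children, and losses are counted from mapping-path depth differences.
Gene-tree edges below the bootstrap threshold (default 70) are collapsed and
the resulting polytomies re-resolved to minimise duplications + losses — an
approximation of Notung-style rearrangement.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import Align

from .core_io import Config, SequenceRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tree representation

@dataclass
class Node:
    """Rooted tree node; leaves carry labels, internal edges may carry
    bootstrap support (0-100)."""

    label: str | None = None
    children: list["Node"] = field(default_factory=list)
    length: float | None = None
    support: float | None = None
    event: str | None = None  # 'D' after reconciliation

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.leaves()]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(l.label for l in self.leaves())

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def copy(self) -> "Node":
        return Node(
            self.label, [c.copy() for c in self.children], self.length,
            self.support, self.event,
        )


def parse_newick(text: str) -> Node:
    tree = dendropy.Tree.get(data=text, schema="newick")
    return _from_dendropy(tree.seed_node)


def _from_dendropy(dnode) -> Node:
    children = [_from_dendropy(c) for c in dnode.child_nodes()]
    label = dnode.taxon.label.replace(" ", "") if dnode.taxon else None
    support = None
    if children and dnode.label is not None:
        try:
            support = float(dnode.label)
        except ValueError:
            pass
    if not children and label is None and dnode.label is not None:
        label = dnode.label.replace(" ", "")
    return Node(label, children, dnode.edge.length, support)


def to_newick(node: Node, with_lengths: bool = True) -> str:
    return _newick(node, with_lengths) + ";"


def _newick(n: Node, with_lengths: bool) -> str:
    if n.is_leaf:
        s = n.label or ""
    else:
        s = "(" + ",".join(_newick(c, with_lengths) for c in n.children) + ")"
        marks = []
        if n.support is not None:
            marks.append(f"{n.support:g}")
        if n.event == "D":
            marks.append("D")
        s += "-".join(marks) if marks else ""
    if with_lengths and n.length is not None:
        s += f":{n.length:g}"
    return s


# ---------------------------------------------------------------------------
# multiple alignment

def _pairwise_global(a: str, b: str, cfg: Config) -> tuple[str, str]:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = cfg.match
    al.mismatch_score = cfg.mismatch
    al.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    al.extend_gap_score = -cfg.gap_extend
    best = al.align(a, b)[0]
    ra, rb = str(best[0]), str(best[1])
    return ra, rb


def _merge_into_msa(
    rows: list[str], center_aln: str, new_aln: str
) -> tuple[list[str], str]:
    """Merge a pairwise (center, new) alignment into an MSA whose first row
    is the (gapped) center; once a gap, always a gap."""
    old_center = rows[0]
    out_rows = [""] * len(rows)
    out_new = ""
    i = j = 0
    while i < len(old_center) or j < len(center_aln):
        a = old_center[i] if i < len(old_center) else None
        b = center_aln[j] if j < len(center_aln) else None
        if a == "-" and (b != "-" or b is None):
            for r in range(len(rows)):
                out_rows[r] += rows[r][i]
            out_new += "-"
            i += 1
        elif b == "-" and (a != "-" or a is None):
            for r in range(len(rows)):
                out_rows[r] += "-"
            out_new += new_aln[j]
            j += 1
        else:
            for r in range(len(rows)):
                out_rows[r] += rows[r][i]
            out_new += new_aln[j]
            i += 1
            j += 1
    return out_rows, out_new


def align_family(
    sequences: list[SequenceRecord] | list[tuple[str, str]],
    cfg: Config | None = None,
    method: str = "builtin",
) -> list[tuple[str, str]]:
    """Multiple alignment of a family (>= 2 sequences).

    ``builtin`` runs centre-star progressive alignment (pairwise global
    alignment of every member to the longest sequence, gap propagation);
    ``mafft`` shells out to the external aligner with 1000 refinement
    iterations.  Either way every input residue reappears in order and the
    alignment is at least as long as the longest input.
    """
    cfg = cfg or Config()
    pairs = [
        (s.id, s.seq) if isinstance(s, SequenceRecord) else (s[0], s[1])
        for s in sequences
    ]
    if len(pairs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if method == "mafft":
        return _mafft_align(pairs)
    center_idx = max(range(len(pairs)), key=lambda i: (len(pairs[i][1]), -i))
    center_id, center_seq = pairs[center_idx]
    rows = [center_seq]
    order = [center_idx]
    for i, (sid, seq) in enumerate(pairs):
        if i == center_idx:
            continue
        ca, na = _pairwise_global(rows[0].replace("-", ""), seq, cfg)
        # re-express the pairwise center with the gaps already in the MSA
        rows, new_row = _merge_into_msa(rows, ca, na)
        rows.append(new_row)
        order.append(i)
    # restore input order
    result = [None] * len(pairs)
    for row, idx in zip(rows, order):
        result[idx] = (pairs[idx][0], row)
    return result


def _mafft_align(pairs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        with open(fin, "w") as fh:
            for sid, seq in pairs:
                fh.write(f">{sid}\n{seq}\n")
        out = subprocess.run(
            ["mafft", "--maxiterate", "1000", "--quiet", str(fin)],
            check=True, capture_output=True, text=True,
        ).stdout
    aligned: dict[str, str] = {}
    cur = None
    for line in out.splitlines():
        if line.startswith(">"):
            cur = line[1:].split()[0]
            aligned[cur] = ""
        elif cur:
            aligned[cur] += line.strip()
    return [(sid, aligned[sid].upper()) for sid, _ in pairs]


# ---------------------------------------------------------------------------
# neighbour joining + bootstrap

def _p_distance_matrix(rows: list[str]) -> np.ndarray:
    arrs = [np.frombuffer(r.encode(), dtype="S1") for r in rows]
    n = len(rows)
    d = np.zeros((n, n))
    gap = b"-"
    for i in range(n):
        for j in range(i + 1, n):
            valid = (arrs[i] != gap) & (arrs[j] != gap)
            nv = int(valid.sum())
            if nv == 0:
                d[i, j] = d[j, i] = 0.0
            else:
                diff = int((arrs[i][valid] != arrs[j][valid]).sum())
                d[i, j] = d[j, i] = diff / nv
    return d


def _neighbor_joining(labels: list[str], d: np.ndarray) -> Node:
    """Deterministic NJ; ties broken by smallest index pair.  Returns a tree
    rooted arbitrarily at the final join (resolved to binary)."""
    nodes = [Node(lbl, length=0.0) for lbl in labels]
    dist = d.copy().astype(float)
    active = list(range(len(labels)))
    while len(active) > 2:
        m = len(active)
        r = {i: sum(dist[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        new = Node(children=[nodes[i], nodes[j]])
        new_idx = len(nodes)
        nodes.append(new)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dist[new_idx, k] = dist[k, new_idx] = 0.5 * (
                dist[i, k] + dist[j, k] - dist[i, j]
            )
        active = [k for k in active if k not in (i, j)] + [new_idx]
    i, j = active
    nodes[i].length = nodes[j].length = max(0.0, dist[i, j] / 2)
    return Node(children=[nodes[i], nodes[j]])


def _splits(root: Node) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each canonicalised to the side not
    containing the lexicographically smallest leaf."""
    all_leaves = root.leaf_labels()
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for n in root.postorder():
        if n is root or n.is_leaf:
            continue
        side = n.leaf_labels()
        canon = all_leaves - side if anchor in side else side
        if 1 < len(canon) < len(all_leaves) - 1:
            out.add(canon)
    return out


def infer_gene_tree(
    alignment: list[tuple[str, str]],
    n_bootstrap: int = 100,
    seed: int = 0,
    cfg: Config | None = None,
) -> Node:
    """Neighbour-joining tree on p-distances with nonparametric bootstrap
    supports (percent of replicates containing each internal split), rooted
    at the midpoint.  Requires >= 3 rows."""
    if len(alignment) < 3:
        raise ValueError("gene tree inference needs >= 3 aligned sequences")
    labels = [sid for sid, _ in alignment]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in alignment")
    rows = [seq for _, seq in alignment]
    d = _p_distance_matrix(rows)
    tree = _neighbor_joining(labels, d)
    # bootstrap
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    L = len(rows[0])
    arr = np.array([list(r) for r in rows])
    for _ in range(max(0, n_bootstrap)):
        cols = rng.integers(0, L, L)
        boot_rows = ["".join(a) for a in arr[:, cols]]
        bt = _neighbor_joining(labels, _p_distance_matrix(boot_rows))
        for s in _splits(bt):
            counts[s] = counts.get(s, 0) + 1
    tree = _midpoint_root(tree)
    all_leaves = tree.leaf_labels()
    anchor = min(all_leaves)
    for n in tree.postorder():
        if n.is_leaf or n is tree:
            continue
        side = n.leaf_labels()
        canon = all_leaves - side if anchor in side else side
        if 1 < len(canon) < len(all_leaves) - 1:
            n.support = (
                100.0 * counts.get(canon, 0) / n_bootstrap if n_bootstrap else 100.0
            )
        else:  # trivial split: fully supported by construction
            n.support = 100.0
    return tree


def _midpoint_root(tree: Node) -> Node:
    """Midpoint rooting via dendropy; falls back to the existing root when
    branch lengths are absent or all zero."""
    nwk = to_newick(tree)
    dt = dendropy.Tree.get(data=nwk, schema="newick")
    total = sum(e.length or 0.0 for e in dt.edges())
    if total <= 0:
        return tree
    dt.reroot_at_midpoint(update_bipartitions=False)
    rooted = _from_dendropy(dt.seed_node)
    return rooted


# ---------------------------------------------------------------------------
# reconciliation

@dataclass
class ReconciliationResult:
    tree: Node
    duplications: int
    losses: int
    events: list[tuple[str, str]]  # (event 'D'/'L', description)

    def annotated_newick(self) -> str:
        return to_newick(self.tree, with_lengths=False)

    def event_table(self) -> str:
        lines = ["event\tlocation"]
        lines += [f"{ev}\t{desc}" for ev, desc in self.events]
        return "\n".join(lines) + "\n"


def species_of(label: str) -> str:
    """Species name of a gene-tree leaf label (copy suffix after '#')."""
    return label.split("#")[0]


def _species_index(species_tree: Node):
    parent: dict[int, Node] = {}
    depth: dict[int, int] = {}

    def walk(n: Node, d: int) -> None:
        depth[id(n)] = d
        for c in n.children:
            parent[id(c)] = n
            walk(c, d + 1)

    walk(species_tree, 0)
    leaf_of = {}
    for l in species_tree.leaves():
        leaf_of[l.label] = l
    return parent, depth, leaf_of


def _lca(a: Node, b: Node, parent, depth) -> Node:
    while a is not b:
        if depth[id(a)] < depth[id(b)]:
            b = parent[id(b)]
        else:
            a = parent[id(a)]
    return a


def lca_mapping_cost(gene: Node, species_tree: Node) -> tuple[int, int, dict]:
    """Duplication and loss counts of the LCA reconciliation.

    Returns (duplications, losses, mapping); mapping maps id(gene node) to
    its species-tree node.  Raises KeyError naming any gene leaf whose
    species is missing from the species tree.
    """
    parent, depth, leaf_of = _species_index(species_tree)
    M: dict[int, Node] = {}
    dups = 0
    losses = 0
    for n in gene.postorder():
        if n.is_leaf:
            sp = species_of(n.label)
            if sp not in leaf_of:
                raise KeyError(
                    f"gene-tree leaf {n.label!r}: species {sp!r} absent from species tree"
                )
            M[id(n)] = leaf_of[sp]
        else:
            m = M[id(n.children[0])]
            for c in n.children[1:]:
                m = _lca(m, M[id(c)], parent, depth)
            M[id(n)] = m
    for n in gene.postorder():
        if n.is_leaf:
            continue
        is_dup = any(M[id(c)] is M[id(n)] for c in n.children)
        if is_dup:
            dups += 1
        for c in n.children:
            d = depth[id(M[id(c)])] - depth[id(M[id(n)])]
            losses += max(0, d - 1 + (1 if is_dup else 0))
    return dups, losses, M


def root_by_duploss(gene_tree: Node, species_tree: Node | str) -> Node:
    """Re-root a gene tree on the edge minimising duplications + losses
    against the species tree (deterministic tie-break on the tree string).

    Midpoint rooting can fabricate clades that conflict with the species
    tree; reconciliation-based rooting removes that artifact.
    """
    sp = parse_newick(species_tree) if isinstance(species_tree, str) else species_tree
    base = dendropy.Tree.get(data=to_newick(gene_tree), schema="newick")
    best = None
    best_key = None
    n_edges = len(base.edges())
    for i in range(n_edges):
        t = base.clone(depth=1)
        edges = [e for e in t.preorder_edge_iter() if e.head_node is not t.seed_node]
        if i >= len(edges):
            continue
        try:
            t.reroot_at_edge(edges[i], update_bipartitions=False)
        except Exception:
            continue
        cand = _from_dendropy(t.seed_node)
        if len(cand.children) != 2:
            continue
        d, l, _ = lca_mapping_cost(cand, sp)
        key = (d + l, to_newick(cand, with_lengths=False))
        if best_key is None or key < best_key:
            best_key, best = key, cand
    return best if best is not None else gene_tree


def _collapse_weak_edges(gene: Node, threshold: float) -> Node:
    g = gene.copy()

    def collapse(n: Node) -> Node:
        new_children = []
        for c in n.children:
            c = collapse(c)
            if (
                not c.is_leaf
                and c.support is not None
                and c.support < threshold
            ):
                new_children.extend(c.children)
            else:
                new_children.append(c)
        n.children = new_children
        return n

    return collapse(g)


def _resolutions(subtrees: list[Node]):
    """All binary topologies joining the given subtrees (standard leaf-
    addition enumeration; (2k-3)!! trees for k subtrees)."""
    if len(subtrees) == 1:
        yield subtrees[0]
        return
    if len(subtrees) == 2:
        yield Node(children=[subtrees[0].copy(), subtrees[1].copy()])
        return
    first, rest = subtrees[0], subtrees[1:]
    for partial in _resolutions(rest):
        for edited in _insert_everywhere(partial, first):
            yield edited


def _insert_everywhere(tree: Node, new: Node):
    # insert on the root edge
    yield Node(children=[tree.copy(), new.copy()])
    # insert on every internal/leaf edge
    def recurse(n: Node, path: list[int]):
        for i, c in enumerate(n.children):
            t = tree.copy()
            target = t
            for p in path:
                target = target.children[p]
            old = target.children[i]
            target.children[i] = Node(children=[old, new.copy()])
            yield t
            yield from recurse(c, path + [i])
    yield from recurse(tree, [])


def _resolve_polytomies(gene: Node, species_tree: Node) -> Node:
    """Re-resolve polytomies to minimise duplications + losses (exhaustive
    for <= 6 children, else a deterministic sequential heuristic)."""
    g = gene.copy()
    changed = True
    while changed:
        changed = False
        for n in g.postorder():
            if len(n.children) <= 2:
                continue
            changed = True
            subtrees = n.children
            if len(subtrees) <= 6:
                best, best_key = None, None
                for cand in _resolutions(subtrees):
                    n.children = cand.children if len(cand.children) == 2 else [cand]
                    dups, losses, _ = lca_mapping_cost(g, species_tree)
                    key = (dups + losses, to_newick(n, with_lengths=False))
                    if best_key is None or key < best_key:
                        best_key, best = key, [c.copy() for c in n.children]
                n.children = best
            else:
                merged = subtrees[0]
                for s in subtrees[1:]:
                    merged = Node(children=[merged, s])
                n.children = merged.children
            break
    return g


def reconcile(
    gene_tree: Node | str,
    species_tree: Node | str,
    bootstrap_threshold: float | None = None,
    cfg: Config | None = None,
) -> ReconciliationResult:
    """Reconcile a rooted gene tree with a rooted species tree.

    Internal gene-tree edges with bootstrap support below the threshold
    (default Config.bootstrap_threshold = 70) are collapsed and re-resolved
    toward minimum duplications + losses; the final binary tree is then
    LCA-mapped.  Duplication nodes are marked 'D' in the annotated tree and
    losses are reported per edge with the species-tree location.
    """
    cfg = cfg or Config()
    thr = cfg.bootstrap_threshold if bootstrap_threshold is None else bootstrap_threshold
    g = parse_newick(gene_tree) if isinstance(gene_tree, str) else gene_tree.copy()
    s = parse_newick(species_tree) if isinstance(species_tree, str) else species_tree
    g = _collapse_weak_edges(g, thr)
    g = _resolve_polytomies(g, s)
    dups, losses, M = lca_mapping_cost(g, s)
    parent, depth, _ = _species_index(s)
    events: list[tuple[str, str]] = []
    for n in g.postorder():
        if n.is_leaf:
            continue
        is_dup = any(M[id(c)] is M[id(n)] for c in n.children)
        if is_dup:
            n.event = "D"
            events.append(
                ("D", f"ancestor of {{{','.join(sorted(n.leaf_labels()))}}}")
            )
        for c in n.children:
            d = depth[id(M[id(c)])] - depth[id(M[id(n)])]
            k = max(0, d - 1 + (1 if is_dup else 0))
            if k:
                sp = M[id(c)]
                walk = sp
                lost_sites = []
                for _ in range(k):
                    p = parent.get(id(walk))
                    if p is None:
                        break
                    sibs = [x for x in p.children if x is not walk]
                    lost_sites.extend(
                        ",".join(sorted(x.leaf_labels())) for x in sibs
                    )
                    walk = p
                for site in lost_sites[:k]:
                    events.append(("L", f"lineage {{{site}}}"))
                for _ in range(k - len(lost_sites)):
                    events.append(("L", "lineage {unresolved}"))
    return ReconciliationResult(g, dups, losses, events)
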