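"""Element and host phylogenetics.

Distances between element sequences use the Tamura–Nei (TN93) model with
pairwise deletion: for each sequence pair, only columns where both rows carry
an unambiguous base are compared, and base frequencies are taken from those
columns.  Trees are built by neighbor joining (Saitou & Nei) with bootstrap
supports from column resampling.  Host-level presence/absence of the element
family is analysed with Fitch parsimony: minimal step count, exhaustive
enumeration of most-parsimonious reconstructions (MPRs), and ACCTRAN/DELTRAN
tracings selected from the MPR set.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import ValidationError

log = logging.getLogger("trimkit")

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturationError(ValueError):
    """Distance undefined: observed divergence outside the model's domain."""


# ---------------------------------------------------------------------------
# Tree type
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A rooted (or conventionally rooted) phylogenetic tree node."""

    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = ""
                if node.support is not None:
                    sup = f"{node.support:g}"
                elif node.name:
                    sup = node.name
                label = f"({inner}){sup}"
            if node.length is not None:
                label += f":{node.length:g}"
            return label

        return fmt(self) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalised as the side lacking the
        alphabetically smallest leaf label (rooting-independent)."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self or node.is_leaf():
                continue
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Patristic (branch-length path) distances between all leaf pairs."""
        dist: dict[tuple[str, str], float] = {}
        for node in self.postorder():
            if node.is_leaf():
                node._below = {node.name: 0.0}  # type: ignore[attr-defined]
                continue
            below: dict[str, float] = {}
            for a, b in itertools.combinations(node.children, 2):
                for la, da in a._below.items():       # type: ignore[attr-defined]
                    for lb, db in b._below.items():   # type: ignore[attr-defined]
                        key = (min(la, lb), max(la, lb))
                        dist[key] = da + db + (a.length or 0.0) + (b.length or 0.0)
            for c in node.children:
                for l, d in c._below.items():         # type: ignore[attr-defined]
                    below[l] = d + (c.length or 0.0)
            node._below = below                        # type: ignore[attr-defined]
        for node in self.postorder():
            if hasattr(node, "_below"):
                del node._below
        return dist

    def find_clades(self):
        """All internal nodes except the root, in preorder."""
        for node in self.preorder():
            if node is not self and not node.is_leaf():
                yield node


# ---------------------------------------------------------------------------
# Alignment container and distances
# ---------------------------------------------------------------------------

@dataclass
class SequenceAlignment:
    """Labelled rows of equal length over {A,C,G,T,N,-}."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValidationError("labels and rows differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate alignment labels")
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("alignment rows have unequal lengths")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def resample_columns(self, rng: np.random.Generator) -> "SequenceAlignment":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return SequenceAlignment(list(self.labels), rows)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValidationError("distance matrix must be symmetric with zero diagonal")
        if (m < -1e-12).any():
            raise ValidationError("negative distances")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def _pair_tn93(ra: str, rb: str, label_a: str, label_b: str,
               freqs: Optional[np.ndarray] = None) -> float:
    """TN93 distance for one row pair under pairwise deletion.

    Base frequencies default to the pair's own comparable sites; a
    pre-computed frequency vector (e.g. alignment-wide) may be supplied.
    """
    pairs = [(x, y) for x, y in zip(ra, rb) if x in _IDX and y in _IDX]
    n = len(pairs)
    if n == 0:
        raise ValidationError(f"no comparable sites for pair ({label_a}, {label_b})")
    if freqs is None:
        counts = np.zeros(4)
        for x, y in pairs:
            counts[_IDX[x]] += 1
            counts[_IDX[y]] += 1
        g = counts / (2 * n)
    else:
        g = freqs
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    p1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n
    p2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n
    q = sum(1 for x, y in pairs if x != y and (x, y) not in _TRANSITIONS) / n

    def safe_log(w: float) -> float:
        if w <= 0:
            raise SaturationError(
                f"TN93 distance undefined for pair ({label_a}, {label_b}): saturated"
            )
        return math.log(w)

    d = 0.0
    if p1 > 0 or (gA * gG > 0 and q > 0):
        if gA * gG == 0:
            raise SaturationError(
                f"TN93 undefined for pair ({label_a}, {label_b}): purine frequency zero"
            )
        k1 = 2 * gA * gG / gR
        d += -k1 * safe_log(1 - p1 / k1 - q / (2 * gR))
    if p2 > 0 or (gC * gT > 0 and q > 0):
        if gC * gT == 0:
            raise SaturationError(
                f"TN93 undefined for pair ({label_a}, {label_b}): pyrimidine frequency zero"
            )
        k2 = 2 * gC * gT / gY
        d += -k2 * safe_log(1 - p2 / k2 - q / (2 * gY))
    if q > 0 or (gR * gY > 0):
        if gR * gY == 0:
            if q > 0:
                raise SaturationError(
                    f"TN93 undefined for pair ({label_a}, {label_b}): one base class absent"
                )
        else:
            k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
            d += -k3 * safe_log(1 - q / (2 * gR * gY))
    return max(d, 0.0)


def tamura_nei_distance(alignment: SequenceAlignment,
                        deletion_mode: str = "pairwise",
                        freq_mode: str = "pair") -> DistanceMatrix:
    """All-against-all TN93 distances.

    ``deletion_mode='pairwise'`` drops gap/N columns per pair;
    ``'complete'`` drops every column containing a gap or N in any row
    first.  ``freq_mode='pair'`` (default) estimates base frequencies from
    each pair's own comparable sites; ``'alignment'`` pools frequencies over
    the whole alignment, the convention of some distance programs.
    """
    rows = alignment.rows
    if deletion_mode == "complete":
        keep = [i for i in range(alignment.n_sites)
                if all(r[i] in _IDX for r in rows)]
        rows = ["".join(r[i] for i in keep) for r in rows]
    elif deletion_mode != "pairwise":
        raise ValidationError(f"unknown deletion mode {deletion_mode!r}")
    global_freqs = None
    if freq_mode == "alignment":
        counts = np.zeros(4)
        for r in rows:
            for c in r:
                if c in _IDX:
                    counts[_IDX[c]] += 1
        global_freqs = counts / counts.sum()
    elif freq_mode != "pair":
        raise ValidationError(f"unknown frequency mode {freq_mode!r}")
    n = len(rows)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _pair_tn93(rows[i], rows[j],
                                           alignment.labels[i], alignment.labels[j],
                                           freqs=global_freqs)
    return DistanceMatrix(list(alignment.labels), m)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the lexicographically smallest pair of cluster
    labels (each cluster is identified by its smallest member label), so the
    result is deterministic.  Negative branch lengths are clamped to zero and
    the clamped deficit is logged.
    """
    labels = list(dm.labels)
    if len(labels) < 2:
        raise ValidationError("neighbor joining needs at least two taxa")
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in labels}
    d = {frozenset((a, b)): dm.get(a, b)
         for a, b in itertools.combinations(labels, 2)}
    active = sorted(labels)
    # cluster key -> smallest contained leaf label (for tie-breaking)
    anchor = {l: l for l in labels}

    def clamp(x: float, where: str) -> float:
        if x < 0:
            log.debug("NJ: clamped negative branch length %.6g at %s", x, where)
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            qv = (n - 2) * d[frozenset((a, b))] - r[a] - r[b]
            key = (qv, min(anchor[a], anchor[b]), max(anchor[a], anchor[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        dab = d[frozenset((a, b))]
        la = dab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = clamp(la, a), clamp(lb, b)
        new_key = f"__nj{len(labels) - n}"
        u = TreeNode(children=[na, nb])
        nodes[new_key] = u
        anchor[new_key] = min(anchor[a], anchor[b])
        for c in active:
            if c in (a, b):
                continue
            duc = (d[frozenset((a, c))] + d[frozenset((b, c))] - dab) / 2
            d[frozenset((new_key, c))] = max(duc, 0.0)
        active = sorted((set(active) - {a, b}) | {new_key},
                        key=lambda k: anchor[k])

    root = TreeNode()
    if len(active) == 3:
        a, b, c = active
        dab = d[frozenset((a, b))]
        dac = d[frozenset((a, c))]
        dbc = d[frozenset((b, c))]
        for x, lx in ((a, (dab + dac - dbc) / 2),
                      (b, (dab + dbc - dac) / 2),
                      (c, (dac + dbc - dab) / 2)):
            node = nodes.pop(x)
            node.length = clamp(lx, x)
            root.children.append(node)
    else:  # exactly two clusters remain
        a, b = active
        dab = d[frozenset((a, b))]
        for x, lx in ((a, dab / 2), (b, dab / 2)):
            node = nodes.pop(x)
            node.length = clamp(lx, x)
            root.children.append(node)
    return root


def bootstrap_support(alignment: SequenceAlignment, n_reps: int = 1000,
                      seed: int = 0, deletion_mode: str = "pairwise") -> TreeNode:
    """NJ tree on the full alignment with bipartition bootstrap supports (%).

    Columns are resampled with replacement; each replicate tree's
    bipartitions are tallied and frequencies are attached to the internal
    nodes of the full-data tree.  Replicates whose distances saturate are
    skipped (counted against the denominator).
    """
    tree = neighbor_joining(tamura_nei_distance(alignment, deletion_mode))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    effective = 0
    for _ in range(n_reps):
        rep = alignment.resample_columns(rng)
        try:
            rep_tree = neighbor_joining(tamura_nei_distance(rep, deletion_mode))
        except (SaturationError, ValidationError):
            continue
        effective += 1
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_leaves = frozenset(tree.leaf_names())
    anchor_label = min(all_leaves)
    for node in tree.find_clades():
        side = frozenset(node.leaf_names())
        if anchor_label in side:
            side = all_leaves - side
        if side in counts and effective > 0:
            node.support = round(100.0 * counts[side] / effective, 1)
    return tree


def cut_subfamilies(tree: TreeNode, min_support: float,
                    max_within_distance: float) -> dict[str, str]:
    """Assign leaves to subfamilies by cutting well-supported compact clades.

    Every internal edge of the (possibly arbitrarily rooted) tree defines a
    split; both sides of a split whose support reaches ``min_support`` are
    candidate subfamilies, provided the mean patristic distance among the
    side's leaves is at most ``max_within_distance``.  Maximal disjoint
    candidates are selected greedily (largest first); leaves outside every
    selected candidate are labelled ``"unassigned"``.  Labels are
    ``SF1, SF2, ...`` ordered by each subfamily's alphabetically smallest
    member.
    """
    pat = tree.leaf_distances()
    all_leaves = frozenset(tree.leaf_names())

    def mean_within(names: frozenset[str]) -> float:
        if len(names) < 2:
            return 0.0
        vals = [pat[(min(a, b), max(a, b))]
                for a, b in itertools.combinations(sorted(names), 2)]
        return float(np.mean(vals))

    candidates: set[frozenset[str]] = set()
    for node in tree.find_clades():
        if node.support is None or node.support < min_support:
            continue
        side = frozenset(node.leaf_names())
        for group in (side, all_leaves - side):
            if 1 < len(group) < len(all_leaves) and \
                    mean_within(group) <= max_within_distance:
                candidates.add(group)

    chosen: list[frozenset[str]] = []
    for group in sorted(candidates, key=lambda g: (-len(g), min(g))):
        if all(group.isdisjoint(c) for c in chosen):
            chosen.append(group)
    chosen.sort(key=lambda g: min(g))
    labels = {leaf: "unassigned" for leaf in tree.leaf_names()}
    for i, group in enumerate(chosen, 1):
        for n in group:
            labels[n] = f"SF{i}"
    return labels


# ---------------------------------------------------------------------------
# Fitch parsimony and MPR enumeration
# ---------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    """All most-parsimonious reconstructions of a binary character."""

    steps: int
    node_order: list[str]                 # postorder node keys (leaves + internals)
    mprs: list[tuple[int, ...]]           # internal+leaf states per node_order
    gains_losses: list[tuple[int, int]]   # per MPR
    acctran: tuple[int, ...]
    deltran: tuple[int, ...]
    mpr_sets: dict[str, set[int]]         # per-node states over all MPRs


def _check_rooted_binary(tree: TreeNode) -> None:
    for node in tree.postorder():
        if node.children and len(node.children) != 2:
            raise ValidationError(
                "parsimony engine requires a rooted binary tree; "
                f"found a node with {len(node.children)} children "
                "(resolve polytomies upstream)"
            )


def _node_keys(tree: TreeNode) -> tuple[list[TreeNode], list[str]]:
    nodes = list(tree.postorder())
    keys = []
    for n in nodes:
        if n.is_leaf():
            keys.append(n.name)
        else:
            keys.append("mrca(" + ",".join(sorted(n.leaf_names())[:2]) +
                        f")+{len(list(n.leaves())) - 2}")
    return nodes, keys


def fitch_parsimony(tree: TreeNode, character: dict[str, int]) -> tuple[int, dict[str, set[int]]]:
    """Fitch small parsimony for a binary (0/1) character on a rooted binary
    tree.  Returns the minimal change count and, per node, the set of states
    realised in at least one most-parsimonious reconstruction.
    """
    _check_rooted_binary(tree)
    leaves = set(tree.leaf_names())
    missing = leaves - set(character)
    if missing:
        raise ValidationError(f"no character state for leaves: {sorted(missing)}")
    nodes, keys = _node_keys(tree)
    below = _sankoff_below(tree, character)
    steps = int(min(below[id(tree)]))
    above = _sankoff_above(tree, below)
    sets: dict[str, set[int]] = {}
    for node, key in zip(nodes, keys):
        total = below[id(node)] + above[id(node)]
        sets[key] = {s for s in (0, 1) if total[s] == steps}
    return steps, sets


def _sankoff_below(tree: TreeNode, character: dict[str, int]) -> dict[int, np.ndarray]:
    INF = 10 ** 9
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            cost = np.array([INF, INF])
            cost[character[node.name]] = 0
        else:
            cost = np.zeros(2)
            for c in node.children:
                child = below[id(c)]
                cost = cost + np.array([
                    min(child[0], child[1] + 1),
                    min(child[1], child[0] + 1),
                ])
        below[id(node)] = cost
    return below


def _sankoff_above(tree: TreeNode, below: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    above: dict[int, np.ndarray] = {id(tree): np.zeros(2)}
    for node in tree.preorder():
        if node.is_leaf():
            continue
        for child in node.children:
            sib_costs = np.zeros(2)
            for sib in node.children:
                if sib is child:
                    continue
                sc = below[id(sib)]
                sib_costs = sib_costs + np.array([
                    min(sc[0], sc[1] + 1), min(sc[1], sc[0] + 1)])
            parent_total = above[id(node)] + sib_costs
            above[id(child)] = np.array([
                min(parent_total[0], parent_total[1] + 1),
                min(parent_total[1], parent_total[0] + 1),
            ])
    return above


def enumerate_mprs(tree: TreeNode, character: dict[str, int]) -> AncestralReconstruction:
    """Exhaustively enumerate all MPRs and pick the ACCTRAN/DELTRAN tracings.

    Backtracking over the Sankoff cost tables yields exactly the assignments
    achieving the minimal change count.  Gains are absent-to-present edges
    (0 to 1), losses the reverse; the state of the root itself is not counted
    as a change.  ACCTRAN is the MPR whose changes sit closest to the root
    (minimal summed root-distance of change edges, then fewest gains —
    favouring reversals); DELTRAN delays changes toward the tips (maximal
    summed root-distance, then most gains — favouring parallel gains).
    """
    steps, _sets = fitch_parsimony(tree, character)
    nodes, keys = _node_keys(tree)
    below = _sankoff_below(tree, character)
    index = {id(n): i for i, n in enumerate(nodes)}
    depth = {id(tree): 0}
    for node in tree.preorder():
        for c in node.children:
            depth[id(c)] = depth[id(node)] + 1

    assignments: list[tuple[int, ...]] = []
    state = [0] * len(nodes)

    def _descend(frontier: list[tuple[TreeNode, int]]) -> None:
        if not frontier:
            assignments.append(tuple(state))
            return
        node, parent_state = frontier[0]
        rest = frontier[1:]
        costs = below[id(node)]
        options = [s for s in (0, 1)
                   if costs[s] + (s != parent_state)
                   == min(costs[t] + (t != parent_state) for t in (0, 1))]
        for s in options:
            state[index[id(node)]] = s
            _descend([(c, s) for c in node.children] + rest)

    root_costs = below[id(tree)]
    for s in (0, 1):
        if root_costs[s] == steps:
            state[index[id(tree)]] = s
            _descend([(c, s) for c in tree.children])

    assignments = sorted(set(assignments))

    def changes(assign_vec: tuple[int, ...]):
        out = []
        for node in tree.preorder():
            ps = assign_vec[index[id(node)]]
            for c in node.children:
                cs = assign_vec[index[id(c)]]
                if cs != ps:
                    out.append((ps, cs, depth[id(c)]))
        return out

    gains_losses = []
    scored = []
    for vec in assignments:
        ch = changes(vec)
        assert len(ch) == steps, "MPR does not realise the Fitch step count"
        gains = sum(1 for a, b, _ in ch if a == 0)
        losses = len(ch) - gains
        depthsum = sum(d for _, _, d in ch)
        gains_losses.append((gains, losses))
        scored.append((depthsum, gains, vec))
    acctran = min(scored, key=lambda t: (t[0], t[1], t[2]))[2]
    deltran = max(scored, key=lambda t: (t[0], t[1], tuple(-x for x in t[2])))[2]

    mpr_sets: dict[str, set[int]] = {k: set() for k in keys}
    for vec in assignments:
        for key, s in zip(keys, vec):
            mpr_sets[key].add(s)

    return AncestralReconstruction(
        steps=steps, node_order=keys, mprs=assignments,
        gains_losses=gains_losses, acctran=acctran, deltran=deltran,
        mpr_sets=mpr_sets,
    )


def gains_and_losses(recon: AncestralReconstruction,
                     vec: tuple[int, ...]) -> tuple[int, int]:
    """(gains, losses) of one enumerated reconstruction."""
    i = recon.mprs.index(vec)
    return recon.gains_losses[i]


# ---------------------------------------------------------------------------
# Packaged host fixture: ant genus tree and element presence/absence
# ---------------------------------------------------------------------------

def load_host_tree() -> TreeNode:
    """The 13-taxon host species tree (12 ant species + Apis outgroup).

    Genus-level relationships follow published ant phylogenies; the tree is
    rooted on *Apis mellifera*.  Within Myrmicinae, Pogonomyrmex branches
    first, Aphaenogaster+Messor form a clade, and Pheidole is sister to
    Solenopsis within the Crematogaster clade.
    """
    from importlib import resources
    from . import core_io

    text = (resources.files("trimkit") / "data" / "ant_host_tree.nwk").read_text()
    return core_io.read_newick(text)


def load_host_presence() -> dict[str, int]:
    """Presence (1) / absence (0) of the TRIM family per host-tree leaf."""
    from importlib import resources

    text = (resources.files("trimkit") / "data" / "ant_trim_presence.tsv").read_text()
    out: dict[str, int] = {}
    for line in text.splitlines():
        if not line or line.startswith("taxon"):
            continue
        taxon, state = line.split("\t")
        out[taxon] = {"present": 1, "absent": 0}[state]
    return out


# ---------------------------------------------------------------------------
# Simple progressive alignment (plumbing for synthetic tests)
# ---------------------------------------------------------------------------

def progressive_align(seqs: dict[str, str]) -> SequenceAlignment:
    """Center-star progressive alignment (global pairwise merges).

    A deliberately simple helper for aligning synthetic element sets that
    differ by substitutions and occasional short indels; it is not a
    replacement for a full multiple-alignment program.
    """
    from Bio import Align

    labels = list(seqs)
    if len({len(s) for s in seqs.values()}) == 1:
        return SequenceAlignment(labels, [seqs[l] for l in labels])

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2

    center = max(labels, key=lambda l: len(seqs[l]))
    center_seq = seqs[center]
    # per-position gap counts to merge pairwise alignments against the center
    master_gaps = [0] * (len(center_seq) + 1)
    pair_rows: dict[str, tuple[str, str]] = {}
    for label in labels:
        if label == center:
            continue
        aln = aligner.align(center_seq, seqs[label])[0]
        c_row, o_row = str(aln[0]), str(aln[1])
        pair_rows[label] = (c_row, o_row)
        pos = 0
        run = 0
        for ch in c_row:
            if ch == "-":
                run += 1
            else:
                master_gaps[pos] = max(master_gaps[pos], run)
                run = 0
                pos += 1
        master_gaps[pos] = max(master_gaps[pos], run)

    def expand(c_row: str, o_row: str) -> str:
        out = []
        pos = 0
        run = 0
        chunks: list[str] = []
        chunk: list[str] = []
        for c_ch, o_ch in zip(c_row, o_row):
            if c_ch == "-":
                run += 1
                chunk.append(o_ch)
            else:
                out.append("-" * (master_gaps[pos] - run) + "".join(chunk))
                chunk = []
                run = 0
                out.append(o_ch)
                pos += 1
        out.append("-" * (master_gaps[pos] - run) + "".join(chunk))
        return "".join(out)

    rows = []
    for label in labels:
        if label == center:
            padded = []
            for pos, ch in enumerate(center_seq):
                padded.append("-" * master_gaps[pos])
                padded.append(ch)
            padded.append("-" * master_gaps[len(center_seq)])
            rows.append("".join(padded))
        else:
            rows.append(expand(*pair_rows[label]))
    return SequenceAlignment(labels, rows)
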