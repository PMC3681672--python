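"""Irreversible (Camin-Sokal-style) parsimony with DELTRAN placement.

Characters are binary SGA presence states rooted at an all-zero LUCA
outgroup; the 1 -> 0 transition carries infinite cost, so the score of a
character is the minimum number of independent 0 -> 1 gains explaining
the tips that carry it.  Under irreversibility that minimum has a unique
realization: one gain on the stem of each maximal clade whose tips all
carry the character — which is also the *latest* (DELTRAN, delayed-
transformation) placement.  A character carried by every tip gains once
on the LUCA -> MRCA stem.

Branches are identified by the sorted tip set below them (stable across
equivalent tree representations).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .matrix import SgaMatrix
from .trees import SampledTree, TreeNode

BranchId = tuple[str, ...]  # sorted tip names below the branch


# --------------------------------------------------------------------------
# topologies
# --------------------------------------------------------------------------

NestedTopology = object  # a tip name, or a 2-tuple of NestedTopology


def topology_from_tuples(spec, tip_time: float = 0.0) -> SampledTree:
    """Build a dated SampledTree from a nested-tuple topology.

    Internal nodes get arbitrary valid times (depth-proportional); tips
    are contemporaneous.  Suitable wherever only the topology matters.
    """

    def depth(s) -> int:
        return 1 + max(depth(c) for c in s) if isinstance(s, tuple) else 0

    total = depth(spec)

    def build(s, level: int) -> TreeNode:
        if not isinstance(s, tuple):
            return TreeNode(str(s), tip_time)
        node = TreeNode(time=tip_time - (total - level))
        for child in s:
            node.add_child(build(child, level + 1))
        return node

    root = build(spec, 0)
    luca = TreeNode("LUCA", root.time - 1.0)
    luca.add_child(root)
    return SampledTree(luca)


def enumerate_rooted_topologies(names: list[str]):
    """All rooted binary topologies on ``names`` as nested tuples.

    (2n-3)!! trees, generated by leaf insertion on every edge including
    the stem above the root; deterministic order.
    """
    if len(names) == 0:
        return
    if len(names) == 1:
        yield names[0]
        return

    def insert(t, leaf):
        yield (t, leaf)
        if isinstance(t, tuple):
            for left in insert(t[0], leaf):
                yield (left, t[1])
            for right in insert(t[1], leaf):
                yield (t[0], right)

    for sub in enumerate_rooted_topologies(names[:-1]):
        yield from insert(sub, names[-1])


def _clades(spec, tip_bit: dict[str, int]) -> tuple[int, list[tuple[int, int]]]:
    """(full mask, list of (clade mask, parent mask)) in postorder.

    The parent mask of the root is 0 (a proxy for the all-zero LUCA)."""
    edges: list[tuple[int, int]] = []

    def walk(s) -> int:
        if not isinstance(s, tuple):
            return tip_bit[s]
        mask = 0
        children = [walk(c) for c in s]
        for m in children:
            mask |= m
        for m in children:
            edges.append((m, mask))
        return mask

    root_mask = walk(spec)
    edges.append((root_mask, 0))
    return root_mask, edges


def _score_masks(edges: list[tuple[int, int]], full: int, char_mask: int) -> int:
    """Gains for one character: maximal carrier-pure clades."""
    if char_mask == 0:
        return 0
    not_s = full & ~char_mask
    gains = 0
    for clade, parent in edges:
        if clade & not_s == 0 and (parent == 0 or parent & not_s != 0):
            gains += 1
    return gains


# --------------------------------------------------------------------------
# scoring on trees
# --------------------------------------------------------------------------

@dataclass
class ParsimonyResult:
    tree: SampledTree
    score: int
    placements: dict[int, list[BranchId]]  # character column -> gain branches
    branch_events: dict[BranchId, list[int]] = field(default_factory=dict)

    def branch_count(self, branch: BranchId) -> int:
        return len(self.branch_events.get(branch, []))


def branch_id_of(node: TreeNode) -> BranchId:
    tips = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            tips.append(n.name)
        else:
            stack.extend(n.children)
    return tuple(sorted(tips))


def camin_sokal_score(tree: SampledTree, matrix: SgaMatrix) -> ParsimonyResult:
    """Minimum-gain score and the (unique, DELTRAN) gain placements.

    Per character, a gain sits on the stem of each maximal clade all of
    whose tips carry the character; reversals are forbidden.
    """
    tip_names = tree.tip_names()
    if set(tip_names) != set(matrix.biopsy_ids):
        raise ValueError("tree tips and matrix rows must match")
    row = {b: i for i, b in enumerate(matrix.biopsy_ids)}
    # postorder purity per character
    pure: dict[int, np.ndarray] = {}
    placements: dict[int, list[BranchId]] = {j: [] for j in range(matrix.n_characters)}
    branch_events: dict[BranchId, list[int]] = {}
    score = 0
    for node in tree.postorder():
        if node.is_leaf:
            pure[id(node)] = matrix.data[row[node.name]].astype(bool)
        elif node is tree.luca:
            pure[id(node)] = np.zeros(matrix.n_characters, dtype=bool)
        else:
            p = pure[id(node.children[0])].copy()
            for c in node.children[1:]:
                p &= pure[id(c)]
            pure[id(node)] = p
    for node in tree.postorder():
        if node is tree.luca:
            continue
        gains = pure[id(node)] & ~pure[id(node.parent)]
        if gains.any():
            bid = branch_id_of(node)
            cols = np.flatnonzero(gains)
            branch_events.setdefault(bid, []).extend(int(j) for j in cols)
            for j in cols:
                placements[int(j)].append(bid)
            score += len(cols)
    return ParsimonyResult(tree, score, placements, branch_events)


def _matrix_masks(matrix: SgaMatrix, names: list[str]) -> list[int]:
    row = {b: i for i, b in enumerate(matrix.biopsy_ids)}
    masks = []
    for j in range(matrix.n_characters):
        m = 0
        for k, nm in enumerate(names):
            if matrix.data[row[nm], j]:
                m |= 1 << k
        masks.append(m)
    return masks


def search_max_parsimony(
    matrix: SgaMatrix,
    strategy: str = "auto",
    max_exhaustive_taxa: int = 9,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[list[SampledTree], int]:
    """Best topologies under irreversible parsimony.

    Exhaustive for small taxon sets; NNI+SPR hill-climbing with random
    restarts beyond.  Returns all co-optimal topologies (exhaustive mode)
    or the distinct optima found (heuristic mode), in a deterministic
    canonical order, plus the optimal score.
    """
    names = sorted(matrix.biopsy_ids)
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")
    tip_bit = {nm: 1 << k for k, nm in enumerate(names)}
    char_masks = _matrix_masks(matrix, names)
    exhaustive = strategy == "exhaustive" or (
        strategy == "auto" and len(names) <= max_exhaustive_taxa
    )

    def score_spec(spec) -> int:
        full, edges = _clades(spec, tip_bit)
        return sum(_score_masks(edges, full, cm) for cm in char_masks)

    if exhaustive:
        best: list = []
        best_score = None
        for spec in enumerate_rooted_topologies(names):
            s = score_spec(spec)
            if best_score is None or s < best_score:
                best, best_score = [spec], s
            elif s == best_score:
                best.append(spec)
        best = sorted(set(best), key=_canonical_key)
        return [topology_from_tuples(b) for b in best], int(best_score)

    rng = np.random.default_rng(seed)
    best_specs: set = set()
    best_score = None
    for _ in range(n_restarts):
        order = list(names)
        rng.shuffle(order)
        spec = (order[0], order[1])
        for nm in order[2:]:
            candidates = list(_insertions(spec, nm))
            scores = [score_spec(c) for c in candidates]
            spec = candidates[int(np.argmin(scores))]
        spec, s = _hill_climb(spec, score_spec)
        if best_score is None or s < best_score:
            best_specs, best_score = {spec}, s
        elif s == best_score:
            best_specs.add(spec)
    ordered = sorted(best_specs, key=_canonical_key)
    return [topology_from_tuples(b) for b in ordered], int(best_score)


def _insertions(t, leaf):
    yield (t, leaf)
    if isinstance(t, tuple):
        for left in _insertions(t[0], leaf):
            yield (left, t[1])
        for right in _insertions(t[1], leaf):
            yield (t[0], right)


def _subtrees(t):
    """All proper subtrees (prunable pieces) of a nested topology."""
    if isinstance(t, tuple):
        for child in t:
            yield child
            yield from _subtrees(child)


def _remove(t, sub):
    """Topology with subtree ``sub`` pruned (None if t == sub)."""
    if t == sub:
        return None
    if not isinstance(t, tuple):
        return t
    left = _remove(t[0], sub)
    right = _remove(t[1], sub)
    if left is None:
        return right
    if right is None:
        return left
    return (left, right)


def _spr_neighbours(t):
    for sub in set(_subtrees(t)):
        rest = _remove(t, sub)
        if rest is None or not isinstance(t, tuple):
            continue
        for candidate in _insertions(rest, sub):
            if candidate != t:
                yield candidate


def _hill_climb(spec, score_fn):
    s = score_fn(spec)
    improved = True
    while improved:
        improved = False
        for nb in _spr_neighbours(spec):
            s_nb = score_fn(nb)
            if s_nb < s:
                spec, s = nb, s_nb
                improved = True
                break
    return spec, s


def _canonical_key(spec):
    """Deterministic ordering key: the sorted-Newick string of a topology."""

    def canon(s):
        if not isinstance(s, tuple):
            return str(s)
        parts = sorted(canon(c) for c in s)
        return "(" + ",".join(parts) + ")"

    return canon(spec)


# --------------------------------------------------------------------------
# epoch classification and branch lengths
# --------------------------------------------------------------------------

def classify_branch_epochs(
    tree: SampledTree, tip_status: dict[str, str], pattern: str
) -> dict[BranchId, str]:
    """Label every branch with the NSAID epoch it evolved in.

    Off->on individuals: any off-NSAID descendant biopsy makes the branch
    "off" (it existed before the transition), otherwise "on"; mirrored
    for on->off individuals.
    """
    if pattern not in ("off_on", "on_off"):
        raise ValueError("pattern must be 'off_on' or 'on_off'")
    first = "off" if pattern == "off_on" else "on"
    second = "on" if pattern == "off_on" else "off"
    labels: dict[BranchId, str] = {}
    has_first: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in tip_status:
                raise ValueError(f"tip {node.name!r} has no NSAID status")
            has_first[id(node)] = tip_status[node.name] == first
        else:
            has_first[id(node)] = any(has_first[id(c)] for c in node.children)
        if node.parent is not None:
            labels[branch_id_of(node)] = first if has_first[id(node)] else second
    return labels


def branch_lengths(
    result: ParsimonyResult, mode: str = "count", sizes_bp: np.ndarray | None = None
) -> dict[BranchId, float]:
    """Per-branch lengths: event count or total genome affected (Mb)."""
    if mode not in ("count", "Mb"):
        raise ValueError("mode must be 'count' or 'Mb'")
    out: dict[BranchId, float] = {}
    for node in result.tree.postorder():
        if node.parent is None:
            continue
        bid = branch_id_of(node)
        cols = result.branch_events.get(bid, [])
        if mode == "count":
            out[bid] = float(len(cols))
        else:
            if sizes_bp is None:
                raise ValueError("mode='Mb' requires character sizes")
            out[bid] = float(sum(sizes_bp[j] for j in cols)) / 1e6
    return out


def brute_force_min_gains(tree: SampledTree, carriers: set[str]) -> int:
    """Independent oracle: minimum gains by exhaustive enumeration of
    internal-node state assignments with reversals forbidden (testing aid;
    exponential in the number of internal nodes)."""
    nodes = [n for n in tree.postorder()]
    internal = [n for n in nodes if not n.is_leaf and n is not tree.luca]
    state = {id(tree.luca): 0}
    for tip in tree.tips():
        state[id(tip)] = 1 if tip.name in carriers else 0
    best = None
    for assign in itertools.product([0, 1], repeat=len(internal)):
        for n, s in zip(internal, assign):
            state[id(n)] = s
        ok = True
        gains = 0
        for n in nodes:
            if n.parent is None:
                continue
            sp, sc = state[id(n.parent)], state[id(n)]
            if sp == 1 and sc == 0:
                ok = False
                break
            if sp == 0 and sc == 1:
                gains += 1
        if ok and (best is None or gains < best):
            best = gains
    return int(best)
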