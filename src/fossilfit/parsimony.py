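"""Maximum parsimony on unordered multistate morphological characters.

Scoring follows Fitch small parsimony: every cell contributes a state set
(singleton if observed, the coded set if polymorphic, the full state set if
missing), and tree length is the minimum number of state changes summed over
characters. Binary trees are scored with the classic bitmask Fitch pass;
arbitrary (multifurcating) trees are scored exactly with unit-cost Sankoff
dynamic programming, which the branch-collapse rule relies on.

Search is provided in two forms: an exact branch-and-bound enumeration of all
most parsimonious trees (MPTs) for small taxon sets, and a heuristic
(random-addition starts, subtree-pruning-regrafting hill climbing, and
parsimony-ratchet reweighting cycles) for larger matrices. Clade support is
estimated by nonparametric bootstrap over characters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .charmatrix import CharacterMatrix
from .trees import PhyloTree, strict_consensus, _canon

__all__ = [
    "SearchConfig",
    "TreeSet",
    "ParsimonyStats",
    "BootstrapResult",
    "encode_matrix",
    "fitch_length",
    "exact_search",
    "heuristic_search",
    "enumerate_binary_trees",
    "parsimony_stats",
    "bootstrap",
    "collapse_zero_length_branches",
    "write_newick",
]

_INF = np.int64(1 << 30)


# ---------------------------------------------------------------------------
# Encoding and scoring
# ---------------------------------------------------------------------------

def encode_matrix(matrix: CharacterMatrix):
    """Bitmask encoding: array (n_chars, n_taxa) of state-set masks.

    Missing cells encode as the full state set of their character.
    """
    n_states = np.array([c.n_states for c in matrix.characters], dtype=np.int64)
    if n_states.max() > 62:
        raise ValueError("more than 62 states per character not supported")
    S = np.zeros((matrix.n_characters, matrix.n_taxa), dtype=np.int64)
    for i in range(matrix.n_taxa):
        for j in range(matrix.n_characters):
            cell = matrix.cells[i][j]
            if cell.kind == "missing":
                S[j, i] = (1 << int(n_states[j])) - 1
            else:
                mask = 0
                for s in cell.states:
                    mask |= 1 << s
                S[j, i] = mask
    return S, n_states


def _fitch_steps(tree: PhyloTree, S: np.ndarray) -> np.ndarray:
    """Per-character Fitch step counts on a binary tree (pairwise merging)."""
    n = tree.n_taxa
    root = min(k for k in tree.adj if k < n)
    steps = np.zeros(S.shape[0], dtype=np.int64)
    sets: dict = {}
    for node, parent in tree.postorder(root=root):
        if node < n:
            sets[node] = S[:, node]
            continue
        acc = None
        for child in tree.adj[node]:
            if child == parent:
                continue
            cs = sets[child]
            if acc is None:
                acc = cs
            else:
                inter = acc & cs
                nz = inter != 0
                steps += ~nz
                acc = np.where(nz, inter, acc | cs)
        sets[node] = acc
    hub = next(iter(tree.adj[root]))
    steps += (sets[hub] & S[:, root]) == 0
    return steps


def _sankoff_steps(tree: PhyloTree, S: np.ndarray, n_states: np.ndarray) -> np.ndarray:
    """Exact per-character minimum changes on an arbitrary tree (unit costs)."""
    n = tree.n_taxa
    kmax = int(n_states.max())
    nch = S.shape[0]
    srange = np.arange(kmax)
    allowed_pad = srange[None, :] < n_states[:, None]  # (nch, kmax)

    def leaf_cost(i):
        present = (S[:, i][:, None] >> srange[None, :]) & 1
        cost = np.where(present.astype(bool), 0, _INF)
        return np.where(allowed_pad, cost, _INF)

    root = min(k for k in tree.adj if k < n)
    costs: dict = {}
    for node, parent in tree.postorder(root=root):
        if node < n:
            costs[node] = leaf_cost(node)
            continue
        total = np.zeros((nch, kmax), dtype=np.int64)
        for child in tree.adj[node]:
            if child == parent:
                continue
            c = costs[child]
            best = c.min(axis=1, keepdims=True)
            total += np.minimum(c, best + 1)
        costs[node] = np.where(allowed_pad, total, _INF)
    hub = next(iter(tree.adj[root]))
    c = costs[hub]
    final = np.minimum(c, c.min(axis=1, keepdims=True) + 1) + leaf_cost(root)
    return final.min(axis=1)


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix, weights=None) -> int:
    """Minimum number of state changes of ``matrix`` on ``tree``.

    Accepts multifurcating trees (scored exactly by Sankoff DP); binary trees
    take the fast Fitch path. ``weights`` are per-character resampling
    weights (bootstrap); default 1.
    """
    if set(tree.taxa) - set(matrix.taxa):
        missing = sorted(set(tree.taxa) - set(matrix.taxa))
        raise ValueError(f"tree leaves without a matrix row: {missing}")
    sub = matrix if list(tree.taxa) == matrix.taxa else _reorder(matrix, tree.taxa)
    S, n_states = encode_matrix(sub)
    if tree.is_binary():
        steps = _fitch_steps(tree, S)
    else:
        steps = _sankoff_steps(tree, S, n_states)
    if weights is None:
        return int(steps.sum())
    return int(np.dot(steps, np.asarray(weights)))


def _reorder(matrix: CharacterMatrix, taxa) -> CharacterMatrix:
    rows = [list(matrix.row(t)) for t in taxa]
    return CharacterMatrix(taxa=list(taxa), characters=list(matrix.characters), cells=rows)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TreeSet:
    """Deduplicated equally parsimonious binary trees with common length."""

    trees: list
    length: int

    def __post_init__(self) -> None:
        seen, uniq = set(), []
        for t in self.trees:
            key = t.splits()
            if key not in seen:
                seen.add(key)
                uniq.append(t)
        self.trees = uniq

    def __len__(self) -> int:
        return len(self.trees)

    def n_mpts_collapsed(self, matrix: CharacterMatrix) -> int:
        """MPT count after collapsing branches with zero minimum length."""
        seen = set()
        for t in self.trees:
            seen.add(collapse_zero_length_branches(t, matrix).splits())
        return len(seen)


@dataclass(frozen=True)
class ParsimonyStats:
    TL: int
    CI: float
    RI: float
    m: int
    g: int

    @property
    def CI_2dp(self) -> float:
        return round(self.CI, 2)

    @property
    def RI_2dp(self) -> float:
        return round(self.RI, 2)


@dataclass
class BootstrapResult:
    n_replicates: int
    seed: int
    supports: dict  # canonical split mask -> percentage [0, 100]
    taxa: tuple

    def support_of(self, group) -> float:
        """Support of the split separating ``group`` (taxon names) from the rest."""
        n = len(self.taxa)
        full = (1 << n) - 1
        mask = 0
        for name in group:
            mask |= 1 << self.taxa.index(name)
        return self.supports.get(_canon(mask, full), 0.0)


# ---------------------------------------------------------------------------
# Branch collapsing (zero-minimum-length rule)
# ---------------------------------------------------------------------------

def collapse_zero_length_branches(tree: PhyloTree, matrix: CharacterMatrix) -> PhyloTree:
    """Collapse internal branches that can carry zero changes on some
    most parsimonious reconstruction.

    An internal edge is collapsible iff contracting it (creating a polytomy)
    leaves the exact tree length unchanged; all such edges are removed.
    """
    sub = matrix if list(tree.taxa) == matrix.taxa else _reorder(matrix, tree.taxa)
    S, n_states = encode_matrix(sub)
    base = int(_sankoff_steps(tree, S, n_states).sum())
    n = tree.n_taxa
    internal_edges = [(u, v) for u, v in tree.edges() if u >= n and v >= n]
    collapsible = []
    for u, v in internal_edges:
        trial = tree.copy()
        _contract(trial, u, v)
        if int(_sankoff_steps(trial, S, n_states).sum()) == base:
            collapsible.append((u, v))
    out = tree.copy()
    alias: dict = {}

    def find(x):
        while x in alias:
            x = alias[x]
        return x

    for u, v in collapsible:
        fu, fv = find(u), find(v)
        if fu == fv or fv not in out.adj.get(fu, ()):
            continue
        _contract(out, fu, fv)
        alias[fv] = fu
    return out


def _contract(tree: PhyloTree, u: int, v: int) -> None:
    """Merge node v into node u (edge u-v disappears)."""
    tree.adj[u].discard(v)
    for nbr in tree.adj.pop(v):
        if nbr == u:
            continue
        tree.adj[nbr].discard(v)
        tree.adj[nbr].add(u)
        tree.adj[u].add(nbr)


# ---------------------------------------------------------------------------
# Tree enumeration and stepwise addition
# ---------------------------------------------------------------------------

def _three_taxon_tree(taxa_order, taxa) -> PhyloTree:
    n = len(taxa)
    hub = n
    a, b, c = taxa_order[:3]
    adj = {hub: {a, b, c}, a: {hub}, b: {hub}, c: {hub}}
    return PhyloTree(taxa=taxa, adj=adj)


def _insert_on_edge(tree: PhyloTree, leaf: int, edge, next_id: int) -> PhyloTree:
    u, v = edge
    t = tree.copy()
    t.adj[u].discard(v)
    t.adj[v].discard(u)
    t.adj[next_id] = {u, v, leaf}
    t.adj[u].add(next_id)
    t.adj[v].add(next_id)
    t.adj[leaf] = {next_id}
    return t


def enumerate_binary_trees(taxa):
    """Yield every unrooted binary tree over ``taxa`` (1·3·5···(2n-5) trees)."""
    taxa = tuple(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    order = list(range(n))

    def grow(tree, next_leaf_pos, next_id):
        if next_leaf_pos == n:
            yield tree
            return
        leaf = order[next_leaf_pos]
        for edge in list(tree.edges()):
            yield from grow(
                _insert_on_edge(tree, leaf, edge, next_id), next_leaf_pos + 1, next_id + 1
            )

    yield from grow(_three_taxon_tree(order, taxa), 3, n + 1)


def _taxon_variability(matrix: CharacterMatrix) -> list:
    """Addition order: decreasing variability, ties by matrix row order."""
    S, n_states = encode_matrix(matrix)
    full = (1 << n_states) - 1
    # modal singleton mask per character
    scores = []
    for i in range(matrix.n_taxa):
        col = S[:, i]
        informative = col != full  # non-missing
        # deviation from the commonest observed mask
        dev = 0
        for j in range(matrix.n_characters):
            if not informative[j]:
                continue
            others = [S[j, k] for k in range(matrix.n_taxa) if k != i and S[j, k] != full[j]]
            if others and all((S[j, i] & o) == 0 for o in others):
                dev += 2
            elif others and any((S[j, i] & o) == 0 for o in others):
                dev += 1
        scores.append((-dev, i))
    return [i for _, i in sorted(scores)]


def exact_search(matrix: CharacterMatrix, max_taxa: int = 12) -> TreeSet:
    """Branch-and-bound enumeration of all MPTs.

    Refuses matrices above ``max_taxa`` taxa to prevent accidental
    exponential runs. Taxa are added in decreasing-variability order and a
    partial tree is abandoned as soon as its length exceeds the best
    complete length found so far (partial length is monotone in taxon
    addition under Fitch).
    """
    n = matrix.n_taxa
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceeds max_taxa={max_taxa}; raise the limit explicitly "
            "or use heuristic_search"
        )
    taxa = tuple(matrix.taxa)
    if n < 4:
        tree = PhyloTree.star(taxa)
        return TreeSet(trees=[tree], length=fitch_length(tree, matrix))
    S, _ = encode_matrix(matrix)
    order = _taxon_variability(matrix)

    # initial upper bound by greedy addition along the same order
    best = [_greedy_length(S, order, taxa)]
    hits: list = []

    def recurse(tree, pos, next_id):
        length = int(_fitch_steps(tree, S).sum())
        if length > best[0]:
            return
        if pos == n:
            if length < best[0]:
                best[0] = length
                hits.clear()
            hits.append(tree)
            return
        leaf = order[pos]
        for edge in list(tree.edges()):
            recurse(_insert_on_edge(tree, leaf, edge, next_id), pos + 1, next_id + 1)

    recurse(_three_taxon_tree(order, taxa), 3, n + 1)
    final = [t for t in hits if int(_fitch_steps(t, S).sum()) == best[0]]
    return TreeSet(trees=final, length=best[0])


def _greedy_length(S, order, taxa) -> int:
    tree = _three_taxon_tree(order, taxa)
    next_id = len(taxa) + 1
    for pos in range(3, len(order)):
        leaf = order[pos]
        best_tree, best_len = None, None
        for edge in list(tree.edges()):
            cand = _insert_on_edge(tree, leaf, edge, next_id)
            ln = int(_fitch_steps(cand, S).sum())
            if best_len is None or ln < best_len:
                best_tree, best_len = cand, ln
        tree = best_tree
        next_id += 1
    return int(_fitch_steps(tree, S).sum())


# ---------------------------------------------------------------------------
# Heuristic search: random addition + SPR + parsimony ratchet
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    n_starts: int = 5
    ratchet_iterations: int = 3
    perturbation_fraction: float = 0.25
    seed: int = 0
    max_equal_trees: int = 64  # cap on the MPT plateau enumeration

    def __post_init__(self) -> None:
        if not 0 <= self.perturbation_fraction <= 1:
            raise ValueError("perturbation_fraction must be in [0, 1]")


def _spr_neighbourhood(tree: PhyloTree):
    """Yield all subtree-pruning-regrafting neighbours of a binary tree."""
    n = tree.n_taxa
    for u, v in list(tree.edges()):
        for prune_root, anchor in ((v, u), (u, v)):
            # detach subtree rooted at prune_root (seen from anchor)
            sub_nodes = _collect(tree, prune_root, anchor)
            if len(sub_nodes) == 2 * n - 2 - 1:
                continue
            rest = tree.copy()
            rest.adj[anchor].discard(prune_root)
            rest.adj[prune_root].discard(anchor)
            # suppress anchor if it became degree 2
            if anchor >= n and len(rest.adj[anchor]) == 2:
                a, b = rest.adj.pop(anchor)
                rest.adj[a].discard(anchor)
                rest.adj[b].discard(anchor)
                rest.adj[a].add(b)
                rest.adj[b].add(a)
                reuse = anchor
            else:
                reuse = max(rest.adj) + 1
            base_edges = [
                (x, y)
                for x, y in rest.edges()
                if x not in sub_nodes and y not in sub_nodes
            ]
            for x, y in base_edges:
                cand = rest.copy()
                cand.adj[x].discard(y)
                cand.adj[y].discard(x)
                cand.adj[reuse] = {x, y, prune_root}
                cand.adj[x].add(reuse)
                cand.adj[y].add(reuse)
                cand.adj[prune_root].add(reuse)
                yield cand


def _collect(tree, node, parent):
    out, stack = set(), [(node, parent)]
    while stack:
        u, p = stack.pop()
        out.add(u)
        for nbr in tree.adj[u]:
            if nbr != p:
                stack.append((nbr, u))
    return out


def _hill_climb(tree, S, weights):
    cur = tree
    cur_len = float(np.dot(_fitch_steps(cur, S), weights))
    improved = True
    while improved:
        improved = False
        for cand in _spr_neighbourhood(cur):
            ln = float(np.dot(_fitch_steps(cand, S), weights))
            if ln < cur_len:
                cur, cur_len = cand, ln
                improved = True
                break
    return cur, cur_len


def _random_addition_tree(S, taxa, rng) -> PhyloTree:
    n = len(taxa)
    order = list(rng.permutation(n))
    tree = _three_taxon_tree(order, tuple(taxa))
    next_id = n + 1
    for pos in range(3, n):
        leaf = order[pos]
        best_tree, best_len = None, None
        for edge in list(tree.edges()):
            cand = _insert_on_edge(tree, leaf, edge, next_id)
            ln = int(_fitch_steps(cand, S).sum())
            if best_len is None or ln < best_len:
                best_tree, best_len = cand, ln
        tree = best_tree
        next_id += 1
    return tree


def heuristic_search(
    matrix: CharacterMatrix,
    config: SearchConfig | None = None,
    weights=None,
) -> TreeSet:
    """Random-addition + SPR + ratchet search for minimum-length trees.

    Deterministic given ``config.seed``. Returns all distinct trees found at
    the best length (plateau explored through equal-length SPR moves, capped
    at ``config.max_equal_trees``).
    """
    if matrix.n_taxa < 4:
        tree = PhyloTree.star(tuple(matrix.taxa))
        return TreeSet(trees=[tree], length=fitch_length(tree, matrix))
    config = config or SearchConfig()
    rng = np.random.default_rng(config.seed)
    S, _ = encode_matrix(matrix)
    nch = S.shape[0]
    w0 = np.ones(nch) if weights is None else np.asarray(weights, dtype=float)

    best_len = None
    best_trees: list = []

    def consider(tree, ln):
        nonlocal best_len
        if best_len is None or ln < best_len:
            best_len = ln
            best_trees.clear()
        if ln == best_len:
            key = tree.splits()
            if all(key != t.splits() for t in best_trees):
                best_trees.append(tree)

    for _ in range(config.n_starts):
        tree = _random_addition_tree(S, matrix.taxa, rng)
        tree, ln = _hill_climb(tree, S, w0)
        consider(tree, ln)
        for _ in range(config.ratchet_iterations):
            boost = rng.random(nch) < config.perturbation_fraction
            wpert = w0 * np.where(boost, 2.0, 1.0)
            tree, _ = _hill_climb(tree, S, wpert)
            tree, ln = _hill_climb(tree, S, w0)
            consider(tree, ln)

    # plateau: equal-length SPR neighbours of the best trees
    frontier = list(best_trees)
    while frontier and len(best_trees) < config.max_equal_trees:
        tree = frontier.pop()
        for cand in _spr_neighbourhood(tree):
            if len(best_trees) >= config.max_equal_trees:
                break
            ln = float(np.dot(_fitch_steps(cand, S), w0))
            if ln == best_len:
                key = cand.splits()
                if all(key != t.splits() for t in best_trees):
                    best_trees.append(cand)
                    frontier.append(cand)

    return TreeSet(trees=best_trees, length=int(round(best_len)))


# ---------------------------------------------------------------------------
# Ensemble indices
# ---------------------------------------------------------------------------

def character_step_bounds(matrix: CharacterMatrix):
    """Per-character (min_steps, max_steps) under any tree.

    min: number of distinct states among singleton-observed cells minus one
    (floored at 0). max: coded taxa minus the largest number of coded taxa
    whose state set can realise a single shared state (polymorphic cells
    count generously toward that shared state).
    """
    mins, maxs = [], []
    for char, col in zip(matrix.characters, matrix.columns()):
        coded = [c for c in col if c.kind != "missing"]
        singles = {next(iter(c.states)) for c in coded if c.kind == "observed"}
        mins.append(max(0, len(singles) - 1))
        if not coded:
            maxs.append(0)
            continue
        best = max(
            sum(1 for c in coded if s in c.states) for s in range(char.n_states)
        )
        maxs.append(len(coded) - best)
    return np.array(mins), np.array(maxs)


def parsimony_stats(matrix: CharacterMatrix, TL: int) -> ParsimonyStats:
    """Ensemble consistency and retention indices for an observed length."""
    mins, maxs = character_step_bounds(matrix)
    m, g = int(mins.sum()), int(maxs.sum())
    if TL < m:
        raise ValueError(f"TL={TL} below theoretical minimum m={m}: scoring bug")
    CI = 1.0 if TL == 0 else m / TL
    RI = 1.0 if g == m else (g - TL) / (g - m)
    return ParsimonyStats(TL=TL, CI=CI, RI=RI, m=m, g=g)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap(
    matrix: CharacterMatrix,
    n_replicates: int = 100,
    seed: int = 0,
    search: SearchConfig | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap over characters.

    Each replicate resamples the characters with replacement (implemented as
    a multinomial weight vector), reruns the heuristic search under those
    weights, and records the splits of the replicate's strict consensus of
    best trees. Support is the percentage of replicates containing a split.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = search or SearchConfig(n_starts=2, ratchet_iterations=1)
    rng = np.random.default_rng(seed)
    nch = matrix.n_characters
    counts: dict = {}
    for rep in range(n_replicates):
        w = rng.multinomial(nch, np.full(nch, 1.0 / nch)).astype(float)
        cfg = SearchConfig(
            n_starts=base.n_starts,
            ratchet_iterations=base.ratchet_iterations,
            perturbation_fraction=base.perturbation_fraction,
            seed=int(rng.integers(0, 2**31 - 1)),
            max_equal_trees=base.max_equal_trees,
        )
        ts = heuristic_search(matrix, cfg, weights=w)
        cons = strict_consensus(ts.trees)
        for split in cons.splits():
            counts[split] = counts.get(split, 0) + 1
    supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    return BootstrapResult(
        n_replicates=n_replicates, seed=seed, supports=supports, taxa=tuple(matrix.taxa)
    )


def write_newick(tree: PhyloTree, supports: BootstrapResult | None = None, path=None, root_taxon=None) -> str:
    """Render (and optionally write) a newick string with support labels."""
    sup = supports.supports if supports is not None else None
    text = tree.to_newick(support=sup, root_taxon=root_taxon)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
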