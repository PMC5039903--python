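"""Maximum-likelihood phylogenetics under HKY + discrete-gamma rates.

The model is HKY85 — unequal base frequencies and a transition/transversion
rate ratio ``kappa`` — with among-site rate variation approximated by ``n``
equal-probability discrete gamma categories of shape ``alpha`` (category
rates are the bin means, averaging 1; the rate matrix is normalised to one
expected substitution per site per unit branch length).

The search starts from a neighbor-joining tree on Kimura two-parameter
distances and alternates bounded one-dimensional optimisation of branch
lengths, ``kappa`` and ``alpha`` with nearest-neighbor-interchange sweeps
that accept only likelihood improvements.  Likelihoods are computed by
Felsenstein pruning on site patterns compressed with multiplicities.

Trees are unrooted (represented with a trifurcating root), round-trip
through newick via dendropy, and carry optional bootstrap supports on
internal edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, special, stats

from dielscan.io import Alignment, SampleMetadata

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
#: transition pairs under the HKY/K80 parameterisation (purine<->purine, pyrimidine<->pyrimidine)
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}

BRANCH_MIN = 1e-8
BRANCH_MAX = 10.0
SATURATION_CAP = 5.0


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------


class Node:
    __slots__ = ("name", "length", "children", "parent", "support")

    def __init__(self, name=None, length=None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.support: float | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree (trifurcating root representation) with branch lengths."""

    root: Node

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        out.reverse()
        return out

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def branch_nodes(self) -> list[Node]:
        """Every node except the root; each owns the edge above it."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[Node]:
        """Child endpoints of internal (non-terminal) edges."""
        return [n for n in self.branch_nodes() if not n.is_tip]

    # -- copying / io ------------------------------------------------------
    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.support = n.support
            for c in n.children:
                m.add(rec(c))
            return m

        return Tree(rec(self.root))

    def newick(self, decimals: int = 6, supports: bool = True) -> str:
        def rec(n: Node) -> str:
            if n.is_tip:
                body = n.name
            else:
                body = "(" + ",".join(rec(c) for c in n.children) + ")"
                if supports and n.support is not None:
                    body += f"{n.support:g}"
                elif n.name:
                    body += n.name
            if n.length is not None and n.parent is not None:
                body += f":{n.length:.{decimals}f}"
            return body

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")

        def rec(dn) -> Node:
            name = dn.taxon.label.replace(" ", "_") if dn.taxon else None
            n = Node(name=name, length=dn.edge.length)
            label = dn.label
            if label is not None and not dn.is_leaf():
                try:
                    n.support = float(label)
                except ValueError:
                    n.name = label
            for c in dn.child_nodes():
                n.add(rec(c))
            return n

        root = rec(dt.seed_node)
        root.length = None
        return cls(root)

    # -- splits / rooting --------------------------------------------------
    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, each as the side excluding the anchor tip."""
        all_tips = frozenset(self.tip_names())
        anchor = min(all_tips)
        out: set[frozenset] = set()
        tipsets = self._tipsets()
        for n in self.internal_edges():
            side = tipsets[id(n)]
            if anchor in side:
                side = all_tips - side
            if 1 < len(side) < len(all_tips) - 1:
                out.add(side)
        return out

    def _tipsets(self) -> dict[int, frozenset]:
        tipsets: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_tip:
                tipsets[id(n)] = frozenset([n.name])
            else:
                s: frozenset = frozenset()
                for c in n.children:
                    s = s | tipsets[id(c)]
                tipsets[id(n)] = s
        return tipsets

    def find_tip(self, name: str) -> Node:
        for n in self.postorder():
            if n.is_tip and n.name == name:
                return n
        raise PhyloError(f"tip {name!r} not in tree")

    def rooted_at(self, tip_name: str) -> "Tree":
        """Return a copy re-rooted so that `tip_name` hangs directly off the root.

        The new root is the internal node the tip attaches to, so clade
        relationships ("is this set of tips monophyletic given this
        outgroup?") read off directly.
        """
        t = self.copy()
        tip = t.find_tip(tip_name)
        p = tip.parent
        if p is None:
            raise PhyloError("cannot root at the only node")
        # reverse parent pointers along the path p -> old root
        path = []
        n = p
        while n is not None:
            path.append(n)
            n = n.parent
        old_lengths = [n.length for n in path]
        for i in range(len(path) - 1, 0, -1):
            upper, lower = path[i], path[i - 1]
            upper.children.remove(lower)
            lower.add(upper)
            upper.length = old_lengths[i - 1]
        p.parent = None
        p.length = None
        t.root = p
        # suppress a unifurcation left at the old root
        old_root = path[-1]
        if len(old_root.children) == 1 and old_root.parent is not None:
            child = old_root.children[0]
            extra = old_root.length or 0.0
            parent = old_root.parent
            idx = parent.children.index(old_root)
            parent.children[idx] = child
            child.parent = parent
            child.length = (child.length or 0.0) + extra
        return t


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------


def k80_distance_matrix(alignment: Alignment) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Kimura two-parameter pairwise distances on a complete-deletion matrix.

    Returns ``(ids, distances, saturated)``.  For each pair, P and Q are the
    proportions of transition and transversion differences over the columns
    where both rows are unambiguous; ``d = -0.5*ln(1-2P-Q) - 0.25*ln(1-2Q)``.
    Pairs where the logarithms are undefined (saturation, or no shared
    columns) are flagged and capped.
    """
    ids = list(alignment.ids)
    arr = alignment.to_array()
    n = len(ids)
    code = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[arr == b] = i
    D = np.zeros((n, n))
    flagged = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = code[i], code[j]
            valid = (a >= 0) & (b >= 0)
            m = int(valid.sum())
            if m == 0:
                D[i, j] = D[j, i] = SATURATION_CAP
                flagged[i, j] = flagged[j, i] = True
                continue
            diff = valid & (a != b)
            ts = sum(
                1 for ai, bi in zip(a[diff], b[diff]) if (int(ai), int(bi)) in _TRANSITIONS
            )
            tv = int(diff.sum()) - ts
            P, Q = ts / m, tv / m
            w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            if w1 <= 0.0 or w2 <= 0.0:
                D[i, j] = D[j, i] = SATURATION_CAP
                flagged[i, j] = flagged[j, i] = True
            else:
                d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
                D[i, j] = D[j, i] = d
    return ids, D, flagged


def neighbor_joining(dist: np.ndarray, ids: list[str]) -> Tree:
    """Standard neighbor joining; exact on additive matrices.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster, cluster) name pair for determinism.  Negative branch lengths
    are clamped to zero with a warning.
    """
    D = np.asarray(dist, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise PhyloError("distance matrix shape does not match ids")
    if not np.allclose(D, D.T):
        raise PhyloError("distance matrix must be symmetric")
    if n < 3:
        raise PhyloError("neighbor joining needs >= 3 taxa")

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0")
            return 0.0
        return x

    nodes = [Node(name=i) for i in ids]
    keys = list(ids)  # lexicographic tie-break key per cluster
    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        na = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (na - 2) * D[i, j] - r[i] - r[j]
                tiekey = tuple(sorted((keys[i], keys[j])))
                cand = (q, tiekey, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        li = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2 * (na - 2)))
        lj = clamp(0.5 * D[i, j] + (r[j] - r[i]) / (2 * (na - 2)))
        u = Node()
        nodes[i].length = li
        nodes[j].length = lj
        u.add(nodes[i])
        u.add(nodes[j])
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        for m in active:
            if m in (i, j):
                continue
            D[k, m] = D[m, k] = 0.5 * (D[i, m] + D[j, m] - D[i, j])
        nodes.append(u)
        keys.append(min(keys[i], keys[j]))
        active = [m for m in active if m not in (i, j)] + [k]
    i, j, k = active
    root = Node()
    nodes[i].length = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    nodes[j].length = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    nodes[k].length = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    for m in (i, j, k):
        root.add(nodes[m])
    return Tree(root)


# ---------------------------------------------------------------------------
# HKY + discrete gamma likelihood
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HKYParams:
    """HKY85 substitution parameters with discrete-gamma rate variation."""

    kappa: float
    base_freqs: tuple[float, float, float, float]  # pi_A, pi_C, pi_G, pi_T
    alpha: float
    n_categories: int = 4

    def __post_init__(self):
        if self.kappa <= 0 or self.alpha <= 0 or self.n_categories < 1:
            raise PhyloError("kappa, alpha must be > 0 and n_categories >= 1")
        f = np.asarray(self.base_freqs, dtype=float)
        if f.min() < 0 or not math.isclose(f.sum(), 1.0, abs_tol=1e-6):
            raise PhyloError("base_freqs must be nonnegative and sum to 1")


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of n equal-probability bins of Gamma(alpha) with mean 1."""
    if n_categories == 1:
        return np.ones(1)
    edges = stats.gamma.ppf(np.arange(1, n_categories) / n_categories, a=alpha, scale=1.0 / alpha)
    cuts = np.concatenate([[0.0], alpha * edges, [np.inf]])
    upper = special.gammainc(alpha + 1.0, cuts[1:])
    lower = special.gammainc(alpha + 1.0, cuts[:-1])
    rates = n_categories * (upper - lower)
    return rates / rates.mean()


def hky_rate_matrix(kappa: float, base_freqs) -> np.ndarray:
    """HKY instantaneous rate matrix normalised to mean rate 1."""
    pi = np.asarray(base_freqs, dtype=float)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = (kappa if (i, j) in _TRANSITIONS else 1.0) * pi[j]
        Q[i, i] = -Q[i].sum()
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


class _HKYModel:
    """Eigen-decomposed HKY model: cheap transition matrices P(t)."""

    def __init__(self, kappa: float, base_freqs):
        pi = np.maximum(np.asarray(base_freqs, dtype=float), 1e-10)
        pi = pi / pi.sum()
        self.pi = pi
        Q = hky_rate_matrix(kappa, pi)
        d = np.sqrt(pi)
        S = (Q * d[:, None]) / d[None, :]  # D^1/2 Q D^-1/2, symmetric for reversible Q
        lam, V = np.linalg.eigh((S + S.T) / 2)
        self.lam = lam
        self.A = V / d[:, None]
        self.B = V.T * d[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self.A * np.exp(self.lam * t)[None, :]) @ self.B
        np.clip(P, 0.0, 1.0, out=P)
        return P / P.sum(axis=1, keepdims=True)


def _compress_patterns(alignment: Alignment) -> tuple[list[str], np.ndarray, np.ndarray]:
    arr = alignment.to_array()
    code = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[arr == b] = i
    if (code < 0).any():
        raise PhyloError(
            "likelihood requires a complete-deletion alignment (A/C/G/T only); "
            "run complete_deletion() first"
        )
    patterns, counts = np.unique(code, axis=1, return_counts=True)
    return list(alignment.ids), patterns, counts.astype(float)


class _PruningEngine:
    """Felsenstein pruning over compressed site patterns, reusable across
    branch-length/parameter updates on a fixed tree object."""

    def __init__(self, tree: Tree, alignment: Alignment, params: HKYParams):
        self.tree = tree
        self.ids, self.patterns, self.counts = _compress_patterns(alignment)
        self.n_sites = int(self.counts.sum())
        self.tip_row = {sid: i for i, sid in enumerate(self.ids)}
        self.set_params(params)

    def set_params(self, params: HKYParams) -> None:
        self.params = params
        self.model = _HKYModel(params.kappa, params.base_freqs)
        self.rates = discrete_gamma_rates(params.alpha, params.n_categories)
        # one-hot tip partials, shared across categories
        npat = self.patterns.shape[1]
        self._tip_partials = {}
        for sid, row in self.tip_row.items():
            one = np.zeros((npat, 4))
            one[np.arange(npat), self.patterns[row]] = 1.0
            self._tip_partials[sid] = one

    def loglik(self) -> float:
        ncat = len(self.rates)
        npat = self.patterns.shape[1]
        pi = self.model.pi
        logscale = np.zeros((ncat, npat))
        partials: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if node.is_tip:
                p = np.broadcast_to(self._tip_partials[node.name], (ncat, npat, 4))
                partials[id(node)] = p
                continue
            acc = np.ones((ncat, npat, 4))
            for child in node.children:
                t = max(child.length if child.length is not None else 0.0, 0.0)
                cp = partials.pop(id(child))
                for c in range(ncat):
                    P = self.model.transition_matrix(t * self.rates[c])
                    acc[c] *= cp[c] @ P.T
            mx = acc.max(axis=2)
            mx[mx == 0.0] = 1.0
            acc /= mx[:, :, None]
            logscale += np.log(mx)
            partials[id(node)] = acc
        rootp = partials[id(self.tree.root)]
        site_cat = np.einsum("cpk,k->cp", rootp, pi)
        with np.errstate(divide="ignore"):
            log_cat = np.log(site_cat) + logscale
        site_log = special.logsumexp(log_cat, axis=0) - math.log(ncat)
        return float((self.counts * site_log).sum())

    # -- optimisation helpers ---------------------------------------------
    def optimize_branch_lengths(self, xatol: float = 1e-6) -> float:
        for node in self.tree.branch_nodes():
            def neg(t, node=node):
                node.length = t
                return -self.loglik()

            res = optimize.minimize_scalar(
                neg, bounds=(BRANCH_MIN, BRANCH_MAX), method="bounded",
                options={"xatol": xatol},
            )
            node.length = float(res.x)
        return self.loglik()

    def optimize_scalar_param(self, name: str, bounds: tuple[float, float]) -> float:
        def neg(x):
            self.set_params(_replace_param(self.params, name, float(x)))
            return -self.loglik()

        res = optimize.minimize_scalar(neg, bounds=bounds, method="bounded", options={"xatol": 1e-4})
        self.set_params(_replace_param(self.params, name, float(res.x)))
        return self.loglik()

    def nni_sweep(self, min_improvement: float = 1e-6) -> tuple[float, int]:
        """One pass of nearest-neighbor interchanges; accepts only improvements."""
        current = self.loglik()
        accepted = 0
        for v in list(self.tree.internal_edges()):
            if v.parent is None or len(v.children) != 2:
                continue
            u = v.parent
            w = next((c for c in u.children if c is not v), None)
            if w is None:
                continue
            best: tuple[float, Node | None] = (current, None)
            for c in list(v.children):
                _swap_children(u, w, v, c)
                ll = self.loglik()
                _swap_children(u, c, v, w)  # undo
                if ll > best[0] + min_improvement:
                    best = (ll, c)
            if best[1] is not None:
                _swap_children(u, w, v, best[1])
                current = best[0]
                accepted += 1
        return current, accepted


def _swap_children(u: Node, w: Node, v: Node, c: Node) -> None:
    """Exchange subtree w (child of u) with subtree c (child of v)."""
    iu, iv = u.children.index(w), v.children.index(c)
    u.children[iu], v.children[iv] = c, w
    c.parent, w.parent = u, v


def _replace_param(params: HKYParams, name: str, value: float) -> HKYParams:
    kw = {
        "kappa": params.kappa,
        "base_freqs": params.base_freqs,
        "alpha": params.alpha,
        "n_categories": params.n_categories,
    }
    kw[name] = value
    return HKYParams(**kw)


def hky_gamma_loglik(tree: Tree, alignment: Alignment, params: HKYParams) -> float:
    """Log-likelihood of a complete-deletion alignment on a tree under HKY+Gamma."""
    for n in tree.branch_nodes():
        if n.length is not None and n.length < 0:
            raise PhyloError("negative branch length")
    return _PruningEngine(tree, alignment, params).loglik()


def empirical_base_freqs(alignment: Alignment) -> tuple[float, float, float, float]:
    arr = alignment.to_array()
    counts = np.array([(arr == b).sum() for b in _BASES], dtype=float)
    if counts.sum() == 0:
        raise PhyloError("no unambiguous bases in alignment")
    f = counts / counts.sum()
    return tuple(float(x) for x in f)


@dataclass
class MLResult:
    tree: Tree
    params: HKYParams
    loglik: float
    n_sites_used: int
    converged: bool = True


def fit_ml_tree(
    alignment: Alignment,
    init: Tree | None = None,
    fixed_alpha: float | None = None,
    n_categories: int = 4,
    kappa0: float = 2.0,
    alpha0: float = 1.0,
    max_cycles: int = 20,
    tol: float = 1e-4,
) -> MLResult:
    """Fit tree topology, branch lengths, kappa (and optionally alpha) by ML.

    The alignment must already be the complete-deletion matrix.  The search
    starts from ``init`` or a neighbor-joining tree on K80 distances, and
    cycles branch-length optimisation, kappa/alpha optimisation and NNI
    sweeps until a full cycle improves the log-likelihood by less than
    ``tol``.  Base frequencies are the empirical counts.
    """
    if alignment.nrow < 4:
        raise PhyloError("ML search needs >= 4 taxa")
    freqs = empirical_base_freqs(alignment)
    params = HKYParams(
        kappa=kappa0,
        base_freqs=freqs,
        alpha=fixed_alpha if fixed_alpha is not None else alpha0,
        n_categories=n_categories,
    )
    if init is None:
        ids, D, _ = k80_distance_matrix(alignment)
        tree = neighbor_joining(D, ids)
    else:
        tree = init.copy()
    for n in tree.branch_nodes():
        if n.length is None or n.length < BRANCH_MIN:
            n.length = BRANCH_MIN
    engine = _PruningEngine(tree, alignment, params)
    ll = engine.loglik()
    converged = False
    for _ in range(max_cycles):
        prev = ll
        ll = engine.optimize_branch_lengths()
        ll = engine.optimize_scalar_param("kappa", (0.05, 100.0))
        if fixed_alpha is None:
            ll = engine.optimize_scalar_param("alpha", (0.05, 100.0))
        ll, n_acc = engine.nni_sweep()
        if n_acc:
            ll = engine.optimize_branch_lengths()
        if ll - prev < tol:
            converged = True
            break
    return MLResult(
        tree=engine.tree,
        params=engine.params,
        loglik=ll,
        n_sites_used=engine.n_sites,
        converged=converged,
    )


def bootstrap_support(
    alignment: Alignment,
    result: MLResult,
    n_replicates: int,
    seed: int,
    refit_cycles: int = 2,
) -> Tree:
    """Nonparametric bootstrap supports for the internal edges of the ML tree.

    Columns of the (complete-deletion) alignment are resampled with
    replacement; each replicate is refit starting from the ML tree (branch
    lengths plus NNI, substitution parameters held at the ML estimates) and
    the support of each internal split of the reference tree is the
    percentage of replicates whose tree contains it.
    """
    if n_replicates < 1:
        raise PhyloError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ref_splits = result.tree.splits()
    hits = {s: 0 for s in ref_splits}
    ncol = alignment.ncol
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_aln = alignment.take_columns(cols.tolist())
        engine = _PruningEngine(result.tree.copy(), rep_aln, result.params)
        for _ in range(refit_cycles):
            engine.optimize_branch_lengths(xatol=1e-4)
            _, n_acc = engine.nni_sweep()
            if not n_acc:
                break
        for s in engine.tree.splits():
            if s in hits:
                hits[s] += 1
    out = result.tree.copy()
    tipsets = out._tipsets()
    all_tips = frozenset(out.tip_names())
    anchor = min(all_tips)
    for n in out.internal_edges():
        side = tipsets[id(n)]
        if anchor in side:
            side = all_tips - side
        if side in hits:
            n.support = 100.0 * hits[side] / n_replicates
    return out


# ---------------------------------------------------------------------------
# Trait monophyly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LevelMonophyly:
    is_monophyletic: bool
    smallest_containing_clade_size: int
    n_intruders: int


def monophyly_test(
    tree: Tree,
    metadata: SampleMetadata,
    trait: str,
    outgroup_id: str,
) -> dict[str, LevelMonophyly]:
    """Is each trait level a clade once the tree is rooted at the outgroup?

    For every level of the trait (outgroup excluded), finds the smallest
    clade of the rooted tree containing all of the level's tips; the level
    is monophyletic iff that clade contains no other tips.
    """
    rooted = tree.rooted_at(outgroup_id)
    tipsets = rooted._tipsets()
    clades = sorted((tipsets[id(n)] for n in rooted.postorder()), key=len)
    tree_tips = set(rooted.tip_names())
    levels: dict[str, set[str]] = {}
    for sid, row in metadata.rows.items():
        if sid == outgroup_id or sid not in tree_tips or not row.in_primate_tests:
            continue
        levels.setdefault(getattr(row, trait), set()).add(sid)
    out: dict[str, LevelMonophyly] = {}
    for level, members in levels.items():
        if not members:
            raise PhyloError(f"trait level {level!r} has no tips")
        clade = next(c for c in clades if members <= c)
        n_intr = len(clade) - len(members)
        out[level] = LevelMonophyly(
            is_monophyletic=(n_intr == 0),
            smallest_containing_clade_size=len(clade),
            n_intruders=n_intr,
        )
    return out
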