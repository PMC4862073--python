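"""HKY85 maximum-likelihood phylogenetics.

Implements the likelihood machinery used to support miRNA and Hox-paralog
orthology calls: Felsenstein pruning over compressed site patterns under
the HKY85 substitution model (transition/transversion ratio kappa,
unequal base frequencies pi), per-branch Brent optimisation of branch
lengths (expected substitutions/site), and topology search by
neighbor-joining start plus nearest-neighbor-interchange hill climbing.

No rate heterogeneity is modelled.  Base frequencies default to empirical
counts from the alignment.  Gaps and N are treated as missing data
(partial likelihood one).  Trees are unrooted; because HKY85 is
time-reversible the likelihood is invariant under the rooting chosen for
pruning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import HoxatlasError, ParameterError

__all__ = [
    "HKY85Params",
    "SiteAlignment",
    "PhyloTree",
    "hky85_loglik",
    "fit_branch_lengths",
    "ml_tree_search",
    "paralog_support",
    "nj_start_tree",
    "enumerate_topologies",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "-": 4, "N": 4, "?": 4}
MISSING = 4


@dataclass
class HKY85Params:
    """kappa > 0 and base frequencies summing to one."""

    kappa: float = 2.0
    base_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.kappa <= 0:
            raise ParameterError(f"kappa must be > 0, got {self.kappa}")
        if self.base_freqs.shape != (4,) or np.any(self.base_freqs <= 0):
            raise ParameterError("base_freqs must be four positive values")
        if abs(self.base_freqs.sum() - 1.0) > 1e-9:
            raise ParameterError("base_freqs must sum to 1")
        self._decompose()

    def _decompose(self) -> None:
        pi = self.base_freqs
        k = self.kappa
        Q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = pi[j] * (k if (i, j) in transitions else 1.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(np.dot(pi, np.diag(Q)))  # mean rate -> 1 sub/site/unit
        Q /= scale
        # reversible: symmetrize with sqrt(pi) similarity, then eigh
        sq = np.sqrt(pi)
        S = (sq[:, None] * Q) / sq[None, :]
        w, U = np.linalg.eigh((S + S.T) / 2)
        # P(t) = D^{-1/2} U diag(exp(w t)) U^T D^{1/2}
        self._eigvals = w
        self._right = (U.T * (1.0 / sq)[None, :]).T  # D^{-1/2} U
        self._left = U.T * sq[None, :]               # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are current states, columns descendant states."""
        if t < 0:
            raise ParameterError("branch length must be >= 0")
        P = (self._right * np.exp(self._eigvals * t)[None, :]) @ self._left
        return np.clip(P, 0.0, None)


@dataclass
class SiteAlignment:
    """Aligned nucleotide matrix with site-pattern compression."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_sites) int codes, 4 = missing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ParameterError("data must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ParameterError("duplicate taxon labels")

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "SiteAlignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ParameterError("aligned sequences must share one length")
        data = np.array(
            [[_CODE.get(c.upper(), MISSING) for c in seqs[t]] for t in taxa],
            dtype=np.int8,
        )
        return cls(taxa=taxa, data=data)

    @classmethod
    def from_fasta(cls, path: str) -> "SiteAlignment":
        from Bio import SeqIO

        return cls.from_sequences(
            {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        )

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site columns and their multiplicities (cached; the data
        matrix is treated as immutable once constructed)."""
        cached = getattr(self, "_patterns", None)
        if cached is None:
            pats, counts = np.unique(self.data.T, axis=0, return_counts=True)
            cached = (pats.T.copy(), counts.astype(float))
            self._patterns = cached
        return cached

    def empirical_freqs(self, pseudocount: float = 1.0) -> np.ndarray:
        counts = np.array([(self.data == b).sum() for b in range(4)], dtype=float)
        counts += pseudocount
        return counts / counts.sum()


class PhyloTree:
    """Unrooted tree: adjacency with branch lengths, leaf labels."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        self._next = 0

    def add_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float = 0.1) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def set_length(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def edges(self) -> list[tuple[int, int, float]]:
        return sorted(
            (u, v, l) for u, nb in self.adj.items() for v, l in nb.items() if u < v
        )

    def leaves(self) -> list[int]:
        return sorted(n for n in self.adj if len(self.adj[n]) <= 1)

    def taxa(self) -> list[str]:
        return sorted(self.labels[n] for n in self.leaves())

    def leaf_of(self, taxon: str) -> int:
        for n, lab in self.labels.items():
            if lab == taxon:
                return n
        raise HoxatlasError(f"taxon {taxon!r} not in tree")

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.adj = {u: dict(nb) for u, nb in self.adj.items()}
        t.labels = dict(self.labels)
        t._next = self._next
        return t

    def are_sisters(self, taxon_a: str, taxon_b: str) -> bool:
        """True when the two leaves form a cherry (share a neighbour)."""
        a, b = self.leaf_of(taxon_a), self.leaf_of(taxon_b)
        na = next(iter(self.adj[a]))
        nb = next(iter(self.adj[b]))
        return na == nb

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for u, v, _ in self.edges()
            if len(self.adj[u]) > 1 and len(self.adj[v]) > 1
        ]

    def to_newick(self, decimals: int = 6) -> str:
        leaves = self.leaves()
        if len(leaves) == 1:
            return f"{self.labels[leaves[0]]};"
        if len(leaves) == 2:
            (u, v, l) = self.edges()[0]
            return f"({self.labels[u]}:{l:.{decimals}f},{self.labels[v]}:0.0);"
        root = next(n for n in self.adj if len(self.adj[n]) > 1)

        def sub(node: int, parent: int) -> str:
            children = [c for c in self.adj[node] if c != parent]
            if not children:
                return f"{self.labels[node]}:{self.adj[parent][node]:.{decimals}f}"
            inner = ",".join(sub(c, node) for c in sorted(children))
            if parent is None:
                return f"({inner})"
            return f"({inner}):{self.adj[parent][node]:.{decimals}f}"

        inner = ",".join(sub(c, root) for c in sorted(self.adj[root]))
        return f"({inner});"


def _root_for_pruning(tree: PhyloTree) -> int:
    internals = [n for n in tree.adj if len(tree.adj[n]) > 1]
    return internals[0] if internals else next(iter(tree.adj))


def _partials(
    tree: PhyloTree,
    node: int,
    parent: int | None,
    pats: np.ndarray,
    taxon_row: dict[str, int],
    params: HKY85Params,
) -> np.ndarray:
    children = [c for c in tree.adj[node] if c != parent]
    npat = pats.shape[1]
    L = np.ones((npat, 4))
    if node in tree.labels:  # observed taxon (covers leaf-rooted pruning)
        states = pats[taxon_row[tree.labels[node]]]
        ind = np.zeros((npat, 4))
        obs = states < MISSING
        ind[np.arange(npat)[obs], states[obs]] = 1.0
        ind[~obs] = 1.0
        L *= ind
    for c in children:
        Lc = _partials(tree, c, node, pats, taxon_row, params)
        P = params.transition_matrix(tree.adj[node][c])
        L *= Lc @ P.T
    return L


def hky85_loglik(
    alignment: SiteAlignment, tree: PhyloTree, params: HKY85Params
) -> float:
    """Log-likelihood by post-order pruning over compressed site patterns."""
    if alignment.n_sites == 0:
        raise HoxatlasError("zero-length alignment")
    if sorted(alignment.taxa) != tree.taxa():
        raise HoxatlasError(
            f"taxa mismatch: alignment {sorted(alignment.taxa)} vs tree {tree.taxa()}"
        )
    pats, counts = alignment.patterns()
    taxon_row = {t: i for i, t in enumerate(alignment.taxa)}
    if len(tree.leaves()) == 1:
        states = pats[taxon_row[tree.taxa()[0]]]
        pi = params.base_freqs
        site = np.where(states < MISSING, pi[np.clip(states, 0, 3)], 1.0)
        return float(np.dot(counts, np.log(site)))
    root = _root_for_pruning(tree)
    L = _partials(tree, root, None, pats, taxon_row, params)
    site_lik = L @ params.base_freqs
    if np.any(site_lik <= 0):
        return -np.inf
    return float(np.dot(counts, np.log(site_lik)))


def fit_branch_lengths(
    alignment: SiteAlignment,
    topology: PhyloTree,
    params: HKY85Params,
    co_estimate_kappa: bool = False,
    tol: float = 1e-6,
    max_rounds: int = 20,
    max_branch: float = 10.0,
) -> tuple[PhyloTree, float, HKY85Params]:
    """Coordinate-wise Brent optimisation of each branch length (and
    optionally kappa) on a fixed topology.

    Stops when a full round improves the log-likelihood by < ``tol``;
    warns and returns best-so-far on non-convergence.
    """
    tree = topology.copy()
    current = hky85_loglik(alignment, tree, params)
    for _ in range(max_rounds):
        for u, v, _l in tree.edges():
            def neg(t: float) -> float:
                tree.set_length(u, v, t)
                return -hky85_loglik(alignment, tree, params)

            res = minimize_scalar(
                neg, bounds=(1e-8, max_branch), method="bounded",
                options={"xatol": 1e-8},
            )
            tree.set_length(u, v, float(res.x))
        if co_estimate_kappa:
            def neg_k(log_k: float) -> float:
                p = HKY85Params(kappa=float(np.exp(log_k)), base_freqs=params.base_freqs)
                return -hky85_loglik(alignment, tree, p)

            res = minimize_scalar(
                neg_k, bounds=(np.log(0.05), np.log(100.0)), method="bounded",
                options={"xatol": 1e-6},
            )
            params = HKY85Params(
                kappa=float(np.exp(res.x)), base_freqs=params.base_freqs
            )
        new = hky85_loglik(alignment, tree, params)
        if new - current < tol:
            current = max(new, current)
            break
        current = new
    else:
        warnings.warn("branch-length optimisation did not converge; returning best-so-far")
    return tree, current, params


def _pairwise_distance(
    alignment: SiteAlignment, i: int, j: int, params: HKY85Params
) -> float:
    """Two-sequence ML distance under HKY85 (Brent on the single branch)."""
    a, b = alignment.data[i], alignment.data[j]
    ok = (a < MISSING) & (b < MISSING)
    if not np.any(ok):
        return 0.5
    pairs, counts = np.unique(np.stack([a[ok], b[ok]]).T, axis=0, return_counts=True)
    pi = params.base_freqs

    def neg(t: float) -> float:
        P = params.transition_matrix(t)
        lik = pi[pairs[:, 0]] * P[pairs[:, 0], pairs[:, 1]]
        return -float(np.dot(counts, np.log(np.clip(lik, 1e-300, None))))

    res = minimize_scalar(neg, bounds=(1e-8, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def nj_start_tree(alignment: SiteAlignment, params: HKY85Params) -> PhyloTree:
    """Neighbor-joining topology from HKY85 pairwise ML distances."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = len(alignment.taxa)
    dm = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = _pairwise_distance(alignment, i, j, params)
        dm[i, j] = dm[j, i] = d
    sk = nj(DistanceMatrix(dm, alignment.taxa))

    tree = PhyloTree()

    def build(node, parent_id: int | None) -> int:
        if node.is_tip():
            nid = tree.add_node(label=str(node.name))
        else:
            nid = tree.add_node()
        if parent_id is not None:
            length = node.length if node.length and node.length > 0 else 1e-6
            tree.add_edge(parent_id, nid, float(length))
        for child in node.children:
            build(child, nid)
        return nid

    build(sk.root(), None)
    _suppress_unifurcations(tree)
    return tree


def _suppress_unifurcations(tree: PhyloTree) -> None:
    changed = True
    while changed:
        changed = False
        for n in list(tree.adj):
            nb = list(tree.adj[n])
            if n not in tree.labels and len(nb) == 2:
                a, b = nb
                length = tree.adj[n][a] + tree.adj[n][b]
                tree.remove_edge(n, a)
                tree.remove_edge(n, b)
                del tree.adj[n]
                tree.add_edge(a, b, length)
                changed = True
            elif n not in tree.labels and len(nb) == 1:
                tree.remove_edge(n, nb[0])
                del tree.adj[n]
                changed = True


def _nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """The two NNI rearrangements of every internal edge."""
    out = []
    for u, v in tree.internal_edges():
        u_nb = sorted(c for c in tree.adj[u] if c != v)
        v_nb = sorted(c for c in tree.adj[v] if c != u)
        if not u_nb or not v_nb:
            continue
        a = u_nb[0]
        for c in v_nb[:2]:
            t = tree.copy()
            la, lc = t.adj[u][a], t.adj[v][c]
            t.remove_edge(u, a)
            t.remove_edge(v, c)
            t.add_edge(u, c, lc)
            t.add_edge(v, a, la)
            out.append(t)
    return out


def ml_tree_search(
    alignment: SiteAlignment,
    params: HKY85Params | None = None,
    seed: int = 0,
    co_estimate_kappa: bool = False,
    constraint=None,
) -> tuple[PhyloTree, float]:
    """ML topology search: NJ start, then NNI hill climbing to a local
    optimum.  Deterministic given the alignment and seed.

    ``constraint`` is an optional predicate on candidate trees; topologies
    failing it are never accepted (used for constrained hypothesis tests).
    """
    if params is None:
        params = HKY85Params(kappa=2.0, base_freqs=alignment.empirical_freqs())
    n = len(alignment.taxa)
    if n < 2:
        raise HoxatlasError("need at least 2 taxa")
    if n < 4:  # the topology is unique; no search needed
        start = enumerate_topologies(sorted(alignment.taxa))[0]
    else:
        start = nj_start_tree(alignment, params)
    if constraint is not None and not constraint(start):
        cands = [t for t in _nni_neighbors(start) if constraint(t)]
        if not cands:
            raise HoxatlasError("no NNI neighbour satisfies the constraint")
        start = cands[0]
    best, best_ll, params = fit_branch_lengths(
        alignment, start, params, co_estimate_kappa=co_estimate_kappa
    )
    if n < 4:
        return best, best_ll
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(best):
            if constraint is not None and not constraint(cand):
                continue
            fitted, ll, params = fit_branch_lengths(
                alignment, cand, params, co_estimate_kappa=co_estimate_kappa
            )
            if ll > best_ll + 1e-6:
                best, best_ll = fitted, ll
                improved = True
                break
    return best, best_ll


def enumerate_topologies(taxa: list[str]) -> list[PhyloTree]:
    """All unrooted binary topologies over the taxa (1, 1, 3, 15, 105, ...)."""
    if len(taxa) < 2:
        raise HoxatlasError("need at least 2 taxa")
    base = PhyloTree()
    if len(taxa) == 2:
        a, b = (base.add_node(t) for t in taxa[:2])
        base.add_edge(a, b, 0.1)
        return [base]
    center = base.add_node()
    for t in taxa[:3]:
        leaf = base.add_node(t)
        base.add_edge(center, leaf, 0.1)
    trees = [base]
    for t in taxa[3:]:
        nxt: list[PhyloTree] = []
        for tr in trees:
            for u, v, l in tr.edges():
                t2 = tr.copy()
                t2.remove_edge(u, v)
                mid = t2.add_node()
                leaf = t2.add_node(t)
                t2.add_edge(u, mid, l / 2)
                t2.add_edge(mid, v, l / 2)
                t2.add_edge(mid, leaf, 0.1)
                nxt.append(t2)
        trees = nxt
    return trees


def paralog_support(
    alignment: SiteAlignment,
    focal_pair: tuple[str, str],
    params: HKY85Params | None = None,
    seed: int = 0,
) -> tuple[bool, float]:
    """Does the ML tree place the focal pair as sisters, and by how much?

    Returns (monophyly, delta log-likelihood vs the best tree constrained
    to separate the pair; 0 when the ML tree itself separates them).
    """
    a, b = focal_pair
    if a not in alignment.taxa or b not in alignment.taxa:
        raise HoxatlasError("focal pair not in alignment taxa")
    best, best_ll = ml_tree_search(alignment, params, seed=seed)
    mono = best.are_sisters(a, b)
    if not mono:
        return False, 0.0
    not_sisters = lambda t: not t.are_sisters(a, b)  # noqa: E731
    if len(alignment.taxa) <= 5:
        if params is None:
            params = HKY85Params(kappa=2.0, base_freqs=alignment.empirical_freqs())
        constr_ll = -np.inf
        for topo in enumerate_topologies(sorted(alignment.taxa)):
            if not not_sisters(topo):
                continue
            _, ll, _ = fit_branch_lengths(alignment, topo, params)
            constr_ll = max(constr_ll, ll)
    else:
        _, constr_ll = ml_tree_search(alignment, params, seed=seed, constraint=not_sisters)
    return True, float(best_ll - constr_ll)
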