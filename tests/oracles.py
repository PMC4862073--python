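"""Independent brute-force oracles used across the test suite.

Everything here recomputes results by exhaustive enumeration or naive
arithmetic, deliberately sharing no code path with the implementations it
checks (the RNA oracle scores enumerated structures with the package's
model-definition function, but performs its own enumeration and
minimisation).
"""

from __future__ import annotations

import itertools
import re

import numpy as np

from hoxatlas.rna import _PAIR_IDX, encode, energy_of_structure


# --- alignment ------------------------------------------------------------

def score_gapped_pair(ga: str, gb: str, scheme) -> float:
    """Score a fully specified alignment: column substitution scores plus
    open + (L-1)*extend per maximal gap run."""
    s = 0.0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            s += scheme.match if x == y else scheme.mismatch
    for row in (ga, gb):
        for m in re.finditer(r"-+", row):
            L = m.end() - m.start()
            s -= scheme.gap_open + (L - 1) * scheme.gap_extend
    return s


def enum_global_score(a: str, b: str, scheme) -> float:
    """Best global alignment score by enumerating every alignment path."""
    best = -np.inf

    def rec(i: int, j: int, ga: str, gb: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score_gapped_pair(ga, gb, scheme))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ga + a[i], gb + b[j])
        if i < len(a):
            rec(i + 1, j, ga + a[i], gb + "-")
        if j < len(b):
            rec(i, j + 1, ga + "-", gb + b[j])

    rec(0, 0, "", "")
    return best


def enum_local_score(a: str, b: str, scheme) -> float:
    """Best local score: max global score over all substring pairs, or 0."""
    best = 0.0
    for i, j in itertools.combinations(range(len(a) + 1), 2):
        for k, l in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, enum_global_score(a[i:j], b[k:l], scheme))
    return best


# --- RNA secondary structure ---------------------------------------------

def enumerate_structures(seq: str):
    """All pseudoknot-free structures (min hairpin 3, allowed pairs only)."""
    enc = encode(seq.upper().replace("T", "U"))

    def gen(positions: tuple[int, ...]):
        if not positions:
            return [[]]
        i = positions[0]
        rest = positions[1:]
        res = list(gen(rest))  # i unpaired
        for j in rest:
            if j - i >= 4 and _PAIR_IDX[enc[i], enc[j]] >= 0:
                inner = tuple(k for k in rest if k < j)
                outer = tuple(k for k in rest if k > j)
                for si in gen(inner):
                    for so in gen(outer):
                        res.append([(i, j)] + si + so)
        return res

    return gen(tuple(range(len(enc))))


def brute_mfe(seq: str) -> float:
    """Minimum energy over every enumerated structure (0 = empty)."""
    best = 0.0
    for pairs in enumerate_structures(seq):
        best = min(best, energy_of_structure(seq, pairs))
    return best


# --- phylogenetic likelihood ----------------------------------------------

def exhaustive_loglik(aln, tree, params) -> float:
    """Likelihood by summing over all internal-node (and missing-leaf)
    state assignments explicitly."""
    pats, counts = np.unique(aln.data.T, axis=0, return_counts=True)
    pats = pats.T
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}
    leaves = set(tree.leaves())
    internals = [n for n in tree.adj if n not in leaves]
    if not internals:  # two-leaf tree: root at first leaf
        internals = [tree.leaves()[0]]
    total = 0.0
    for p in range(pats.shape[1]):
        col = pats[:, p]
        free = [n for n in tree.adj if n not in leaves] + [
            n for n in leaves if col[taxon_row[tree.labels[n]]] == 4
        ]
        lik = 0.0
        for assign in itertools.product(range(4), repeat=len(free)):
            amap = dict(zip(free, assign))
            for n in leaves:
                s = col[taxon_row[tree.labels[n]]]
                if s < 4:
                    amap[n] = s
            root = internals[0]

            def down(node, parent, acc):
                for c in tree.adj[node]:
                    if c == parent:
                        continue
                    P = params.transition_matrix(tree.adj[node][c])
                    acc *= P[amap[node], amap[c]]
                    acc = down(c, node, acc)
                return acc

            lik += down(root, None, params.base_freqs[amap[root]])
        total += counts[p] * np.log(lik)
    return float(total)


# --- cluster metrics ------------------------------------------------------

def brute_cluster_metrics(cluster_map, annotation) -> dict:
    """Naive single-scaffold metrics via per-bp position sets."""
    genes = [annotation.genes[e.gene_id] for e in cluster_map.entries]
    units = sorted(g.transcription_unit for g in genes)
    lo = min(s for s, _ in units)
    hi = max(e for _, e in units)
    covered = set()
    for s, e in units:
        covered.update(range(s, e))
    gaps = []
    ordered = sorted(
        zip(cluster_map.entries, genes), key=lambda eg: eg[1].transcription_unit
    )
    for (ea, ga), (eb, gb) in zip(ordered, ordered[1:]):
        g = gb.transcription_unit[0] - ga.transcription_unit[1]
        gaps.append(((ea.hox_class, eb.hox_class), max(g, 0)))
    hox_ids = {e.gene_id for e in cluster_map.entries}
    counts = []
    for (ea, ga), (eb, gb) in zip(ordered, ordered[1:]):
        lo_g, hi_g = ga.transcription_unit[1], gb.transcription_unit[0]
        c = sum(
            1
            for g in annotation.genes.values()
            if g.gene_id not in hox_ids
            and g.biotype == "protein_coding"
            and g.scaffold_id == ga.scaffold_id
            and g.transcription_unit[0] >= lo_g
            and g.transcription_unit[1] <= hi_g
        )
        counts.append(((ea.hox_class, eb.hox_class), c))
    return {
        "span": hi - lo,
        "intervening_space": (hi - lo) - len(covered),
        "gaps": gaps,
        "counts": counts,
    }


# --- misc -----------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle via a random Eulerian trail on the
    dinucleotide transition multigraph."""
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for k in edges:
        edges[k] = list(rng.permutation(edges[k]))
    # ensure the trail can finish: for each node, keep one edge leading back
    # toward the final vertex last (simple repeated-restart rejection works
    # fine at hairpin scale)
    for _ in range(200):
        pool = {k: list(v) for k, v in edges.items()}
        out = [seq[0]]
        node = seq[0]
        ok = True
        while any(pool.values()):
            nxt = pool.get(node)
            if not nxt:
                ok = False
                break
            node = nxt.pop()
            out.append(node)
        if ok and len(out) == len(seq):
            return "".join(out)
        for k in edges:
            edges[k] = list(rng.permutation(edges[k]))
    return "".join(out)  # pragma: no cover - fallback, still dinucleotide-rich
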