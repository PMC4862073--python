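"""RNA secondary structure prediction by free-energy minimisation.

A nearest-neighbour model in the Turner style: base-pair stacking terms
plus destabilising loop penalties (hairpin, bulge and internal loops by
size, with Jacobson-Stockmayer extrapolation beyond the tabulated sizes,
and an affine multiloop term).  Structures are pseudoknot-free with a
minimum hairpin loop of three unpaired bases; GU wobble pairs are allowed.
Internal/bulge loops are capped at 30 unpaired nucleotides, the usual
dynamic-programming restriction.

The minimisation is a Zuker-style dynamic program (``mfe_fold``); the
model itself is defined by :func:`energy_of_structure`, which scores any
given structure by loop decomposition and serves as the reference the DP
is validated against by exhaustive enumeration on short sequences.

Energies are in kcal/mol at 37 degC; more negative is more stable.  The
model aims at threshold behaviour (stable miRNA hairpins score well below
the -20 kcal/mol acceptance cut-off, shuffled sequences do not), not at
parity with any particular full parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ParameterError

__all__ = [
    "HairpinFold",
    "mfe_fold",
    "fold_hairpin",
    "energy_of_structure",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
]

MIN_HAIRPIN = 3
MAXLOOP = 30
ML_CLOSE = 3.4   # multiloop initiation
ML_BRANCH = 0.4  # per branch (closing helix included)
ASYM = 0.5       # internal-loop asymmetry, per unpaired-count difference
ASYM_MAX = 3.0
_RT37 = 0.616    # kcal/mol
INF = 1e9

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# pair index: AU=0 UA=1 CG=2 GC=3 GU=4 UG=5
_PAIR_IDX = -np.ones((4, 4), dtype=np.int64)
for _k, (_a, _b) in enumerate([(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]):
    _PAIR_IDX[_a, _b] = _k

# Stacking free energies, STACK[outer pair, inner pair]; Turner-style
# magnitudes for Watson-Crick and wobble stacks.
_STACK = np.array(
    [
        # inner:  AU     UA     CG     GC     GU     UG
        [-0.9, -1.1, -2.2, -2.1, -0.6, -1.4],  # outer AU
        [-1.3, -0.9, -2.4, -2.1, -1.0, -1.3],  # outer UA
        [-2.1, -2.1, -3.3, -2.4, -1.4, -2.1],  # outer CG
        [-2.4, -2.2, -3.4, -3.3, -1.5, -2.5],  # outer GC
        [-1.3, -1.4, -2.5, -2.1, -0.5, -0.6],  # outer GU
        [-1.0, -0.6, -1.5, -1.4, -0.3, -0.5],  # outer UG
    ]
)

_HAIRPIN_TAB = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_TAB = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_TAB = {2: 1.5, 3: 1.6, 4: 1.7, 5: 2.0, 6: 2.1, 7: 2.3, 8: 2.4, 9: 2.5}


def _loop_table(tab: dict[int, float], max_size: int) -> np.ndarray:
    """Tabulated sizes plus 1.75*RT*ln(n/n_max) extrapolation."""
    sizes = max(tab)
    out = np.full(max_size + 1, INF)
    for s, e in tab.items():
        if s <= max_size:
            out[s] = e
    for s in range(sizes + 1, max_size + 1):
        out[s] = tab[sizes] + 1.75 * _RT37 * math.log(s / sizes)
    return out


def encode(seq: str) -> np.ndarray:
    s = seq.upper()
    try:
        return np.array([_CODE[c] for c in s], dtype=np.int64)
    except KeyError as exc:
        raise ParameterError(f"non-ACGU(T) symbol in RNA sequence: {exc}") from exc


def hairpin_energy(size: int) -> float:
    if size < MIN_HAIRPIN:
        raise ParameterError(f"hairpin loop of size {size} < {MIN_HAIRPIN}")
    tab = _HAIRPIN_TAB
    if size in tab:
        return tab[size]
    m = max(tab)
    return tab[m] + 1.75 * _RT37 * math.log(size / m)


def bulge_energy(size: int) -> float:
    tab = _BULGE_TAB
    if size in tab:
        return tab[size]
    m = max(tab)
    return tab[m] + 1.75 * _RT37 * math.log(size / m)


def internal_energy(s1: int, s2: int) -> float:
    size = s1 + s2
    tab = _INTERNAL_TAB
    base = tab[size] if size in tab else tab[max(tab)] + 1.75 * _RT37 * math.log(
        size / max(tab)
    )
    return base + min(ASYM * abs(s1 - s2), ASYM_MAX)


def stack_energy(a: int, b: int, c: int, d: int) -> float:
    """Stack of inner pair (c,d) on outer pair (a,b), encoded bases."""
    p = _PAIR_IDX[a, b]
    q = _PAIR_IDX[c, d]
    if p < 0 or q < 0:
        raise ParameterError("stack on non-pairable bases")
    return float(_STACK[p, q])


def pairs_to_dotbracket(n: int, pairs: list[tuple[int, int]]) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)


def dotbracket_to_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ParameterError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ParameterError(f"invalid dot-bracket symbol {c!r}")
    if stack:
        raise ParameterError("unbalanced dot-bracket string")
    return sorted(pairs)


def energy_of_structure(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Free energy of a given structure by loop decomposition.

    This is the definition of the energy model: for each pair, the loop it
    closes is classified as a stack, hairpin, bulge, internal loop or
    multiloop and scored; exterior bases are free.  Crossing pairs or
    hairpins below the minimum loop size raise.
    """
    enc = encode(seq)
    n = len(enc)
    partner = {-1: -1}
    mate = [-1] * n
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ParameterError(f"pair ({i},{j}) out of range")
        if _PAIR_IDX[enc[i], enc[j]] < 0:
            raise ParameterError(f"bases at {i},{j} cannot pair")
        if mate[i] != -1 or mate[j] != -1:
            raise ParameterError("base paired twice")
        mate[i], mate[j] = j, i
    del partner

    def children(i: int, j: int) -> list[tuple[int, int]]:
        out = []
        k = i + 1
        while k < j:
            if mate[k] != -1:
                if mate[k] < k or mate[k] >= j:
                    raise ParameterError("crossing pairs (pseudoknot)")
                out.append((k, mate[k]))
                k = mate[k] + 1
            else:
                k += 1
        return out

    total = 0.0
    for i, j in sorted(pairs):
        kids = children(i, j)
        if not kids:
            total += hairpin_energy(j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                total += stack_energy(enc[i], enc[j], enc[k], enc[l])
            elif s1 == 0 or s2 == 0:
                total += bulge_energy(s1 + s2)
            else:
                total += internal_energy(s1, s2)
        else:
            total += ML_CLOSE + ML_BRANCH * (len(kids) + 1)
    # exterior-loop children must not cross either
    k = 0
    while k < n:
        if mate[k] != -1:
            if mate[k] < k:
                raise ParameterError("crossing pairs at exterior")
            k = mate[k] + 1
        else:
            k += 1
    return total


@njit(cache=True)
def _fill(enc, pair_idx, stack, hairpin_arr, bulge_arr, internal_arr):
    n = enc.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    WM2 = np.full((n, n), INF)
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            # WM2: at least two branches
            best2 = INF
            for k in range(i, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    v = WM[i, k] + WM[k + 1, j]
                    if v < best2:
                        best2 = v
            WM2[i, j] = best2
            p = pair_idx[enc[i], enc[j]]
            if p >= 0:
                best = hairpin_arr[j - i - 1]
                kmax = min(i + MAXLOOP + 1, j - 4)
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    lmin = j - 1 - (MAXLOOP - s1)
                    if lmin < k + 4:
                        lmin = k + 4
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        q = pair_idx[enc[k], enc[l]]
                        if q < 0:
                            continue
                        s2 = j - l - 1
                        if s1 == 0 and s2 == 0:
                            e = V[k, l] + stack[p, q]
                        elif s1 == 0 or s2 == 0:
                            e = V[k, l] + bulge_arr[s1 + s2]
                        else:
                            asym = ASYM * abs(s1 - s2)
                            if asym > ASYM_MAX:
                                asym = ASYM_MAX
                            e = V[k, l] + internal_arr[s1 + s2] + asym
                        if e < best:
                            best = e
                if WM2[i + 1, j - 1] < INF:
                    e = ML_CLOSE + ML_BRANCH + WM2[i + 1, j - 1]
                    if e < best:
                        best = e
                V[i, j] = best
            # WM: >=1 branch segment inside a multiloop (unpaired free)
            w = INF
            if V[i, j] < INF:
                w = V[i, j] + ML_BRANCH
            if WM[i + 1, j] < w:
                w = WM[i + 1, j]
            if WM[i, j - 1] < w:
                w = WM[i, j - 1]
            if WM2[i, j] < w:
                w = WM2[i, j]
            WM[i, j] = w
    W = np.zeros(n)
    for j in range(n):
        w = W[j - 1] if j > 0 else 0.0
        for k in range(0, j - 3):
            if V[k, j] < INF:
                prev = W[k - 1] if k > 0 else 0.0
                if prev + V[k, j] < w:
                    w = prev + V[k, j]
        W[j] = w
    return V, WM, WM2, W


_EPS = 1e-9


def _traceback(enc, V, WM, WM2, W, stack, bulge_arr, internal_arr, hairpin_arr):
    n = len(enc)
    pairs: list[tuple[int, int]] = []

    def close(a: float, b: float) -> bool:
        return abs(a - b) <= _EPS

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        p = _PAIR_IDX[enc[i], enc[j]]
        e = V[i, j]
        if close(e, hairpin_arr[j - i - 1]):
            return
        kmax = min(i + MAXLOOP + 1, j - 4)
        for k in range(i + 1, kmax + 1):
            s1 = k - i - 1
            lmin = max(j - 1 - (MAXLOOP - s1), k + 4)
            for l in range(lmin, j):
                if V[k, l] >= INF:
                    continue
                q = _PAIR_IDX[enc[k], enc[l]]
                if q < 0:
                    continue
                s2 = j - l - 1
                if s1 == 0 and s2 == 0:
                    cand = V[k, l] + stack[p, q]
                elif s1 == 0 or s2 == 0:
                    cand = V[k, l] + bulge_arr[s1 + s2]
                else:
                    cand = V[k, l] + internal_arr[s1 + s2] + min(ASYM * abs(s1 - s2), ASYM_MAX)
                if close(e, cand):
                    trace_V(k, l)
                    return
        if WM2[i + 1, j - 1] < INF and close(e, ML_CLOSE + ML_BRANCH + WM2[i + 1, j - 1]):
            trace_WM2(i + 1, j - 1)
            return
        raise AssertionError("traceback failed in V")

    def trace_WM(i: int, j: int) -> None:
        e = WM[i, j]
        if V[i, j] < INF and close(e, V[i, j] + ML_BRANCH):
            trace_V(i, j)
            return
        if i + 1 <= j and close(e, WM[i + 1, j]):
            trace_WM(i + 1, j)
            return
        if i <= j - 1 and close(e, WM[i, j - 1]):
            trace_WM(i, j - 1)
            return
        if close(e, WM2[i, j]):
            trace_WM2(i, j)
            return
        raise AssertionError("traceback failed in WM")

    def trace_WM2(i: int, j: int) -> None:
        e = WM2[i, j]
        for k in range(i, j):
            if WM[i, k] < INF and WM[k + 1, j] < INF and close(e, WM[i, k] + WM[k + 1, j]):
                trace_WM(i, k)
                trace_WM(k + 1, j)
                return
        raise AssertionError("traceback failed in WM2")

    def trace_W(j: int) -> None:
        while j >= 0:
            if j > 0 and close(W[j], W[j - 1]):
                j -= 1
                continue
            if close(W[j], 0.0) and j == 0:
                return
            found = False
            for k in range(0, j - 3):
                if V[k, j] < INF:
                    prev = W[k - 1] if k > 0 else 0.0
                    if close(W[j], prev + V[k, j]):
                        trace_V(k, j)
                        j = k - 1
                        found = True
                        break
            if not found:
                if close(W[j], 0.0):
                    return
                raise AssertionError("traceback failed in W")

    if n > 0 and W[n - 1] < -_EPS:
        trace_W(n - 1)
    return sorted(pairs)


def mfe_fold(sequence: str) -> tuple[float, str]:
    """Minimum free energy and dot-bracket structure of ``sequence``.

    The empty (all-unpaired) structure has energy 0, so the MFE is never
    positive.
    """
    seq = sequence.upper().replace("T", "U")
    enc = encode(seq)
    n = len(enc)
    if n < 5:
        return 0.0, "." * n
    hairpin_arr = _loop_table(_HAIRPIN_TAB, max(n, MIN_HAIRPIN))
    bulge_arr = _loop_table(_BULGE_TAB, MAXLOOP)
    internal_arr = _loop_table(_INTERNAL_TAB, MAXLOOP)
    V, WM, WM2, W = _fill(enc, _PAIR_IDX, _STACK, hairpin_arr, bulge_arr, internal_arr)
    mfe = float(min(0.0, W[n - 1]))
    pairs = _traceback(enc, V, WM, WM2, W, _STACK, bulge_arr, internal_arr, hairpin_arr)
    return mfe, pairs_to_dotbracket(n, pairs)


@dataclass
class HairpinFold:
    """A folded candidate: sequence, dot-bracket structure, and energy.

    ``arms`` and ``loop`` (0-based half-open intervals) are set only when
    the structure is a single stem-loop (exactly one terminal loop).
    """

    sequence: str
    structure: str
    mfe: float
    arms: tuple[tuple[int, int], tuple[int, int]] | None = None
    loop: tuple[int, int] | None = None

    @property
    def n_terminal_loops(self) -> int:
        return _count_terminal_loops(dotbracket_to_pairs(self.structure))

    def paired_fraction(self, start: int, end: int) -> float:
        seg = self.structure[start:end]
        if not seg:
            return 0.0
        return sum(1 for c in seg if c in "()") / len(seg)


def stemloop_components(structure: str) -> list[tuple[int, int, int]]:
    """Outermost helix components of a structure.

    Returns (start, end_exclusive, n_terminal_loops) per component — one
    entry for each pair not enclosed by any other pair.  A candidate
    extended with flanking genomic sequence often carries small
    independent side-stems; component-level anatomy lets a filter judge
    the hairpin that matters rather than the whole window.
    """
    pairs = dotbracket_to_pairs(structure)
    out = []
    for i, j in pairs:
        if any(a < i and j < b for a, b in pairs):
            continue
        inside = [(a, b) for a, b in pairs if i <= a and b <= j]
        out.append((i, j + 1, _count_terminal_loops(inside)))
    return sorted(out)


def component_arms(
    structure: str, start: int, end: int
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """(5' arm, 3' arm, loop) intervals of a single stem-loop component."""
    pairs = [
        (a, b) for a, b in dotbracket_to_pairs(structure) if start <= a and b < end
    ]
    if not pairs:
        raise ParameterError("component has no pairs")
    inner_a, inner_b = max(pairs, key=lambda p: p[0])
    return (start, inner_a + 1), (inner_b, end), (inner_a + 1, inner_b)


def _count_terminal_loops(pairs: list[tuple[int, int]]) -> int:
    opens = set(i for i, _ in pairs)
    closes = set(j for _, j in pairs)
    count = 0
    for i, j in pairs:
        if not any(i < a < j for a in opens) and not any(i < b < j for b in closes):
            count += 1
    return count


def fold_hairpin(sequence: str) -> HairpinFold:
    """Fold a candidate pre-miRNA (40-400 nt) and annotate its stem-loop
    anatomy when the MFE structure is a single hairpin."""
    if not 40 <= len(sequence) <= 400:
        raise ParameterError(
            f"fold_hairpin expects 40-400 nt, got {len(sequence)}"
        )
    seq = sequence.upper().replace("T", "U")
    mfe, structure = mfe_fold(seq)
    fold = HairpinFold(sequence=seq, structure=structure, mfe=mfe)
    pairs = dotbracket_to_pairs(structure)
    if pairs and _count_terminal_loops(pairs) == 1:
        innermost = max(pairs, key=lambda p: p[0])
        outer_i = min(i for i, _ in pairs)
        outer_j = max(j for _, j in pairs)
        fold.loop = (innermost[0] + 1, innermost[1])
        fold.arms = ((outer_i, innermost[0] + 1), (innermost[1], outer_j + 1))
    return fold
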