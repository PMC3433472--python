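"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive: textbook recursions and exhaustive
enumeration, sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache


# ---------------------------------------------------------------------------
# Levenshtein distance: textbook recursion (memoized)
# ---------------------------------------------------------------------------

def levenshtein_recursive(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        sub = d(i - 1, j - 1) + (0 if a[i - 1] == b[j - 1] else 1)
        return min(d(i - 1, j) + 1, d(i, j - 1) + 1, sub)

    return d(len(a), len(b))


# ---------------------------------------------------------------------------
# Tree edit distance: exhaustive recursion over all edit scripts
# ---------------------------------------------------------------------------

def forest_edit_distance(f1: tuple, f2: tuple) -> int:
    """Unmemoized forest edit recursion; each tree is (label, (children...))."""

    def size(forest: tuple) -> int:
        return sum(1 + size(t[1]) for t in forest)

    if not f1:
        return size(f2)
    if not f2:
        return size(f1)
    (l1, c1), *r1 = f1
    (l2, c2), *r2 = f2
    r1, r2 = tuple(r1), tuple(r2)
    delete = 1 + forest_edit_distance(c1 + r1, f2)
    insert = 1 + forest_edit_distance(f1, c2 + r2)
    match = ((0 if l1 == l2 else 1)
             + forest_edit_distance(c1, c2)
             + forest_edit_distance(r1, r2))
    return min(delete, insert, match)


def tree_to_tuple(tree) -> tuple:
    """Convert a selexkit StructureTree to the nested-tuple form."""
    return (tree.label, tuple(tree_to_tuple(c) for c in tree.children))


def tree_dist_oracle(t1, t2) -> int:
    """Edit distance between two trees, matching virtual roots."""
    a, b = tree_to_tuple(t1), tree_to_tuple(t2)
    # roots share the label R; the best mapping pairs them (cost 0)
    return forest_edit_distance(a[1], b[1])


# ---------------------------------------------------------------------------
# Exhaustive secondary-structure enumeration
# ---------------------------------------------------------------------------

def enumerate_structures(seq: str, config) -> list[frozenset]:
    """All legal non-crossing pair sets under the folding constraints."""
    legal = config.legal_pairs()
    minhp = config.min_hairpin_loop
    n = len(seq)

    def pairable(i: int, j: int) -> bool:
        return j - i - 1 >= minhp and (seq[i] + seq[j]) in legal

    def gen(i: int, j: int) -> list[frozenset]:
        if i > j:
            return [frozenset()]
        out = [s for s in gen(i + 1, j)]
        for k in range(i + 1, j + 1):
            if pairable(i, k):
                for inner in gen(i + 1, k - 1):
                    for rest in gen(k + 1, j):
                        out.append(inner | rest | {(i, k)})
        return out

    structures = gen(0, n - 1)
    if not config.allow_lonely_pairs:
        structures = [s for s in structures if not _has_lonely_pair(s)]
    return structures


def _has_lonely_pair(pairs: frozenset) -> bool:
    for i, j in pairs:
        if (i + 1, j - 1) not in pairs and (i - 1, j + 1) not in pairs:
            return True
    return False


def structure_energy(seq: str, pairs: frozenset, config) -> float:
    legal = config.legal_pairs()
    return sum(legal[seq[i] + seq[j]] for i, j in pairs)


def ensemble_by_enumeration(seq: str, config) -> dict:
    """Z, G_mfe, G_ens, P_mfe, pair probabilities, diversity — all by
    explicit summation over the enumerated ensemble."""
    rt = config.rt
    structures = enumerate_structures(seq, config)
    energies = [structure_energy(seq, s, config) for s in structures]
    weights = [math.exp(-e / rt) for e in energies]
    z = sum(weights)
    g_mfe = min(energies)
    g_ens = -rt * math.log(z)
    p_mfe = math.exp(-g_mfe / rt) / z
    pair_prob: dict[tuple[int, int], float] = {}
    for s, w in zip(structures, weights):
        for pair in s:
            pair_prob[pair] = pair_prob.get(pair, 0.0) + w / z
    diversity = sum(2.0 * p * (1.0 - p) for p in pair_prob.values())
    return {
        "Z": z, "G_mfe": g_mfe, "G_ens": g_ens, "P_mfe": p_mfe,
        "pair_prob": pair_prob, "diversity": diversity,
        "n_structures": len(structures),
    }


def diversity_by_pairwise_distance(seq: str, config) -> float:
    """Expected base-pair distance between two independent ensemble draws,
    by direct double summation over structure pairs."""
    rt = config.rt
    structures = enumerate_structures(seq, config)
    weights = [math.exp(-structure_energy(seq, s, config) / rt) for s in structures]
    z = sum(weights)
    total = 0.0
    for (s1, w1), (s2, w2) in itertools.product(zip(structures, weights), repeat=2):
        total += (w1 / z) * (w2 / z) * len(s1 ^ s2)
    return total


# ---------------------------------------------------------------------------
# Single-linkage clustering (scipy) helpers
# ---------------------------------------------------------------------------

def single_linkage_labels(matrix, threshold: int):
    """Cluster labels from cutting a scipy single-linkage tree at height t."""
    import numpy as np
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    condensed = squareform(np.asarray(matrix, dtype=float), checks=False)
    tree = linkage(condensed, method="single")
    return fcluster(tree, t=threshold, criterion="distance")


def single_linkage_heights(matrix):
    import numpy as np
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    condensed = squareform(np.asarray(matrix, dtype=float), checks=False)
    return linkage(condensed, method="single")[:, 2]
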