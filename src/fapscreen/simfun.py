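"""The 4D flexible atom-pair similarity function.

Two encoded molecules A and B are compared tree-by-tree: every pair of
atom-pair prefix trees (T_i from A, T_j from B) gets a similarity entry S^ij
combining a multiset Tanimoto on the rigid sub-trees with a label-gated
Gaussian-mixture correlation kernel on the flexible sub-trees.  The final
score is either an optimal assignment over S (the OA variant used for virtual
screening) or the normalized sum of all entries (the original QSAR variant).
All scores live in [0, 1], are symmetric, and self-similarity under the OA
variant is exactly 1.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .chemgraph import AtomLabel
from .encoder import AtomPairTree, EncodedMolecule, FlexibleLeaf, RigidLeaf
from .gmmfit import gmm_correlation


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the similarity function.

    ``w_rigid``/``w_flex`` combine the two sub-tree scores (equal-weight
    average by default, keeping entries in [0, 1]); ``literal_sum=True``
    instead adds them unweighted (range [0, 2], kept for comparison with the
    plain-sum formulation).  ``final_norm`` divides the assignment total by
    the larger or the smaller molecule's atom count; ``flex_norm`` selects
    cosine self-normalization (default) or division by the leaf-count product.
    """

    w_rigid: float = 0.5
    w_flex: float = 0.5
    final_norm: str = "max_atoms"  # or "min_atoms"
    flex_norm: str = "cosine"  # or "pair_count"
    literal_sum: bool = False

    def __post_init__(self) -> None:
        if self.w_rigid < 0 or self.w_flex < 0:
            raise ValueError("sub-tree weights must be non-negative")
        if not self.literal_sum and abs(self.w_rigid + self.w_flex - 1.0) > 1e-12:
            raise ValueError("w_rigid + w_flex must equal 1")
        if self.final_norm not in ("max_atoms", "min_atoms"):
            raise ValueError("final_norm must be 'max_atoms' or 'min_atoms'")
        if self.flex_norm not in ("cosine", "pair_count"):
            raise ValueError("flex_norm must be 'cosine' or 'pair_count'")


def label_similarity(l_m: AtomLabel, l_n: AtomLabel) -> float:
    """Dirac comparison of atom labels: 1.0 iff all three fields match."""
    return 1.0 if l_m == l_n else 0.0


def rigid_similarity(r_i: Sequence[RigidLeaf], r_j: Sequence[RigidLeaf]) -> float:
    """Multiset Tanimoto on (label, topological distance) items.

    |i n j| / (|R_i| + |R_j| - |i n j|) with the intersection counted per-item
    as the minimum multiplicity.  Two empty sub-trees are identical (1.0); an
    empty against a non-empty one shares nothing (0.0).
    """
    if not r_i and not r_j:
        return 1.0
    if not r_i or not r_j:
        return 0.0
    ci = Counter((l.leaf_label, l.topo_distance) for l in r_i)
    cj = Counter((l.leaf_label, l.topo_distance) for l in r_j)
    inter = sum((ci & cj).values())
    return inter / (len(r_i) + len(r_j) - inter)


def _flex_raw(f_i: Sequence[FlexibleLeaf], f_j: Sequence[FlexibleLeaf]) -> float:
    # sum over leaf pairs of label_similarity * gmm_correlation; the Dirac on
    # labels lets us restrict to label-matched groups
    by_label: Dict[AtomLabel, List[FlexibleLeaf]] = {}
    for leaf in f_j:
        by_label.setdefault(leaf.leaf_label, []).append(leaf)
    # fsum is exactly rounded, so the value is independent of iteration order
    # and the kernel is exactly symmetric
    return math.fsum(
        gmm_correlation(leaf_m.model, leaf_n.model)
        for leaf_m in f_i
        for leaf_n in by_label.get(leaf_m.leaf_label, ())
    )


def flexible_similarity(
    f_i: Sequence[FlexibleLeaf],
    f_j: Sequence[FlexibleLeaf],
    config: SimConfig = SimConfig(),
) -> float:
    """Normalized flexible sub-tree similarity in [0, 1].

    The raw kernel sums label-gated mixture correlations over all leaf pairs;
    cosine mode normalizes by sqrt(raw(F_i,F_i) * raw(F_j,F_j)) so identical
    sub-trees score exactly 1.  Two empty sub-trees are identical (1.0), one
    empty gives 0.0.
    """
    if not f_i and not f_j:
        return 1.0
    if not f_i or not f_j:
        return 0.0
    raw = _flex_raw(f_i, f_j)
    if config.flex_norm == "cosine":
        denom = math.sqrt(_flex_raw(f_i, f_i) * _flex_raw(f_j, f_j))
        return min(raw / denom, 1.0)
    return min(raw / (len(f_i) * len(f_j)), 1.0)


def _tree_rigid_counter(tree: AtomPairTree) -> Counter:
    cache = tree.__dict__.get("_rigid_counter")
    if cache is None:
        cache = Counter((l.leaf_label, l.topo_distance) for l in tree.rigid)
        tree.__dict__["_rigid_counter"] = cache
    return cache


def _tree_flex_self(tree: AtomPairTree) -> float:
    cache = tree.__dict__.get("_flex_self_raw")
    if cache is None:
        cache = _flex_raw(tree.flexible, tree.flexible)
        tree.__dict__["_flex_self_raw"] = cache
    return cache


def _rigid_sim_trees(t_i: AtomPairTree, t_j: AtomPairTree) -> float:
    if not t_i.rigid and not t_j.rigid:
        return 1.0
    if not t_i.rigid or not t_j.rigid:
        return 0.0
    inter = sum((_tree_rigid_counter(t_i) & _tree_rigid_counter(t_j)).values())
    return inter / (len(t_i.rigid) + len(t_j.rigid) - inter)


def _flex_sim_trees(t_i: AtomPairTree, t_j: AtomPairTree, config: SimConfig) -> float:
    if not t_i.flexible and not t_j.flexible:
        return 1.0
    if not t_i.flexible or not t_j.flexible:
        return 0.0
    raw = _flex_raw(t_i.flexible, t_j.flexible)
    if config.flex_norm == "cosine":
        return min(raw / math.sqrt(_tree_flex_self(t_i) * _tree_flex_self(t_j)), 1.0)
    return min(raw / (len(t_i.flexible) * len(t_j.flexible)), 1.0)


def _pair_weights(a: EncodedMolecule, b: EncodedMolecule, config: SimConfig) -> Tuple[float, float]:
    """Sub-tree weights for a molecule pair.

    When neither molecule has any flexible pair the flexible term carries no
    information and all weight shifts to the rigid sub-tree; symmetrically for
    an all-flexible pair (only possible for single-atom trees' empty rigid
    sub-trees, where both terms are trivial anyway).
    """
    if config.literal_sum:
        return config.w_rigid, config.w_flex
    n_flex = sum(len(t.flexible) for t in a.trees) + sum(len(t.flexible) for t in b.trees)
    n_rigid = sum(len(t.rigid) for t in a.trees) + sum(len(t.rigid) for t in b.trees)
    if n_flex == 0 and n_rigid > 0:
        return 1.0, 0.0
    if n_rigid == 0 and n_flex > 0:
        return 0.0, 1.0
    return config.w_rigid, config.w_flex


def tree_similarity(
    t_i: AtomPairTree,
    t_j: AtomPairTree,
    config: SimConfig = SimConfig(),
    weights: Optional[Tuple[float, float]] = None,
) -> float:
    """Similarity entry S^ij between two atom-pair trees.

    Weighted combination of the rigid and flexible sub-tree scores; the
    molecule-level weight override (all-rigid or all-flexible pairs of
    molecules) is supplied by :func:`similarity_matrix` via ``weights``.
    """
    w_r, w_f = weights if weights is not None else (config.w_rigid, config.w_flex)
    score = 0.0
    if w_r > 0.0:
        score += w_r * _rigid_sim_trees(t_i, t_j)
    if w_f > 0.0:
        score += w_f * _flex_sim_trees(t_i, t_j, config)
    return score


def similarity_matrix(
    a: EncodedMolecule, b: EncodedMolecule, config: SimConfig = SimConfig()
) -> np.ndarray:
    """|A| x |B| matrix of tree similarities; S(A,B) = S(B,A)^T."""
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValueError("cannot compare empty molecules")
    weights = _pair_weights(a, b, config)
    s = np.empty((a.n_atoms, b.n_atoms))
    for i, t_i in enumerate(a.trees):
        for j, t_j in enumerate(b.trees):
            s[i, j] = tree_similarity(t_i, t_j, config, weights=weights)
    return s


@dataclass
class Assignment:
    """Maximum-total injective mapping from the smaller axis to the larger."""

    mapping: Dict[int, int]
    total: float


def optimal_assignment(s: np.ndarray) -> Assignment:
    """Maximum-weight injective matching over a (rectangular) similarity matrix.

    Solved by the rectangular Hungarian algorithm; rows of the smaller
    dimension are mapped injectively into the larger one so that the sum of
    assigned entries is maximal.
    """
    s = np.asarray(s, dtype=float)
    transposed = s.shape[0] > s.shape[1]
    m = s.T if transposed else s
    rows, cols = linear_sum_assignment(m, maximize=True)
    total = math.fsum(m[rows, cols])
    mapping = dict(zip(rows.tolist(), cols.tolist()))
    return Assignment(mapping=mapping, total=total)


def fap_oa_similarity(
    a: EncodedMolecule, b: EncodedMolecule, config: SimConfig = SimConfig()
) -> float:
    """Optimal-assignment 4D FAP score in [0, 1].

    Assignment total over the tree-similarity matrix, normalized by the
    larger molecule's atom count (default), which penalizes size mismatch and
    keeps self-similarity at exactly 1.
    """
    s = similarity_matrix(a, b, config)
    total = optimal_assignment(s).total
    denom = max(a.n_atoms, b.n_atoms) if config.final_norm == "max_atoms" else min(
        a.n_atoms, b.n_atoms
    )
    return total / denom


def fap_sum_similarity(
    a: EncodedMolecule, b: EncodedMolecule, config: SimConfig = SimConfig()
) -> float:
    """Sum-variant score: mean of all similarity-matrix entries, in [0, 1]."""
    s = similarity_matrix(a, b, config)
    return math.fsum(s.flat) / (a.n_atoms * b.n_atoms)


def screen(
    query: EncodedMolecule,
    library: Sequence[EncodedMolecule],
    config: SimConfig = SimConfig(),
    variant: str = "oa",
) -> pd.DataFrame:
    """Rank a library against one query molecule.

    Returns a DataFrame (rank, name, score) sorted by descending score with
    ties kept in input order.
    """
    if not library:
        raise ValueError("empty library")
    if variant not in ("oa", "sum"):
        raise ValueError("variant must be 'oa' or 'sum'")
    fn = fap_oa_similarity if variant == "oa" else fap_sum_similarity
    scores = [fn(query, mol, config) for mol in library]
    frame = pd.DataFrame(
        {"name": [m.name for m in library], "score": scores, "_pos": range(len(library))}
    )
    frame = frame.sort_values(["score", "_pos"], ascending=[False, True], kind="stable")
    frame = frame.drop(columns="_pos").reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame
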