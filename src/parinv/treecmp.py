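"""Tree building and comparison for inverted-site validation.

Distance trees are built with neighbor-joining from BLOSUM80-based pairwise
distances.  Trees are compared with the edge-matching similarity of
Nye et al. (2006): every internal bipartition of one tree scores against
its best match in the other, where a pair of bipartitions scores the
maximum over the two side pairings of the minimum Jaccard overlap of the
paired sides.  The bootstrap experiment asks whether the tree built from
candidate inverted columns is *less* similar to the full-alignment tree
than trees from random column samples of the same size — the expected
signature when inverted columns carry a phylogeny-contradicting signal.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import nj as skbio_nj

from . import AMINO_ACIDS, GAP
from .align_io import GroupAssignment, SequenceRecord
from .scoring import _encode, _GAP_CODE

__all__ = [
    "DistanceMatrix",
    "TreeSimilarity",
    "BootstrapResult",
    "pairwise_distance",
    "nj_tree",
    "nye_similarity",
    "eligible_columns",
    "bootstrap_experiment",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v


@dataclass
class TreeSimilarity:
    """Nye-style similarity: sum of best edge matches out of ``max_score``."""

    score: float
    max_score: int


def _blosum_submatrix(name: str = "BLOSUM80") -> np.ndarray:
    B = substitution_matrices.load(name)
    idx = [B.alphabet.index(a) for a in AMINO_ACIDS]
    return np.asarray(B)[np.ix_(idx, idx)]


def pairwise_distance(
    records: Sequence[SequenceRecord], matrix_name: str = "BLOSUM80"
) -> DistanceMatrix:
    """BLOSUM-score distances between aligned sequences.

    For each pair, similarity is the summed substitution score over columns
    where both sequences carry an unambiguous residue.  It is min-max
    normalized per pair: the upper bound is the mean of the two self-scores
    over the same columns, the lower bound is the smallest matrix entry
    times the number of shared columns; distance = 1 - normalized
    similarity.  Pairs with no shared columns get the maximal distance 1.
    """
    B = _blosum_submatrix(matrix_name)
    b_min = B.min()
    enc = _encode(list(records))
    n = len(records)
    D = np.zeros((n, n))
    valid = enc >= 0  # residues only; gaps and unknowns excluded
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            L = int(both.sum())
            if L == 0:
                warnings.warn(
                    f"sequences {records[i].id!r} and {records[j].id!r} share no "
                    "ungapped column; assigning maximal distance",
                    UserWarning,
                    stacklevel=2,
                )
                D[i, j] = D[j, i] = 1.0
                continue
            xi = enc[i][both]
            xj = enc[j][both]
            s = B[xi, xj].sum()
            upper = 0.5 * (B[xi, xi].sum() + B[xj, xj].sum())
            lower = b_min * L
            if upper <= lower:
                d = 1.0
            else:
                d = 1.0 - (s - lower) / (upper - lower)
            D[i, j] = D[j, i] = min(1.0, max(0.0, float(d)))
    return DistanceMatrix(labels=[r.id for r in records], values=D)


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree; recovers additive distance matrices exactly."""
    if len(dist.labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    dm = SkbioDistanceMatrix(dist.values, ids=dist.labels)
    sk_tree = skbio_nj(dm)
    buf = io.StringIO()
    sk_tree.write(buf, format="newick")
    return dendropy.Tree.get(
        data=buf.getvalue(), schema="newick", preserve_underscores=True
    )


def _internal_bipartitions(tree: dendropy.Tree) -> list[tuple[frozenset, frozenset]]:
    """Unique internal bipartitions as (side, other side) leaf-label sets."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    seen = set()
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = frozenset((side, other))
        if key in seen:
            continue
        seen.add(key)
        out.append((side, other))
    return out


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 1.0


def nye_similarity(tree1: dendropy.Tree, tree2: dendropy.Tree) -> TreeSimilarity:
    """Edge-matching tree similarity (one-sided over tree1's internal edges).

    Each internal bipartition of ``tree1`` contributes the best score over
    ``tree2``'s internal bipartitions, where a bipartition pair scores
    ``max`` over the two consistent side pairings of ``min`` of the two
    Jaccard overlaps.  A tree against itself scores ``max_score``, the
    number of its internal edges.
    """
    leaves1 = {lf.taxon.label for lf in tree1.leaf_node_iter()}
    leaves2 = {lf.taxon.label for lf in tree2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(
            f"trees have different leaf sets (difference: {sorted(leaves1 ^ leaves2)[:5]})"
        )
    bips1 = _internal_bipartitions(tree1)
    bips2 = _internal_bipartitions(tree2)
    total = 0.0
    for a, b in bips1:
        best = 0.0
        for c, d in bips2:
            s = max(
                min(_jaccard(a, c), _jaccard(b, d)),
                min(_jaccard(a, d), _jaccard(b, c)),
            )
            best = max(best, s)
        total += best
    return TreeSimilarity(score=total, max_score=len(bips1))


def eligible_columns(
    records: Sequence[SequenceRecord], max_gap: float = 0.90
) -> np.ndarray:
    """0-based indices of columns with gap fraction below ``max_gap``."""
    enc = _encode(list(records))
    gap_fraction = (enc == _GAP_CODE).mean(axis=0)
    return np.flatnonzero(gap_fraction < max_gap)


def _subalignment(records: Sequence[SequenceRecord], cols: np.ndarray) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=r.id, residues="".join(r.residues[c] for c in cols),
                       species=r.species)
        for r in records
    ]


@dataclass
class BootstrapResult:
    full_tree: dendropy.Tree
    inverted_tree: dendropy.Tree
    inverted_similarity: float
    max_score: int
    table: pd.DataFrame
    t_statistic: float
    p_value: float


def bootstrap_experiment(
    records: Sequence[SequenceRecord],
    groups: GroupAssignment | None,
    inverted_sites: Sequence[int],
    lengths: Sequence = ("full", 250, 100, 20),
    replicates: int = 500,
    seed: int | None = None,
    matrix_name: str = "BLOSUM80",
    max_gap: float = 0.90,
) -> BootstrapResult:
    """Compare the inverted-sites tree with length-matched bootstrap trees.

    Builds NJ trees from the full alignment and from the 1-based
    ``inverted_sites`` columns, then for each requested length draws
    ``replicates`` bootstrap column samples (with replacement, restricted
    to columns under ``max_gap`` gaps, resampling whenever a sequence ends
    up all-gap), builds their trees, and records similarities to both
    reference trees.  The comparison statistic is a one-sample t-test of
    the shortest-length bootstrap similarities against the inverted-sites
    similarity (one-sided: bootstraps more similar to the full tree).
    """
    if len(inverted_sites) == 0:
        raise ValueError("inverted_sites must not be empty")
    records = list(records)
    rng = np.random.default_rng(seed)
    eligible = eligible_columns(records, max_gap=max_gap)
    if eligible.size == 0:
        raise ValueError("no columns below the gap threshold")
    site_idx = np.asarray(inverted_sites, dtype=int) - 1
    bad = set(site_idx) - set(eligible.tolist())
    if bad:
        raise ValueError(f"inverted sites not scoreable (too gappy): {sorted(b + 1 for b in bad)}")

    full_tree = nj_tree(pairwise_distance(_subalignment(records, eligible), matrix_name))
    inverted_tree = nj_tree(pairwise_distance(_subalignment(records, site_idx), matrix_name))
    inv_sim = nye_similarity(full_tree, inverted_tree)

    enc_valid = _encode(records) != _GAP_CODE
    rows = []
    numeric_lengths = []
    for length in lengths:
        L = eligible.size if length == "full" else int(length)
        numeric_lengths.append(L)
        for rep in range(replicates):
            for _attempt in range(1000):
                cols = rng.choice(eligible, size=L, replace=True)
                if enc_valid[:, cols].any(axis=1).all():
                    break
            else:
                raise RuntimeError("could not draw a bootstrap sample without all-gap sequences")
            boot_tree = nj_tree(pairwise_distance(_subalignment(records, cols), matrix_name))
            rows.append(
                {
                    "length": length,
                    "replicate": rep,
                    "sim_to_full": nye_similarity(full_tree, boot_tree).score,
                    "sim_to_inverted": nye_similarity(inverted_tree, boot_tree).score,
                }
            )
    table = pd.DataFrame(rows)
    shortest = lengths[int(np.argmin(numeric_lengths))]
    boot_sims = table.loc[table["length"] == shortest, "sim_to_full"].to_numpy()
    t_stat, p_value = stats.ttest_1samp(
        boot_sims, popmean=inv_sim.score, alternative="greater"
    )
    return BootstrapResult(
        full_tree=full_tree,
        inverted_tree=inverted_tree,
        inverted_similarity=inv_sim.score,
        max_score=inv_sim.max_score,
        table=table,
        t_statistic=float(t_stat),
        p_value=float(p_value),
    )
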