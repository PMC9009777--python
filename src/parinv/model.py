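"""Probabilistic quartet model of site evolution after gene duplication.

The model tree has a duplication node at the root, two pre-speciation
branches ``b1``/``b2`` (length ``t1``) leading to the speciation node of
each paralog copy, and four post-speciation branches ``b3``..``b6``
(length ``t2``) leading to the leaves ``Xa``, ``Ya``, ``Xb``, ``Yb``
(species group X/Y, copy a/b).  Each branch independently carries zero or
one substitution, with probability ``1 - exp(-t)``; after a substitution
every alternative amino acid is equiprobable and there is no selection.
Enumerating the 64 binary branch configurations and applying match rules
between leaves yields the probabilities of seven evolutionary outcome
categories, among them the *inversion* (paralogs match across species
groups, orthologs do not) and the *species-specific adaptation* (both
copies of one species group share a residue the other group lacks).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    import dendropy

    from .align_io import GroupAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "ModelParams",
    "BranchConfiguration",
    "CategoryProbabilities",
    "substitution_probability",
    "match_probability",
    "enumerate_configurations",
    "category_probability",
    "category_heatmap",
    "estimate_branch_lengths",
    "expected_inversion_probability",
]

CATEGORIES = (
    "conserved",
    "type1",
    "type2",
    "recent",
    "inversion",
    "species_specific",
    "non_conserved",
)

LEAVES = ("Xa", "Ya", "Xb", "Yb")

#: Branches incident to each leaf, as indices into (b1..b6) = (0..5).
_LEAF_BRANCHES = {"Xa": (0, 2), "Ya": (0, 3), "Xb": (1, 4), "Yb": (1, 5)}

#: Private path (branch indices) of each member of a leaf pair, below the
#: pair's most recent common ancestor.  Inner pairs share the speciation
#: node of their copy; all other (outer) pairs coalesce at the duplication.
_PAIR_PATHS: dict[tuple[str, str], tuple[tuple[int, ...], tuple[int, ...]]] = {
    ("Xa", "Ya"): ((2,), (3,)),
    ("Xb", "Yb"): ((4,), (5,)),
    ("Xa", "Xb"): ((0, 2), (1, 4)),
    ("Xa", "Yb"): ((0, 2), (1, 5)),
    ("Ya", "Xb"): ((0, 3), (1, 4)),
    ("Ya", "Yb"): ((0, 3), (1, 5)),
}

INNER_PAIRS = (("Xa", "Ya"), ("Xb", "Yb"))
OUTER_PAIRS = (("Xa", "Xb"), ("Xa", "Yb"), ("Ya", "Xb"), ("Ya", "Yb"))


class InvalidParameterError(ValueError):
    """A model parameter violates its domain."""


class GroupingError(ValueError):
    """A group assignment cannot be resolved on the given tree."""


@dataclass(frozen=True)
class ModelParams:
    """Branch lengths of the duplication quartet.

    Parameters
    ----------
    t1
        Pre-speciation branch length (duplication -> speciation), in
        expected substitutions per site.
    t2
        Post-speciation branch length (speciation -> leaf).
    alphabet_size
        Number of residue states; 20 for proteins.  Exposed so exact
        small-alphabet enumeration can cross-check the formulas.
    """

    t1: float
    t2: float
    alphabet_size: int = 20

    def __post_init__(self) -> None:
        for name in ("t1", "t2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")
        if self.alphabet_size < 2:
            raise InvalidParameterError(
                f"alphabet_size must be >= 2, got {self.alphabet_size}"
            )


@dataclass(frozen=True)
class BranchConfiguration:
    """One binary substitution assignment to the six branches b1..b6."""

    states: tuple[int, ...]
    probability: float
    leaf_states: Mapping[str, int] = field(default_factory=dict)
    path_counts: Mapping[tuple[str, str], tuple[int, int]] = field(default_factory=dict)


@dataclass(frozen=True)
class CategoryProbabilities:
    """Probabilities of the seven evolutionary outcome categories."""

    probabilities: Mapping[str, float]

    def __getitem__(self, category: str) -> float:
        return self.probabilities[category]

    @property
    def inversion(self) -> float:
        return self.probabilities["inversion"]

    @property
    def species_specific(self) -> float:
        return self.probabilities["species_specific"]


def substitution_probability(t: float) -> float:
    """Probability that a branch of length ``t`` carries a substitution.

    ``P = 1 - exp(-t)``: the chance that at least one replacement event
    fires on a branch of ``t`` expected substitutions per site.
    """
    if not np.isfinite(t) or t < 0:
        raise InvalidParameterError(f"branch length must be finite and >= 0, got {t!r}")
    return float(-np.expm1(-t))


@lru_cache(maxsize=None)
def _jump_matrix_powers(alphabet_size: int) -> tuple[np.ndarray, ...]:
    """Powers J^0, J^1, J^2 of the uniform jump chain on ``alphabet_size`` states."""
    a = alphabet_size
    J = np.full((a, a), 1.0 / (a - 1))
    np.fill_diagonal(J, 0.0)
    return np.eye(a), J, J @ J


def match_probability(k_u: int, k_v: int, alphabet_size: int = 20) -> float:
    """Probability that two leaves carry the same residue.

    ``k_u`` and ``k_v`` count the substitutions on each leaf's private path
    below the pair's most recent common ancestor.  Conditional on the
    ancestral residue ``c``, each path performs ``k`` uniform jumps (a
    substitution never preserves the residue, then lands on any of the
    ``A - 1`` alternatives with equal probability), so the match chance is
    ``sum_x [J^k_u]_{c,x} [J^k_v]_{c,x}`` — independent of ``c`` by
    symmetry of the jump chain.
    """
    for name, k in (("k_u", k_u), ("k_v", k_v)):
        if k not in (0, 1, 2):
            raise InvalidParameterError(
                f"{name} must be in 0..2 (at most one substitution per branch), got {k!r}"
            )
    powers = _jump_matrix_powers(alphabet_size)
    return float(powers[k_u][0] @ powers[k_v][0])


def _config_tables(alphabet_size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-configuration substitution counts and conditional category probabilities.

    Returns ``(n1, n2, cond)`` where ``n1[s]``/``n2[s]`` count substitutions
    on the t1/t2 branches of configuration ``s`` and ``cond`` is the 64 x 6
    matrix of P(category | configuration) for the six explicit categories,
    in CATEGORIES order.  These do not depend on branch lengths, so the
    result is cached.
    """
    return _config_tables_cached(alphabet_size)


@lru_cache(maxsize=None)
def _config_tables_cached(alphabet_size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    configs = list(itertools.product((0, 1), repeat=6))
    n1 = np.array([s[0] + s[1] for s in configs])
    n2 = np.array([sum(s[2:]) for s in configs])
    cond = np.empty((64, 6))
    for row, states in enumerate(configs):
        m = _pair_match_probs(states, alphabet_size)
        cond[row] = _conditional_category_probs(m)
    return n1, n2, cond


def _pair_match_probs(
    states: Sequence[int], alphabet_size: int
) -> dict[tuple[str, str], float]:
    """Match probability for every leaf pair under one branch configuration."""
    out = {}
    for pair, (path_u, path_v) in _PAIR_PATHS.items():
        k_u = sum(states[i] for i in path_u)
        k_v = sum(states[i] for i in path_v)
        out[pair] = match_probability(k_u, k_v, alphabet_size)
    return out


def _conditional_category_probs(m: Mapping[tuple[str, str], float]) -> np.ndarray:
    """The six explicit category formulas, instantiated from pair match probabilities.

    ``m`` maps each unordered leaf pair to its match probability; the inner
    matches are m(Xa,Ya) and m(Xb,Yb), all others are outer matches.  The
    conserved and type-1 formulas use max/min over the outer matches as the
    best approximation of the joint conditional, so the six values need not
    sum to one; the residual is absorbed by ``non_conserved``.
    """
    mi1 = m[("Xa", "Ya")]
    mi2 = m[("Xb", "Yb")]
    mo_xaxb = m[("Xa", "Xb")]
    mo_xayb = m[("Xa", "Yb")]
    mo_yaxb = m[("Ya", "Xb")]
    mo_yayb = m[("Ya", "Yb")]

    p_cons = mi1 * mi2 * max(mo_xaxb, mo_xayb, mo_yaxb, mo_yayb)
    p_type1 = mi1 * (1 - mi2) * (1 - min(mo_xaxb, mo_yaxb)) * (1 - min(mo_xayb, mo_yayb))
    p_type1 += (1 - mi1) * mi2 * (1 - min(mo_xaxb, mo_xayb)) * (1 - min(mo_yaxb, mo_yayb))
    p_type2 = mi1 * mi2 * (1 - p_cons)
    # one leaf diverged while the other three agree: the diverged leaf is,
    # in order of the terms, Yb, Xb, Ya, Xa
    p_recent = (
        mi1 * mo_xaxb * (1 - mi2)
        + mi1 * mo_xayb * (1 - mi2)
        + mi2 * mo_xaxb * (1 - mi1)
        + mi2 * mo_yaxb * (1 - mi1)
    )
    not_both_inner = 1 - min(mi1, mi2)
    p_inv = mo_xayb * mo_yaxb * not_both_inner
    p_ssa = mo_xaxb * mo_yayb * not_both_inner
    return np.array([p_cons, p_type1, p_type2, p_recent, p_inv, p_ssa])


def _configuration_weights(params: ModelParams) -> np.ndarray:
    """Probability of each of the 64 branch configurations at the given lengths."""
    n1, n2, _ = _config_tables(params.alphabet_size)
    p1 = substitution_probability(params.t1)
    p2 = substitution_probability(params.t2)
    return (
        p1**n1 * (1 - p1) ** (2 - n1) * p2**n2 * (1 - p2) ** (4 - n2)
    )


def enumerate_configurations(params: ModelParams) -> list[BranchConfiguration]:
    """All 64 substitution configurations with probabilities and leaf states."""
    weights = _configuration_weights(params)
    out = []
    for states, prob in zip(itertools.product((0, 1), repeat=6), weights):
        leaf_states = {
            leaf: states[i] + states[j] for leaf, (i, j) in _LEAF_BRANCHES.items()
        }
        path_counts = {
            pair: (sum(states[i] for i in pu), sum(states[i] for i in pv))
            for pair, (pu, pv) in _PAIR_PATHS.items()
        }
        out.append(
            BranchConfiguration(
                states=states,
                probability=float(prob),
                leaf_states=leaf_states,
                path_counts=path_counts,
            )
        )
    return out


_CLAMP_TOL = 1e-9


def category_probability(
    params: ModelParams | None = None,
    t1: float | None = None,
    t2: float | None = None,
    alphabet_size: int = 20,
) -> CategoryProbabilities:
    """Probabilities of the seven outcome categories at branch lengths (t1, t2).

    Each category probability is ``sum_conf P(conf) * P(cat | conf)`` over
    the 64 configurations; ``non_conserved`` is the residual
    ``1 - sum(others)``, clamped at zero.
    """
    if params is None:
        if t1 is None or t2 is None:
            raise InvalidParameterError("provide ModelParams or both t1 and t2")
        params = ModelParams(t1=t1, t2=t2, alphabet_size=alphabet_size)
    _, _, cond = _config_tables(params.alphabet_size)
    weights = _configuration_weights(params)
    explicit = weights @ cond
    residual = 1.0 - float(explicit.sum())
    if residual < -_CLAMP_TOL:
        warnings.warn(
            f"explicit categories sum to {explicit.sum():.12f} > 1 at "
            f"(t1={params.t1}, t2={params.t2}); clamping non_conserved to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    probs = dict(zip(CATEGORIES[:6], (float(v) for v in explicit)))
    probs["non_conserved"] = min(1.0, max(0.0, residual))
    return CategoryProbabilities(probabilities=probs)


def category_heatmap(
    t1_grid: Sequence[float],
    t2_grid: Sequence[float],
    alphabet_size: int = 20,
) -> dict[str, np.ndarray]:
    """Evaluate all category probabilities on a (t1, t2) grid.

    Returns a mapping category -> matrix with ``matrix[i, j]`` the category
    probability at ``(t1_grid[i], t2_grid[j])``.
    """
    t1_grid = np.asarray(t1_grid, dtype=float)
    t2_grid = np.asarray(t2_grid, dtype=float)
    if t1_grid.size == 0 or t2_grid.size == 0:
        raise InvalidParameterError("heatmap grids must be non-empty")
    if (t1_grid < 0).any() or (t2_grid < 0).any():
        raise InvalidParameterError("grid branch lengths must be >= 0")
    n1, n2, cond = _config_tables(alphabet_size)
    p1 = -np.expm1(-t1_grid)[:, None]  # (len(t1), 1)
    p2 = -np.expm1(-t2_grid)[:, None]
    w1 = p1**n1 * (1 - p1) ** (2 - n1)  # (len(t1), 64)
    w2 = p2**n2 * (1 - p2) ** (4 - n2)
    # weights[i, j, s] = w1[i, s] * w2[j, s]; contract with cond over s
    explicit = np.einsum("is,js,sc->ijc", w1, w2, cond)
    out = {cat: explicit[:, :, k] for k, cat in enumerate(CATEGORIES[:6])}
    out["non_conserved"] = np.clip(1.0 - explicit.sum(axis=2), 0.0, 1.0)
    return out


def default_heatmap_grid(steps: int = 50, lo: float = 0.02, hi: float = 5.0) -> np.ndarray:
    """Linear grid over (lo, hi] substitutions/site used for heatmaps and bounds."""
    return np.linspace(lo, hi, steps)


def estimate_branch_lengths(
    tree: "dendropy.Tree", groups: "GroupAssignment"
) -> tuple[float, float]:
    """Estimate quartet (t1, t2) from a duplication tree.

    Convention: the duplication node is the split separating the two
    paralog clades; within each paralog clade the species-group split node
    is taken as the most recent common ancestor of the clade's grouped
    leaves.  ``t1`` is the mean path length from the duplication node to
    the two split nodes, ``t2`` the mean split-node-to-leaf path length.
    """
    tree.is_rooted = True  # the seed node is the duplication split
    taxon_ns = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    paralogs = sorted(set(groups.paralog_label.values()))
    if len(paralogs) != 2:
        raise GroupingError(f"exactly two paralog labels required, got {paralogs}")
    clades = {}
    for copy in paralogs:
        ids = [i for i, p in groups.paralog_label.items() if p == copy and i in taxon_ns]
        if len(ids) < 2:
            raise GroupingError(f"paralog clade {copy!r} has fewer than 2 leaves on the tree")
        mrca = tree.mrca(taxa=[taxon_ns[i].taxon for i in ids])
        clade_leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
        if clade_leaves != set(ids):
            raise GroupingError(
                f"paralog copy {copy!r} is not monophyletic on the tree "
                f"(extra leaves: {sorted(clade_leaves - set(ids))[:5]})"
            )
        clades[copy] = (mrca, ids)
    dup = tree.mrca(taxa=[lf.taxon for lf in tree.leaf_node_iter()])

    def _depth_between(anc, node) -> float:
        d = 0.0
        while node is not anc:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    t1_parts, t2_parts = [], []
    for copy, (mrca, ids) in clades.items():
        t1_parts.append(_depth_between(dup, mrca))
        for i in ids:
            t2_parts.append(_depth_between(mrca, taxon_ns[i]))
    t1 = float(np.mean(t1_parts))
    t2 = float(np.mean(t2_parts))
    logger.info(
        "estimated quartet branch lengths: t1=%.6g (duplication -> clade split, "
        "mean of %d paths), t2=%.6g (split -> leaf, mean of %d paths)",
        t1, len(t1_parts), t2, len(t2_parts),
    )
    return t1, t2


def expected_inversion_probability(
    tree: "dendropy.Tree", groups: "GroupAssignment", alphabet_size: int = 20
) -> float:
    """Model-expected per-site inversion probability for a given tree and grouping."""
    t1, t2 = estimate_branch_lengths(tree, groups)
    return category_probability(t1=t1, t2=t2, alphabet_size=alphabet_size).inversion
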