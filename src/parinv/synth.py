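"""Synthetic duplication phylogenies with planted inversion columns.

The generator emulates the study design end to end: a duplication tree
whose two paralog clades each contain the same species tree, a neutral
alignment simulated under JTT with gamma rate heterogeneity, and a small
number of columns overwritten with the inversion pattern (group1-copy-a
and group2-copy-b share one residue, the other two cells the other) or the
species-specific-adaptation pattern, plus independent per-leaf noise.
Ground truth is returned so detection power can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import AMINO_ACIDS
from .align_io import GroupAssignment, GroupedAlignment, SequenceRecord
from .simevo import SimulatedAlignment, SubstitutionModel, simulate_alignment

__all__ = ["SynthConfig", "SynthDataset", "make_duplication_tree", "plant_columns",
           "generate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic fixture.

    Defaults describe a moderately diverged duplication: 8 + 8 species,
    pre-speciation branch t1 = 0.3 and post-speciation depth t2 = 0.1
    substitutions/site, 2000 simulated sites under JTT with 4-category
    gamma rates (shape 1.0), 10 planted inversion columns and 5% per-leaf
    noise on planted columns.
    """

    n_species_group1: int = 8
    n_species_group2: int = 8
    t1: float = 0.3
    t2: float = 0.1
    n_sites: int = 2000
    n_planted_inversions: int = 10
    n_planted_ssa: int = 0
    inversion_residue_pair: tuple[str, str] = ("A", "C")
    noise: float = 0.05
    seed: int = 0
    model_name: str = "JTT"
    gamma_shape: float | None = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.n_species_group1 < 1 or self.n_species_group2 < 1:
            raise ValueError("each species group needs at least one species")
        if self.n_planted_inversions + self.n_planted_ssa > self.n_sites:
            raise ValueError("cannot plant more columns than there are sites")
        r1, r2 = self.inversion_residue_pair
        if r1 == r2 or r1 not in AMINO_ACIDS or r2 not in AMINO_ACIDS:
            raise ValueError("inversion_residue_pair must be two distinct amino acids")
        if not 0 <= self.noise <= 1:
            raise ValueError("noise must be a probability")


def _ultrametric_newick(names: Sequence[str], height: float) -> str:
    """Balanced ultrametric subtree over ``names`` with total depth ``height``."""
    if len(names) == 1:
        return f"{names[0]}:{height:.10g}"
    half = len(names) // 2
    step = height / 2
    left = _ultrametric_newick(names[:half], height - step)
    right = _ultrametric_newick(names[half:], height - step)
    return f"({left},{right}):{step:.10g}"


def make_duplication_tree(cfg: SynthConfig) -> tuple[dendropy.Tree, GroupAssignment]:
    """Mirrored duplication tree and its exact group assignment.

    The root is the duplication node; each paralog clade hangs from a stem
    of length t1 and contains the two species-group subtrees (stem t2/2,
    internal depth t2/2), so every leaf sits t1 + t2 below the root.  With
    one species per group this is exactly the four-leaf quartet of the
    model.  Leaves are labeled ``<species>_<copy>``.
    """
    sp1 = [f"g1s{i + 1}" for i in range(cfg.n_species_group1)]
    sp2 = [f"g2s{i + 1}" for i in range(cfg.n_species_group2)]

    def clade(copy: str) -> str:
        # each species-group subtree has total depth t2 below the clade root
        # (stem t2/2 + internal depth t2/2; a single species gets pendant t2)
        parts = [
            _ultrametric_newick([f"{s}_{copy}" for s in names], cfg.t2)
            for names in (sp1, sp2)
        ]
        return f"({parts[0]},{parts[1]}):{cfg.t1:.10g}"

    newick = f"({clade('a')},{clade('b')});"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

    paralog, sgroup, species = {}, {}, {}
    for copy in ("a", "b"):
        for names, grp in ((sp1, "group1"), (sp2, "group2")):
            for s in names:
                label = f"{s}_{copy}"
                paralog[label] = copy
                sgroup[label] = grp
                species[label] = s
    groups = GroupAssignment(
        paralog_label=paralog, species_group=sgroup, species=species,
        mode="manual", grouping_id="synthetic_truth",
    )
    return tree, groups


@dataclass
class SynthDataset:
    records: list[SequenceRecord]
    tree: dendropy.Tree
    groups: GroupAssignment
    truth: pd.DataFrame
    config: SynthConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def grouped(self, reference_id: str | None = None) -> GroupedAlignment:
        return GroupedAlignment(records=self.records, groups=self.groups,
                                reference_id=reference_id)


def plant_columns(
    alignment: SimulatedAlignment | Sequence[SequenceRecord],
    cfg: SynthConfig,
    groups: GroupAssignment,
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Overwrite random columns with inversion / SSA patterns.

    Planted inversion columns put one residue in cells Xa and Yb and the
    other in Ya and Xb; planted SSA columns put one residue in Xa and Xb
    and the other in Ya and Yb.  Each leaf of a planted column is then
    independently replaced by a random different residue with probability
    ``cfg.noise``.  Returns the modified records and a ground-truth table
    with 1-based column indices.
    """
    records = list(alignment.records) if isinstance(alignment, SimulatedAlignment) \
        else [SequenceRecord(id=r.id, residues=r.residues, species=r.species)
              for r in alignment]
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_cols = len(records[0].residues)
    n_plant = cfg.n_planted_inversions + cfg.n_planted_ssa
    if n_plant > n_cols:
        raise ValueError("cannot plant more columns than the alignment has")
    planted_cols = rng.choice(n_cols, size=n_plant, replace=False)
    inv_cols = planted_cols[: cfg.n_planted_inversions]
    ssa_cols = planted_cols[cfg.n_planted_inversions:]

    r1, r2 = cfg.inversion_residue_pair
    seqs = [list(r.residues) for r in records]
    cell_of = {r.id: groups.cell(r.id) for r in records}

    truth_rows = []
    for kind, cols in (("inversion", inv_cols), ("ssa", ssa_cols)):
        first_cells = ("Xa", "Yb") if kind == "inversion" else ("Xa", "Xb")
        for col in cols:
            for k, rec in enumerate(records):
                cell = cell_of[rec.id]
                if cell is None:
                    continue
                residue = r1 if cell in first_cells else r2
                if cfg.noise > 0 and rng.random() < cfg.noise:
                    alternatives = [a for a in AMINO_ACIDS if a != residue]
                    residue = alternatives[rng.integers(len(alternatives))]
                seqs[k][col] = residue
            truth_rows.append(
                {"column": int(col) + 1, "kind": kind, "residue_1": r1, "residue_2": r2}
            )
    out_records = [
        SequenceRecord(id=r.id, residues="".join(s), species=r.species)
        for r, s in zip(records, seqs)
    ]
    truth = pd.DataFrame(truth_rows, columns=["column", "kind", "residue_1", "residue_2"])
    return out_records, truth.sort_values("column").reset_index(drop=True)


def generate_dataset(cfg: SynthConfig | None = None) -> SynthDataset:
    """Full synthetic fixture: tree, groups, planted alignment, truth table."""
    cfg = cfg or SynthConfig()
    tree, groups = make_duplication_tree(cfg)
    rng = np.random.default_rng(cfg.seed)
    sim_seed = int(rng.integers(2**31 - 1))
    model = SubstitutionModel(
        name=cfg.model_name, gamma_shape=cfg.gamma_shape, n_categories=cfg.n_categories
    )
    sim = simulate_alignment(tree, model=model, n_sites=cfg.n_sites, seed=sim_seed)
    records, truth = plant_columns(sim, cfg, groups, rng=rng)
    return SynthDataset(records=records, tree=tree, groups=groups, truth=truth, config=cfg)
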