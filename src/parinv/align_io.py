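"""Alignment/tree I/O and four-way group assignment.

Sequences are assigned to the four cells Xa/Ya/Xb/Yb: species group X
(group1) or Y (group2), crossed with paralog copy a or b.  Assignments come
from a TSV mapping file (manual mode) or are inferred from the tree
topology (automatic mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from . import AMINO_ACIDS, GAP, UNKNOWN

__all__ = [
    "SequenceRecord",
    "GroupAssignment",
    "GroupedAlignment",
    "AlignmentFormatError",
    "TreeFormatError",
    "GroupingError",
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "check_labels",
    "read_groups_tsv",
    "write_groups_tsv",
    "assign_groups_auto",
    "species_from_labels",
]

_VALID_CHARS = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}


class AlignmentFormatError(ValueError):
    """The alignment file is malformed (ragged, empty, or bad characters)."""


class TreeFormatError(ValueError):
    """The tree file cannot be parsed or is inconsistent with the alignment."""


class GroupingError(ValueError):
    """Sequences cannot be partitioned into the four groups."""


@dataclass
class SequenceRecord:
    """One aligned protein sequence (gapped, upper-case)."""

    id: str
    residues: str
    species: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GroupAssignment:
    """Partition of sequence ids into species group x paralog copy.

    ``paralog_label`` maps id -> 'a'/'b' (exactly two labels in use);
    ``species_group`` maps id -> 'group1'/'group2'.  ``species`` keeps the
    organism of each id so automatic grouping can check that species clades
    mirror across the two paralog clades.
    """

    paralog_label: dict[str, str]
    species_group: dict[str, str]
    mode: str = "manual"
    species: dict[str, str] = field(default_factory=dict)
    grouping_id: str = "grouping0"

    def __post_init__(self) -> None:
        labels = sorted(set(self.paralog_label.values()))
        if len(labels) != 2:
            raise GroupingError(
                f"exactly two paralog labels are required, got {labels}"
            )
        sgroups = set(self.species_group.values())
        if not sgroups <= {"group1", "group2"}:
            raise GroupingError(f"species groups must be group1/group2, got {sorted(sgroups)}")

    @property
    def paralog_labels(self) -> tuple[str, str]:
        return tuple(sorted(set(self.paralog_label.values())))  # type: ignore[return-value]

    def cell(self, seq_id: str) -> str | None:
        """Cell name 'Xa'/'Ya'/'Xb'/'Yb' for a sequence, or None if unassigned."""
        sg = self.species_group.get(seq_id)
        pl = self.paralog_label.get(seq_id)
        if sg is None or pl is None:
            return None
        first, second = self.paralog_labels
        copy = "a" if pl == first else "b"
        return ("X" if sg == "group1" else "Y") + copy

    def members(self, cell: str, ids: list[str]) -> list[str]:
        """Ids among ``ids`` assigned to the given cell, in input order."""
        return [i for i in ids if self.cell(i) == cell]


@dataclass
class GroupedAlignment:
    """An alignment together with its four-way grouping."""

    records: list[SequenceRecord]
    groups: GroupAssignment
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if self.reference_id is not None:
            ids = {r.id for r in self.records}
            if self.reference_id not in ids:
                raise GroupingError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_alignment(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA file into upper-cased, validated records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - _VALID_CHARS
        if bad:
            raise AlignmentFormatError(
                f"sequence {rec.id!r} contains invalid characters: {sorted(bad)}"
            )
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    lengths = {len(r.residues) for r in records}
    if len(lengths) > 1:
        raise AlignmentFormatError(
            f"alignment is ragged: sequence lengths {sorted(lengths)} in {path}"
        )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentFormatError(f"duplicate sequence ids: {dupes}")
    return records


def write_alignment(records: list[SequenceRecord], path: str | Path) -> None:
    bio = [BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree, keeping underscores in labels literal.

    Edges without a branch length get unit length (with a warning) so that
    topology-only trees remain usable.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeFormatError(f"cannot parse Newick file {path}: {exc}") from exc
    missing = [
        e for e in tree.preorder_edge_iter()
        if e.length is None and e.head_node is not tree.seed_node
    ]
    if missing:
        warnings.warn(
            f"{len(missing)} edges in {path} lack branch lengths; using unit lengths",
            UserWarning,
            stacklevel=2,
        )
        for e in missing:
            e.length = 1.0
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def check_labels(tree: dendropy.Tree, records: list[SequenceRecord]) -> None:
    """Require tree leaf labels and alignment ids to match exactly."""
    tree_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    seq_ids = {r.id for r in records}
    only_tree = sorted(tree_labels - seq_ids)
    only_aln = sorted(seq_ids - tree_labels)
    if only_tree or only_aln:
        raise TreeFormatError(
            "tree/alignment label mismatch; "
            f"only in tree: {only_tree[:10]}, only in alignment: {only_aln[:10]}"
        )


def read_groups_tsv(path: str | Path) -> GroupAssignment:
    """Read a mapping TSV with columns: id, species, paralog, species_group."""
    paralog, sgroup, species = {}, {}, {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.strip().lower() for p in parts]
                expected = ["id", "species", "paralog", "species_group"]
                if header != expected:
                    raise GroupingError(
                        f"groups TSV must have header {expected}, got {header}"
                    )
                continue
            if len(parts) != 4:
                raise GroupingError(f"bad groups TSV row: {line!r}")
            sid, sp, pl, sg = (p.strip() for p in parts)
            paralog[sid] = pl
            sgroup[sid] = sg
            species[sid] = sp
    if not paralog:
        raise GroupingError(f"no assignments found in {path}")
    return GroupAssignment(
        paralog_label=paralog, species_group=sgroup, species=species, mode="manual"
    )


def write_groups_tsv(groups: GroupAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tparalog\tspecies_group\n")
        for sid in groups.paralog_label:
            fh.write(
                f"{sid}\t{groups.species.get(sid, '')}\t"
                f"{groups.paralog_label[sid]}\t{groups.species_group.get(sid, '')}\n"
            )


def species_from_labels(labels: list[str]) -> dict[str, str]:
    """Derive species names by stripping a trailing '_<copy>' token from leaf labels."""
    out = {}
    for lab in labels:
        if "_" not in lab:
            raise GroupingError(
                f"cannot derive species from label {lab!r}; provide a species map"
            )
        out[lab] = lab.rsplit("_", 1)[0]
    return out


def _clades_with_stems(node) -> list[tuple[frozenset, float]]:
    """(leaf label set, stem length) for every non-root subtree under ``node``."""
    out = []
    for nd in node.preorder_iter():
        if nd is node:
            continue
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        out.append((leaves, nd.edge.length or 0.0))
    return out


def assign_groups_auto(
    tree: dendropy.Tree,
    distance_param: float = 0.0,
    min_group: int = 2,
    species_map: dict[str, str] | None = None,
) -> list[GroupAssignment]:
    """Infer candidate four-way groupings from the tree alone.

    The two paralog clades are the two subtrees flanking the root-most
    split.  A candidate species grouping is a set of species that is
    monophyletic in *both* paralog clades with stem length exceeding
    ``distance_param`` and at least ``min_group`` species; each candidate
    puts that clade in group1 and the remaining species in group2.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if species_map is None:
        species_map = species_from_labels(leaves)
    root = tree.seed_node
    children = root.child_nodes()
    if len(children) != 2:
        raise GroupingError(
            f"tree root must split into exactly two paralog clades, has {len(children)} children"
        )
    clade_leaves = [
        {lf.taxon.label for lf in ch.leaf_iter()} for ch in children
    ]
    species_sets = [frozenset(species_map[l] for l in cl) for cl in clade_leaves]
    if species_sets[0] != species_sets[1]:
        raise GroupingError(
            "the two clades under the root do not contain the same species; "
            "not a duplication bipartition "
            f"(difference: {sorted(species_sets[0] ^ species_sets[1])[:5]})"
        )
    all_species = species_sets[0]
    paralog = {l: ("a" if l in clade_leaves[0] else "b") for l in leaves}

    # species clades (by stem threshold and size) within each paralog subtree
    candidates_per_clade = []
    for ch in children:
        cands = {}
        for leafset, stem in _clades_with_stems(ch):
            sp = frozenset(species_map[l] for l in leafset)
            if len(sp) != len(leafset):
                continue  # not a pure one-leaf-per-species clade
            if len(sp) < min_group or stem <= distance_param:
                continue
            cands[sp] = max(stem, cands.get(sp, 0.0))
        candidates_per_clade.append(cands)
    mirrored = sorted(
        set(candidates_per_clade[0]) & set(candidates_per_clade[1]),
        key=lambda s: (-len(s), sorted(s)),
    )

    out = []
    seen_bipartitions = set()
    for k, sp_set in enumerate(mirrored):
        complement = all_species - sp_set
        if not complement:
            continue
        key = frozenset((sp_set, frozenset(complement)))
        if key in seen_bipartitions:
            continue
        seen_bipartitions.add(key)
        sgroup = {
            l: ("group1" if species_map[l] in sp_set else "group2") for l in leaves
        }
        out.append(
            GroupAssignment(
                paralog_label=dict(paralog),
                species_group=sgroup,
                species=dict(species_map),
                mode="automatic",
                grouping_id="auto_" + "+".join(sorted(sp_set)),
            )
        )
    return out
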