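"""Per-column inversion and species-specific-adaptation scoring.

For each alignment column the four groups Xa/Ya/Xb/Yb yield amino-acid
frequency arrays (optionally smoothed with pseudo-counts toward a
background distribution).  The match probability between two groups is the
dot product of their frequency arrays.  The inversion score is the joint
probability that the two cross-species paralog pairs match while the site
is not uniformly conserved; the species-specific-adaptation (SSA) score is
the same construction with the within-species pairs in the cross role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import AMINO_ACIDS, GAP, GROUP_CELLS, UNKNOWN
from ._matrices import lg_frequencies
from .align_io import GroupAssignment, GroupedAlignment, GroupingError, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnProfile",
    "SiteScore",
    "PseudoCountConfig",
    "column_frequencies",
    "match_prob",
    "inversion_score",
    "ssa_score",
    "scan_alignment",
    "percentile_threshold",
    "ortholog_paralog_matching",
    "map_column_to_reference",
    "frequency_table",
    "scores_to_dataframe",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_GAP_CODE = -1
_UNKNOWN_CODE = -2


class EmptyGroupError(ValueError):
    """A column has no scorable residues in one of the four groups."""


@dataclass(frozen=True)
class PseudoCountConfig:
    """Dirichlet-style pseudo-count smoothing of column frequencies.

    With group size ``n`` and raw frequency ``f``, the smoothed frequency is
    ``(n*f + beta*g) / (n + beta)`` where ``g`` is the background
    distribution (LG stationary frequencies by default).  ``beta = 0``
    disables smoothing.
    """

    beta: float = 5.0
    background: np.ndarray = field(default_factory=lg_frequencies)

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must be a length-20 frequency array summing to 1")
        object.__setattr__(self, "background", bg)


@dataclass
class ColumnProfile:
    """Frequency arrays of the four groups at one alignment column."""

    column_index: int  # 1-based
    freq: dict[str, np.ndarray]
    counts: dict[str, int]
    gap_fraction: float

    @property
    def empty_cells(self) -> list[str]:
        return [c for c in GROUP_CELLS if self.counts.get(c, 0) == 0]


@dataclass
class SiteScore:
    """Scores and reference coordinates for one scanned column."""

    column_index: int  # 1-based MSA column
    inversion_score: float
    ssa_score: float
    grouping_id: str
    ref_position: int | None = None
    ref_exact: bool = True
    ref_residue_a: str | None = None
    ref_residue_b: str | None = None
    conservation_a: float = 0.0
    conservation_b: float = 0.0


def _encode(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Alignment as an int8 matrix: 0..19 residues, -1 gap, -2 unknown."""
    lut = np.full(128, _UNKNOWN_CODE, dtype=np.int8)
    for aa, i in _AA_INDEX.items():
        lut[ord(aa)] = i
    lut[ord(GAP)] = _GAP_CODE
    rows = [
        lut[np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8)]
        for r in records
    ]
    return np.vstack(rows) if rows else np.empty((0, 0), dtype=np.int8)


def _cell_rows(groups: GroupAssignment, ids: Sequence[str]) -> dict[str, np.ndarray]:
    index = {sid: k for k, sid in enumerate(ids)}
    out = {}
    for cell in GROUP_CELLS:
        members = groups.members(cell, list(ids))
        out[cell] = np.array([index[m] for m in members], dtype=int)
    return out


def _group_count_arrays(
    matrix: np.ndarray, rows: Mapping[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-cell residue count matrices (n_cols x 20) and non-gap counts."""
    counts, totals = {}, {}
    for cell, idx in rows.items():
        sub = matrix[idx]  # (n_members, n_cols)
        c = np.zeros((matrix.shape[1], 20))
        for aa in range(20):
            c[:, aa] = (sub == aa).sum(axis=0)
        counts[cell] = c
        totals[cell] = c.sum(axis=1)
    return counts, totals


def _frequencies(
    counts: np.ndarray, totals: np.ndarray, pc: PseudoCountConfig | None
) -> np.ndarray:
    """Column frequencies from counts, with optional pseudo-count smoothing."""
    with np.errstate(invalid="ignore", divide="ignore"):
        if pc is None or pc.beta == 0:
            f = counts / totals[:, None]
        else:
            f = (counts + pc.beta * pc.background) / (totals + pc.beta)[:, None]
    return np.nan_to_num(f, nan=0.0)


def column_frequencies(
    grouped: GroupedAlignment, column: int, pc: PseudoCountConfig | None = None
) -> ColumnProfile:
    """Frequency profile of one 1-based column.

    Gaps and unknown residues are excluded from the counts; a cell with no
    scorable residue gets an all-zero array and is listed in
    ``ColumnProfile.empty_cells``.
    """
    n_cols = grouped.n_columns
    if not 1 <= column <= n_cols:
        raise ValueError(f"column {column} out of range 1..{n_cols}")
    matrix = _encode(grouped.records)[:, [column - 1]]
    rows = _cell_rows(grouped.groups, grouped.ids)
    counts, totals = _group_count_arrays(matrix, rows)
    assigned = np.concatenate([rows[c] for c in GROUP_CELLS])
    col = matrix[assigned, 0]
    gap_fraction = float((col == _GAP_CODE).mean()) if assigned.size else 0.0
    freq = {
        c: _frequencies(counts[c], totals[c], pc)[0] for c in GROUP_CELLS
    }
    return ColumnProfile(
        column_index=column,
        freq=freq,
        counts={c: int(totals[c][0]) for c in GROUP_CELLS},
        gap_fraction=gap_fraction,
    )


def match_prob(p: np.ndarray, q: np.ndarray) -> float:
    """Probability that independent draws from two frequency arrays match."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for arr in (p, q):
        if arr.shape != (20,):
            raise ValueError("frequency arrays must have length 20")
        if not np.isclose(arr.sum(), 1.0, atol=1e-6):
            raise ValueError(f"frequency array sums to {arr.sum()!r}, not 1")
    return float(p @ q)


def _joint_score(a1: np.ndarray, a2: np.ndarray, b1: np.ndarray, b2: np.ndarray) -> float:
    """Joint probability that pairs (a1,a2) and (b1,b2) match while the site
    is not uniformly conserved, in division-free form
    ``sum_i a1[i] a2[i] (M(b1,b2) - b1[i] b2[i])``."""
    m_b = float(b1 @ b2)
    val = float(np.sum(a1 * a2 * (m_b - b1 * b2)))
    return min(1.0, max(0.0, val))


def inversion_score(profile: ColumnProfile) -> float:
    """Joint probability of an inter-paralog inversion at this column.

    Both cross pairs (Xa,Yb) and (Ya,Xb) match while the column is not
    simply conserved across all four groups.
    """
    if profile.empty_cells:
        raise EmptyGroupError(f"empty groups at column {profile.column_index}: "
                              f"{profile.empty_cells}")
    f = profile.freq
    return _joint_score(f["Xa"], f["Yb"], f["Ya"], f["Xb"])


def ssa_score(profile: ColumnProfile) -> float:
    """Joint probability of a species-specific adaptation at this column.

    Both within-species pairs (Xa,Xb) and (Ya,Yb) match while the column is
    not simply conserved; equals the inversion score after exchanging the
    Xb and Yb arrays.
    """
    if profile.empty_cells:
        raise EmptyGroupError(f"empty groups at column {profile.column_index}: "
                              f"{profile.empty_cells}")
    f = profile.freq
    return _joint_score(f["Xa"], f["Xb"], f["Ya"], f["Yb"])


def map_column_to_reference(
    records: Sequence[SequenceRecord], reference_id: str, column: int
) -> tuple[int | None, str | None, bool]:
    """Map a 1-based MSA column to an ungapped position in the reference.

    Returns ``(position, residue, exact)``.  If the reference is gapped at
    the column, the nearest preceding non-gap position is reported with
    ``exact=False`` (position ``None`` if there is none).
    """
    by_id = {r.id: r for r in records}
    if reference_id not in by_id:
        raise KeyError(f"unknown reference id {reference_id!r}")
    seq = by_id[reference_id].residues
    if not 1 <= column <= len(seq):
        raise ValueError(f"column {column} out of range 1..{len(seq)}")
    prefix = seq[:column]
    position = len(prefix) - prefix.count(GAP)
    residue = seq[column - 1]
    if residue != GAP:
        return position, residue, True
    if position == 0:
        return None, None, False
    last = prefix.rstrip(GAP)
    return position, last[-1], False


def _vector_scores(
    freq: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized inversion and SSA scores from per-cell (n_cols x 20) arrays."""
    xa, ya, xb, yb = (freq[c] for c in GROUP_CELLS)
    m_yaxb = np.sum(ya * xb, axis=1)
    inv = np.sum(xa * yb * (m_yaxb[:, None] - ya * xb), axis=1)
    m_yayb = np.sum(ya * yb, axis=1)
    ssa = np.sum(xa * xb * (m_yayb[:, None] - ya * yb), axis=1)
    return np.clip(inv, 0.0, 1.0), np.clip(ssa, 0.0, 1.0)


def _modal_identity(matrix: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Per-column fraction of non-gap residues equal to the modal residue."""
    sub = matrix[rows]
    counts = np.zeros((matrix.shape[1], 20))
    for aa in range(20):
        counts[:, aa] = (sub == aa).sum(axis=0)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = counts.max(axis=1) / totals
    return np.nan_to_num(ident, nan=0.0)


def scan_alignment(
    grouped: GroupedAlignment,
    pc: PseudoCountConfig | None = None,
    gap_threshold: float = 0.60,
    groupings: GroupAssignment | Iterable[GroupAssignment] | None = None,
) -> list[SiteScore]:
    """Score every eligible column of the alignment.

    Columns whose overall gap fraction (over all assigned sequences) is at
    or above ``gap_threshold`` are excluded, as are columns where any of
    the four groups has no scorable residue.  With several candidate
    groupings, each column reports the grouping that maximizes its
    inversion score.  Results are sorted by column index.
    """
    if groupings is None:
        grouping_list = [grouped.groups]
    elif isinstance(groupings, GroupAssignment):
        grouping_list = [groupings]
    else:
        grouping_list = list(groupings)
    if not grouping_list:
        raise GroupingError("at least one grouping is required")

    matrix = _encode(grouped.records)
    n_cols = matrix.shape[1]
    ids = grouped.ids

    best_inv = np.full(n_cols, -1.0)
    best_ssa = np.zeros(n_cols)
    best_grouping = np.full(n_cols, -1, dtype=int)
    any_eligible = np.zeros(n_cols, dtype=bool)

    for g_idx, groups in enumerate(grouping_list):
        rows = _cell_rows(groups, ids)
        if any(len(rows[c]) == 0 for c in GROUP_CELLS):
            logger.warning("grouping %s leaves a cell empty; skipped", groups.grouping_id)
            continue
        assigned = np.concatenate([rows[c] for c in GROUP_CELLS])
        gap_fraction = (matrix[assigned] == _GAP_CODE).mean(axis=0)
        counts, totals = _group_count_arrays(matrix, rows)
        nonempty = np.ones(n_cols, dtype=bool)
        for c in GROUP_CELLS:
            nonempty &= totals[c] > 0
        eligible = (gap_fraction < gap_threshold) & nonempty
        if not eligible.any():
            continue
        freq = {c: _frequencies(counts[c], totals[c], pc) for c in GROUP_CELLS}
        inv, ssa = _vector_scores(freq)
        better = eligible & (inv > best_inv)
        best_inv[better] = inv[better]
        best_ssa[better] = ssa[better]
        best_grouping[better] = g_idx
        any_eligible |= eligible

    if not any_eligible.any():
        logger.warning("no scoreable columns (gap threshold %.2f)", gap_threshold)
        return []

    # reference coordinates and per-copy conservation
    ref_info = _reference_rows(grouped)
    first_label = grouping_list[0].paralog_labels[0]
    copy_a_rows = np.array(
        [k for k, sid in enumerate(ids)
         if grouping_list[0].paralog_label.get(sid) == first_label],
        dtype=int,
    )
    copy_b_rows = np.array(
        [k for k in range(len(ids)) if k not in set(copy_a_rows)
         and grouping_list[0].paralog_label.get(ids[k]) is not None],
        dtype=int,
    )
    cons_a = _modal_identity(matrix, copy_a_rows) if copy_a_rows.size else np.zeros(n_cols)
    cons_b = _modal_identity(matrix, copy_b_rows) if copy_b_rows.size else np.zeros(n_cols)

    out = []
    for col in np.flatnonzero(any_eligible):
        score = SiteScore(
            column_index=int(col) + 1,
            inversion_score=float(best_inv[col]),
            ssa_score=float(best_ssa[col]),
            grouping_id=grouping_list[best_grouping[col]].grouping_id,
            conservation_a=float(cons_a[col]),
            conservation_b=float(cons_b[col]),
        )
        if ref_info is not None:
            ref_a, ref_b = ref_info
            pos, _res, exact = map_column_to_reference(
                grouped.records, ref_a.id, int(col) + 1
            )
            score.ref_position = pos
            score.ref_exact = exact
            score.ref_residue_a = ref_a.residues[col]
            if ref_b is not None:
                score.ref_residue_b = ref_b.residues[col]
        out.append(score)
    return out


def _reference_rows(
    grouped: GroupedAlignment,
) -> tuple[SequenceRecord, SequenceRecord | None] | None:
    """The reference sequence and its other-copy partner (same species)."""
    if grouped.reference_id is None:
        return None
    by_id = {r.id: r for r in grouped.records}
    ref = by_id[grouped.reference_id]
    groups = grouped.groups
    first_label = groups.paralog_labels[0]
    ref_label = groups.paralog_label.get(ref.id)
    ref_species = groups.species.get(ref.id)
    partner = None
    if ref_species:
        for sid, sp in groups.species.items():
            if sid != ref.id and sp == ref_species and sid in by_id:
                partner = by_id[sid]
                break
    if ref_label is not None and ref_label != first_label and partner is not None:
        return partner, ref  # report coordinates in the copy-a row
    return ref, partner


def percentile_threshold(scores: Sequence[float], q: float = 99.0) -> float:
    """Linear-interpolation percentile of a score distribution.

    Sites *strictly above* the returned threshold count as selected.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot take a percentile of an empty score list")
    if not 0 <= q <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {q}")
    return float(np.percentile(scores, q, method="linear"))


def ortholog_paralog_matching(
    grouped: GroupedAlignment,
    pc: PseudoCountConfig | None = None,
    gap_threshold: float = 0.60,
) -> pd.DataFrame:
    """Per-site mean ortholog vs mean paralog match probabilities.

    The ortholog coordinate averages M(Xa,Ya) and M(Xb,Yb) (same copy
    across species groups); the paralog coordinate averages M(Xa,Yb) and
    M(Ya,Xb).  Conserved sites sit near (1,1); inverted sites have high
    paralog and low ortholog matching.
    """
    matrix = _encode(grouped.records)
    rows = _cell_rows(grouped.groups, grouped.ids)
    if any(len(rows[c]) == 0 for c in GROUP_CELLS):
        raise GroupingError("all four groups must be non-empty")
    assigned = np.concatenate([rows[c] for c in GROUP_CELLS])
    gap_fraction = (matrix[assigned] == _GAP_CODE).mean(axis=0)
    counts, totals = _group_count_arrays(matrix, rows)
    nonempty = np.ones(matrix.shape[1], dtype=bool)
    for c in GROUP_CELLS:
        nonempty &= totals[c] > 0
    eligible = (gap_fraction < gap_threshold) & nonempty
    freq = {c: _frequencies(counts[c], totals[c], pc) for c in GROUP_CELLS}
    ortho = 0.5 * (
        np.sum(freq["Xa"] * freq["Ya"], axis=1)
        + np.sum(freq["Xb"] * freq["Yb"], axis=1)
    )
    para = 0.5 * (
        np.sum(freq["Xa"] * freq["Yb"], axis=1)
        + np.sum(freq["Ya"] * freq["Xb"], axis=1)
    )
    cols = np.flatnonzero(eligible)
    return pd.DataFrame(
        {
            "column_index": cols + 1,
            "ortholog_match": ortho[cols],
            "paralog_match": para[cols],
        }
    )


def frequency_table(
    grouped: GroupedAlignment,
    columns: Sequence[int],
    pc: PseudoCountConfig | None = None,
) -> pd.DataFrame:
    """Long-format per-site group frequencies (logo-ready).

    One row per (column, group cell, amino acid) with its frequency, for
    the given 1-based columns.
    """
    rows = []
    for col in columns:
        prof = column_frequencies(grouped, int(col), pc=pc)
        for cell in GROUP_CELLS:
            for k, aa in enumerate(AMINO_ACIDS):
                rows.append(
                    {"msa_pos": int(col), "group": cell, "residue": aa,
                     "frequency": float(prof.freq[cell][k])}
                )
    return pd.DataFrame(rows, columns=["msa_pos", "group", "residue", "frequency"])


def scores_to_dataframe(
    scores: Sequence[SiteScore], threshold: float | None = None
) -> pd.DataFrame:
    """Tabulate site scores; ``selected_flag`` marks sites strictly above threshold."""
    df = pd.DataFrame(
        {
            "msa_pos": [s.column_index for s in scores],
            "ref_pos": [s.ref_position for s in scores],
            "ref_exact": [s.ref_exact for s in scores],
            "ref_residue_a": [s.ref_residue_a for s in scores],
            "ref_residue_b": [s.ref_residue_b for s in scores],
            "conservation_a": [s.conservation_a for s in scores],
            "conservation_b": [s.conservation_b for s in scores],
            "inversion_score": [s.inversion_score for s in scores],
            "ssa_score": [s.ssa_score for s in scores],
            "grouping_id": [s.grouping_id for s in scores],
        }
    )
    if threshold is not None:
        df["selected_flag"] = df["inversion_score"] > threshold
    return df
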