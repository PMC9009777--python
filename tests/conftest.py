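import numpy as np
import pytest

from parinv import scoring, synth
from parinv.align_io import GroupAssignment, GroupedAlignment, SequenceRecord


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic duplication dataset (8+8 species, 10 planted inversions)."""
    return synth.generate_dataset(synth.SynthConfig(seed=7))


@pytest.fixture(scope="session")
def quartet_dataset():
    """Minimal four-leaf quartet dataset (one species per group)."""
    cfg = synth.SynthConfig(
        n_species_group1=1, n_species_group2=1, n_sites=50,
        n_planted_inversions=2, seed=3,
    )
    return synth.generate_dataset(cfg)


def make_grouped(cell_residues: dict[str, list[str]],
                 reference_id: str | None = None) -> GroupedAlignment:
    """Build a toy GroupedAlignment from per-cell residue strings.

    ``cell_residues`` maps each cell ('Xa','Ya','Xb','Yb') to a list of
    aligned sequences (one string per member).
    """
    records, paralog, sgroup, species = [], {}, {}, {}
    for cell, seqs in cell_residues.items():
        sg = "group1" if cell[0] == "X" else "group2"
        copy = cell[1]
        for k, seq in enumerate(seqs):
            sid = f"{cell}_{k}"
            records.append(SequenceRecord(id=sid, residues=seq))
            paralog[sid] = copy
            sgroup[sid] = sg
            species[sid] = f"{sg}_sp{k}"
    groups = GroupAssignment(paralog_label=paralog, species_group=sgroup,
                             species=species)
    return GroupedAlignment(records=records, groups=groups,
                            reference_id=reference_id)


def random_profile(rng: np.random.Generator, concentration: float = 0.5):
    """Random valid four-group frequency profile."""
    freq = {c: rng.dirichlet(np.full(20, concentration)) for c in
            ("Xa", "Ya", "Xb", "Yb")}
    return scoring.ColumnProfile(
        column_index=1, freq=freq, counts={c: 10 for c in freq}, gap_fraction=0.0
    )
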