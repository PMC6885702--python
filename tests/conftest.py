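import numpy as np
import pandas as pd
import pytest

from mstriad.quantio import ReporterMatrix, validate_design


def make_design(channels, conditions, roles=None, replicates=None, set_id="set1",
                timepoints=None, temperatures=None):
    n = len(channels)
    roles = roles or ["sample"] * n
    replicates = replicates or list(range(1, n + 1))
    rows = dict(
        set_id=set_id,
        channel_label=channels,
        condition=conditions,
        replicate=replicates,
        role=roles,
    )
    if timepoints is not None:
        rows["timepoint_h"] = timepoints
    if temperatures is not None:
        rows["temperature_C"] = temperatures
    return validate_design(pd.DataFrame(rows))


def make_matrix(values, design, ids=None, peptide_count=2, is_reverse=False,
                is_contaminant=False, normalized=False):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    abund = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"),
                         columns=list(design.index))
    n = len(ids)
    meta = pd.DataFrame(
        {
            "gene_name": [f"G{i}" for i in range(n)],
            "peptide_count": np.broadcast_to(peptide_count, n).copy(),
            "is_reverse": np.broadcast_to(is_reverse, n).copy(),
            "is_contaminant": np.broadcast_to(is_contaminant, n).copy(),
        },
        index=abund.index,
    )
    return ReporterMatrix(abund, meta, design, normalized=normalized)


@pytest.fixture
def sixplex_design():
    return make_design(
        ["126", "127", "128", "129", "130", "131"],
        ["A"] * 6,
        roles=["free"] * 3 + ["oxidized"] * 3,
        replicates=[1, 2, 3, 1, 2, 3],
    )


@pytest.fixture
def toy_protein_groups(tmp_path):
    """4-protein proteinGroups-style TSV with channels 126-131."""
    channels = ["126", "127", "128", "129", "130", "131"]
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "Majority protein IDs": [f"P{i}" for i in range(4)],
            "Gene names": [f"G{i}" for i in range(4)],
            "Razor + unique peptides": [5, 3, 2, 8],
            "Reverse": ["", "", "", ""],
            "Potential contaminant": ["", "", "", ""],
        }
    )
    for ch in channels:
        table[f"Reporter intensity corrected {ch}"] = rng.uniform(1e4, 1e6, 4)
    path = tmp_path / "proteinGroups.txt"
    table.to_csv(path, sep="\t", index=False)
    design = make_design(channels, ["ctl", "a", "a", "b", "b", "ctl"],
                         roles=["reference", "sample", "sample", "sample", "sample", "bridge"],
                         replicates=[1, 1, 2, 1, 2, 2])
    return path, design, table
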