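import numpy as np
import pytest

from tloopsrm.kinome import KinaseRecord, TargetPeptide


@pytest.fixture
def toy_kinase() -> KinaseRecord:
    """A minimal kinase whose T-loop tryptic peptide is GHLSEGLVTK.

    Layout: N-flank ending in K (tryptic cut), then DFG + filler + K,
    then the target peptide GHLSEGLVTK (S at local 4, T at local 9),
    then filler + APE + C-flank. Gap between DFG and APE is 17 residues.
    """
    seq = "MAAAAK" + "DFG" + "LLK" + "GHLSEGLVTK" + "RAGW" + "APE" + "AAAK"
    return KinaseRecord(kinase_id="KIN001", gene="TOY1", sequence=seq)


@pytest.fixture
def toy_target() -> TargetPeptide:
    return TargetPeptide(
        backbone="GHLSEGLVTK",
        phospho_positions=frozenset({4}),
        kinase_ids=frozenset({"KIN001"}),
        site_labels=frozenset({"TOY1_S16"}),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_target(backbone: str, positions, kinases, labels=None) -> TargetPeptide:
    return TargetPeptide(
        backbone=backbone,
        phospho_positions=frozenset(positions),
        kinase_ids=frozenset(kinases),
        site_labels=frozenset(labels or {f"{k}_site" for k in kinases}),
    )
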