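import json
from pathlib import Path

import pytest

from ribovar.genemodel import Sequence, TranscriptModel
from ribovar.synthetic_data import write_fixture_bundle


@pytest.fixture
def toy_transcript() -> TranscriptModel:
    """Hand-built 2-exon transcript: 30-nt cDNA, CDS 3..29 (MKWVTAAG + stop).

    Layout: 2-nt 5' UTR | ATG AAA TGG GTG ACC GCA GCT GGA TAA | 1-nt 3' UTR.
    """
    cdna = "GG" + "ATGAAATGGGTGACCGCAGCTGGATAA" + "T"
    return TranscriptModel(
        id="toy",
        cdna=Sequence("toy", cdna),
        exons=[(1, 10), (11, 30)],
        cds_start=3,
        cds_end=29,
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory) -> Path:
    """One seed-1 fixture bundle shared across the session."""
    outdir = tmp_path_factory.mktemp("bundle") / "seed1"
    write_fixture_bundle(outdir, seed=1)
    return outdir


@pytest.fixture(scope="session")
def bundle_truth(bundle_dir) -> dict:
    with open(bundle_dir / "ground_truth.json") as fh:
        return json.load(fh)
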