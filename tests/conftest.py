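import logging

import pandas as pd
import pytest

import methtopo as mt

logging.getLogger("methtopo").setLevel(logging.ERROR)

SEED = 11


@pytest.fixture(scope="session")
def study() -> mt.SyntheticStudy:
    """Default six-group synthetic study (the standard test conditions)."""
    return mt.simulate_study(seed=SEED)


@pytest.fixture(scope="session")
def result(study) -> mt.PipelineResult:
    """Full pipeline run on the default study."""
    return mt.run_pipeline(study, mt.PipelineConfig(seed=SEED))


@pytest.fixture()
def tiny_genome() -> mt.GenomeTable:
    """One 400 bp chromosome with a centromere gap at 1-based (100, 200)."""
    return mt.GenomeTable(
        {"chrA": 400},
        pd.DataFrame({"chrom": ["chrA"], "start": [99], "end": [200]}),
        pd.DataFrame(
            {
                "chrom": ["chrA"] * 4,
                "start": [0, 99, 200, 300],
                "end": [99, 200, 300, 400],
                "name": ["p1", "cen", "q1", "q2"],
                "stain": ["gneg", "acen", "gpos50", "gneg"],
            }
        ),
    )


def make_manifest_frame(rows):
    """rows: (probe_id, chrom, pos, regions, genes, platforms)."""
    recs, ids = [], []
    for probe_id, chrom, pos, regions, genes, platforms in rows:
        ids.append(probe_id)
        recs.append(
            {
                "chromosome": chrom,
                "position": pos,
                "strand": "+",
                **{r: r in regions for r in mt.REGIONS},
                "genes": tuple(genes),
                **{p: p in platforms for p in mt.PLATFORMS},
            }
        )
    df = pd.DataFrame(recs, index=pd.Index(ids, name="probe_id"))
    return mt.ProbeManifest(df)


@pytest.fixture()
def manifest_factory():
    return make_manifest_frame
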