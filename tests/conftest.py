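import logging

import numpy as np
import pytest

from famcensus import pipeline, repeat_scan, synthetic_data

logging.getLogger("famcensus").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def study_bundle():
    """The 200-protein study population: default class counts, substitution
    rate 0.05, fixed seed."""
    spec = synthetic_data.FamilySpec(seed=1)
    return spec, synthetic_data.generate_proteome(spec)


@pytest.fixture(scope="session")
def study_profile():
    aln = synthetic_data.generate_seed_alignment(seed=1)
    return repeat_scan.build_profile([s for _, s in aln])


@pytest.fixture(scope="session")
def study_census(study_bundle, study_profile):
    _, bundle = study_bundle
    return repeat_scan.census(bundle.proteins, study_profile,
                              repeat_scan.ScanParams(seed=1))


@pytest.fixture(scope="session")
def golden_run(tmp_path_factory):
    """One full pipeline run (seed 42, default config) shared by the pipeline
    and acceptance tests."""
    out = tmp_path_factory.mktemp("golden") / "run"
    cfg = pipeline.PipelineConfig(out_dir=str(out), seed=42)
    manifest = pipeline.run_pipeline(cfg)
    return cfg, manifest


TRUTH_TO_SUBFAMILY = {
    "NONE": "NOT_MYB", "1R": "MYB_RELATED", "2R3R": "R2R3",
    "3R": "R1R2R3", "4R": "FOUR_R", "ATYPICAL": "ATYPICAL",
}


def classification_accuracy(truth, archs) -> float:
    hits = [archs[p].subfamily == TRUTH_TO_SUBFAMILY[t.architecture]
            for p, t in truth.proteins.items()]
    return float(np.mean(hits))
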