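import pytest

from secistrome import pipeline as pl
from secistrome.simulate import ScenarioParams, generate_scenario


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """The default synthetic scenario (fixed seed), generated once."""
    outdir = tmp_path_factory.mktemp("scenario")
    return generate_scenario(ScenarioParams(), outdir)


@pytest.fixture(scope="session")
def pipeline_results(scenario, tmp_path_factory):
    """Full pipeline run on the default scenario."""
    outdir = tmp_path_factory.mktemp("results")
    config = pl.validate_config(scenario.config_path)
    return pl.run_pipeline(config, outdir)


def truth_constituent_labels(truth):
    to_label = {"shared": "SHARED", "A_specific": "A_SPECIFIC",
                "B_specific": "B_SPECIFIC"}
    return {
        c["id"]: to_label[c["label"]]
        for se in truth["ses"]
        for c in se["constituents"]
    }


def interval_jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
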