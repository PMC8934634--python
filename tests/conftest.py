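import pytest

from rtscout.pipeline import run_pipeline
from rtscout.synthetic import generate_all


@pytest.fixture(scope="session")
def bundle():
    """The default planted-genome fixture (seed 1): 5 classes x 15
    members, 3 contigs x 30 genes, 10 planted RTs, 1 decoy."""
    return generate_all(seed=1)


@pytest.fixture(scope="session")
def predictions(bundle):
    return run_pipeline(
        bundle.genes,
        bundle.rt_library,
        bundle.broad_library,
        bundle.ref_tree,
        bundle.ref_alignment,
    )


@pytest.fixture(scope="session")
def truth_rt(bundle):
    return {r.gene_id: r.class_name for r in bundle.truth if r.kind == "rt"}
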