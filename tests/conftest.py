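import pytest

from variantscreen.annotation import build_annotation, read_gene_map
from variantscreen.fixtures import FixtureSpec, generate, labrador_example


@pytest.fixture(scope="session")
def example_bundle(tmp_path_factory):
    """The fixed one-sample worked example (five catalogued loci, dog1)."""
    return labrador_example(tmp_path_factory.mktemp("example"))


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """A seeded 4-sample bundle with planted QC defects and missingness."""
    spec = FixtureSpec(
        seed=7,
        missing_rate=0.2,
        n_incomplete_rows=2,
        n_wrong_assembly_rows=1,
        n_ref_mismatch_rows=2,
    )
    bundle, truth = generate(spec, tmp_path_factory.mktemp("bundle"))
    return bundle, truth


@pytest.fixture(scope="session")
def default_annotations(default_bundle):
    bundle, _ = default_bundle
    return build_annotation(bundle.bed, gene_map=read_gene_map(bundle.gene_map))
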