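import pytest

from annotweave.fixtures import ScenarioSpec, make_annotation_pair


@pytest.fixture(scope="session")
def default_scenario():
    """A moderate scenario exercising every planted evidence class."""
    spec = ScenarioSpec(
        seed=11,
        n_ref_genes=40,
        n_exact=6,
        n_novel_isoforms=7,
        merge_groups=(2, 3, 4),
        n_novel_genes=4,
        n_opposite_strand=3,
        n_intergenic_discard=3,
    )
    return make_annotation_pair(spec)
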