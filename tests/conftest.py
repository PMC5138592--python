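import pytest

from cpgnet import (
    GeneratorParams,
    PipelineConfig,
    Protein,
    SignalingNetwork,
    generate,
    run_all,
    write_dataset,
)


def make_network(nodes, edges):
    """nodes: iterable of (id, pathways, is_ligand, is_tf)."""
    proteins = {
        nid: Protein(
            nid,
            pathways=frozenset(paths),
            is_ligand=is_ligand,
            is_tf=is_tf,
        )
        for nid, paths, is_ligand, is_tf in nodes
    }
    net = SignalingNetwork(proteins=proteins, edges=set(edges))
    net.validate()
    return net


@pytest.fixture
def chain_network():
    """L -> A -> B -> T, a single unique signaling route."""
    return make_network(
        [
            ("L", {"WNT"}, True, False),
            ("A", {"WNT"}, False, False),
            ("B", {"WNT"}, False, False),
            ("T", {"WNT"}, False, True),
        ],
        [("L", "A"), ("A", "B"), ("B", "T")],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study dataset (fixed seed, zero noise)."""
    return generate(GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def dataset_dir(default_dataset, tmp_path_factory):
    directory = tmp_path_factory.mktemp("dataset")
    write_dataset(default_dataset, directory)
    return directory


@pytest.fixture(scope="session")
def pipeline_result(default_dataset, dataset_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig.from_dataset_dir(dataset_dir, outdir=str(outdir))
    return run_all(config)


@pytest.fixture(scope="session")
def small_params():
    """A reduced dataset for fast pipeline-level tests."""
    return GeneratorParams(
        seed=7,
        n_pathways=3,
        proteins_per_pathway=36,
        n_layers=5,
        n_groups=12,
        n_tissues=6,
        raw_tissues_per_organ=3,
    )
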