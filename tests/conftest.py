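import pytest

from ehrkg import (
    GeneratorSpec,
    build_mimic_schema,
    default_mappings,
    generate,
    load,
    map_dataset,
)


@pytest.fixture(scope="session")
def schema():
    return build_mimic_schema()


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Seeded synthetic dataset (seed 42, 100 patients) plus its manifest."""
    path = tmp_path_factory.mktemp("synth100")
    manifest = generate(GeneratorSpec(seed=42, n_patients=100), path)
    return path, manifest


@pytest.fixture(scope="session")
def mapped(small_dataset, schema):
    path, _ = small_dataset
    graph, report = map_dataset(path, schema, default_mappings())
    return graph, report


@pytest.fixture(scope="session")
def handle(mapped):
    graph, _ = mapped
    return load(graph)
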