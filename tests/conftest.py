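import pytest

from filadose import datasets, screen_combinations
from filadose.multivariate import assemble_feature_table


@pytest.fixture(scope="session")
def materials():
    """Bundled reference material set (drug, two solvents, four filaments)."""
    return datasets.load_reference_materials()


@pytest.fixture(scope="session")
def screen_results(materials):
    drug = materials["NFD"]
    solvents = [materials["ethanol"], materials["ethyl_acetate"]]
    filaments = [materials[f] for f in ("PVA", "HS", "PLA", "TPU")]
    return screen_combinations(drug, solvents, filaments)


@pytest.fixture(scope="session")
def feature_table(screen_results):
    """The eight-row (solvent, filament) feature table of the reference study."""
    return assemble_feature_table(
        screen_results,
        datasets.reference_mechanics_table(),
        datasets.reference_flux_table(),
        datasets.SATURATION_SOLUBILITY,
    )
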