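import pandas as pd
import pytest

from ogxpand.formats_io import OrthoGroupTable
from ogxpand.simulate import PlantedExpansion, PlantedTerm, SimConfig, generate


def make_table(cells: dict[str, dict[str, int]], species: list[str]) -> OrthoGroupTable:
    """Build an OrthoGroupTable from og_id -> species -> count."""
    rows = {}
    for og, counts in cells.items():
        rows[og] = {
            sp: [f"{og}_{sp}_g{i}" for i in range(counts.get(sp, 0))]
            for sp in species
        }
    return OrthoGroupTable(rows=rows, species_order=list(species))


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(
        species={"A": 2, "B": 2, "C": 4, "D": 2},
        n_ogs=80,
        planted_expansions=[
            PlantedExpansion(
                fraction=0.1, expanded_in=("A",), compared_to=("B", "C"),
                factor=3.0, margin=1,
            )
        ],
        planted_enriched_terms=[PlantedTerm(study_rate=0.6, background_rate=0.1)],
        deg_rate_background=0.02,
        deg_rate_in_expanded=0.6,
        padj_na_rate=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def fixture_paths(sim_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return generate(sim_config, out)


@pytest.fixture(scope="session")
def truth_expansions(fixture_paths) -> set[str]:
    df = pd.read_csv(fixture_paths["truth_expansions"], sep="\t")
    return set(df["og_id"])
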