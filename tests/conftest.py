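import pytest

from bioprospect import Dataset, SpeciesRecord, materia_medica_fixture
from bioprospect.transactions import encode_transactions


@pytest.fixture(scope="session")
def fixture_ds() -> Dataset:
    """The marginal-exact 1,091-species fixture (built once per session)."""
    return materia_medica_fixture()


@pytest.fixture(scope="session")
def fixture_ts(fixture_ds):
    return encode_transactions(fixture_ds)


def record(name, nature="none", aa=False, **lineage) -> SpeciesRecord:
    """Terse record builder: ranks passed as keyword args (class_ -> class)."""
    lineage = {k.rstrip("_"): v for k, v in lineage.items()}
    return SpeciesRecord(latin_name=name, lineage=lineage, nature=nature, aa=aa)


@pytest.fixture
def toy_ds() -> Dataset:
    """Three species, two brown-algae families and one green alga."""
    return Dataset(
        [
            record(
                "Sargassum fusiforme",
                nature="cold",
                aa=True,
                superkingdom="Eukaryota",
                class_="Phaeophyceae",
                order="Fucales",
                family="Sargassaceae",
                genus="Sargassum",
            ),
            record(
                "Sargassum pallidum",
                nature="cold",
                aa=True,
                superkingdom="Eukaryota",
                class_="Phaeophyceae",
                order="Fucales",
                family="Sargassaceae",
                genus="Sargassum",
            ),
            record(
                "Ulva pertusa",
                nature="cold",
                aa=True,
                superkingdom="Eukaryota",
                kingdom="Viridiplantae",
                phylum="Chlorophyta",
                family="Ulvaceae",
                genus="Ulva",
            ),
        ]
    )
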