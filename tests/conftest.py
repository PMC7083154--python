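import numpy as np
import pandas as pd
import pytest

from island_discovery import Island, SpecimenRecord


@pytest.fixture
def islands4():
    """Four islands, one with a harbor, spread over ~2 degrees."""
    return [
        Island("SA", "Santo Anto", 17.05, -25.17, 779.0, 7.6, 1979.0, 120.0, 0),
        Island("SV", "Sao Vicente", 16.85, -24.97, 227.0, 6.6, 725.0, 60.0, 1),
        Island("ST", "Santiago", 15.05, -23.63, 991.0, 10.0, 1392.0, 90.0, 1),
        Island("FG", "Fogo", 14.95, -24.38, 476.0, 4.5, 2829.0, 150.0, 0),
    ]


def _record(taxon, earliest, type_year, pub, dist, island=None,
            collector="Coll_A", type_collector="Coll_A", author="Auth_A"):
    dist = frozenset(dist)
    island = island or sorted(dist)[0]
    return SpecimenRecord(
        taxon_id=taxon, family="Fam",
        earliest_year=earliest, earliest_collector=collector,
        earliest_island=island,
        type_year=type_year, type_collector=type_collector, type_island=island,
        publication_year=pub, describing_author=author,
        distribution=dist,
    )


@pytest.fixture
def records10():
    """Ten taxa, four of them single-island endemics."""
    return [
        _record("t01", 1787, 1840, 1849, {"SA", "SV"}, island="SA"),
        _record("t02", 1822, 1822, 1849, {"SV", "ST"}, island="SV",
                collector="Coll_B", author="Auth_B"),
        _record("t03", 1841, 1851, 1852, {"ST", "FG"}, island="ST",
                collector="Coll_B", type_collector="Coll_B"),
        _record("t04", 1851, 1851, 1852, {"SA", "ST", "FG"}, island="FG"),
        _record("t05", 1860, 1900, 1934, {"SV", "FG"}, island="SV",
                collector="Coll_C", author="Auth_B"),
        _record("t06", 1900, 1935, 1952, {"SA", "FG"}, island="SA"),
        _record("t07", 1790, 1790, 1950, {"SA"}),       # SIE
        _record("t08", 1838, 1838, 1840, {"ST"}),       # SIE
        _record("t09", 1866, 1980, 1982, {"SV"}),       # SIE
        _record("t10", 1934, 1934, 1936, {"FG"},        # SIE
                collector="Coll_C", author="Auth_B"),
    ]


@pytest.fixture
def records_csv(tmp_path, records10):
    from island_discovery import write_records

    path = tmp_path / "records.csv"
    write_records(records10, path)
    return path


@pytest.fixture
def islands_csv(tmp_path, islands4):
    from island_discovery import write_islands

    path = tmp_path / "islands.csv"
    write_islands(islands4, path)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
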