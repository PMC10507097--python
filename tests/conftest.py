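import numpy as np
import pandas as pd
import pytest

import phenoclim as pc


@pytest.fixture(scope="session")
def weather_years():
    """Three seeded synthetic template seasons (shared across tests)."""
    return pc.generate_weather(pc.WeatherGenConfig(n_years=3), seed=11)


@pytest.fixture(scope="session")
def phenotypes():
    table, truth = pc.generate_phenotypes(seed=11)
    return table, truth


@pytest.fixture(scope="session")
def genotype_mean_blues(phenotypes):
    table, _ = phenotypes
    return (
        table.groupby(["environment", "genotype", "das"])["plant_height"]
        .mean()
        .rename("value")
        .reset_index()
    )


@pytest.fixture(scope="session")
def population_fit(genotype_mean_blues):
    return pc.fit_logistic_population(genotype_mean_blues)


def make_weather_csv(path, rows):
    """Write a minimal weather CSV from (timestamp, temp, rh[, rad]) tuples."""
    lines = ["timestamp,temperature,relative_humidity,global_radiation"]
    for row in rows:
        ts, t, rh = row[:3]
        rad = row[3] if len(row) > 3 else ""
        lines.append(f"{ts},{t},{rh},{rad}")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def tiny_csv(tmp_path):
    return make_weather_csv(
        tmp_path / "tiny.csv",
        [
            ("2016-05-02T00:00:00", 10.0, 80.0, 0.0),
            ("2016-05-02T01:00:00", 11.0, 78.0, 0.0),
            ("2016-05-02T02:00:00", 12.0, 76.0, 0.0),
        ],
    )
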