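import dataclasses

import numpy as np
import pytest

from shrubring import RingWidthSeries, generate_stand, default_scenario


def make_series(
    widths,
    first_year=2000,
    series_id="WE101a",
    site="WE",
    stock="WE1",
    shoot="01",
    radius="a",
):
    return RingWidthSeries(
        series_id=series_id,
        site=site,
        stock=stock,
        shoot=shoot,
        radius_label=radius,
        first_year=first_year,
        widths=np.asarray(widths, dtype=float),
    )


@pytest.fixture(scope="session")
def scenario_stand():
    """One full default-scenario stand (3 stocks, 4 radii)."""
    return generate_stand(default_scenario(seed=1))


@pytest.fixture(scope="session")
def small_stand():
    """One stock, 6 shoots, 4 radii — cheap input for pipeline tests."""
    params = dataclasses.replace(
        default_scenario(seed=7), n_stocks=1, shoots_per_stock=6
    )
    return generate_stand(params)
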