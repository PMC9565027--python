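import numpy as np
import pytest

from lcmort import MortalitySurface


@pytest.fixture
def small_surface():
    """Fully observed 3-age x 2-year surface with simple counts."""
    return MortalitySurface(
        ages=np.array([0, 1, 2]),
        years=np.array([2000, 2001]),
        deaths=np.array([[10.0, 9.0], [5.0, 4.0], [8.0, 7.0]]),
        exposures=np.array([[1000.0, 1000.0], [2000.0, 2000.0], [1500.0, 1500.0]]),
        observed_mask=np.ones((3, 2), dtype=bool),
    )


def write_csv_pair(tmp_path, deaths_rows, exposures_rows, years=(2000, 2001)):
    """Write small wide-layout CSV pairs for parsing tests.

    Rows are (age, *values); None becomes an empty field.
    """
    def render(rows, path):
        header = "age," + ",".join(str(y) for y in years)
        lines = [header]
        for row in rows:
            lines.append(",".join("" if v is None else str(v) for v in row))
        path.write_text("\n".join(lines) + "\n")

    dp, ep = tmp_path / "deaths.csv", tmp_path / "exposures.csv"
    render(deaths_rows, dp)
    render(exposures_rows, ep)
    return dp, ep
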