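"""Bundled reference series.

``china_kappa_1997_2019`` returns published Lee-Carter period-index
estimates for Chinese male and female mortality, 1997-2019, as printed in
a national mortality analysis.  The underlying yearbook death and
population data are not publicly deposited, but the fitted index series
is, which makes it the natural verification input for the forecasting
stage: refitting the published ARIMA(1, 2, 1) specification to these 23
values should reproduce the published 2020-2039 extrapolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["china_kappa_1997_2019"]

_YEARS = np.arange(1997, 2020)

_MALE = np.array([
    39.71694, 39.37878, 26.90062, 33.22122, 28.28746, 23.76912, 21.81028,
    16.12240, -18.00578, 4.64959, 0.74380, 13.01404, -7.32940, -22.27087,
    -5.84174, -7.58277, -9.67512, -11.03544, -52.66777, -34.43803,
    -28.12194, -30.28050, -20.36489,
])

_FEMALE = np.array([
    49.62551, 44.25081, 44.27759, 41.42727, 23.72562, 25.18467, 33.53104,
    23.64792, -28.60565, 5.93254, 1.80809, 2.12542, -9.68799, -5.76496,
    -10.94736, -20.49683, -18.16568, -17.79088, -41.73031, -42.25345,
    -39.70408, -33.61352, -26.77579,
])


def china_kappa_1997_2019(sex: str | None = None):
    """Published period-index series, 1997-2019.

    With ``sex`` ("male" or "female") returns a pandas Series indexed by
    year; without, a DataFrame with both columns.
    """
    df = pd.DataFrame({"male": _MALE, "female": _FEMALE},
                      index=pd.Index(_YEARS, name="year"))
    if sex is None:
        return df
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    return df[sex]
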