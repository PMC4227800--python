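import numpy as np
import pytest

from gqthermo import (
    ConditionLabel,
    CurveDesign,
    ThermoParams,
    fit_two_state,
    simulate_curve,
)

# Published POPC-titration rows for the 1cG_3 G-quadruplex:
# (conc mM, dH, TdS25, dG25 in kcal/mol, Tm in degC)
TABLE2_ROWS = [
    (0.0, -40.0, -36.9, -3.1, 50.0),
    (0.5, -30.7, -28.4, -2.3, 48.5),
    (1.0, -23.3, -21.9, -1.4, 43.9),
    (2.0, -22.1, -20.9, -1.2, 40.5),
]


def ols_oracle(x, y):
    """Closed-form normal-equations OLS, independent of scipy."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


@pytest.fixture(scope="session")
def noiseless_design():
    return CurveDesign(
        dH_true=-40.0,
        Tm_true=323.2,
        condition=ConditionLabel(sequence="1cG3", lipid_mixture="POPC"),
    )


@pytest.fixture(scope="session")
def noiseless_curve(noiseless_design):
    return simulate_curve(noiseless_design)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_curve):
    return fit_two_state(noiseless_curve)


@pytest.fixture
def table2_params():
    """ThermoParams hydrated from the published titration table."""
    return [
        ThermoParams(
            label=f"POPC {conc:g} mM", dH=dh, TdS_ref=tds, dG_ref=dg,
            Tm=tm_c + 273.15,
        )
        for conc, dh, tds, dg, tm_c in TABLE2_ROWS
    ]
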