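import warnings

import pytest

import lcxlc as L


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    """Evaluation routes warn on non-eluting analytes; tests assert on results."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def column_d1():
    """Amide HILIC first-dimension column, 150 x 1.0 mm, 1.7 µm."""
    return L.Column(length=150, internal_diameter=1.0, dp=1.7, porosity=0.5,
                    max_pressure=1000)


@pytest.fixture(scope="session")
def column_d2():
    """C18 second-dimension column, 50 x 3.0 mm, 1.8 µm."""
    return L.Column(length=50, internal_diameter=3.0, dp=1.8, porosity=0.6,
                    max_pressure=1300)


@pytest.fixture(scope="session")
def analytes3():
    return L.generate_synthetic_analytes(L.SyntheticSpec(n_analytes=3, seed=11))


@pytest.fixture(scope="session")
def focused_ranges(column_d1, column_d2):
    """Small candidate grid in the well-focused injection regime.

    High make-up dilution keeps the sample solvent weak for every
    fraction, so the theoretical injection equation and the simulator
    rank configurations consistently.
    """
    return L.ParameterRanges(
        column_d1=column_d1,
        column_d2=column_d2,
        flows_d1=[17.0],
        flows_d2=[2000.0],
        sampling_times=[0.5, 0.75, 1.0],
        makeup_flows=[153.0],
        loop_volumes=[120.0, 180.0, 260.0],
        gradients_d1=[L.GradientSpec(0.01, 0.25, 55.0)],
    )


@pytest.fixture(scope="session")
def mismatch_ranges(column_d1, column_d2):
    """Grid spanning solvent-mismatch / volume-overload conditions.

    Low make-up flows leave the transferred fractions in a strong
    (ACN-rich) sample solvent, where the simulator predicts breakthrough
    and the two evaluation routes disagree.
    """
    return L.ParameterRanges(
        column_d1=column_d1,
        column_d2=column_d2,
        flows_d1=[17.0],
        flows_d2=[2000.0],
        sampling_times=[0.65, 0.75, 1.1],
        makeup_flows=[68.0, 153.0],
        loop_volumes=[80.0, 160.0, 230.0],
        gradients_d1=[L.GradientSpec(0.01, 0.25, 55.0)],
    )
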