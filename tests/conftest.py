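import pytest

from fuzzydose import build_diagnosis_system, build_dosing_system


@pytest.fixture(scope="session")
def diag_system():
    return build_diagnosis_system()


@pytest.fixture(scope="session")
def dose_system():
    return build_dosing_system()


def truncated_trapezoid_centroid(term, lo, hi):
    """Closed-form centroid of a trapezoid clipped to the universe [lo, hi].

    Open shoulders become flat plateaus reaching the universe bound.  Serves
    as an independent oracle for the grid-based centroid defuzzifier.
    """
    a, b = (lo, lo) if term.open_left else (term.a, term.b)
    c, d = (hi, hi) if term.open_right else (term.c, term.d)
    num = (d * d + c * d + c * c) - (a * a + a * b + b * b)
    den = 3.0 * ((c + d) - (a + b))
    return num / den
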