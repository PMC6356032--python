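import pytest

from owbscreen import Substance, load_registry

#: Effective application rates behind the published reference tables (kg/ha).
RATE_TRACTOR = 1.156
RATE_HANDHELD = 0.768

#: Published mixing/loading rows: (technique, formulation) ->
#: (dermal mg/kg bw/day, inhalation mg/m^3, total RCR), at the rates above.
PRINTED_ML_ROWS = {
    ("boom", "liquid"): (0.793, 0.0014, 0.264),
    ("boom", "WP"): (1.982, 0.1618, 0.675),
    ("boom", "WG"): (0.661, 0.0185, 0.222),
    ("airblast", "liquid"): (0.317, 0.0006, 0.106),
    ("airblast", "WP"): (0.793, 0.0647, 0.270),
    ("airblast", "WG"): (0.264, 0.0074, 0.089),
    ("handheld", "liquid"): (2.249, 0.0038, 0.750),
    # the published table prints 0.188 for this row (rounded from internal
    # unrounded exposures); recomputing from the printed exposures gives
    # 0.549/3 + 0.0614/11 = 0.1886 -> 0.189, which is what we assert
    ("handheld", "WP"): (0.549, 0.0614, 0.189),
    ("handheld", "WG"): (0.230, 0.0015, 0.077),
}

#: Published application rows: technique/environment -> (dermal, inhalation, RCR).
PRINTED_APP_ROWS = {
    ("boom", "outdoor"): (0.674, 0.0023, 0.225),
    ("airblast", "outdoor"): (1.519, 0.0166, 0.508),
    ("handheld", "outdoor"): (0.443, 0.0230, 0.150),
    ("handheld", "indoor"): (0.443, 0.0230, 0.150),
}

#: Published indirect-exposure rows at the tractor rate.
PRINTED_REENTRY = (0.8778, 0.293)
PRINTED_BYSTANDER = (0.1512, 0.0102, 0.105)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def ref_substance():
    """The hypothetical solid co-formulant of the reference maximization run."""
    return Substance(
        name="reference co-formulant",
        physical_state="solid",
        vapour_pressure=0.001,
        dnel_worker_dermal=3.0,
        dnel_worker_inhalation=11.0,
        dnel_general_dermal=1.5,
        dnel_general_inhalation=2.6,
    )


@pytest.fixture(scope="session")
def volatile_substance():
    return Substance(
        name="volatile solvent",
        physical_state="liquid",
        vapour_pressure=1.0,
        dnel_worker_dermal=3.0,
        dnel_worker_inhalation=11.0,
        dnel_general_dermal=1.5,
        dnel_general_inhalation=2.6,
    )
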