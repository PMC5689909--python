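import numpy as np
import pytest

import rmwcal as rc

# The three clinically representative scout beams studied throughout:
# (predicted detector WEPL, modulation width) -> range = WEPL + 1 cm.
BEAM_CONFIGS = {
    "10/9.9": dict(wepl=9.0, modulation=9.9, energy=168.0),
    "15/14": dict(wepl=14.0, modulation=14.0, energy=177.0),
    "21/18": dict(wepl=20.0, modulation=18.0, energy=210.0),
}


@pytest.fixture(scope="session")
def beams() -> dict[str, rc.ScoutBeam]:
    """The three scout beams, designed and BCM-refined once per session."""
    out = {}
    for key, cfg in BEAM_CONFIGS.items():
        beam = rc.design_scout_beam(
            cfg["wepl"], cfg["modulation"], nominal_energy_mev=cfg["energy"]
        )
        out[key] = rc.refine_bcm(beam)
    return out


@pytest.fixture(scope="session")
def beam10(beams) -> rc.ScoutBeam:
    return beams["10/9.9"]


@pytest.fixture(scope="session")
def water() -> rc.SlabPhantom:
    return rc.water_phantom(40.0)


@pytest.fixture(scope="session")
def calibrations(beams, water):
    """(scan, window, curve) per beam from the noiseless plateau scan."""
    return {k: rc.calibrate_beam(b, water) for k, b in beams.items()}


@pytest.fixture(scope="session")
def cal10(calibrations):
    return calibrations["10/9.9"]
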