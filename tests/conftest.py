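import pytest
from hypothesis import settings

from dem1066 import default_coefficients, generate_pilot_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from dem1066.synthetic_data import default_pilot_config

# Published per-site 2x2 agreement counts between the short-form and
# standard algorithms: (both_neg, short_only_pos, standard_only_pos,
# both_pos) with the published kappa (2 dp) and short-form prevalence
# (1 dp, on the same denominator).  Only rows whose four cells sum to
# the published total are included; the rural India row is internally
# inconsistent and one urban Mexico percentage is a typo, so those are
# not verification fixtures.
SITE_AGREEMENT_ROWS = {
    "Cuba": ((2539, 54, 21, 247), 0.85, 10.5),
    "Dominican Republic": ((1700, 76, 33, 183), 0.74, 13.0),
    "Peru, urban": ((1228, 18, 12, 74), 0.82, 6.9),
    "Peru, rural": ((500, 12, 10, 24), 0.66, 6.6),
    "Venezuela": ((1783, 35, 14, 110), 0.80, 7.5),
    "Mexico, urban": ((881, 34, 14, 67), 0.71, 10.1),
    "Mexico, rural": ((880, 30, 11, 66), 0.74, 9.7),
    "Puerto Rico": ((1735, 25, 10, 130), 0.87, 8.2),
    "China, urban": ((1068, 9, 4, 45), 0.87, 4.8),
    "China, rural": ((934, 2, 7, 31), 0.87, 3.4),
    "India, urban": ((908, 13, 32, 39), 0.61, 5.2),
}

# Published OR column next to the beta column, per predictor level.
PUBLISHED_ORS = {
    ("eurod", "1-2"): 1.8,
    ("eurod", "3-5"): 0.7,
    ("eurod", ">5"): 0.3,
    ("recall", "5-6"): 4.5,
    ("recall", "4"): 5.6,
    ("recall", "1-3"): 11.6,
    ("recall", "0"): 25.5,
    ("cogscore", "30.67-31.83"): 1.0,
    ("cogscore", "28.62-30.66"): 3.2,
    ("cogscore", "23.70-28.61"): 9.1,
    ("cogscore", "0-23.69"): 44.3,
    ("relscore", "0.5-1.5"): 4.5,
    ("relscore", "2-5"): 9.5,
    ("relscore", "5.5-12"): 76.9,
    ("relscore", ">12"): 441.0,
}


@pytest.fixture(scope="session")
def coeffs():
    return default_coefficients()


@pytest.fixture(scope="session")
def pilot_cohort():
    """Default known-group cohort at the historical group sizes."""
    return generate_pilot_cohort(default_pilot_config(seed=20160525))
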