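"""Built-in reference values for the Pavlodar northern industrial zone survey.

MPCs are the maximum permissible concentrations for gross metal forms from the
hygienic standards used in Kazakhstan (APC literature values where no MPC is
established).  Background concentrations come from environmentally unaffected
soil near Pavlodar; for the six elements never detected in background soil
(Pb, Ni, Mo, V, Hg, Co) the MPC is substituted, which makes CF and HQ coincide
for them.

``SURVEY_STATS`` carries the published per-element summary statistics of the
39-site survey (mg/kg): min, max, mean, median, sample sd, CV%, and the share
of sites above MPC.  These printed summaries are enough to reproduce the
area-mean indicator table; the per-site table is not redistributed here.
"""

from __future__ import annotations

import pandas as pd

from .sample_io import ElementReference

ELEMENTS = ["Fe", "Mn", "Cr", "Sr", "Zn", "Cu", "Pb", "Ni", "Mo", "V", "Hg", "Co"]

# element -> (mpc, background or None, hazard_class)
_REFERENCE = {
    "Fe": (40000.0, 20680.0, 3),
    "Mn": (1500.0, 600.0, 3),
    "Cr": (200.0, 440.0, 2),
    "Sr": (600.0, 90.0, 3),
    "Zn": (55.0, 60.0, 1),
    "Cu": (33.0, 80.0, 2),
    "Pb": (32.0, None, 1),
    "Ni": (20.0, None, 2),
    "Mo": (50.0, None, 2),
    "V": (150.0, None, 3),
    "Hg": (2.1, None, 1),
    "Co": (50.0, None, 2),
}

# element -> (min, max, mean, median, sd, cv_percent, pct_over_mpc)
SURVEY_STATS = pd.DataFrame.from_dict(
    {
        "Fe": (11380.0, 34360.0, 20406.92, 19860.0, 4810.28, 24, 0),
        "Mn": (240.0, 1900.0, 553.85, 460.0, 366.24, 66, 8),
        "Cr": (0.0, 820.0, 203.85, 150.0, 206.88, 101, 79),
        "Sr": (110.0, 250.0, 173.33, 170.0, 23.24, 13, 0),
        "Zn": (30.0, 910.0, 121.28, 70.0, 159.10, 131, 79),
        "Cu": (0.0, 630.0, 64.87, 0.0, 110.06, 170, 46),
        "Pb": (0.0, 200.0, 46.92, 50.0, 42.56, 91, 67),
        "Ni": (0.0, 150.0, 34.10, 0.0, 47.65, 140, 36),
        "Mo": (0.0, 440.0, 11.28, 0.0, 69.55, 617, 3),
        "V": (0.0, 90.0, 7.69, 0.0, 23.26, 302, 0),
        "Hg": (0.0, 100.0, 2.56, 0.0, 15.81, 618, 3),
        "Co": (0.0, 80.0, 2.05, 0.0, 12.64, 617, 3),
    },
    orient="index",
    columns=["min", "max", "mean", "median", "sd", "cv_percent", "pct_over_mpc"],
)

N_SURVEY_SITES = 39
SURVEY_AREA_KM2 = 202.29


def pavlodar_registry() -> dict[str, ElementReference]:
    """Reference registry for the 12 surveyed elements, in survey order."""
    registry = {}
    for el in ELEMENTS:
        mpc, background, hazard_class = _REFERENCE[el]
        registry[el] = ElementReference(
            element=el,
            mpc=mpc,
            background=mpc if background is None else background,
            background_is_mpc=background is None,
            detection_limit=0.0,
            hazard_class=hazard_class,
        )
    return registry
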