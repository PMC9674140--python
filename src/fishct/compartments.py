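"""Shared label conventions for tissue compartments and skeletal elements."""

import enum


class Compartment(enum.IntEnum):
    """Voxel tissue classes.

    ``ADIPOSE`` is "presumptive adipose": everything inside the body below the
    lower threshold, which includes internal air (swim bladder) by the
    intensity-based definition.
    """

    BACKGROUND = 0
    ADIPOSE = 1
    LEAN = 2
    BONE = 3


class Element(enum.IntEnum):
    """Skeletal elements of one vertebra."""

    NONE = 0
    CENTRUM = 1
    NEURAL_ARCH = 2
    HAEMAL_ARCH = 3


#: measure-name order of the ten primary phenome measures plus the two
#: auxiliary neural-arch measures (myomere correlates)
PHENOME_MEASURES = (
    "Cent.Vol", "Cent.Th", "Cent.TMD",
    "Neur.Vol", "Neur.Th", "Neur.TMD",
    "Haem.Vol", "Haem.Th", "Haem.TMD",
    "Cent.Le",
)
AUX_MEASURES = ("Neur.Le", "Neur.Angle")

MEASURE_UNITS = {
    "Cent.Vol": "mm^3", "Neur.Vol": "mm^3", "Haem.Vol": "mm^3",
    "Cent.Th": "mm", "Neur.Th": "mm", "Haem.Th": "mm",
    "Cent.TMD": "mg HA/cm^3", "Neur.TMD": "mg HA/cm^3", "Haem.TMD": "mg HA/cm^3",
    "Cent.Le": "mm", "Neur.Le": "mm", "Neur.Angle": "deg",
}
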