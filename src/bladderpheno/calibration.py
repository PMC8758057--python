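"""Default per-phenotype item statistics used to calibrate synthetic cohorts.

The three symptomatic phenotypes are:

* **BPS** — bladder-specific pain tied to the filling/voiding cycle,
* **NUPP** — non-urologic pelvic pain centred on the urethra and vagina,
* **MFP** — myofascial pelvic pain with pressure, incomplete-emptying and
  defecatory symptoms.

Each ordinal item carries the published per-group (mean, SD) summary; the
eight binary fGUPI pain location/activity items carry endorsement
proportions.  The CONTROL column is a package-constructed asymptomatic
profile (near-floor ordinal means, 4% binary endorsement): the source
study recruited controls by requiring asymptomatic questionnaire responses
but did not publish their item-level statistics.

Default group sizes are 56 BPS, 31 NUPP, 58 MFP cases and 69 controls.
"""

from __future__ import annotations

from .instruments import battery

__all__ = [
    "PHENOTYPES",
    "GROUP_SIZES",
    "AGE_PARAMS",
    "ORDINAL_PARAMS",
    "BINARY_PARAMS",
    "THERAPIES",
    "RESPONDER_COUNTS",
    "default_group_specs",
]

PHENOTYPES = ("BPS", "NUPP", "MFP")
GROUP_SIZES = {"BPS": 56, "NUPP": 31, "MFP": 58, "CONTROL": 69}

# age in years: (mean, sd)
AGE_PARAMS = {
    "MFP": (31.34, 7.0),   # published SD of 19.7 is inconsistent with a
    # premenopausal (<=45 y) cohort and with the other groups; a 7 y SD in
    # line with BPS/NUPP/controls is used instead.
    "BPS": (31.53, 7.18),
    "NUPP": (37.8, 6.3),
    "CONTROL": (34.1, 6.4),
}

# ordinal items: item_id -> {group: (mean, sd)}
ORDINAL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "icsi_1": {"MFP": (2.98, 1.41), "BPS": (3.16, 1.48), "NUPP": (1.04, 1.14)},
    "icsi_2": {"MFP": (4.19, 1.04), "BPS": (4.29, 0.96), "NUPP": (2.16, 1.37)},
    "icsi_3": {"MFP": (2.95, 1.36), "BPS": (1.97, 1.15), "NUPP": (1.10, 1.11)},
    "icsi_4": {"MFP": (2.13, 1.67), "BPS": (2.61, 1.48), "NUPP": (1.16, 1.23)},
    "icpi_1": {"MFP": (3.12, 1.02), "BPS": (3.33, 0.62), "NUPP": (1.46, 1.14)},
    "icpi_2": {"MFP": (3.10, 1.08), "BPS": (2.53, 1.19), "NUPP": (0.92, 1.14)},
    "icpi_3": {"MFP": (2.84, 0.90), "BPS": (2.40, 1.20), "NUPP": (0.88, 1.11)},
    "icpi_4": {"MFP": (3.10, 1.30), "BPS": (3.05, 1.38), "NUPP": (1.75, 1.46)},
    "oabq_2": {"MFP": (4.77, 1.38), "BPS": (4.76, 1.11), "NUPP": (2.33, 1.22)},
    "oabq_3": {"MFP": (4.19, 1.70), "BPS": (3.74, 1.62), "NUPP": (1.92, 1.17)},
    "oabq_4": {"MFP": (3.97, 1.87), "BPS": (2.05, 1.42), "NUPP": (1.89, 1.26)},
    "oabq_5": {"MFP": (4.45, 1.69), "BPS": (3.67, 1.66), "NUPP": (2.02, 1.05)},
    "oabq_6": {"MFP": (4.55, 1.46), "BPS": (3.93, 1.53), "NUPP": (2.20, 1.17)},
    "oabq_8": {"MFP": (3.87, 1.89), "BPS": (2.59, 1.85), "NUPP": (1.41, 0.97)},
    "fgupi_3": {"MFP": (3.90, 1.10), "BPS": (3.67, 1.13), "NUPP": (2.98, 1.15)},
    "fgupi_4": {"MFP": (6.39, 1.76), "BPS": (6.13, 1.52), "NUPP": (2.98, 1.61)},
    "fgupi_5": {"MFP": (3.37, 1.37), "BPS": (2.65, 1.67), "NUPP": (1.67, 1.64)},
    "fgupi_6": {"MFP": (3.60, 1.16), "BPS": (4.05, 1.02), "NUPP": (2.01, 1.42)},
    "fgupi_7": {"MFP": (2.29, 0.64), "BPS": (1.89, 1.04), "NUPP": (1.27, 1.14)},
    "fgupi_8": {"MFP": (2.65, 0.75), "BPS": (2.66, 0.61), "NUPP": (2.18, 0.92)},
    "fgupi_9": {"MFP": (5.32, 0.83), "BPS": (5.01, 0.97), "NUPP": (4.33, 1.62)},
    "pfdi_01": {"MFP": (2.81, 1.78), "BPS": (1.91, 1.67), "NUPP": (1.64, 1.52)},
    "pfdi_02": {"MFP": (2.83, 1.60), "BPS": (1.76, 1.60), "NUPP": (1.32, 1.44)},
    "pfdi_03": {"MFP": (0.76, 1.40), "BPS": (0.34, 0.87), "NUPP": (0.54, 1.16)},
    "pfdi_04": {"MFP": (1.58, 1.13), "BPS": (0.40, 0.92), "NUPP": (0.57, 0.99)},
    "pfdi_05": {"MFP": (3.39, 1.22), "BPS": (1.62, 1.57), "NUPP": (1.07, 1.25)},
    "pfdi_06": {"MFP": (0.87, 0.75), "BPS": (0.12, 0.59), "NUPP": (0.02, 0.13)},
    "pfdi_07": {"MFP": (2.26, 1.18), "BPS": (0.76, 1.13), "NUPP": (1.07, 1.21)},
    "pfdi_08": {"MFP": (2.32, 1.56), "BPS": (0.74, 1.09), "NUPP": (1.18, 1.31)},
    "pfdi_09": {"MFP": (1.03, 1.35), "BPS": (0.02, 0.13), "NUPP": (0.02, 0.13)},
    "pfdi_10": {"MFP": (1.56, 1.62), "BPS": (0.23, 0.66), "NUPP": (0.16, 0.56)},
    "pfdi_11": {"MFP": (2.03, 1.43), "BPS": (0.21, 0.69), "NUPP": (0.39, 0.98)},
    "pfdi_12": {"MFP": (1.29, 1.51), "BPS": (0.14, 0.43), "NUPP": (0.43, 0.81)},
    "pfdi_13": {"MFP": (2.75, 1.03), "BPS": (0.70, 1.08), "NUPP": (0.59, 1.01)},
    "pfdi_14": {"MFP": (1.37, 1.52), "BPS": (0.05, 0.30), "NUPP": (0.07, 1.03)},
    "pfdi_15": {"MFP": (3.05, 1.39), "BPS": (2.83, 1.22), "NUPP": (1.32, 1.33)},
    "pfdi_16": {"MFP": (2.60, 1.63), "BPS": (1.24, 1.48), "NUPP": (0.41, 0.85)},
    "pfdi_17": {"MFP": (1.98, 1.47), "BPS": (1.05, 1.33), "NUPP": (1.00, 1.21)},
    "pfdi_18": {"MFP": (2.46, 1.47), "BPS": (0.86, 1.22), "NUPP": (0.55, 1.06)},
    "pfdi_19": {"MFP": (2.02, 1.65), "BPS": (1.28, 1.46), "NUPP": (0.73, 1.17)},
    "pfdi_20": {"MFP": (3.05, 1.04), "BPS": (2.18, 1.59), "NUPP": (1.66, 1.61)},
}

# binary items: item_id -> {group: endorsement proportion}
BINARY_PARAMS: dict[str, dict[str, float]] = {
    "fgupi_1a": {"MFP": 0.48, "BPS": 0.38, "NUPP": 0.58},
    "fgupi_1b": {"MFP": 0.48, "BPS": 0.43, "NUPP": 0.61},
    "fgupi_1c": {"MFP": 0.43, "BPS": 0.47, "NUPP": 0.55},
    "fgupi_1d": {"MFP": 0.74, "BPS": 0.76, "NUPP": 0.59},
    "fgupi_2a": {"MFP": 0.41, "BPS": 0.53, "NUPP": 0.71},
    "fgupi_2b": {"MFP": 0.54, "BPS": 0.63, "NUPP": 0.64},
    "fgupi_2c": {"MFP": 0.58, "BPS": 0.79, "NUPP": 0.25},
    "fgupi_2d": {"MFP": 0.71, "BPS": 0.63, "NUPP": 0.22},
}

# asymptomatic control profile (constructed, not published): ordinal items
# sit near the scale floor with mild spread; binaries rarely endorsed.
_CONTROL_ORDINAL_MEAN_OFFSET = 0.4   # above scale_min
_CONTROL_ORDINAL_SD = 0.7
_CONTROL_BINARY_P = 0.04

THERAPIES = ("analgesic", "instillation", "pfpt", "amitriptyline")

# responders / attempted per (phenotype, therapy), from the published
# responder contingency table.
RESPONDER_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "BPS": {"analgesic": (9, 12), "instillation": (18, 20), "pfpt": (3, 4), "amitriptyline": (5, 8)},
    "MFP": {"analgesic": (1, 6), "instillation": (2, 4), "pfpt": (23, 27), "amitriptyline": (1, 2)},
    "NUPP": {"analgesic": (4, 13), "instillation": (1, 10), "pfpt": (5, 21), "amitriptyline": (5, 15)},
}


def default_group_specs():
    """Build the four default :class:`~bladderpheno.simulate.GroupSpec` objects."""
    from .simulate import GroupSpec  # local import to avoid a cycle

    specs = []
    batt = battery()
    for name in ("BPS", "NUPP", "MFP", "CONTROL"):
        ordinal = {}
        binary = {}
        for item, d in batt.items():
            if d.kind == "binary":
                if name == "CONTROL":
                    binary[item] = _CONTROL_BINARY_P
                else:
                    binary[item] = BINARY_PARAMS[item][name]
            else:
                if name == "CONTROL":
                    ordinal[item] = (d.scale_min + _CONTROL_ORDINAL_MEAN_OFFSET, _CONTROL_ORDINAL_SD)
                else:
                    ordinal[item] = ORDINAL_PARAMS[item][name]
        mean, sd = AGE_PARAMS[name]
        specs.append(GroupSpec(
            name=name, n=GROUP_SIZES[name],
            ordinal_params=ordinal, binary_params=binary,
            age_mean=mean, age_sd=sd,
        ))
    return specs
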