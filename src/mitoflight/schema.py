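"""Column names for the CSV interchange formats.

All stages read and write plain CSV with these documented headers; JSON is
used for configs, simulation-parameter sidecars, manifests and model reports.
"""

TRAJECTORY_COLUMNS = ["frame", "x_m", "y_m", "z_m"]

TRACE_COLUMNS = ["time_s", "o2_um"]
EVENT_COLUMNS = ["time_s", "event"]
EVENT_KINDS = ("pyruvate", "oligomycin", "cccp_step", "antimycin")

#: One row per bird. Respiration rates are antimycin-corrected and expressed
#: per microlitre of blood (pmol O2 s^-1 ul^-1); ratios are dimensionless.
COHORT_COLUMNS = [
    "bird_id",
    "body_mass_g",
    "blood_cell_count_per_ul",
    "endurance_s",
    "takeoff_energy_j",
    "routine_c",
    "leak_c",
    "oxphos_c",
    "ets_c",
    "coupling_efficiency",
    "reserve_capacity",
]

#: Mitochondrial predictors entered one at a time in the linkage models.
MITO_PREDICTORS = [
    "routine_c",
    "leak_c",
    "oxphos_c",
    "ets_c",
    "coupling_efficiency",
    "reserve_capacity",
]

#: Covariates present in every linkage model.
COVARIATES = ["body_mass_g", "blood_cell_count_per_ul"]

RESPONSES = ["endurance_s", "takeoff_energy_j"]
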