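"""Physical constants and package-wide defaults."""

#: Standard gravity, m s^-2 (used everywhere a weight or potential energy appears).
G = 9.80665

#: Default video frame rate, frames s^-1.
DEFAULT_FPS = 60.0

#: Default take-off averaging window, frames.
DEFAULT_WINDOW_LENGTH = 10

#: Default onset-detection speed threshold, m s^-1.
DEFAULT_SPEED_THRESHOLD = 0.5

#: Respirometry steady-state policy: settle time after a titration event (s)
#: and length of the least-squares window at the end of each segment (s).
DEFAULT_SETTLE_S = 30.0
DEFAULT_FLUX_WINDOW_S = 60.0

#: Chamber reading of the assay: 50 ul whole blood diluted into 0.95 ml medium,
#: the suspension added to a chamber holding 1 ml medium -> 2 ml, 50 ul blood.
DEFAULT_CHAMBER_VOLUME_ML = 2.0
DEFAULT_BLOOD_VOLUME_UL = 50.0

#: Exponential time constant of the flux transition after a titration event (s).
TRANSITION_TAU_S = 15.0

#: Statistics defaults.
DEFAULT_COLLINEARITY_THRESHOLD = 0.7
DEFAULT_ALPHA = 0.05
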