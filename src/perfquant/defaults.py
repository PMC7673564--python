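"""Single home for every tunable default.

Operations never hard-code numeric defaults; they pull them from here (or
from a parameter object whose field defaults point here), so a run's
provenance log can always name the values actually used.
"""

ROI_NAMES = ("D1", "D2", "D3")
STATE_LABELS = ("T0", "T1", "T2", "T3")

# ---------------------------------------------------------------- simulator
# Reference bolus: the proximal (reference) ROI at unit flow scale.
BOLUS_BASELINE = 10.0          # a.u., pre-arrival intensity
BOLUS_AMPLITUDE = 100.0        # a.u., peak height above baseline at unit flow
BOLUS_TIME_TO_PEAK = 6.0       # s, onset->peak at unit flow
BOLUS_SHAPE = 3.0              # gamma-variate sharpness alpha
RECIRCULATION_FRACTION = 0.15  # second-passage bump relative amplitude
RECIRCULATION_DELAY = 30.0     # s

SYSTEMIC_LAG = 4.0             # s, injection -> arrival at the reference ROI

FRAME_RATE = 25.0              # Hz
DURATION = 120.0               # s recorded
INJECTION_TIME = 10.0          # s into the recording
BIT_DEPTH = 8                  # frame-grabber quantization
NOISE_SD = 2.0                 # a.u. = 2% of the reference amplitude

# Per-state flow scaling (baseline, hypo-, normo-, hypertension).
STATE_FLOW_SCALES = {"T0": 0.85, "T1": 0.6, "T2": 1.0, "T3": 1.25}

# Proximal-to-distal arcade gradient: flow ratio to the reference ROI,
# extra transit delay, and per-injection residual-dye baseline increment.
ROI_SPECS = {
    "D1": {"relative_flow": 0.5, "arrival_delay": 4.0, "pooling_offset": 3.0},
    "D2": {"relative_flow": 0.75, "arrival_delay": 1.5, "pooling_offset": 3.0},
    "D3": {"relative_flow": 1.0, "arrival_delay": 0.0, "pooling_offset": 3.0},
}

REFERENCE_FLOW = 1.0           # ml/min/g at relative_flow=1, state scale 1

# ------------------------------------------------------------------ metrics
BASELINE_WINDOW = 5.0          # s before injection
SMOOTH_HALF_WIDTH = 4          # frames, centered moving average
ONSET_K = 3.0                  # threshold multiplier on baseline sd
ONSET_M = 5                    # consecutive frames above threshold
SD_FLOOR = 0.5                 # a.u., floor for the threshold sd
ONSET_REFINE_MARGIN = 1.0      # sd multiples for the walk-back refinement
SLOPE_WINDOW = 25              # frames (1.0 s at 25 fps); 2 = finite differences
ANALYSIS_WINDOW = 60.0         # s after injection
SATURATION_FLAG_FRACTION = 0.01

# --------------------------------------------------------------- microspheres
WITHDRAWAL_RATE = 3.18         # mL/min reference withdrawal
SAMPLE_WEIGHT = 3.5            # g mean tissue-sample weight
SAMPLE_WEIGHT_SD = 0.2         # g
REFERENCE_COUNT_SCALE = 20000.0  # expected reference-sample signal
MIN_SIGNAL = 400.0             # QC floor (conventional sphere-count minimum)

# -------------------------------------------------------------------- stats
N_PERMUTATIONS = 5000
N_BOOTSTRAP = 2000

# ----------------------------------------------------------------- pipeline
N_ANIMALS = 4
ANIMAL_FLOW_SD = 0.15          # lognormal sd of the per-animal flow multiplier
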