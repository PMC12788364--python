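"""Default calibration targets for the synthetic cohort.

Group means and SDs of the biomechanical metrics for a 10-subject trained
amateur cohort running 3 elevations x 3 speeds x 2 surfaces, used as the
default recovery surface for the synthetic pipeline.  Speed-level marginals
carry the dominant structure; elevation enters as small additive offsets
(centred so speed marginals are preserved); surface has no mean effect and
only inflates within-bout variability on trail.
"""

from __future__ import annotations

ELEVATIONS_M = (50, 1000, 2300)
SPEED_LEVELS = ("v1", "v2", "v3")
SURFACES = ("ROAD", "TRAIL")

# speed-level marginal mean +/- SD per metric
CAD_SPEED_MEANS = {"v1": 160.0, "v2": 166.0, "v3": 172.0}  # spm
CAD_SPEED_SDS = {"v1": 7.0, "v2": 9.0, "v3": 9.0}

PTA_SPEED_MEANS = {"v1": 7.8, "v2": 10.6, "v3": 12.5}  # g
PTA_SPEED_SDS = {"v1": 1.6, "v2": 1.8, "v3": 1.6}

ALA_SPEED_MEANS = {"v1": 0.093, "v2": 0.082, "v3": 0.069}  # fraction
ALA_SPEED_SDS = {"v1": 0.046, "v2": 0.027, "v3": 0.023}

RSH_SPEED_MEANS = {"v1": 0.501, "v2": 0.412, "v3": 0.362}  # fraction
RSH_SPEED_SDS = {"v1": 0.080, "v2": 0.074, "v3": 0.076}

# per-elevation marginal means used to derive additive elevation offsets
CAD_ELEVATION_MEANS = {50: 166.8, 1000: 165.8, 2300: 164.6}  # spm
PTA_ELEVATION_MEANS = {50: 10.7, 1000: 10.2, 2300: 10.1}  # g
ALA_ELEVATION_MEANS = {50: 0.080, 1000: 0.075, 2300: 0.089}  # fraction
# no per-elevation structure reported for residual shock
RSH_ELEVATION_MEANS = {50: 0.425, 1000: 0.425, 2300: 0.425}  # fraction

# cohort threshold-speed distribution (km/h)
VVT1_MEAN_KMH, VVT1_SD_KMH = 10.4, 0.7
VVT2_MEAN_KMH, VVT2_SD_KMH = 15.0, 1.6

# mean prescribed sea-level speeds per zone (km/h), cohort average
PRESCRIBED_SPEED_MEANS_KMH = {"v1": 9.4, "v2": 12.7, "v3": 14.9}


def centred_offsets(marginals: dict) -> dict:
    """Additive offsets per level, centred to zero mean so that the other
    factor's marginals are preserved under the additive cell model."""
    grand = sum(marginals.values()) / len(marginals)
    return {k: v - grand for k, v in marginals.items()}
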