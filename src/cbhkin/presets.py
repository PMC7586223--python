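"""Published kinetic parameters of CfCel6B constructs, usable as simulation truth.

The four constructs are the full-length enzyme (Intact), the catalytic
domain alone (CD), the linker–binding-domain fragment (FN3s-CBD) and the
cellulose-binding domain alone (CBD). ``kon_total`` is the single-bundle
binding rate constant (M⁻¹ μm⁻¹ s⁻¹); the dissociation mixture is given as
fast/slow rate constants (s⁻¹) with area fractions.
"""

from __future__ import annotations

from .models import GroundTruth, ImagingConditions

# Measured kinetic table: kon_total, koff components and their area fractions.
TABLE1: dict[str, dict[str, float]] = {
    "Intact": dict(kon_total=4.3e8, koff_fast=0.85, koff_slow=0.086,
                   frac_fast=0.33, frac_slow=0.67),
    "CD": dict(kon_total=1.7e7, koff_fast=1.7, koff_slow=0.13,
               frac_fast=0.81, frac_slow=0.19),
    "FN3s-CBD": dict(kon_total=2.0e8, koff_fast=2.7, koff_slow=0.29,
                     frac_fast=0.26, frac_slow=0.74),
    "CBD": dict(kon_total=1.5e8, koff_fast=3.1, koff_slow=0.47,
                frac_fast=0.30, frac_slow=0.70),
}

# Motility/bulk parameters measured for the full-length enzyme:
# slow (processive) k_tr peak 11.6 nm/s, fast (diffusive) peak 25.3 nm/s,
# tail-restricted moving-time constant 4.6 s, kcat 2.4 1/s, Km 0.51 mg/ml.
INTACT_MOTILITY = dict(v_proc=11.6, v_diff=25.3, tau_move=4.6, kcat=2.4, Km=0.51)

# Previously reported values for the fungal homologue TrCel6A, used for
# side-by-side processivity arithmetic.
TRCEL6A = dict(v_proc=8.8, tau_move=7.7, kon_slow=2.3e8, koff_slow=0.10)

CELLOBIOSE_NM = 1.0  # length of the cellobiose product released per step

BLEACH_RATE_BINDING = 0.053   # 1/s at the binding-movie laser power
BLEACH_TAU_MOTILITY = 14.9    # s at the higher motility-movie laser power
LOC_PRECISION_X = 4.5         # nm
LOC_PRECISION_Y = 4.6         # nm


def intact_truth(**overrides) -> GroundTruth:
    """Ground truth for the full-length enzyme (Table values + motility)."""
    params = TABLE1["Intact"] | INTACT_MOTILITY | overrides
    return GroundTruth(**params)


def construct_truth(name: str, **overrides) -> GroundTruth:
    """Ground truth for any construct; motility defaults from Intact."""
    params = TABLE1[name] | INTACT_MOTILITY | overrides
    return GroundTruth(**params)


def binding_movie(**overrides) -> ImagingConditions:
    """Acquisition preset for binding/dissociation movies (5 fps)."""
    params = dict(
        frame_rate=5.0, duration=400.0, bleach_rate=BLEACH_RATE_BINDING,
        loc_precision_x=LOC_PRECISION_X, loc_precision_y=LOC_PRECISION_Y,
        enzyme_conc=50e-12, labeling_ratio=1.0,
    )
    params.update(overrides)
    return ImagingConditions(**params)


def motility_movie(**overrides) -> ImagingConditions:
    """Acquisition preset for motility movies (1 fps, higher laser power)."""
    params = dict(
        frame_rate=1.0, duration=600.0, bleach_rate=1.0 / BLEACH_TAU_MOTILITY,
        loc_precision_x=LOC_PRECISION_X, loc_precision_y=LOC_PRECISION_Y,
        enzyme_conc=50e-12, labeling_ratio=1.0,
    )
    params.update(overrides)
    return ImagingConditions(**params)
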