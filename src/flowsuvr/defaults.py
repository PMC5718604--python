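"""Built-in baseline parameters: average healthy-control (HC) kinetics.

The three regions are the ones the study design needs: a cortical amyloid
target (precuneus) and the two candidate SUVR reference regions, cerebellar
grey matter (CB) and subcortical white matter (WM). Values are the average
HC 2TCM-4k-Vb estimates (K1 mL/min/mL, k2-k4 1/min, Vb fractional); the
percent standard errors of those estimates are kept alongside as a
plausibility reference for fit diagnostics.
"""

from __future__ import annotations

from .kinetics import KineticParams

__all__ = ["HC_BASELINE", "HC_BASELINE_PCT_SE", "TARGET_REGION", "REFERENCE_REGIONS"]

TARGET_REGION = "precuneus"
REFERENCE_REGIONS = ("CB", "WM")

HC_BASELINE: dict[str, KineticParams] = {
    "precuneus": KineticParams(K1=0.77, k2=0.17, k3=0.02, k4=0.02, Vb=0.054),
    "CB": KineticParams(K1=0.66, k2=0.17, k3=0.01, k4=0.02, Vb=0.052),
    "WM": KineticParams(K1=0.28, k2=0.14, k3=0.19, k4=0.04, Vb=0.020),
}

# percent standard error of each estimate (K1, k2, k3, k4, Vb)
HC_BASELINE_PCT_SE: dict[str, dict[str, float]] = {
    "precuneus": {"K1": 4.9, "k2": 4.2, "k3": 18.5, "k4": 14.7, "Vb": 6.4},
    "CB": {"K1": 5.8, "k2": 5.4, "k3": 14.7, "k4": 21.6, "Vb": 4.6},
    "WM": {"K1": 6.3, "k2": 8.2, "k3": 16.1, "k4": 9.8, "Vb": 9.8},
}
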