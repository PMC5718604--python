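#!/usr/bin/env python
"""Scan the flow effect across synthetic target regions spanning a range of
total distribution volumes, and correlate dSUVR with V_T.

Only the three built-in regions have shipped kinetics, so the scan uses four
synthetic grey-matter-like targets whose V_T (3, 6, 9, 12) varies through
specific binding (k3) at common delivery and clearance: the amyloid-load
axis. The expectation is an inverse relationship: high-binding regions are
less flow-sensitive.

Writes:  region_scan.csv, region_scan.json
"""

import argparse
import json
from pathlib import Path

from flowsuvr import (
    DEFAULT_FRAME_SCHEDULE,
    HC_BASELINE,
    KineticParams,
    default_aif_spec,
    generate_input_function,
    region_scan_table,
    region_vt_correlation,
)


def synthetic_binding_ladder() -> dict[str, KineticParams]:
    """Four targets, V_T in {3,6,9,12} via k3 alone (V_ND = 3 throughout)."""
    regions = {}
    k2, k4, vb, vnd = 0.17, 0.02, 0.05, 3.0
    for vt in (3.0, 6.0, 9.0, 12.0):
        bp = vt / vnd - 1.0
        regions[f"VT={vt:g}"] = KineticParams(K1=vnd * k2, k2=k2, k3=bp * k4,
                                              k4=k4, Vb=vb)
    return regions


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    inp = generate_input_function(default_aif_spec())
    scan = region_scan_table(synthetic_binding_ladder(), HC_BASELINE["CB"], inp,
                             DEFAULT_FRAME_SCHEDULE, dk1_levels=(-10.0, -30.0))
    scan.to_csv(args.out / "region_scan.csv", index=False)
    print(scan.round(2).to_string(index=False))

    for level in ("-10", "-30"):
        col = f"delta_suvr_pct_at_{level}"
        r, p = region_vt_correlation(
            dict(zip(scan["region"], scan[col])),
            dict(zip(scan["region"], scan["VT"])),
        )
        print(f"dSUVR({level}%) vs V_T: Pearson r = {r:.3f} (p = {p:.4f})")
        if level == "-30":
            out = {"pearson_r": r, "p_value": p, "dk1_pct": -30, "seed": args.seed}
    (args.out / "region_scan.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
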