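#!/usr/bin/env python
"""Regenerate the shipped calibrated catalogue from scratch.

Runs the two deterministic calibration stages (physiological baseline, then
scenario catalogue) and overwrites ``src/lvadloop/data/calibrated.yaml``.
Takes on the order of ten minutes on one CPU.

Usage:  python scripts/recalibrate.py [--out PATH] [--max-nfev N]
"""

from __future__ import annotations

import argparse
import pathlib
import time


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--out",
        type=pathlib.Path,
        default=pathlib.Path(__file__).resolve().parent.parent
        / "src" / "lvadloop" / "data" / "calibrated.yaml",
    )
    ap.add_argument("--max-nfev", type=int, default=300)
    args = ap.parse_args()

    from lvadloop.calibrate import calibrate_baseline, calibrate_catalogue

    t0 = time.time()
    stage1 = calibrate_baseline(max_nfev=80)
    print(f"stage 1 ({time.time() - t0:.0f} s):")
    print(stage1.summary().to_string(), "\n")

    t0 = time.time()
    stage2 = calibrate_catalogue(stage1.params, max_nfev=args.max_nfev)
    print(f"stage 2 ({time.time() - t0:.0f} s):")
    print(stage2.summary().to_string())

    cat = stage2.catalogue
    cat.meta["calibration"] = {
        "residual_norm": stage2.residual_norm,
        "n_evaluations": stage2.n_evaluations,
    }
    cat.to_yaml(args.out)
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
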