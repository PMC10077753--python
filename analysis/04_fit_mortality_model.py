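#!/usr/bin/env python
"""Contrast selection before parturition with selection after neonate loss.

Drops the half-normal process (no time-varying terms) and fits a
state-specific logistic selection model on pre-parturition rows plus the
post-mortality rows of females whose neonate died within 30 days,
reporting each covariate's Pre and AD (after-death) posterior summaries
and their overlap.
"""

import argparse
from pathlib import Path

from reprorsf.pipeline import RunConfig, run_fit_mortality, run_prep


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=Path("results/run"))
    ap.add_argument("--min-rows", type=int, default=200)
    args = ap.parse_args()

    cfg = RunConfig.from_yaml(args.run / "sim" / "config.yaml")
    prepared = run_prep(cfg, args.run / "sim")
    try:
        res = run_fit_mortality(cfg, prepared, args.run / "fit", force=True,
                                min_rows=args.min_rows)
    except (RuntimeError, ValueError) as exc:
        print(f"mortality model not fit: {exc}")
        return
    print("pre-parturition vs post-mortality summary:")
    print(res["summary"].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
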