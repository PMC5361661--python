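"""Per-arm figures: median trough curves of all four compounds against the
EM standard-therapy benchmark band (percentiles 5-95), holiday shaded.

Writes results/figures/<arm>.svg for the four headline arms by default
(EM/IM onset pairs), or all 20 arms with --all.

Run:  python analysis/03_figures.py [--seed 1234] [--n-per-arm 1000] [--all]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from tamoxsim.report import RunConfig, _benchmark_bands, plot_arm
from tamoxsim.trial import TrialConfig, run_virtual_trial

ROOT = Path(__file__).resolve().parents[1]
HEADLINE = ("A-EM-case", "A-EM-control", "A-IM-case", "A-IM-control",
            "B-EM-case-2wk", "B-EM-control-2wk",
            "B-IM-case-2wk", "B-IM-control-2wk")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1234)
    ap.add_argument("--n-per-arm", type=int, default=1000)
    ap.add_argument("--all", action="store_true", help="all 20 arms")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "figures")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, out_dir=args.out,
                    n_per_arm=args.n_per_arm,
                    arm_filter=() if args.all else HEADLINE)
    trial = run_virtual_trial(TrialConfig(
        parameter_set=cfg.parameter_set(), n_per_arm=cfg.n_per_arm,
        seed=cfg.seed, arm_filter=cfg.arm_filter))
    bands = _benchmark_bands(trial)
    args.out.mkdir(parents=True, exist_ok=True)
    for arm_id, result in trial.arms.items():
        p = plot_arm(result, bands, args.out / f"{arm_id}.svg")
        print(f"wrote {p}")


if __name__ == "__main__":
    main()
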