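#!/usr/bin/env python
"""Collagen fiber morphometrics on synthetic traced fibers.

Emulates the baseline-vs-stretch contrast: a 'baseline' condition with
broadly distributed fiber orientations and strong crimp/bow, and a
'stretched' condition with fibers rotated toward the reference (stretch)
axis and partially straightened. Quantifies orientation histograms,
alignment fraction, tortuosity, and crimp wavelength per condition.
Writes results/fiber_metrics.csv and results/fiber_orientation.json.
"""

import json
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from sanstretch.fibers import crimp_wavelength, fiber_direction, orientation_histogram, tortuosity
from sanstretch.synthetic import FiberGenParams, gen_fiber

OUT = Path(__file__).resolve().parent.parent / "results"

N_SAMPLES = 3   # preparations per condition
N_FIBERS = 50   # traced fibers per preparation


def build_condition(name, direction_sd_deg, crimp_amplitude, bow_amplitude, seed0):
    rng = np.random.default_rng(seed0)
    rows, dirs_by_sample = [], {}
    for s in range(N_SAMPLES):
        sid = f"{name}_{s + 1}"
        dirs = []
        for k in range(N_FIBERS):
            direction = float(np.mod(rng.normal(0.0, direction_sd_deg), 180.0))
            params = FiberGenParams(
                direction_deg=direction,
                crimp_wavelength=10.0,
                crimp_amplitude=crimp_amplitude,
                bow_amplitude=bow_amplitude,
                length=60.0,
                jitter_sd=0.1,
                seed=int(rng.integers(2**31)),
            )
            path, _ = gen_fiber(params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wl = crimp_wavelength(path)
            measured_dir = fiber_direction(path)
            dirs.append(measured_dir)
            rows.append(
                {
                    "condition": name,
                    "sample": sid,
                    "fiber": k,
                    "direction_deg": measured_dir,
                    "tortuosity": tortuosity(path),
                    "mean_wavelength_um": np.mean(wl) if wl else np.nan,
                }
            )
        dirs_by_sample[sid] = dirs
    hist = orientation_histogram(dirs_by_sample)
    return pd.DataFrame(rows), hist


def main():
    OUT.mkdir(exist_ok=True)
    base_df, base_hist = build_condition("baseline", 60.0, 1.2, 3.0, seed0=1)
    str_df, str_hist = build_condition("stretched", 12.0, 0.8, 0.5, seed0=2)
    df = pd.concat([base_df, str_df], ignore_index=True)
    df.to_csv(OUT / "fiber_metrics.csv", index=False)
    with open(OUT / "fiber_orientation.json", "w") as fh:
        json.dump(
            {
                "bin_edges_deg": base_hist.bin_edges_deg.tolist(),
                "baseline_mean_fractions": base_hist.mean_fractions.tolist(),
                "stretched_mean_fractions": str_hist.mean_fractions.tolist(),
                "baseline_alignment_fraction": base_hist.alignment_fraction,
                "stretched_alignment_fraction": str_hist.alignment_fraction,
            },
            fh, indent=2,
        )

    summary = df.groupby("condition")[["tortuosity", "mean_wavelength_um"]].mean()
    print(summary.round(3).to_string())
    ratio = str_hist.alignment_fraction / base_hist.alignment_fraction
    print(f"\nalignment fraction (+/-20 deg of stretch axis): "
          f"baseline {base_hist.alignment_fraction:.2f} -> "
          f"stretched {str_hist.alignment_fraction:.2f} ({ratio:.1f}-fold)")
    print("stretched fibers are straighter (lower tortuosity) at an unchanged "
          "crimp wavelength: straightening of the bow precedes loss of crimp")
    print(f"wrote {OUT / 'fiber_metrics.csv'}")


if __name__ == "__main__":
    sys.exit(main())
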