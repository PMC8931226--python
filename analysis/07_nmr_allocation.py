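#!/usr/bin/env python
"""Phosphonate allocation from 31P spectra.

Simulates whole-cell spectra for exponential (phosphonate/phosphate
area ratio 0.72) and stationary (2.4) phase cultures at 1% peak-height
noise, integrates the phosphonate (18-27 ppm) and phosphate (-12 to 12
ppm) regions, reports the recovered ratios and the cellular P
allocation ratio/(1+ratio), and runs the base-hydrolysis comparison
(re-noised identical composition: no region should change by > 10%).
Spectra are written to scratch/ as two-column TSV.
"""

import sys
from pathlib import Path

import numpy as np

from phoscycle import io, synthio
from phoscycle.nmr31p import hydrolysis_compare, phosphonate_ratio

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "spectra"
RESULTS = ROOT / "results"

SEED = 53
PEAK_MAX = 1.0 / (np.pi * 0.3)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    specs = {}
    for label, phn_area, seed in [
        ("exponential", 0.72, SEED),
        ("stationary", 2.4, SEED + 1),
        ("post_hydrolysis", 0.72, SEED + 2),
    ]:
        spec, _ = synthio.gen_spectrum(
            [(21.0, phn_area, 0.3), (2.0, 1.0, 0.3)],
            noise_sd=0.01 * PEAK_MAX, n_points=20_001,
            ppm_range=(-30, 40), seed=seed, label=label)
        io.write_spectrum(spec, SCRATCH / f"{label}.tsv")
        specs[label] = spec

    out = {}
    for label in ("exponential", "stationary"):
        res = phosphonate_ratio(specs[label])
        out[label] = {
            "ratio": res.ratio,
            "allocation_pct": 100 * res.allocation_fraction,
            "integrals": res.integrals,
        }
        print(f"{label:12s}: phosphonate/phosphate = {res.ratio:.2f}, "
              f"allocation = {100 * res.allocation_fraction:.1f}%")

    hyd = hydrolysis_compare(specs["exponential"], specs["post_hydrolysis"])
    out["hydrolysis"] = hyd
    print(f"hydrolysis comparison changed: {hyd['changed']} "
          f"(region deltas all within {hyd['tolerance']:.0%})")
    print(
        "\nAn exponential-phase ratio near 0.72 corresponds to ~40% of "
        "cellular P allocated to phosphonates; the stationary-phase ratio "
        "near 2.4 shows allocation rising under P starvation."
    )

    RESULTS.mkdir(exist_ok=True)
    io.write_json(out, RESULTS / "07_nmr_allocation.json")


if __name__ == "__main__":
    sys.exit(main())
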