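"""Region integration of 31P NMR spectra.

Phosphonate esters resonate at 18-27 ppm; phosphate and pyrophosphate
esters (pooled) at -12 to 12 ppm. Integrating those regions gives the
phosphonate/phosphate ratio and the cellular allocation fraction
ratio/(1+ratio). A pre/post base-hydrolysis comparison checks whether
cyclic phosphates (which can appear at 14-20 ppm) contaminate the
phosphonate region: unchanged integrals after hydrolysis mean they do
not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import Spectrum

#: Default chemical-shift regions (ppm).
PHOSPHONATE_REGION = (18.0, 27.0)
PHOSPHATE_REGION = (-12.0, 12.0)
#: Diagnostic region where cyclic phosphates could be misassigned.
CYCLIC_AMBIGUITY_REGION = (14.0, 20.0)


@dataclass
class RegionSet:
    """Named integration regions; overlap requires an explicit opt-in."""

    regions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "phosphonate": PHOSPHONATE_REGION,
            "phosphate": PHOSPHATE_REGION,
        }
    )
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.regions.items():
            if lo >= hi:
                raise ValueError(f"region {name}: lo must be < hi")
        if not self.allow_overlap:
            items = sorted(self.regions.items(), key=lambda kv: kv[1][0])
            for (na, (_, hia)), (nb, (lob, _)) in zip(items, items[1:]):
                if lob < hia:
                    raise ValueError(f"regions {na} and {nb} overlap")


@dataclass
class IntegralResult:
    integrals: dict[str, float]
    baseline: str
    ratio: float
    allocation_fraction: float
    flags: list[str] = field(default_factory=list)


def integrate_region(
    spectrum: Spectrum,
    lo: float,
    hi: float,
    baseline: str = "none",
    flank_points: int = 5,
) -> float:
    """Trapezoidal integral of intensity over [lo, hi] ppm.

    baseline='linear-endpoints' subtracts the line through the mean
    intensity of the ``flank_points`` points just outside each boundary
    (a standard manual-phasing-free region baseline).
    """
    ppm, inten = spectrum.ppm, spectrum.intensity
    if lo < ppm[0] or hi > ppm[-1]:
        raise ValueError(f"region [{lo}, {hi}] outside spectrum range")
    mask = (ppm >= lo) & (ppm <= hi)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points in region")
    x, y = ppm[mask], inten[mask]
    if baseline == "none":
        base = np.zeros_like(y)
    elif baseline == "linear-endpoints":
        i0 = int(np.flatnonzero(mask)[0])
        i1 = int(np.flatnonzero(mask)[-1])
        left = inten[max(i0 - flank_points, 0) : i0]
        right = inten[i1 + 1 : i1 + 1 + flank_points]
        y0 = float(left.mean()) if len(left) else float(y[0])
        y1 = float(right.mean()) if len(right) else float(y[-1])
        base = y0 + (y1 - y0) * (x - x[0]) / (x[-1] - x[0])
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(y - base, x))


def integrate_regions(
    spectrum: Spectrum, regions: RegionSet, baseline: str = "none"
) -> dict[str, float]:
    return {
        name: integrate_region(spectrum, lo, hi, baseline)
        for name, (lo, hi) in regions.regions.items()
    }


def phosphonate_ratio(
    spectrum: Spectrum,
    regions: RegionSet | None = None,
    baseline: str = "none",
) -> IntegralResult:
    """Phosphonate/phosphate integral ratio and P-allocation fraction.

    allocation = ratio / (1 + ratio) is the phosphonate share of the
    combined phosphonate + phosphate pool.
    """
    regions = regions or RegionSet()
    ints = integrate_regions(spectrum, regions, baseline)
    flags = []
    phn = ints.get("phosphonate", 0.0)
    pho = ints.get("phosphate", 0.0)
    if pho <= 0:
        return IntegralResult(
            integrals=ints,
            baseline=baseline,
            ratio=float("nan"),
            allocation_fraction=float("nan"),
            flags=["undefined: phosphate integral <= 0"],
        )
    ratio = max(phn, 0.0) / pho
    return IntegralResult(
        integrals=ints,
        baseline=baseline,
        ratio=ratio,
        allocation_fraction=ratio / (1.0 + ratio),
        flags=flags,
    )


def allocation_from_ratio(ratio: float) -> float:
    """Allocation fraction implied by a phosphonate/phosphate ratio."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return ratio / (1.0 + ratio)


def hydrolysis_compare(
    pre: Spectrum,
    post: Spectrum,
    regions: RegionSet | None = None,
    baseline: str = "none",
    tolerance: float = 0.10,
) -> dict:
    """Per-region change between pre- and post-hydrolysis spectra.

    Relative change |post - pre| / pre per region; ``changed`` is true
    when any region exceeds ``tolerance``. A region with zero pre
    integral is reported as an absolute change instead.
    """
    regions = regions or RegionSet()
    pre_ints = integrate_regions(pre, regions, baseline)
    post_ints = integrate_regions(post, regions, baseline)
    deltas: dict[str, dict] = {}
    changed = False
    for name in regions.regions:
        a, b = pre_ints[name], post_ints[name]
        if a != 0:
            rel = abs(b - a) / abs(a)
            deltas[name] = {"relative_change": rel, "absolute_change": b - a}
            if rel > tolerance:
                changed = True
        else:
            deltas[name] = {"relative_change": float("nan"), "absolute_change": b - a}
            if abs(b - a) > tolerance:
                changed = True
    return {"deltas": deltas, "changed": changed, "tolerance": tolerance}
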