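#!/usr/bin/env python
"""Group-wise phosphonate standing stocks and budget shares.

The SAR11 scenario uses published parameters: 9.9e26 producer cells in
the sunlit ocean, P quota 0.16e-16 mol/cell, phosphonate content 10%
of cellular P, giving 1.584e9 mol phosphonate-P. Companion scenarios
for Prochlorococcus and MGI Thaumarchaeota use published cell
densities (4.4e7 and 5e4 cells/L) with an illustrative euphotic volume
and quotas, so their shares demonstrate the arithmetic rather than
reproduce any published fraction. Shares are computed in 'sum' mode
and against the SAR11-anchored denominator.
"""

import sys
from pathlib import Path

from phoscycle import io
from phoscycle.budget import (
    GroupScenario,
    budget_shares,
    group_stock,
    group_stock_tg,
    sar11_sunlit_ocean,
    sensitivity,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

EUPHOTIC_VOLUME_L = 3.6e19  # ~100 m over the (sub)tropical ocean; illustrative


def main() -> None:
    sar11 = sar11_sunlit_ocean()
    pro = GroupScenario(
        name="Prochlorococcus",
        producer_fraction=0.06,  # metagenome-estimated trait carriage
        p_quota_mol=5e-18,       # illustrative streamlined-cell quota
        phn_fraction=0.40,       # whole-cell allocation from the 31P analysis
        density_cells_per_l=4.4e7,
        volume_l=EUPHOTIC_VOLUME_L,
    )
    mgi = GroupScenario(
        name="MGI_Thaumarchaeota",
        producer_fraction=1.0,
        p_quota_mol=1e-17,       # illustrative
        phn_fraction=0.10,
        density_cells_per_l=5e4,
        volume_l=EUPHOTIC_VOLUME_L,
    )
    groups = [sar11, pro, mgi]
    shares = budget_shares(groups, "sum")

    print(f"SAR11 phosphonate-P stock: {group_stock(sar11):.4g} mol "
          f"({group_stock_tg(sar11):.3g} Tg P)")
    print("\nshares of the summed stock:")
    for name, pct in shares["shares_pct"].items():
        print(f"  {name:20s} {pct:6.1f}%  ({shares['stocks_mol'][name]:.3g} mol)")

    grid = sensitivity(sar11, "phn_fraction", [0.05, 0.10, 0.20])
    print("\nSAR11 stock vs phosphonate content (linear):")
    for row in grid:
        print(f"  content {row['phn_fraction']:.2f} -> {row['stock_mol']:.3g} mol")

    RESULTS.mkdir(exist_ok=True)
    io.write_json(
        {"shares": shares, "sar11_sensitivity_phn_fraction": grid},
        RESULTS / "08_budget.json",
    )


if __name__ == "__main__":
    sys.exit(main())
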