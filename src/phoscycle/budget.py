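"""Group-wise phosphonate standing stocks and budget shares.

Each taxonomic group contributes

    stock [mol P] = cells x producer_fraction x P quota x phosphonate
                    share of cellular P

Cell inventories come either as a direct count or as density x volume
(a density without a volume is a hard error, never a silent per-liter
assumption). Budget shares need an explicit denominator or "sum" mode;
under "sum" the shares total exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

MOL_P_TO_TG = 30.973761998e-12  # g/mol * Tg/g


@dataclass
class GroupScenario:
    """Phosphonate-stock parameters for one taxonomic group."""

    name: str
    producer_fraction: float
    p_quota_mol: float  # mol P per cell
    phn_fraction: float  # phosphonate share of cellular P
    total_cells: float | None = None
    density_cells_per_l: float | None = None
    volume_l: float | None = None

    def __post_init__(self) -> None:
        vals = [self.producer_fraction, self.p_quota_mol, self.phn_fraction]
        if any(v < 0 for v in vals):
            raise ValueError(f"{self.name}: negative parameter")
        if not (0 <= self.producer_fraction <= 1 and 0 <= self.phn_fraction <= 1):
            raise ValueError(f"{self.name}: fractions must lie in [0, 1]")
        has_total = self.total_cells is not None
        has_density = self.density_cells_per_l is not None
        if has_total == has_density:
            raise ValueError(
                f"{self.name}: supply exactly one of total_cells or "
                "density_cells_per_l (+ volume_l)"
            )
        if has_density and self.volume_l is None:
            raise ValueError(f"{self.name}: density requires an explicit volume_l")
        if has_total and self.total_cells < 0:
            raise ValueError(f"{self.name}: negative cell count")

    @property
    def cells(self) -> float:
        if self.total_cells is not None:
            return float(self.total_cells)
        return float(self.density_cells_per_l * self.volume_l)


def group_stock(s: GroupScenario) -> float:
    """Standing phosphonate-P stock of one group, in mol P."""
    return s.cells * s.producer_fraction * s.p_quota_mol * s.phn_fraction


def group_stock_tg(s: GroupScenario) -> float:
    return group_stock(s) * MOL_P_TO_TG


def budget_shares(
    groups: list[GroupScenario], denominator: float | str = "sum"
) -> dict:
    """Per-group stocks and percentage shares of a phosphonate budget.

    ``denominator`` is either a total budget in mol P or "sum" (shares
    of the summed group stocks, totalling exactly 100%).
    """
    if not groups:
        raise ValueError("no groups")
    stocks = {g.name: group_stock(g) for g in groups}
    if denominator == "sum":
        denom = sum(stocks.values())
    else:
        denom = float(denominator)
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return {
        "stocks_mol": stocks,
        "stocks_tg": {k: v * MOL_P_TO_TG for k, v in stocks.items()},
        "denominator_mol": denom,
        "shares_pct": {k: 100.0 * v / denom for k, v in stocks.items()},
    }


def sensitivity(s: GroupScenario, parameter: str, grid: list[float]) -> list[dict]:
    """Stock across a grid of one parameter (stock is linear in each)."""
    allowed = {"producer_fraction", "p_quota_mol", "phn_fraction"}
    if parameter not in allowed:
        raise ValueError(f"unknown parameter {parameter!r}; one of {sorted(allowed)}")
    rows = []
    for v in grid:
        kwargs = dict(
            name=s.name,
            producer_fraction=s.producer_fraction,
            p_quota_mol=s.p_quota_mol,
            phn_fraction=s.phn_fraction,
            total_cells=s.total_cells,
            density_cells_per_l=s.density_cells_per_l,
            volume_l=s.volume_l,
        )
        kwargs[parameter] = v
        rows.append({parameter: v, "stock_mol": group_stock(GroupScenario(**kwargs))})
    return rows


def sar11_sunlit_ocean() -> GroupScenario:
    """Published-parameter scenario: 9.9e26 SAR11 producer cells in the
    sunlit ocean (the count is already producers), P quota 0.16e-16 mol
    P/cell, phosphonate content 10% of cellular P."""
    return GroupScenario(
        name="SAR11",
        producer_fraction=1.0,
        p_quota_mol=0.16e-16,
        phn_fraction=0.10,
        total_cells=9.9e26,
    )
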