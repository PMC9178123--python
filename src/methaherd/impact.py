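"""Population-level CO2-equivalent and monetary impact of methane response.

Translates a per-cow genetic response delta in methane production (g/d)
into annual per-cow emissions, national totals, CO2 equivalents under a
global-warming-potential factor, and carbon-cost savings — the Danish
dairy population serving as the default case.  Every line item is a single
multiplication of its predecessor, so the whole cascade is linear in the
input delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ImpactAssumptions",
    "ImpactReport",
    "annualize",
    "population_total",
    "to_co2e",
    "to_currency",
    "national_share",
    "methane_impact",
]

#: GWP factors for methane: kg CO2e per kg CH4 over 100-year / 20-year horizons.
GWP100 = 25.0
GWP20 = 84.0


@dataclass
class ImpactAssumptions:
    """Population and pricing assumptions for the impact cascade.

    ``carbon_price_per_ton`` is in DKK per ton CO2e; ``exchange_rate`` in
    DKK per euro.  ``rounded_price_eur`` switches to a rounded euro price
    per ton (200 euro for the default 1500 DKK at 7.45 DKK/euro) instead of
    the exact quotient 1500/7.45 = 201.3; both modes are reported with the
    mode labelled.
    """

    lactation_days: float = 305.0
    n_cows: float = 550_000.0
    gwp_factors: tuple[float, ...] = (GWP100, GWP20)
    carbon_price_per_ton: float = 1500.0
    exchange_rate: float = 7.45
    rounded_price_eur: float | None = 200.0
    national_total_kt: float = 86.59

    def __post_init__(self) -> None:
        for name in (
            "lactation_days",
            "n_cows",
            "carbon_price_per_ton",
            "exchange_rate",
            "national_total_kt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(g <= 0 for g in self.gwp_factors):
            raise ValueError("GWP factors must be strictly positive")

    @property
    def price_eur_per_ton(self) -> float:
        if self.rounded_price_eur is not None:
            return float(self.rounded_price_eur)
        return self.carbon_price_per_ton / self.exchange_rate


def annualize(delta_g_per_day: float, lactation_days: float = 305.0) -> float:
    """kg CH4 per cow-year from a g/d delta over the lactation."""
    return delta_g_per_day * lactation_days / 1000.0


def population_total(kg_per_cow_year: float, n_cows: float) -> float:
    """Metric tons CH4 per year over the population."""
    if n_cows < 0:
        raise ValueError("n_cows must be non-negative")
    return kg_per_cow_year * n_cows / 1000.0


def to_co2e(ton_ch4: float, gwp: float) -> float:
    """Kilotons CO2 equivalent from tons CH4 under a GWP factor."""
    if gwp <= 0:
        raise ValueError("GWP must be strictly positive")
    return ton_ch4 * gwp / 1000.0


def to_currency(
    kiloton_co2e: float, price_per_ton: float, exchange_rate: float = 1.0
) -> float:
    """Million euro saved: kt CO2e times a per-ton price.

    ``price_per_ton`` is divided by ``exchange_rate`` (pass 1 when the price
    is already in euro, e.g. the rounded 200 euro/ton mode).
    """
    if price_per_ton <= 0 or exchange_rate <= 0:
        raise ValueError("price and exchange rate must be strictly positive")
    return kiloton_co2e * 1000.0 * (price_per_ton / exchange_rate) / 1e6


def national_share(ton_ch4: float, national_total_kt: float) -> float:
    """Percent of the national dairy CH4 inventory."""
    if national_total_kt <= 0:
        raise ValueError("national total must be strictly positive")
    return 100.0 * (ton_ch4 / 1000.0) / national_total_kt


@dataclass
class ImpactReport:
    """Line items of one impact cascade; each reproducible from the previous
    by a single multiplication."""

    delta_g_per_day: float
    kg_per_cow_year: float
    population_ton_per_year: float
    national_share_percent: float
    kiloton_co2e: dict[float, float] = field(default_factory=dict)
    million_eur: dict[float, float] = field(default_factory=dict)
    price_mode: str = "rounded"
    price_eur_per_ton: float = 200.0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("delta", "g CH4/d per cow", self.delta_g_per_day),
            ("annual per cow", "kg CH4/yr", self.kg_per_cow_year),
            ("population", "t CH4/yr", self.population_ton_per_year),
            ("national share", "% of dairy CH4", self.national_share_percent),
        ]
        for g, v in self.kiloton_co2e.items():
            rows.append((f"CO2e (GWP {g:g})", "kt CO2e/yr", v))
        for g, v in self.million_eur.items():
            rows.append(
                (
                    f"saving (GWP {g:g}, {self.price_eur_per_ton:g} eur/t)",
                    "M eur/yr",
                    v,
                )
            )
        return pd.DataFrame(rows, columns=["item", "unit", "value"])


def methane_impact(
    delta_g_per_day: float, assumptions: ImpactAssumptions | None = None
) -> ImpactReport:
    """Full cascade: g/d delta -> kg/cow-yr -> t/yr -> kt CO2e -> M euro."""
    a = assumptions or ImpactAssumptions()
    kg = annualize(delta_g_per_day, a.lactation_days)
    ton = population_total(kg, a.n_cows)
    share = national_share(ton, a.national_total_kt)
    price = a.price_eur_per_ton
    co2e = {g: to_co2e(ton, g) for g in a.gwp_factors}
    eur = {g: to_currency(v, price, 1.0) for g, v in co2e.items()}
    return ImpactReport(
        delta_g_per_day=delta_g_per_day,
        kg_per_cow_year=kg,
        population_ton_per_year=ton,
        national_share_percent=share,
        kiloton_co2e=co2e,
        million_eur=eur,
        price_mode="rounded" if a.rounded_price_eur is not None else "exact",
        price_eur_per_ton=price,
    )
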