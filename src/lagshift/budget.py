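"""Per-cell one-carbon (C1) and ATP budgets, and methyl-supply coverage.

A duplicating bacterial cell consumes C1 (methyl/formyl) groups to build a
small set of C1-sink metabolites — the purine and pyrimidine triphosphates
ATP, GTP, dATP, dGTP and dTTP, plus histidine and methionine.  The packaged
default sink table quantifies these sinks from the standard biochemical
composition of an exponentially growing *E. coli* cell (amounts per gram dry
weight scaled by a 280 fg/cell dry weight), giving a total assimilatory
demand of ~190.1 amol C1 per cell duplication.

The dissimilatory (energy) demand is the growth-associated ATP maintenance
(GAM) of the *P. inhibens* metabolic model, 85 mmol ATP per gram dry weight,
i.e. 23,800 amol ATP per cell at 280 fg.  Dissimilating one methyl group via
the THF oxidation branch yields one ATP, so an external methyl supply can be
expressed as percent coverage of either demand:

    coverage_assim  = 100 * supply_per_cell / 190.1 amol
    coverage_dissim = 100 * supply_per_cell * atp_per_methyl / 23,800 amol

Unit conventions: dry weight in fg/cell, molar amounts per dry weight in
mmol/gDW, per-cell amounts in amol/cell (1 mmol/gDW x 1 fg = 1 amol exactly),
compound concentrations in mol/L and cell densities in CFU/ml (CFU are
equated with cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DataError, ParameterError

#: Printed total assimilatory demand, usable when no sink table is wanted.
FALLBACK_ASSIMILATORY_C1_AMOL = 190.1

__all__ = [
    "C1Sink",
    "CellModel",
    "C1Budget",
    "SupplyScenario",
    "CoverageResult",
    "load_default_sinks",
    "load_sink_table",
    "per_cell_amount",
    "total_c1_requirement",
    "atp_requirement",
    "default_budget",
    "methyl_supply_per_cell",
    "coverage",
    "FALLBACK_ASSIMILATORY_C1_AMOL",
]


@dataclass(frozen=True)
class C1Sink:
    """One C1-consuming building block: per-cell amount and net C1 count."""

    name: str
    amount_per_cell: float  # amol/cell
    c1_per_molecule: int  # net C1 groups incorporated per molecule

    def __post_init__(self) -> None:
        if self.amount_per_cell < 0:
            raise ParameterError(f"sink {self.name!r}: negative amount")
        if self.c1_per_molecule < 1:
            raise ParameterError(f"sink {self.name!r}: c1_per_molecule must be >= 1")


@dataclass(frozen=True)
class CellModel:
    """Cell-level constants: dry weight (fg) and GAM (mmol ATP/gDW)."""

    dry_weight: float = 280.0
    gam: float = 85.0

    def __post_init__(self) -> None:
        if not (self.dry_weight > 0 and self.gam > 0):
            raise ParameterError("dry_weight and gam must be positive")


@dataclass(frozen=True)
class C1Budget:
    """Per-cell demand: assimilatory C1 and dissimilatory ATP (amol/cell)."""

    assimilatory_c1: float
    dissimilatory_atp: float

    def __post_init__(self) -> None:
        if not (self.assimilatory_c1 > 0 and self.dissimilatory_atp > 0):
            raise ParameterError("budget components must be positive")


@dataclass(frozen=True)
class SupplyScenario:
    """An external methylated-compound supply shared by a cell population."""

    compound: str
    concentration: float  # mol/L
    methyl_groups_per_molecule: int
    cell_density: float  # CFU/ml

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ParameterError("concentration must be >= 0")
        if self.methyl_groups_per_molecule < 0:
            raise ParameterError("methyl_groups_per_molecule must be >= 0")
        if not self.cell_density > 0:
            raise ParameterError("cell_density must be positive")


@dataclass(frozen=True)
class CoverageResult:
    """Supply per cell and percent coverage of each demand (can exceed 100)."""

    supply_per_cell: float  # amol C1/cell
    assimilatory_coverage: float  # percent, full precision
    dissimilatory_coverage: float  # percent, full precision

    def formatted(self) -> str:
        """Display-rounded report: integer % assimilatory, one decimal % dissimilatory."""
        return (
            f"{self.supply_per_cell:.1f} amol C1/cell covers "
            f"{self.assimilatory_coverage:.0f}% of assimilatory C1 and "
            f"{self.dissimilatory_coverage:.1f}% of dissimilatory ATP demand"
        )


def load_sink_table(path: str | Path, dry_weight_fg: float | None = None) -> list[C1Sink]:
    """Read a C1-sink CSV.

    Accepts either ``name,amount_per_cell_amol,c1_per_molecule`` or
    ``name,amount_mmol_per_gDW,c1_per_molecule`` (the latter requires
    ``dry_weight_fg`` for the per-cell conversion).
    """
    df = pd.read_csv(path)
    if "amount_per_cell_amol" in df.columns:
        amounts = df["amount_per_cell_amol"].astype(float)
    elif "amount_mmol_per_gDW" in df.columns:
        if dry_weight_fg is None:
            raise ParameterError(
                "amount_mmol_per_gDW columns require dry_weight_fg for conversion"
            )
        cell = CellModel(dry_weight=dry_weight_fg)
        amounts = df["amount_mmol_per_gDW"].astype(float).map(
            lambda a: per_cell_amount(a, cell)
        )
    else:
        raise ParameterError(
            "sink table needs amount_per_cell_amol or amount_mmol_per_gDW column"
        )
    return [
        C1Sink(str(n), float(a), int(c))
        for n, a, c in zip(df["name"], amounts, df["c1_per_molecule"])
    ]


def load_default_sinks() -> list[C1Sink]:
    """The packaged seven-sink table (ATP, GTP, dATP, dGTP, dTTP, His, Met)."""
    with resources.as_file(
        resources.files("lagshift.data").joinpath("c1_sinks.csv")
    ) as path:
        return load_sink_table(path)


def per_cell_amount(amount_mmol_per_g: float, cell: CellModel) -> float:
    """Convert a per-dry-weight amount (mmol/gDW) to a per-cell amount (amol).

    Exact: 1 mmol/g x 1 fg = 1e-3 mol/g x 1e-15 g = 1e-18 mol = 1 amol, so
    the result is simply ``amount * dry_weight``.
    """
    if amount_mmol_per_g < 0:
        raise ParameterError("amount must be >= 0")
    return amount_mmol_per_g * cell.dry_weight


def total_c1_requirement(sinks: list[C1Sink]) -> float:
    """Total assimilatory C1 demand: sum of amount x net C1 count (amol/cell)."""
    if not sinks:
        raise ParameterError("sink list must be non-empty")
    return float(sum(s.amount_per_cell * s.c1_per_molecule for s in sinks))


def atp_requirement(cell: CellModel) -> float:
    """Dissimilatory ATP demand per duplication: GAM scaled to one cell (amol)."""
    return per_cell_amount(cell.gam, cell)


def default_budget(cell: CellModel | None = None, use_fallback_total: bool = False) -> C1Budget:
    """Budget from the packaged sink table (or the printed fallback total)."""
    cell = cell or CellModel()
    if use_fallback_total:
        assim = FALLBACK_ASSIMILATORY_C1_AMOL
    else:
        assim = total_c1_requirement(load_default_sinks())
    return C1Budget(assimilatory_c1=assim, dissimilatory_atp=atp_requirement(cell))


def methyl_supply_per_cell(scenario: SupplyScenario) -> float:
    """Methyl groups available per cell from the external pool (amol C1/cell).

    (concentration [mol/L] x methyls/molecule) / (density [cells/L]), with
    CFU/ml -> CFU/L (x1000) and mol -> amol (x1e18).
    """
    cells_per_litre = scenario.cell_density * 1000.0
    if not cells_per_litre > 0:
        raise ParameterError("cell density must be positive")
    mol_per_cell = (
        scenario.concentration * scenario.methyl_groups_per_molecule / cells_per_litre
    )
    return mol_per_cell * 1e18


def coverage(
    scenario: SupplyScenario,
    budget: C1Budget,
    atp_per_methyl: float = 1.0,
) -> CoverageResult:
    """Percent of each per-cell demand covered by the external methyl supply.

    ``atp_per_methyl`` is the dissimilation yield (default one ATP per methyl
    group oxidized through the THF pathway).
    """
    if atp_per_methyl < 0:
        raise ParameterError("atp_per_methyl must be >= 0")
    supply = methyl_supply_per_cell(scenario)
    return CoverageResult(
        supply_per_cell=supply,
        assimilatory_coverage=100.0 * supply / budget.assimilatory_c1,
        dissimilatory_coverage=100.0 * supply * atp_per_methyl / budget.dissimilatory_atp,
    )
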