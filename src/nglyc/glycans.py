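"""Permethylated N-glycan mass arithmetic, peak assignment and Hex profiles.

High-mannose N-glycans released by PNGase F are permethylated before MALDI
profiling; spectra are acquired in positive reflector mode where singly
sodiated [M+Na]+ ions dominate.  Mannose and galactofuranose are isomers
and indistinguishable by mass, so compositions are labelled ``Hex_n``
rather than ``Man_n``.

Two independent mass routes are implemented:

* the *site-count* route builds the elemental composition explicitly —
  free-glycan residue masses plus water, plus one CH2 per methylation site,
  where an n-residue glycan with h hexoses and k HexNAcs exposes
  ``5h + 5k - 2(h + k - 1)`` exchangeable positions (each glycosidic bond
  consumes two);
* the *residue-shortcut* route sums permethylated residue masses
  (Hex C9H16O5, HexNAc C11H19NO5) plus the C2H6O end correction.

They are algebraically equivalent and serve as mutual checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
from pyteomics.mass import calculate_mass as _cm

from .records import RecordError

# Monoisotopic building blocks (Da), all derived from one element table.
HEX_RESIDUE = _cm(formula="C6H10O5")          # 162.0528
HEXNAC_RESIDUE = _cm(formula="C8H13NO5")      # 203.0794
WATER = _cm(formula="H2O")                    # 18.0106
CH2 = _cm(formula="CH2")                      # 14.0157
PERMETHYL_HEX = _cm(formula="C9H16O5")        # 204.0999
PERMETHYL_HEXNAC = _cm(formula="C11H19NO5")   # 245.1263
END_CORRECTION = _cm(formula="C2H6O")         # 46.0419
ELECTRON = 0.000548579909
ADDUCTS = {
    "Na": _cm(formula="Na") - ELECTRON,       # [M+Na]+ cation
    "H": _cm(formula="H") - ELECTRON,         # [M+H]+
    "K": _cm(formula="K") - ELECTRON,         # [M+K]+
}


@dataclass(frozen=True)
class GlycanComposition:
    """A Hex/HexNAc composition; N-glycans carry the HexNAc2 chitobiose core."""

    n_hex: int
    n_hexnac: int = 2

    def __post_init__(self) -> None:
        if self.n_hex < 0 or self.n_hexnac < 0:
            raise RecordError("residue counts must be nonnegative")
        if self.n_hexnac < 2:
            warnings.warn(
                f"HexNAc{self.n_hexnac} lacks the canonical N-glycan core",
                stacklevel=2,
            )

    @property
    def label(self) -> str:
        return f"Hex_{self.n_hex}HexNAc_{self.n_hexnac}"

    @property
    def total_residues(self) -> int:
        return self.n_hex + self.n_hexnac


def methylation_sites(n_hex: int, n_hexnac: int) -> int:
    """Exchangeable (hydroxyl + acetamido NH) positions of the free glycan."""
    return 5 * n_hex + 5 * n_hexnac - 2 * (n_hex + n_hexnac - 1)


def permethylated_mz(
    composition: GlycanComposition,
    adduct: str = "Na",
    reduced: bool = False,
) -> float:
    """m/z of the permethylated glycan, site-count route (singly charged).

    ``reduced=True`` models borohydride-reduced alditols: +H2 on reduction
    and one extra O-methyl on the new hydroxyl (+CH2).
    """
    h, k = composition.n_hex, composition.n_hexnac
    mass = h * HEX_RESIDUE + k * HEXNAC_RESIDUE + WATER
    mass += methylation_sites(h, k) * CH2
    if reduced:
        mass += _cm(formula="H2") + CH2
    try:
        return mass + ADDUCTS[adduct]
    except KeyError:
        raise RecordError(f"unknown adduct {adduct!r}") from None


def permethylated_mz_shortcut(
    composition: GlycanComposition,
    adduct: str = "Na",
    reduced: bool = False,
) -> float:
    """m/z via permethylated residue masses + end correction (check route)."""
    mass = (
        composition.n_hex * PERMETHYL_HEX
        + composition.n_hexnac * PERMETHYL_HEXNAC
        + END_CORRECTION
    )
    if reduced:
        mass += _cm(formula="H2") + CH2
    return mass + ADDUCTS[adduct]


def theoretical_grid(
    hex_range: tuple[int, int] = (0, 20),
    hexnac_range: tuple[int, int] = (2, 6),
    adduct: str = "Na",
) -> list[tuple[GlycanComposition, float]]:
    grid = []
    for k in range(hexnac_range[0], hexnac_range[1] + 1):
        for h in range(hex_range[0], hex_range[1] + 1):
            comp = GlycanComposition(h, k)
            grid.append((comp, permethylated_mz(comp, adduct=adduct)))
    return grid


@dataclass(frozen=True)
class PeakAssignment:
    observed_mz: float
    intensity: float
    composition: GlycanComposition | None
    mass_error: float | None
    adduct: str = "Na"
    condition: str = ""


def assign_compositions(
    peaks: pd.DataFrame,
    tolerance_da: float = 0.2,
    hex_range: tuple[int, int] = (0, 20),
    hexnac_range: tuple[int, int] = (2, 6),
    adduct: str = "Na",
) -> list[PeakAssignment]:
    """Assign each peak its nearest theoretical composition within tolerance.

    ``peaks`` needs columns ``mz`` and ``intensity`` (optionally
    ``condition``).  Ties in |mass error| are broken toward the smaller
    total residue count.  Unmatched peaks come back with composition None.
    Assignment is per-peak, hence independent of input order and idempotent.
    """
    if tolerance_da <= 0:
        raise RecordError("tolerance must be positive")
    grid = theoretical_grid(hex_range, hexnac_range, adduct)
    # sort by residue count so that on exact |error| ties the smaller wins
    grid.sort(key=lambda ct: ct[0].total_residues)
    theo_mz = np.array([mz for _, mz in grid])
    out: list[PeakAssignment] = []
    has_cond = "condition" in peaks.columns
    for row in peaks.itertuples(index=False):
        errors = np.abs(theo_mz - row.mz)
        best = int(np.argmin(errors))
        # argmin returns the first (smallest residue count) among ties
        if errors[best] <= tolerance_da:
            comp, mz = grid[best]
            out.append(
                PeakAssignment(
                    observed_mz=float(row.mz),
                    intensity=float(row.intensity),
                    composition=comp,
                    mass_error=float(row.mz - mz),
                    adduct=adduct,
                    condition=str(row.condition) if has_cond else "",
                )
            )
        else:
            out.append(
                PeakAssignment(
                    observed_mz=float(row.mz),
                    intensity=float(row.intensity),
                    composition=None,
                    mass_error=None,
                    adduct=adduct,
                    condition=str(row.condition) if has_cond else "",
                )
            )
    return out


def assignments_frame(assignments: Iterable[PeakAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            {
                "mz": a.observed_mz,
                "intensity": a.intensity,
                "label": a.composition.label if a.composition else "",
                "n_hex": a.composition.n_hex if a.composition else pd.NA,
                "n_hexnac": a.composition.n_hexnac if a.composition else pd.NA,
                "mass_error": a.mass_error,
                "condition": a.condition,
            }
        )
    return pd.DataFrame(rows)


def hexose_distribution(
    assignments: Sequence[PeakAssignment],
) -> pd.DataFrame:
    """Intensity-weighted Hex-count proportions per condition.

    Proportions sum to 1 within each condition; the modal Hex count (the
    most abundant glycan size) is flagged per condition.
    """
    rows = [
        {"condition": a.condition, "n_hex": a.composition.n_hex, "intensity": a.intensity}
        for a in assignments
        if a.composition is not None
    ]
    if not rows:
        raise RecordError("no assigned peaks to profile")
    df = pd.DataFrame(rows)
    totals = df.groupby("condition")["intensity"].transform("sum")
    df["weight"] = df["intensity"] / totals
    prof = (
        df.groupby(["condition", "n_hex"], as_index=False)["weight"]
        .sum()
        .rename(columns={"weight": "proportion"})
    )
    modal = prof.loc[prof.groupby("condition")["proportion"].idxmax()]
    modal_map = dict(zip(modal["condition"], modal["n_hex"]))
    prof["modal_hex"] = prof["condition"].map(modal_map)
    return prof
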