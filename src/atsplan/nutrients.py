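"""Stoichiometric nutrient accounting.

Converts an elemental composition of algal biomass into mass fractions,
classifies each grid cell's limiting nutrient by comparing the cell's P:N
mass ratio against the biomass (Redfield) P:N mass ratio, and sizes the
annual biomass harvest needed to recycle the cell's excess nutrients.

Cells are represented as rows of a :class:`pandas.DataFrame` with columns
``lon``, ``lat``, ``excess_n_kg``, ``excess_p_kg``.  N excess is
nonnegative where present; P excess may be negative (a deficit).  ``NaN``
means "no data", which is distinct from an explicit zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ATOMIC_MASS",
    "ElementalComposition",
    "REDFIELD_COMPOSITION",
    "MassRatios",
    "mass_fraction",
    "redfield_pn_ratio",
    "classify_limitation",
    "required_biomass",
    "cell_requirements",
]

#: Standard atomic masses (u) for the elements of organic matter.
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "P": 30.974}

KG_PER_TONNE = 1000.0

N_LIMITED = "N_limited"
P_LIMITED = "P_limited"
UNLIMITED = "none"


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a reference organic-matter molecule (C/H/O/N/P)."""

    c: int = 0
    h: int = 0
    o: int = 0
    n: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        counts = (self.c, self.h, self.o, self.n, self.p)
        if any((not np.isfinite(x)) or x < 0 for x in counts):
            raise ValueError("atom counts must be finite and nonnegative")
        if all(x == 0 for x in counts):
            raise ValueError("composition must contain at least one atom")

    @property
    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "O": self.o, "N": self.n, "P": self.p}

    @property
    def molar_mass(self) -> float:
        """Molecular mass in unified atomic mass units."""
        return sum(ATOMIC_MASS[el] * k for el, k in self.counts.items())

    def mass_fraction(self, element: str) -> float:
        """Mass fraction of ``element`` in the molecule (dimensionless)."""
        if element not in ATOMIC_MASS:
            raise KeyError(f"unknown element {element!r}; expected one of C/H/O/N/P")
        return ATOMIC_MASS[element] * self.counts[element] / self.molar_mass


#: Classical Redfield-type organic matter, C106:H263:O110:N16:P1.  Its C, N
#: and P mass fractions are ~36%, 6.3% and 0.87% of ash-free dry weight.
REDFIELD_COMPOSITION = ElementalComposition(c=106, h=263, o=110, n=16, p=1)


def mass_fraction(composition: ElementalComposition, element: str) -> float:
    """Mass fraction of one element in a reference composition."""
    return composition.mass_fraction(element)


@dataclass(frozen=True)
class MassRatios:
    """Biomass mass fractions of C, N and P (of ash-free dry weight)."""

    r_c: float
    r_n: float
    r_p: float

    def __post_init__(self) -> None:
        for name, r in (("r_c", self.r_c), ("r_n", self.r_n), ("r_p", self.r_p)):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [0, 1]")
        if self.r_c + self.r_n + self.r_p > 1.0 + 1e-12:
            raise ValueError("mass fractions sum to more than 1")

    @classmethod
    def from_composition(cls, composition: ElementalComposition = REDFIELD_COMPOSITION) -> "MassRatios":
        return cls(
            r_c=composition.mass_fraction("C"),
            r_n=composition.mass_fraction("N"),
            r_p=composition.mass_fraction("P"),
        )

    @property
    def r_pn(self) -> float:
        """Biomass P:N mass ratio, R_PN = R_P / R_N."""
        return redfield_pn_ratio(self)


def redfield_pn_ratio(ratios: MassRatios) -> float:
    """P:N mass ratio of the biomass, R_P / R_N."""
    if ratios.r_n == 0:
        raise ValueError("R_N is zero; P:N ratio undefined")
    return ratios.r_p / ratios.r_n


def classify_limitation(excess_n_kg, excess_p_kg, r_pn: float):
    """Label each cell ``N_limited``, ``P_limited`` or ``none``.

    A cell's P:N mass ratio GC_PN = excess_P / excess_N is compared with the
    biomass ratio R_PN: cells with R_PN < GC_PN are P-limited, cells with
    R_PN >= GC_PN are N-limited.  Cells whose usable (positive, present)
    excesses are both absent get ``none``.  A cell with zero N but positive
    P excess has unbounded GC_PN and is P-limited (the N->0+ limit of the
    rule).

    Accepts scalars or array-likes; returns a scalar ``str`` or an
    ``object`` ndarray of labels.
    """
    n = np.asarray(excess_n_kg, dtype=float)
    p = np.asarray(excess_p_kg, dtype=float)
    scalar = n.ndim == 0 and p.ndim == 0
    n, p = np.atleast_1d(n), np.atleast_1d(p)
    n, p = np.broadcast_arrays(n, p)
    if np.any(n[np.isfinite(n)] < 0):
        raise ValueError("excess N must be nonnegative where present")

    usable_n = np.where(np.isfinite(n), np.maximum(n, 0.0), 0.0)
    usable_p = np.where(np.isfinite(p), np.maximum(p, 0.0), 0.0)

    labels = np.full(n.shape, UNLIMITED, dtype=object)
    active = (usable_n > 0) | (usable_p > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_pn = np.where(usable_n > 0, usable_p / np.where(usable_n > 0, usable_n, 1.0), np.inf)
    labels[active & (gc_pn > r_pn)] = P_LIMITED
    labels[active & (gc_pn <= r_pn)] = N_LIMITED
    if scalar:
        return labels.item()
    return labels


def required_biomass(excess_n_kg, excess_p_kg, ratios: MassRatios, policy: str = "complete"):
    """Annual biomass (t) needed to take up a cell's excess nutrients.

    Policies
    --------
    ``complete`` (default)
        B = max(excess_N/R_N, excess_P/R_P) over the positive, present
        excesses.  A harvest of this size incorporates at least the whole
        excess of *both* nutrients.
    ``nonlimiting``
        Size by the non-limiting nutrient only: recycle P in N-limited
        cells and N in P-limited cells (the smaller of the two quotients).
    ``N`` / ``P``
        Size by a single nutrient regardless of limitation.

    Negative or missing excesses contribute nothing: deficits are not
    transferable between cells.  Returns ``(biomass_t, sizing_nutrient)``
    as scalars or arrays; ``sizing_nutrient`` is "N", "P" or "" where no
    usable excess exists.
    """
    if ratios.r_n <= 0 or ratios.r_p <= 0:
        raise ValueError("mass ratios must be positive to size biomass")
    if policy not in ("complete", "nonlimiting", "N", "P"):
        raise ValueError(f"unknown sizing policy {policy!r}")

    n = np.asarray(excess_n_kg, dtype=float)
    p = np.asarray(excess_p_kg, dtype=float)
    scalar = n.ndim == 0 and p.ndim == 0
    n, p = np.broadcast_arrays(np.atleast_1d(n), np.atleast_1d(p))

    usable_n = np.where(np.isfinite(n), np.maximum(n, 0.0), 0.0)
    usable_p = np.where(np.isfinite(p), np.maximum(p, 0.0), 0.0)
    by_n = usable_n / ratios.r_n
    by_p = usable_p / ratios.r_p

    if policy == "complete":
        biomass_kg = np.maximum(by_n, by_p)
        sizing = np.where(by_n >= by_p, "N", "P")
    elif policy == "nonlimiting":
        labels = classify_limitation(n, p, ratios.r_pn)
        biomass_kg = np.where(labels == N_LIMITED, by_p, by_n)
        sizing = np.where(labels == N_LIMITED, "P", "N")
    elif policy == "N":
        biomass_kg, sizing = by_n, np.full(n.shape, "N")
    else:
        biomass_kg, sizing = by_p, np.full(n.shape, "P")

    sizing = np.where(biomass_kg > 0, sizing, "").astype(object)
    biomass_t = biomass_kg / KG_PER_TONNE
    if scalar:
        return biomass_t.item(), sizing.item()
    return biomass_t, sizing


def cell_requirements(
    cells: pd.DataFrame,
    ratios: MassRatios | None = None,
    policy: str = "complete",
) -> pd.DataFrame:
    """Per-cell limitation labels and required biomass.

    Parameters
    ----------
    cells
        Frame with columns ``lon``, ``lat``, ``excess_n_kg``, ``excess_p_kg``.
    ratios
        Biomass mass fractions; defaults to the Redfield-type composition.
    policy
        Sizing policy, see :func:`required_biomass`.

    Returns a copy with added columns ``limitation``, ``sizing_nutrient``
    and ``biomass_t``.
    """
    if ratios is None:
        ratios = MassRatios.from_composition()
    out = cells.copy()
    n = out["excess_n_kg"].to_numpy(dtype=float)
    p = out["excess_p_kg"].to_numpy(dtype=float)
    out["limitation"] = classify_limitation(n, p, ratios.r_pn)
    biomass_t, sizing = required_biomass(n, p, ratios, policy=policy)
    out["sizing_nutrient"] = sizing
    out["biomass_t"] = biomass_t
    return out
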