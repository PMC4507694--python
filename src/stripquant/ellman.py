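"""Reference spectrophotometric (Ellman) activity calculation.

Thiocholine released by butyrylcholinesterase from butyrylthiocholine
reduces DTNB to the yellow 5-thio-2-nitrobenzoate anion, read at
412 nm.  With two absorbance readings dt seconds apart, Beer-Lambert
gives the product formation rate, and the enzyme activity per mL of
sample is

    activity = (dA / dt) / (epsilon * l) * (V_total / 1000) / V_sample
             [kat / mL of sample]

where dA/dt is in absorbance units per second, epsilon = 14150
L mol^-1 cm^-1 (5-thio-2-nitrobenzoate at pH 7.4), l the optical path
in cm, V_total the cuvette volume in mL (converted to litres) and
V_sample the sample volume in mL.  One katal is one mole of substrate
converted per second; 1:1 stoichiometry between thiocholine released
and chromophore formed is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "AssayGeometry",
    "EllmanMeasurement",
    "DilutionSeries",
    "activity_from_absorbance",
    "dilution_series",
    "final_concentration",
    "method_comparison",
]


@dataclass(frozen=True)
class AssayGeometry:
    """Cuvette geometry and constants of the reference assay.

    Defaults reproduce the standard protocol: 400 uL DTNB + 100 uL
    sample + 400 uL buffer + 100 uL substrate = 1.0 mL total, 1 cm
    path, readings 120 s apart.
    """

    epsilon: float = 14150.0       # L mol^-1 cm^-1
    path_length_cm: float = 1.0
    v_total_ml: float = 1.0
    v_sample_ml: float = 0.1
    dt_s: float = 120.0

    def __post_init__(self):
        for name in ("epsilon", "path_length_cm", "v_total_ml", "v_sample_ml", "dt_s"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")


@dataclass(frozen=True)
class EllmanMeasurement:
    """Paired A412 readings of one sample under a given geometry."""

    a412_start: float
    a412_end: float
    geometry: AssayGeometry = field(default_factory=AssayGeometry)
    label: str = ""

    def __post_init__(self):
        if self.a412_end < self.a412_start:
            raise InputError(
                f"absorbance decreased ({self.a412_start} -> {self.a412_end}); "
                "negative rate is not a valid activity"
            )

    @property
    def activity(self) -> float:
        return activity_from_absorbance(self)


def activity_from_absorbance(m: EllmanMeasurement) -> float:
    """Enzyme activity in kat per mL of sample from a paired reading."""
    g = m.geometry
    rate_mol_per_l_s = (m.a412_end - m.a412_start) / g.dt_s / (
        g.epsilon * g.path_length_cm
    )
    mol_per_s = rate_mol_per_l_s * (g.v_total_ml / 1000.0)  # cuvette volume in L
    return mol_per_s / g.v_sample_ml


@dataclass(frozen=True)
class DilutionSeries:
    """Serial dilution of a stock activity: activities[k] = stock / factor^k."""

    stock_activity: float
    factor: float
    n_steps: int
    activities: tuple = field(init=False)

    def __post_init__(self):
        if self.stock_activity <= 0:
            raise InputError("stock activity must be > 0")
        if self.factor <= 1:
            raise InputError(f"dilution factor must be > 1, got {self.factor}")
        if self.n_steps < 0:
            raise InputError("n_steps must be >= 0")
        acts = tuple(
            self.stock_activity / self.factor**k for k in range(self.n_steps + 1)
        )
        object.__setattr__(self, "activities", acts)


def dilution_series(stock: float, factor: float = 2.0, n_steps: int = 5) -> DilutionSeries:
    """Serial dilution (default two-fold), steps 0..n_steps inclusive."""
    return DilutionSeries(stock_activity=stock, factor=factor, n_steps=n_steps)


def final_concentration(stock_conc: float, v_added: float, v_total: float) -> float:
    """Concentration after injecting ``v_added`` of stock into ``v_total``
    (same units of volume; e.g. 100 uL of 50 mmol/L into 1000 uL -> 5 mmol/L)."""
    if v_added <= 0 or v_total <= 0:
        raise InputError("volumes must be > 0")
    if v_added > v_total:
        raise InputError(
            f"added volume {v_added} exceeds the total volume {v_total}"
        )
    return stock_conc * v_added / v_total


def method_comparison(reference, candidate) -> tuple[float, float, float]:
    """OLS line of candidate activities on reference activities.

    Returns (slope, intercept, r_squared); used to validate the strip
    assay against the spectrophotometric reference, where agreement
    shows as slope near 1 and R-squared near 1.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(candidate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("reference and candidate must be equal-length 1-D")
    if len(x) < 3:
        raise InputError("need >= 3 paired measurements")
    if np.ptp(x) == 0:
        raise InputError("reference values have zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
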