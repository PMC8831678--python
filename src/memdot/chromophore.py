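"""Two-wavelength hemoglobin unmixing (modified Beer-Lambert spectroscopy).

Absorption changes at each cortical vertex relate linearly to oxy- and
deoxy-hemoglobin concentration changes through the molar extinction
coefficients:  d_mu_a(lambda) = ln(10) * [eps_HbO(lambda) dHbO +
eps_HbR(lambda) dHbR].  With two wavelengths the 2x2 system inverts
exactly; more wavelengths are solved in least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExtinctionTable", "unmix", "hb_to_absorption"]

LN10 = float(np.log(10.0))

# molar extinction coefficients, cm^-1 M^-1 (standard compilation values)
_DEFAULT = {
    685.0: (277.0, 2230.0),     # (eps_HbO, eps_HbR)
    830.0: (974.0, 693.0),
}


@dataclass
class ExtinctionTable:
    """eps_HbO / eps_HbR (cm^-1 M^-1) per wavelength (nm)."""

    wavelengths: tuple = (685.0, 830.0)
    eps_hbo: tuple = field(default=None)
    eps_hbr: tuple = field(default=None)

    def __post_init__(self):
        if self.eps_hbo is None:
            self.eps_hbo = tuple(_DEFAULT[w][0] for w in self.wavelengths)
        if self.eps_hbr is None:
            self.eps_hbr = tuple(_DEFAULT[w][1] for w in self.wavelengths)
        if len(self.eps_hbo) != len(self.wavelengths) or len(self.eps_hbr) != len(self.wavelengths):
            raise ValueError("extinction coefficients must match wavelengths")

    def design(self) -> np.ndarray:
        """(n_wavelengths, 2) matrix mapping (dHbO, dHbR) to d_mu_a / ln(10)."""
        return np.column_stack([self.eps_hbo, self.eps_hbr]).astype(float)

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            wavelengths=tuple(df["wavelength_nm"].astype(float)),
            eps_hbo=tuple(df["eps_hbo"].astype(float)),
            eps_hbr=tuple(df["eps_hbr"].astype(float)),
        )


def hb_to_absorption(hbo, hbr, table: ExtinctionTable) -> dict:
    """Forward relation: concentration changes -> absorption change per wavelength."""
    out = {}
    for wl, eo, er in zip(table.wavelengths, table.eps_hbo, table.eps_hbr):
        out[wl] = LN10 * (eo * np.asarray(hbo) + er * np.asarray(hbr))
    return out


def unmix(delta_mu_a: dict, table: ExtinctionTable):
    """Recover (dHbO, dHbR) per vertex/time from per-wavelength absorption.

    ``delta_mu_a`` maps wavelength -> array (any matching shape).  Solves
    the (weighted) least-squares Beer-Lambert system; exact for two
    wavelengths.  Warns when the spectral system is ill-conditioned.
    """
    wls = [w for w in table.wavelengths if w in delta_mu_a]
    if len(wls) < 2:
        raise ValueError("need at least two wavelengths to unmix HbO/HbR")
    E = LN10 * np.column_stack(
        [
            [table.eps_hbo[list(table.wavelengths).index(w)] for w in wls],
            [table.eps_hbr[list(table.wavelengths).index(w)] for w in wls],
        ]
    )
    cond = np.linalg.cond(E)
    if not np.isfinite(cond):
        raise ValueError("singular wavelength pair: cannot unmix chromophores")
    if cond > 100:
        warnings.warn(f"ill-conditioned extinction system (cond={cond:.1f})")
    shapes = [np.asarray(delta_mu_a[w]) for w in wls]
    stacked = np.stack([s.reshape(-1) for s in shapes], axis=0)   # (n_wl, N)
    sol, *_ = np.linalg.lstsq(E, stacked, rcond=None)
    hbo = sol[0].reshape(shapes[0].shape)
    hbr = sol[1].reshape(shapes[0].shape)
    return hbo, hbr
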