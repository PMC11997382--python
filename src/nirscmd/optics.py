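"""Modified Beer-Lambert optics shared by the simulator and the preprocessor.

The linear model is, per wavelength ``λ`` and sample ``t``::

    ΔOD(λ, t) = [ε_HbO(λ) · ΔHbO(t) + ε_HbR(λ) · ΔHbR(t)] · d · DPF

with concentrations in mol/L, extinction coefficients ``ε`` in
cm⁻¹/(mol/L), source-detector distance ``d`` in cm and the dimensionless
differential path-length factor ``DPF``. Concentration changes are exposed
in µmol/L throughout the package.
"""
from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .errors import ConfigurationError

CHROMOPHORES = ("hbo", "hbr")

_MATCH_TOL_NM = 2.0


def _load_table() -> dict:
    with resources.files("nirscmd.data").joinpath("extinction_hb.json").open() as fh:
        return json.load(fh)


_TABLE = _load_table()


def extinction_matrix(wavelengths_nm) -> np.ndarray:
    """Return the (n_wavelengths, 2) matrix of [ε_HbO, ε_HbR] rows.

    Wavelengths are matched against the shipped table within ±2 nm; an
    unmatched wavelength is a configuration error (the table is versioned,
    not interpolated on the fly).
    """
    known = np.array(_TABLE["wavelengths_nm"], dtype=float)
    rows = []
    for wl in wavelengths_nm:
        diffs = np.abs(known - float(wl))
        i = int(np.argmin(diffs))
        if diffs[i] > _MATCH_TOL_NM:
            raise ConfigurationError(
                f"no extinction coefficients for {wl} nm (table covers {known.tolist()})"
            )
        key = f"{known[i]:.1f}"
        rows.append([_TABLE["hbo"][key], _TABLE["hbr"][key]])
    e = np.asarray(rows, dtype=float)
    if e.shape[0] < 2:
        raise ConfigurationError("at least two wavelengths are required")
    if np.linalg.cond(e) > 1e8:
        raise ConfigurationError("extinction matrix is ill-conditioned")
    return e


def forward_matrix(wavelengths_nm, dpf: float = 6.0, distance_cm: float = 3.0) -> np.ndarray:
    """Matrix mapping (ΔHbO, ΔHbR) in µmol/L to ΔOD per wavelength."""
    e = extinction_matrix(wavelengths_nm)
    return e * 1e-6 * float(dpf) * float(distance_cm)


def concentrations_to_od(dhbo_um, dhbr_um, wavelengths_nm, dpf: float = 6.0,
                         distance_cm: float = 3.0) -> np.ndarray:
    """Forward model: stack ΔOD time courses, shape (..., n_wl, n_t)."""
    a = forward_matrix(wavelengths_nm, dpf, distance_cm)
    conc = np.stack([np.asarray(dhbo_um, float), np.asarray(dhbr_um, float)], axis=-2)
    # (..., 2, n_t) -> (..., n_wl, n_t)
    return np.einsum("wc,...ct->...wt", a, conc)


def od_to_concentrations(dod, wavelengths_nm, dpf: float = 6.0,
                         distance_cm: float = 3.0) -> np.ndarray:
    """Least-squares inverse over wavelengths, output (..., 2, n_t) in µmol/L."""
    a = forward_matrix(wavelengths_nm, dpf, distance_cm)
    pinv = np.linalg.pinv(a)
    return np.einsum("cw,...wt->...ct", pinv, np.asarray(dod, float))
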