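"""Frequency-dependent dielectric properties of the tissue classes.

Each tissue class is represented by tables of conductivity sigma(f) [S/m] and
absolute permittivity eps(f) [F/m] over the DBS band, from which the complex
admittivity kappa(f) = sigma(f) + j*2*pi*f*eps(f) entering the electro-
quasistatic equation is interpolated (log-frequency linear).

The dispersion *shape* follows the standard four-term Cole-Cole
parameterisation of brain tissue; the conductivity curve is then rescaled to
pass through an editable 50 kHz anchor value per tissue class.  The shipped
anchors (GM 0.25 S/m, WM 0.15 S/m) are implementation defaults, not measured
values.  Cerebrospinal fluid is modelled as a frequency-independent 2 S/m
conductor, and the encapsulation layer is dielectrically identical to gray
matter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import CSF, GM, WM, ENCAP, LABEL_NAMES

logger = logging.getLogger("dbsfem.dielectrics")

EPS0 = 8.8541878128e-12  # F/m

# 50 kHz conductivity anchors, S/m.  GM/WM are editable implementation
# defaults standing in for unavailable literature averages; CSF is the
# conventional 2 S/m.
DEFAULT_SIGMA_50K = {GM: 0.25, WM: 0.15, CSF: 2.0}
ANCHOR_FREQUENCY = 50e3  # Hz

# Four-term Cole-Cole dispersion parameters for brain tissue
# (eps_inf, [d_eps], [tau_s], [alpha], sigma_ionic):
_COLE_COLE = {
    GM: (4.0, [45.0, 400.0, 2.0e5, 4.5e7],
         [7.958e-12, 15.915e-9, 106.103e-6, 5.305e-3],
         [0.10, 0.15, 0.22, 0.00], 0.02),
    WM: (4.0, [32.0, 100.0, 4.0e4, 3.5e7],
         [7.958e-12, 7.958e-9, 53.052e-6, 7.958e-3],
         [0.10, 0.10, 0.30, 0.02], 0.02),
}

DBS_BAND = (10.0, 1e6)  # Hz, band over which monotonicity is guaranteed


def cole_cole_complex_permittivity(tissue: int, f: np.ndarray) -> np.ndarray:
    """Relative complex permittivity eps_hat(f) of the dispersion model."""
    eps_inf, d_eps, tau, alpha, sig_i = _COLE_COLE[tissue]
    f = np.asarray(f, dtype=float)
    w = 2 * np.pi * f
    eps = np.full(f.shape, eps_inf, dtype=complex)
    for de, t, a in zip(d_eps, tau, alpha):
        eps = eps + de / (1.0 + (1j * w * t) ** (1.0 - a))
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = eps + sig_i / (1j * w * EPS0)
    return eps


@dataclass
class DispersiveMedium:
    """Tabulated sigma(f)/eps(f) for one tissue class with a 50 kHz anchor."""

    tissue_class: int
    sigma_table: np.ndarray      # (n, 2): frequency Hz, conductivity S/m
    eps_table: np.ndarray        # (n, 2): frequency Hz, permittivity F/m
    anchor: tuple[float, float] = (ANCHOR_FREQUENCY, np.nan)

    def __post_init__(self):
        self.sigma_table = np.asarray(self.sigma_table, dtype=float)
        self.eps_table = np.asarray(self.eps_table, dtype=float)
        for t, nm in ((self.sigma_table, "sigma"), (self.eps_table, "eps")):
            if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 1:
                raise ValueError(f"{nm}_table must be (n, 2)")
            if np.any(np.diff(t[:, 0]) <= 0):
                raise ValueError(f"{nm}_table frequencies must be increasing")
        if np.any(self.sigma_table[:, 1] <= 0):
            raise ValueError("conductivity must be positive")
        lo = self.sigma_table[(self.sigma_table[:, 0] >= DBS_BAND[0])
                              & (self.sigma_table[:, 0] <= DBS_BAND[1]), 1]
        if lo.size > 1 and np.any(np.diff(lo) < -1e-12 * lo[:-1]):
            raise ValueError("conductivity must be non-decreasing over the DBS band")

    # ---- constructors -------------------------------------------------------

    @classmethod
    def from_cole_cole(cls, tissue: int, sigma_50k: float | None = None,
                       f_lo: float = 1.0, f_hi: float = 1e7,
                       n_points: int = 71) -> "DispersiveMedium":
        """Medium with Cole-Cole dispersion shape rescaled through the anchor."""
        if sigma_50k is None:
            sigma_50k = DEFAULT_SIGMA_50K[GM if tissue == ENCAP else tissue]
        base = GM if tissue == ENCAP else tissue
        f = np.logspace(np.log10(f_lo), np.log10(f_hi), n_points)
        if base == CSF:
            sigma = np.full_like(f, sigma_50k)
            eps = np.full_like(f, 109.0 * EPS0)
        else:
            eh = cole_cole_complex_permittivity(base, f)
            w = 2 * np.pi * f
            sigma = -w * EPS0 * eh.imag
            eps = EPS0 * np.clip(eh.real, 1.0, None)
            s50 = float(np.interp(np.log(ANCHOR_FREQUENCY), np.log(f), sigma))
            sigma = sigma * (sigma_50k / s50)
        return cls(tissue, np.stack([f, sigma], axis=1),
                   np.stack([f, eps], axis=1),
                   anchor=(ANCHOR_FREQUENCY, float(sigma_50k)))

    @classmethod
    def constant(cls, tissue: int, sigma: float,
                 eps: float = EPS0) -> "DispersiveMedium":
        """Non-dispersive medium (useful for oracles and resistive limits)."""
        f = np.array([1.0, 1e7])
        return cls(tissue, np.stack([f, [sigma, sigma]], axis=1),
                   np.stack([f, [eps, eps]], axis=1),
                   anchor=(ANCHOR_FREQUENCY, sigma))

    # ---- evaluation ---------------------------------------------------------

    def _interp(self, table: np.ndarray, f: float) -> float:
        fs = table[:, 0]
        if f <= fs[0]:
            return float(table[0, 1])
        if f > fs[-1]:
            warnings.warn(f"frequency {f:.3g} Hz above table range "
                          f"{fs[-1]:.3g} Hz; clamping")
            return float(table[-1, 1])
        return float(np.interp(np.log(f), np.log(fs), table[:, 1]))

    def sigma(self, f: float) -> float:
        return self._interp(self.sigma_table, max(float(f), 0.0))

    def eps(self, f: float) -> float:
        return self._interp(self.eps_table, max(float(f), 0.0))

    def admittivity(self, f: float) -> complex:
        """kappa(f) = sigma(f) + j*2*pi*f*eps(f) in S/m; purely real at DC."""
        if f < 0:
            raise ValueError("frequency must be non-negative")
        if f == 0:
            return complex(self.sigma_table[0, 1])
        return complex(self.sigma(f), 2 * np.pi * f * self.eps(f))

    # ---- I/O ----------------------------------------------------------------

    def to_csv(self, path: str) -> None:
        import pandas as pd
        pd.DataFrame({"frequency_hz": self.sigma_table[:, 0],
                      "sigma_s_per_m": self.sigma_table[:, 1],
                      "eps_f_per_m": np.interp(self.sigma_table[:, 0],
                                               self.eps_table[:, 0],
                                               self.eps_table[:, 1]),
                      }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, tissue: int) -> "DispersiveMedium":
        import pandas as pd
        df = pd.read_csv(path)
        f = df["frequency_hz"].to_numpy()
        return cls(tissue, np.stack([f, df["sigma_s_per_m"].to_numpy()], axis=1),
                   np.stack([f, df["eps_f_per_m"].to_numpy()], axis=1))


def admittivity_at(medium: DispersiveMedium, frequency: float) -> complex:
    """Complex admittivity of a medium at one frequency (S/m)."""
    return medium.admittivity(frequency)


def admittivity_tensor(medium: DispersiveMedium, tensor: np.ndarray,
                       frequency: float) -> np.ndarray:
    """Scalar admittivity times a unit-determinant SPD structure tensor.

    The result is complex symmetric with the eigenvector frame of ``tensor``;
    the geometric mean of the real-part eigenvalues equals sigma(f).
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-10):
        raise ValueError("tensor must be symmetric 3x3")
    ev = np.linalg.eigvalsh(t)
    if np.any(ev <= 0):
        raise ValueError("tensor must be positive-definite")
    if abs(np.prod(ev) - 1.0) > 1e-6:
        raise ValueError("tensor must have unit determinant")
    return admittivity_at(medium, frequency) * t


def default_media(sigma_overrides: dict[int, float] | None = None,
                  dispersive: bool = True) -> dict[int, DispersiveMedium]:
    """Default media set keyed by tissue label (ENCAP shares GM's kappa)."""
    over = sigma_overrides or {}
    media: dict[int, DispersiveMedium] = {}
    for tissue in (CSF, GM, WM):
        s = over.get(tissue)
        if dispersive:
            media[tissue] = DispersiveMedium.from_cole_cole(tissue, s)
        else:
            media[tissue] = DispersiveMedium.constant(
                tissue, s if s is not None else DEFAULT_SIGMA_50K[tissue])
    gm = media[GM]
    media[ENCAP] = DispersiveMedium(ENCAP, gm.sigma_table.copy(),
                                    gm.eps_table.copy(), gm.anchor)
    logger.debug("media built: %s", {LABEL_NAMES[k]: v.anchor for k, v in media.items()})
    return media
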