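"""Generalized two-dimensional correlation spectroscopy (2D-COS).

With water concentration as the perturbation variable, spectra ordered by
ascending concentration are turned into dynamic spectra by subtracting a
reference (by default the mean spectrum).  The synchronous map
``Phi = X~^T X~ / (m-1)`` carries in-phase covariance of intensity changes;
the asynchronous map ``Psi = X~^T N X~ / (m-1)``, with N the discrete
Hilbert-Noda transform, carries the out-of-phase part whose sign
(together with Phi's) encodes the sequential order of band responses.
The 1/(m-1) normalization makes Phi's diagonal the per-channel sample
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpectraError, SpectraSet, WavenumberGrid


@dataclass
class TwoDCOSResult:
    grid: WavenumberGrid
    reference: np.ndarray
    dynamic: np.ndarray          # m x p
    synchronous: np.ndarray      # p x p, symmetric PSD
    asynchronous: np.ndarray     # p x p, antisymmetric, zero diagonal

    def at(self, wn1: float, wn2: float) -> tuple[float, float]:
        """(synchronous, asynchronous) intensity at a wavenumber pair."""
        i = self.grid.nearest_index(wn1)
        j = self.grid.nearest_index(wn2)
        return float(self.synchronous[i, j]), float(self.asynchronous[i, j])


def dynamic_spectra(X: np.ndarray,
                    reference: np.ndarray | str = "mean") -> np.ndarray:
    """Row-wise subtraction of the reference spectrum.

    ``X`` holds m perturbation-ordered spectra.  With the default mean
    reference the dynamic spectra have zero column means.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise SpectraError("need at least two perturbation-ordered spectra")
    ref = X.mean(axis=0) if isinstance(reference, str) and \
        reference == "mean" else np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise SpectraError("reference length does not match spectra")
    return X - ref


def sync_spectrum(Xd: np.ndarray) -> np.ndarray:
    """Synchronous correlation map Phi = X~^T X~ / (m-1)."""
    Xd = np.asarray(Xd, dtype=float)
    return Xd.T @ Xd / (Xd.shape[0] - 1)


def noda_matrix(m: int) -> np.ndarray:
    """Discrete Hilbert-Noda transform: N[j,k] = 1/(pi (k-j)), 0 on the
    diagonal."""
    if m < 2:
        raise SpectraError("Hilbert-Noda matrix needs m >= 2")
    j, k = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    with np.errstate(divide="ignore"):
        N = 1.0 / (np.pi * (k - j))
    N[j == k] = 0.0
    return N


def async_spectrum(Xd: np.ndarray) -> np.ndarray:
    """Asynchronous correlation map Psi = X~^T N X~ / (m-1)."""
    Xd = np.asarray(Xd, dtype=float)
    m = Xd.shape[0]
    psi = Xd.T @ noda_matrix(m) @ Xd / (m - 1)
    # exact antisymmetry / zero diagonal despite floating-point noise
    psi = 0.5 * (psi - psi.T)
    np.fill_diagonal(psi, 0.0)
    return psi


def twodcos(spectra: SpectraSet,
            reference: np.ndarray | str = "mean") -> TwoDCOSResult:
    """Full 2D-COS analysis of a set ordered by ascending water fraction."""
    s = spectra.ensure_absorbance()
    order = np.argsort(s.water_fractions(), kind="stable")
    X = s.matrix[order]
    ref = X.mean(axis=0) if isinstance(reference, str) else \
        np.asarray(reference, dtype=float)
    Xd = dynamic_spectra(X, ref)
    return TwoDCOSResult(s.grid, ref, Xd, sync_spectrum(Xd),
                         async_spectrum(Xd))


def plot_contour(result: TwoDCOSResult, which: str = "synchronous",
                 ax=None, levels: int = 12, vlim: float | None = None):
    """Contour plot of a correlation map (wavenumbers descending, the
    spectroscopic convention).  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    Z = getattr(result, which)
    if ax is None:
        _, ax = plt.subplots()
    v = vlim if vlim is not None else float(np.abs(Z).max()) or 1.0
    wn = result.grid.values
    ax.contourf(wn, wn, Z, levels=levels, cmap="RdBu_r", vmin=-v, vmax=v)
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_xlabel("wavenumber / cm$^{-1}$")
    ax.set_ylabel("wavenumber / cm$^{-1}$")
    ax.set_title(f"{which} 2D-COS")
    return ax
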