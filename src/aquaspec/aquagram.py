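"""Two-band aquagrams: standardized water-band absorbance on a radar chart.

Classical aquagrams display the ~6900 cm^-1 water band only; here both
major water regions are covered — the overtone region 7300-6500 cm^-1 and
the combination region 5400-5000 cm^-1.  For one polymer's averaged,
SNV-treated concentration spectra, wavenumbers of interest are selected
per region (largest across-concentration variance merged with local maxima
of the mean spectrum) and the normalized absorbance

    An_lambda = (A_lambda - mu_lambda) / sigma_lambda

is computed per spectrum and wavenumber, where mu/sigma are the mean and
sample standard deviation across that polymer's spectra (0-10 % w/w
inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpectraError, SpectraSet, snv

OVERTONE_REGION = (7300.0, 6500.0)
COMBINATION_REGION = (5400.0, 5000.0)
DEFAULT_REGIONS = (OVERTONE_REGION, COMBINATION_REGION)


@dataclass
class Aquagram:
    polymer: str
    wavenumbers: np.ndarray          # descending, overtone group first
    region_of: np.ndarray            # region index per wavenumber
    water_fractions: np.ndarray      # ascending, one per trace
    values: np.ndarray               # n_spectra x n_wavenumbers (An_lambda)


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima of a 1-D array."""
    if y.size < 3:
        return np.array([], dtype=int)
    return np.nonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]))[0] + 1


def select_wavenumbers(spectra: SpectraSet,
                       regions=DEFAULT_REGIONS,
                       n_per_region: int = 8) -> np.ndarray:
    """Wavenumbers of interest from one polymer's SNV-treated averaged set.

    Per region: the ``n_per_region`` grid points with the largest
    across-concentration variance, merged with local maxima of the mean
    spectrum; deduplicated and sorted descending.
    """
    s = spectra.ensure_absorbance()
    grid = s.grid
    chosen: list[float] = []
    for region in regions:
        idx = grid.window_indices(*region)
        sub = s.matrix[:, idx]
        mean = sub.mean(axis=0)
        var = sub.var(axis=0, ddof=1) if len(s) > 1 else np.zeros(idx.size)
        picks = set()
        if n_per_region > 0 and np.any(var > 0):
            top = np.argsort(var, kind="stable")[::-1][:n_per_region]
            picks.update(int(i) for i in top)
        picks.update(int(i) for i in _local_maxima(mean))
        chosen.extend(float(grid.values[idx[i]]) for i in sorted(picks))
    return np.array(sorted(set(chosen), reverse=True))


def normalized_absorbance(spectra: SpectraSet, wavenumbers,
                          apply_snv: bool = True,
                          regions=DEFAULT_REGIONS) -> Aquagram:
    """Standardize the (SNV-treated) absorbance at selected wavenumbers
    across one polymer's spectra; errors on any zero-variance wavenumber."""
    labels = {m.polymer for m in spectra.meta}
    if len(labels) != 1:
        raise SpectraError(f"set mixes polymers {sorted(labels)}")
    if len(spectra) < 2:
        raise SpectraError("need at least two spectra to standardize")
    s = snv(spectra) if apply_snv else spectra.ensure_absorbance()
    order = np.argsort(s.water_fractions(), kind="stable")
    wn = np.asarray(wavenumbers, dtype=float)
    cols = np.array([s.grid.nearest_index(v) for v in wn])
    A = s.matrix[order][:, cols]
    mu = A.mean(axis=0)
    sigma = A.std(axis=0, ddof=1)
    dead = np.nonzero(sigma == 0)[0]
    if dead.size:
        raise SpectraError(
            f"zero variance at wavenumber {wn[dead[0]]:g} cm^-1")
    region_of = np.array([_region_index(v, regions) for v in wn])
    return Aquagram(labels.pop(), wn, region_of,
                    s.water_fractions()[order], (A - mu) / sigma)


def _region_index(wn: float, regions) -> int:
    for r, (a, b) in enumerate(regions):
        if min(a, b) <= wn <= max(a, b):
            return r
    return -1


def build_aquagram(aq: Aquagram) -> dict:
    """Radar-chart data: angular axes (overtone wavenumbers first, then
    combination), one closed trace per concentration, ascending in w."""
    order = np.lexsort((-aq.wavenumbers, aq.region_of))
    wn = aq.wavenumbers[order]
    k = wn.size
    angles = 2.0 * np.pi * np.arange(k) / max(k, 1)
    traces = []
    for i, w in enumerate(aq.water_fractions):
        vals = aq.values[i][order]
        traces.append({"water_fraction": float(w),
                       "values": np.append(vals, vals[:1])})
    return {"polymer": aq.polymer,
            "axes": wn,
            "region_of": aq.region_of[order],
            "angles": np.append(angles, angles[:1]),
            "traces": traces}


def plot_radar(aq: Aquagram, ax=None):
    """Render the aquagram on a polar axis; returns the axes."""
    import matplotlib.pyplot as plt

    chart = build_aquagram(aq)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for trace in chart["traces"]:
        ax.plot(chart["angles"], trace["values"],
                label=f"{100 * trace['water_fraction']:g}%")
    ax.set_xticks(chart["angles"][:-1])
    ax.set_xticklabels([f"{v:g}" for v in chart["axes"]], fontsize=7)
    ax.set_title(f"Aquagram — {chart['polymer']}")
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=7)
    return ax
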