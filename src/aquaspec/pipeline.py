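"""End-to-end orchestration: simulate (or load) -> preprocess -> analyses
-> machine-readable report.

A pipeline run is driven by a plain-dict (YAML-friendly) configuration,
validated strictly — unknown keys are rejected so typos cannot silently
change an analysis.  Every run writes ``manifest.json`` (config echo,
package and dependency versions, seed) sufficient to reproduce it, plus a
``summary.json`` with the per-stage headline numbers and per-stage CSV
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .aquagram import normalized_absorbance, select_wavenumbers
from .chemometrics import (cosine_similarity, flag_outliers, match_components,
                           mcr_als, mlc_cluster, pca_nipals, plsr_fit,
                           plsr_loo)
from .core import (DESIGN_WATER_FRACTIONS, SpectraError, SpectraSet,
                   WavenumberGrid, average_group, linear_offset_correct, snv)
from .diffspec import band_shift_range, polymer_difference_series, \
    water_difference_series
from .io import read_spectra_table, write_spectra_table
from .synthetic import (NoiseModel, bulk_water_profile, load_profile_library,
                        synthesize_dataset, synthesize_sample, water_component)
from .twodcos import twodcos

logger = logging.getLogger(__name__)

OVERTONE_WINDOW = (6500.0, 7300.0)
COMBINATION_WINDOW = (5000.0, 5400.0)

_SCHEMA = {
    "input": str,
    "simulation": {
        "profiles": list, "concentrations": list, "n_prep": int,
        "n_meas": int, "baseline_sd": float, "additive_sd": float,
        "seed": int,
    },
    "grid": {"lo": float, "hi": float, "step": float},
    "preprocess": {"offset_lo": float, "offset_hi": float},
    "stages": list,
    "pca": {"k": int},
    "cluster": {"n_clusters": int},
    "plsr": {"k": int},
    "mcr": {"tol": float, "max_iter": int},
    "aquagram": {"n_per_region": int},
}

_ALL_STAGES = ("diffspec", "pca", "cluster", "plsr", "mcr", "cos2d",
               "aquagram")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def validate_config(config: dict) -> dict:
    """Reject unknown keys; require exactly one of input / simulation and a
    seed for simulation."""
    def _check(node, schema, path):
        for key, val in node.items():
            if key not in schema:
                raise SpectraError(f"unknown config key {path}{key}")
            if isinstance(schema[key], dict):
                if not isinstance(val, dict):
                    raise SpectraError(f"{path}{key} must be a mapping")
                _check(val, schema[key], f"{path}{key}.")

    if not isinstance(config, dict):
        raise SpectraError("config must be a mapping")
    _check(config, _SCHEMA, "")
    if ("input" in config) == ("simulation" in config):
        raise SpectraError(
            "config needs exactly one of 'input' or 'simulation'")
    if "simulation" in config and "seed" not in config["simulation"]:
        raise SpectraError("simulation block requires a master seed")
    for stage in config.get("stages", []):
        if stage not in _ALL_STAGES:
            raise SpectraError(f"unknown stage {stage!r}")
    return config


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_json_default) + "\n")


def _grid(config: dict) -> WavenumberGrid:
    g = config.get("grid", {})
    return WavenumberGrid.default(g.get("lo", 4000.0), g.get("hi", 10000.0),
                                  g.get("step", 2.0))


def _acquire(config: dict) -> tuple[SpectraSet, dict]:
    if "input" in config:
        return read_spectra_table(config["input"]), {}
    sim = config["simulation"]
    lib = load_profile_library()
    names = sim.get("profiles", list(lib))
    unknown = [n for n in names if n not in lib]
    if unknown:
        raise SpectraError(f"unknown profiles {unknown}")
    profiles = [lib[n] for n in names]
    noise = NoiseModel(sim.get("baseline_sd", 0.01),
                       sim.get("additive_sd", 3e-4))
    dataset = synthesize_dataset(
        profiles,
        concentrations=sim.get("concentrations",
                               list(DESIGN_WATER_FRACTIONS)),
        n_prep=sim.get("n_prep", 6), n_meas=sim.get("n_meas", 3),
        noise=noise, seed=sim["seed"], grid=_grid(config))
    return dataset, {p.name: p for p in profiles}


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the configured stages; returns (and writes) the summary."""
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(_ALL_STAGES))

    raw, profiles = _acquire(config)
    pre = config.get("preprocess", {})
    region = None
    if "offset_lo" in pre or "offset_hi" in pre:
        region = (pre.get("offset_lo", raw.grid.values[0]),
                  pre.get("offset_hi", raw.grid.values[-1]))
    corrected = linear_offset_correct(raw, region)
    averaged = average_group(corrected)
    write_spectra_table(averaged, out / "averaged_spectra.csv")

    grid = corrected.grid
    water_ref = linear_offset_correct(
        synthesize_sample(bulk_water_profile(), 0.10, grid=grid))
    polymers = list(dict.fromkeys(m.polymer for m in corrected.meta))
    summary: dict = {"n_samples": len(raw), "polymers": polymers,
                     "stages": list(stages)}

    for stage in stages:
        try:
            summary[stage] = _STAGE_FUNCS[stage](
                config, corrected, averaged, water_ref, profiles, out)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            digest = hashlib.sha256(raw.matrix.tobytes()).hexdigest()[:12]
            logger.error("stage %s failed on input %s: %s", stage, digest,
                         exc)
            raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "aquaspec_version": __version__,
        "numpy_version": np.__version__,
        "config": config,
        "grid": {"lo": grid.values[0], "hi": grid.values[-1],
                 "step": grid.spacing},
    }
    _dump(manifest, out / "manifest.json")
    _dump(summary, out / "summary.json")
    return summary


# --------------------------------------------------------------------------
# stages


def _per_polymer_sets(averaged: SpectraSet):
    for name in dict.fromkeys(m.polymer for m in averaged.meta):
        yield name, averaged.select(lambda m, n=name: m.polymer == n)


def _stage_diffspec(config, corrected, averaged, water_ref, profiles, out):
    res = {}
    for name, sub in _per_polymer_sets(averaged):
        pure_idx = [i for i, m in enumerate(sub.meta)
                    if m.water_fraction == 0]
        if not pure_idx:
            continue
        series = water_difference_series(
            sub.select(lambda m: m.water_fraction > 0),
            sub.row(pure_idx[0]))
        res[name] = {
            "scaling_factors": series.scaling_factors,
            "overtone_shift": band_shift_range(series, OVERTONE_WINDOW),
            "combination_shift": band_shift_range(series,
                                                  COMBINATION_WINDOW),
        }
        np.savetxt(out / f"diffspec_water_{name}.csv",
                   series.differences, delimiter=",")
    return res


def _stage_pca(config, corrected, averaged, water_ref, profiles, out):
    k = config.get("pca", {}).get("k", 2)
    model = pca_nipals(corrected.matrix, k)
    np.savetxt(out / "pca_scores.csv", model.scores, delimiter=",")
    return {"explained_variance_fraction":
            model.explained_variance_fraction}


def _stage_cluster(config, corrected, averaged, water_ref, profiles, out):
    n_clusters = config.get("cluster", {}).get(
        "n_clusters", min(8, len(averaged)))
    tree = mlc_cluster(averaged.matrix, n_clusters)
    labels = tree.flat_labels(n_clusters)
    return {"n_clusters": n_clusters,
            "labels": {m.sample_id: int(l)
                       for m, l in zip(averaged.meta, labels)},
            "merge_heights": [h for _, _, h in tree.merges]}


def _stage_plsr(config, corrected, averaged, water_ref, profiles, out):
    k = config.get("plsr", {}).get("k", 2)
    res = {}
    for name in dict.fromkeys(m.polymer for m in corrected.meta):
        sub = corrected.select(lambda m, n=name: m.polymer == n)
        y = sub.water_fractions()
        kk = min(k, len(sub) - 2)
        model = plsr_fit(sub.matrix, y, kk)
        cv = plsr_loo(sub.matrix, y, kk)
        res[name] = {
            "r2_cv": cv.r2_cv, "rmsecv": cv.rmsecv,
            "explained_x_variance_2": model.explained_x_variance[
                min(1, kk - 1)],
            "outliers": [int(i) for i in flag_outliers(cv)],
        }
    return res


def _stage_mcr(config, corrected, averaged, water_ref, profiles, out):
    mc = config.get("mcr", {})
    res = {}
    for name, sub in _per_polymer_sets(averaged):
        pure_idx = [i for i, m in enumerate(sub.meta)
                    if m.water_fraction == 0]
        if not pure_idx:
            continue
        S_init = np.vstack([np.maximum(sub.matrix[pure_idx[0]], 0.0),
                            np.maximum(water_ref.intensity, 0.0)])
        r = mcr_als(sub.matrix, S_init, tol=mc.get("tol", 1e-8),
                    max_iter=mc.get("max_iter", 200))
        entry = {"lack_of_fit": r.lack_of_fit[-1],
                 "iterations": r.iterations, "converged": r.converged,
                 "cosine_polymer": cosine_similarity(
                     r.S[0], sub.matrix[pure_idx[0]]),
                 "cosine_water": cosine_similarity(
                     r.S[1], water_ref.intensity)}
        np.savetxt(out / f"mcr_spectra_{name}.csv", r.S, delimiter=",")
        res[name] = entry
    return res


def _stage_cos2d(config, corrected, averaged, water_ref, profiles, out):
    res = {}
    for name, sub in _per_polymer_sets(averaged):
        r = twodcos(sub)
        if name in profiles:
            wr = profiles[name].water
            o, c = wr.overtone_center_hi, wr.combination_center_hi
        else:
            o, c = 6900.0, 5200.0
        sync_oc, async_oc = r.at(o, c)
        res[name] = {"sync_overtone_combination": sync_oc,
                     "async_overtone_combination": async_oc}
    return res


def _stage_aquagram(config, corrected, averaged, water_ref, profiles, out):
    n_per = config.get("aquagram", {}).get("n_per_region", 8)
    res = {}
    rows = []
    for name, sub in _per_polymer_sets(averaged):
        treated = snv(sub)
        wns = select_wavenumbers(treated, n_per_region=n_per)
        aq = normalized_absorbance(sub, wns)
        res[name] = {"n_wavenumbers": int(wns.size)}
        for i, w in enumerate(aq.water_fractions):
            for j, wn in enumerate(aq.wavenumbers):
                rows.append(f"{name},{w:g},{wn:g},{aq.values[i, j]:.10g}")
    (out / "aquagram.csv").write_text(
        "polymer,water_fraction,wavenumber,An\n" + "\n".join(rows) + "\n")
    return res


_STAGE_FUNCS = {
    "diffspec": _stage_diffspec,
    "pca": _stage_pca,
    "cluster": _stage_cluster,
    "plsr": _stage_plsr,
    "mcr": _stage_mcr,
    "cos2d": _stage_cos2d,
    "aquagram": _stage_aquagram,
}


def default_demo_config(seed: int = 1) -> dict:
    """The bundled end-to-end demonstration: two contrasting matrices
    (hydrophobic PP, hydrophilic cellulose) under the reference design."""
    return {
        "simulation": {"profiles": ["PP", "cellulose"], "seed": seed},
        "stages": list(_ALL_STAGES),
    }
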