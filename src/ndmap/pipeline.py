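"""End-to-end orchestration: contrast -> rectify -> epicenter -> eigenmodes
-> null -> craving, driven by one YAML/JSON config.

The config either points at real inputs::

    inputs:
      connectome: conn.tsv
      labels: labels.csv
      cohort: cohort.csv

or requests a fully synthetic study::

    synthetic: {n_regions: 46, rng_seed: 7, ...}

with analysis parameters under ``params`` (beta, t_max, n_modes, n_nulls,
alpha, eigenmode_p, null_scope, statistic, seed) and an ``output_dir``.
Both alteration directions (atrophy and expansion) are analyzed; the null
model runs for the top-ranked epicenter of each direction.  Every stage
writes TSV/JSON artifacts, and a manifest records SHA-256 hashes of all
inputs and outputs so a rerun with the same config and seeds is
byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import warnings

import numpy as np
import yaml

from .connectome import build_laplacian, load_connectome
from .contrast import GMVTable, fit_regional_glm, rectify_contrast
from .craving import craving_correlations
from .diffusion import DiffusionParams, eigenmode_correlation
from .epicenter import find_epicenters
from .nullmodel import null_distribution
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "beta": 1.0,
    "t_max": 50,
    "n_modes": 5,
    "n_nulls": 1000,
    "alpha": 0.05,
    "eigenmode_p": 0.01,
    "null_scope": "all_seeds",
    "statistic": "tvalue",
    "seed": 0,
}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config) as fh:
        if str(config).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def run_pipeline(config) -> dict:
    """Run every stage and return the summary report (also written to disk).

    ``config`` is a dict or a path to a YAML/JSON file; see the module
    docstring for the schema.  Raises on any stage error with a
    stage-attributed message.
    """
    cfg = _load_config(config)
    params = {**DEFAULT_PARAMS, **cfg.get("params", {})}
    outdir = cfg.get("output_dir", "ndmap_output")
    os.makedirs(outdir, exist_ok=True)
    collected_warnings: list[str] = []
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    def _stage(name):
        logger.info("stage %s: start", name)
        return time.perf_counter()

    def _done(name, t0):
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.2fs", name, timings[name])

    def _write_tsv(name, df):
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs[name] = path
        return path

    # ---- inputs ----------------------------------------------------------
    t0 = _stage("load")
    input_paths: dict[str, str] = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if "synthetic" in cfg:
            spec = SyntheticSpec(**cfg["synthetic"])
            connectome, table = generate_dataset(spec)
            spec.to_json(os.path.join(outdir, "synthetic_spec.json"))
            outputs["synthetic_spec.json"] = os.path.join(outdir, "synthetic_spec.json")
        elif "inputs" in cfg:
            paths = cfg["inputs"]
            for key in ("connectome", "labels", "cohort"):
                if key not in paths:
                    raise ValueError(f"stage load: config inputs missing '{key}'")
                input_paths[key] = paths[key]
            connectome = load_connectome(paths["connectome"], paths["labels"])
            table = GMVTable.from_csv(paths["cohort"], region_ids=connectome.region_ids)
        else:
            raise ValueError("stage load: config needs 'synthetic' or 'inputs'")
        laplacian = build_laplacian(connectome)
    collected_warnings += [str(w.message) for w in caught]
    _done("load", t0)

    dparams = DiffusionParams(
        beta=params["beta"], times=np.arange(params["t_max"] + 1.0)
    )
    rng_children = np.random.SeedSequence(params["seed"]).generate_state(8) % (2**31 - 1)

    # ---- contrast --------------------------------------------------------
    t0 = _stage("contrast")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        contrast = fit_regional_glm(table)
    collected_warnings += [str(w.message) for w in caught]
    _write_tsv("contrast.tsv", contrast.to_frame())
    _done("contrast", t0)

    summary: dict = {
        "params": params,
        "n_regions": connectome.n_regions,
        "n_subjects": table.n_subjects,
        "directions": {},
    }

    # ---- per-direction epicenter / eigenmode / null ----------------------
    for k, mode in enumerate(("atrophy", "expansion")):
        t0 = _stage(mode)
        try:
            pattern = rectify_contrast(contrast, mode, statistic=params["statistic"])
        except ValueError as exc:
            raise ValueError(f"stage {mode}: {exc}") from exc
        result = find_epicenters(laplacian, pattern, dparams, pattern_mode=mode)
        _write_tsv(f"{mode}_ranking.tsv", result.to_frame())
        import pandas as pd

        curve_df = pd.DataFrame(
            result.curves, columns=[f"t{t:g}" for t in dparams.times]
        )
        curve_df.insert(0, "region", connectome.region_ids)
        _write_tsv(f"{mode}_curves.tsv", curve_df)

        modes = eigenmode_correlation(
            laplacian,
            pattern,
            n_modes=params["n_modes"],
            tiers=connectome.tiers,
            p_threshold=params["eigenmode_p"],
        )
        _write_tsv(f"{mode}_eigenmodes.tsv", modes)

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            null = null_distribution(
                connectome,
                pattern,
                dparams,
                candidate_seed=result.top_seed,
                n_nulls=params["n_nulls"],
                rng_seed=int(rng_children[k]),
                scope=params["null_scope"],
            )
        collected_warnings += [str(w.message) for w in caught]
        _write_tsv("%s_null_peaks.tsv" % mode, pd.DataFrame({"peak_r": null.null_peaks}))
        null_json = {
            "empirical_r": null.empirical_r,
            "percentile95": null.percentile95,
            "empirical_p": null.empirical_p,
            "p_raw": null.p_raw,
            "n_nulls": null.n_nulls,
            "rng_seed": null.rng_seed,
        }
        path = os.path.join(outdir, f"{mode}_null.json")
        with open(path, "w") as fh:
            json.dump(null_json, fh, indent=2)
        outputs[f"{mode}_null.json"] = path

        summary["directions"][mode] = {
            "top_seed": result.top_seed,
            "top_region": connectome.region_ids[result.top_seed],
            "peak_r": float(result.peak_r[result.top_seed]),
            "peak_t": float(result.peak_t[result.top_seed]),
            "significant_modes": int(modes.query("scope == 'whole'")["significant"].sum()),
            "null": null_json,
        }
        _done(mode, t0)

    # ---- craving ---------------------------------------------------------
    if table.craving is not None and np.isfinite(
        table.craving[table.group == "case"]
    ).all():
        t0 = _stage("craving")
        craving = craving_correlations(
            table, alpha=params["alpha"], tiers=connectome.tiers
        )
        _write_tsv("craving.tsv", craving)
        top = craving.iloc[0]
        summary["craving"] = {
            "n_significant": int(craving["significant"].sum()),
            "top_region": str(top["region"]),
            "top_r": float(top["r"]),
        }
        _done("craving", t0)

    summary["warnings"] = collected_warnings
    summary["timings_s"] = timings

    spath = os.path.join(outdir, "summary.json")
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=2)
    outputs["summary.json"] = spath

    manifest = {
        "inputs": {k: _sha256(v) for k, v in input_paths.items()},
        "outputs": {k: _sha256(v) for k, v in outputs.items()},
        "config": cfg if isinstance(config, dict) else str(config),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return summary
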