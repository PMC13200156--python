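"""Synthetic connectomes and cohorts with a planted, recoverable epicenter.

The generator emulates the data shapes of a case-control morphometry study
on a structural connectome, with full ground truth:

* a modular weighted connectome (stochastic-block-style: dense lognormal
  intra-module connectivity, sparse inter-module bridges, guaranteed
  connected);
* per-subject total intracranial volume (TIV) acting as a confound on
  every region, plus i.i.d. Gaussian observation noise;
* a planted group effect: case subjects lose volume along the diffusion
  pattern x(plant_time) seeded at ``true_seed`` — the forward model of the
  epicenter analysis itself, so recovery of ``true_seed`` is a genuine
  inverse problem;
* craving scores for cases linearly coupled to designated (subcortical)
  regions' volumes at a known correlation.

All randomness flows from one spec-level seed through named substreams
(graph, baseline, tiv, noise, craving), making every fixture bitwise
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .connectome import Connectome, build_laplacian
from .contrast import GMVTable
from .diffusion import DiffusionParams, diffuse

_SUBSTREAMS = ("graph", "baseline", "tiv", "noise", "craving")


@dataclass
class SyntheticSpec:
    """Ground-truth parameters for one synthetic study.

    Default cohort sizes mirror a 288-case / 165-control study; volumes
    are in mm^3-like units (regional means ~4000-9000, observation noise
    sd 150), TIV in mm^3 (mean 1.5e6).  ``plant_time`` places the planted
    pattern mid-diffusion so the seed identity is still encoded;
    ``effect_scale`` and ``noise_sd`` jointly set the contrast
    signal-to-noise (see docs/methods.md for the calibration).
    """

    n_regions: int = 46
    n_modules: int = 4
    intra_density: float = 0.6
    inter_density: float = 0.02
    intra_weight_scale: float = 1.0
    inter_weight_scale: float = 0.3
    weight_sigma: float = 0.5
    n_cases: int = 288
    n_controls: int = 165
    true_seed: int = 7
    plant_time: float = 2.0
    effect_scale: float = 400.0
    noise_sd: float = 150.0
    tiv_mean: float = 1.5e6
    tiv_sd: float = 1.5e5
    tiv_loading: float = 0.003
    craving_regions: list[int] | None = None
    craving_effect: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.intra_density <= 1 and 0 <= self.inter_density <= 1):
            raise ValueError("densities must lie in (0, 1]")
        if self.n_cases < 3 or self.n_controls < 3:
            raise ValueError("need at least 3 subjects per group")
        if not (0 <= self.true_seed < self.n_regions):
            raise ValueError("true_seed out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_modules < 1 or self.n_modules > self.n_regions:
            raise ValueError("n_modules must be in [1, n_regions]")
        if self.craving_regions is not None:
            bad = [i for i in self.craving_regions if not 0 <= i < self.n_regions]
            if bad:
                raise ValueError(f"craving_regions out of range: {bad}")

    def resolved_craving_regions(self) -> list[int]:
        # default: the last (subcortical) region
        if self.craving_regions is not None:
            return list(self.craving_regions)
        return [self.n_regions - 1]

    def substreams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.rng_seed).spawn(len(_SUBSTREAMS))
        return {
            name: np.random.default_rng(child)
            for name, child in zip(_SUBSTREAMS, children)
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _region_meta(n_regions: int) -> pd.DataFrame:
    n_sub = max(2, round(0.15 * n_regions))
    tier = ["cortical"] * (n_regions - n_sub) + ["subcortical"] * n_sub
    hemi = ["L" if i % 2 == 0 else "R" for i in range(n_regions)]
    names = [f"R{i + 1:03d}" for i in range(n_regions)]
    return pd.DataFrame(
        {"index": np.arange(1, n_regions + 1), "name": names,
         "hemisphere": hemi, "tier": tier}
    )


def generate_connectome(spec: SyntheticSpec) -> Connectome:
    """Weighted stochastic-block-style connectome, connected and symmetric."""
    rng = spec.substreams()["graph"]
    n = spec.n_regions
    module = np.repeat(np.arange(spec.n_modules), -(-n // spec.n_modules))[:n]
    same = module[:, None] == module[None, :]
    prob = np.where(same, spec.intra_density, spec.inter_density)
    scale = np.where(same, spec.intra_weight_scale, spec.inter_weight_scale)
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < prob[iu]
    raw = rng.lognormal(mean=0.0, sigma=spec.weight_sigma, size=iu[0].size)
    w = np.zeros((n, n))
    w[iu] = present * raw * scale[iu]
    w = w + w.T
    # guarantee connectivity: bridge components with a typical weight
    nz = w[w > 0]
    bridge = float(np.median(nz)) if nz.size else 1.0
    ncomp, labels = connected_components(w > 0, directed=False)
    while ncomp > 1:
        for k in range(1, ncomp):
            i = int(rng.choice(np.flatnonzero(labels == 0)))
            j = int(rng.choice(np.flatnonzero(labels == k)))
            w[i, j] = w[j, i] = bridge
        ncomp, labels = connected_components(w > 0, directed=False)
    meta = _region_meta(n)
    return Connectome(
        weights=w, region_ids=meta["name"].tolist(), region_meta=meta
    )


def planted_pattern(spec: SyntheticSpec, c: Connectome) -> np.ndarray:
    """Diffusion profile x(plant_time) from the true seed, peak-normalized."""
    L = build_laplacian(c)
    x0 = np.zeros(spec.n_regions)
    x0[spec.true_seed] = 1.0
    params = DiffusionParams(beta=1.0, times=np.array([spec.plant_time]))
    x = diffuse(L, x0, params).trajectory[0]
    return x / x.max()


def generate_cohort(spec: SyntheticSpec, c: Connectome) -> GMVTable:
    """Subject-by-region volume table with the planted group effect.

    Baseline volume = region mean + tiv_loading * TIV + N(0, noise_sd^2);
    cases additionally lose effect_scale * x(plant_time) (peak-normalized),
    i.e. volume loss planted along the diffusion pattern from the true
    seed.  Case craving scores correlate with the designated regions'
    composite volume at ``craving_effect`` (before sampling noise).
    """
    streams = spec.substreams()
    n = spec.n_regions
    s = spec.n_cases + spec.n_controls
    if c.n_regions != n:
        raise ValueError("connectome size does not match spec.n_regions")

    baseline = streams["baseline"].uniform(4000.0, 9000.0, size=n)
    tiv = streams["tiv"].normal(spec.tiv_mean, spec.tiv_sd, size=s)
    tiv = np.clip(tiv, spec.tiv_mean * 0.3, None)
    noise = streams["noise"].normal(0.0, spec.noise_sd, size=(s, n))

    group = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)
    effect = spec.effect_scale * planted_pattern(spec, c)
    values = baseline[None, :] + spec.tiv_loading * tiv[:, None] + noise
    values[group == "case"] -= effect[None, :]

    craving = np.full(s, np.nan)
    case_idx = np.flatnonzero(group == "case")
    regions = spec.resolved_craving_regions()
    composite = values[case_idx][:, regions].mean(axis=1)
    z = (composite - composite.mean()) / composite.std()
    rho = spec.craving_effect
    eps = streams["craving"].normal(0.0, 1.0, size=case_idx.size)
    raw = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
    craving[case_idx] = 50.0 + 10.0 * raw  # questionnaire-like scale

    subject_ids = [f"case{i + 1:03d}" for i in range(spec.n_cases)] + [
        f"ctrl{i + 1:03d}" for i in range(spec.n_controls)
    ]
    return GMVTable(
        values=values,
        subject_ids=subject_ids,
        group=group,
        tiv=tiv,
        region_ids=list(c.region_ids),
        craving=craving,
    )


def generate_dataset(spec: SyntheticSpec) -> tuple[Connectome, GMVTable]:
    """Convenience: connectome + cohort from one spec."""
    c = generate_connectome(spec)
    return c, generate_cohort(spec, c)


def write_dataset(spec: SyntheticSpec, outdir) -> dict[str, str]:
    """Materialize a synthetic study in the same formats the pipeline reads."""
    import os

    os.makedirs(outdir, exist_ok=True)
    c, table = generate_dataset(spec)
    paths = {
        "connectome": os.path.join(outdir, "connectome.tsv"),
        "labels": os.path.join(outdir, "labels.csv"),
        "cohort": os.path.join(outdir, "cohort.csv"),
        "spec": os.path.join(outdir, "synthetic_spec.json"),
    }
    np.savetxt(paths["connectome"], c.weights, delimiter="\t")
    c.region_meta.to_csv(paths["labels"], index=False)
    table.to_csv(paths["cohort"])
    spec.to_json(paths["spec"])
    return paths
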