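"""End-to-end experiment orchestration.

Wires the stages into one reproducible run: simulate (or ingest) a cohort,
obtain the template set, quantify every scan under both template modes
(single normal template vs the 8-template set), and run the cohort-level
statistics. Every artifact embeds the configuration hash and the global
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cs
from .phantom import (
    CohortMixture,
    PhantomSpec,
    category_truth,
    make_anatomy,
    paint_truth,
    painted_template_set,
    simulate_cohort,
    simulate_scan,
)
from .quantify import quantify_scan
from .registration import RegistrationOptions
from .template_builder import TemplateSet, build_template_set
from .voxel_core import ROIMaskSet, VolumetricImage, gaussian_smooth

log = logging.getLogger("datspect")

SETTINGS = [
    (mode, method, char)
    for mode in ("single", "multiple")
    for method in ("HV", "AAL")
    for char in ("min", "mean", "left", "right")
]


@dataclass
class RunConfig:
    """Configuration of one experiment run (YAML-serializable).

    ``phantom_overrides`` / ``mixture_overrides`` patch scalar fields of the
    phantom and cohort-mixture defaults; the ellipsoid geometry itself is
    part of the phantom's documented defaults. ``masks_dir`` optionally
    points at user-supplied template-space masks instead of the synthetic
    anatomy.
    """

    out_dir: str = "runs/experiment"
    seed: int = 0
    n_subjects: int = 60
    build_templates: bool = False
    template_scans_per_category: int = 4
    template_iterations: int = 2
    scalp_fraction: float = 0.5
    phantom_overrides: dict[str, Any] = field(default_factory=dict)
    mixture_overrides: dict[str, Any] = field(default_factory=dict)
    registration_overrides: dict[str, Any] = field(default_factory=dict)
    subsample_reps: int = 200
    subsample_frac: float = 0.9
    bin_width: float = 0.1
    masks_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.masks_dir is not None and not Path(self.masks_dir).is_dir():
            raise FileNotFoundError(f"masks_dir not found: {self.masks_dir}")
        # fail fast on bad overrides, before any compute
        self.phantom()
        self.mixture()
        self.registration()

    def phantom(self) -> PhantomSpec:
        overrides = dict(self.phantom_overrides)
        for key in ("grid_shape", "native_shape", "zoom_range", "scale_range",
                    "scalp_dvr_range"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        return dataclasses.replace(PhantomSpec(), **overrides)

    def mixture(self) -> CohortMixture:
        return dataclasses.replace(CohortMixture(), **self.mixture_overrides)

    def registration(self) -> RegistrationOptions:
        opts = RegistrationOptions()
        for k, v in self.registration_overrides.items():
            if not hasattr(opts, k):
                raise ValueError(f"unknown registration option {k!r}")
            setattr(opts, k, [tuple(lv) for lv in v] if k == "pyramid" else v)
        return opts

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def obtain_templates(
    config: RunConfig,
    spec: PhantomSpec,
    masks: ROIMaskSet,
    seed: int,
) -> TemplateSet:
    """Painted 8-template set, or one built from simulated category scans."""
    if not config.build_templates:
        templates, labels = painted_template_set(spec)
        return TemplateSet(tuple(templates), tuple(labels))
    rng = np.random.default_rng(seed)
    target0 = gaussian_smooth(
        paint_truth(spec, category_truth(spec, "normal")), spec.psf_fwhm_mm
    )
    scans_by_label = {}
    for cat in ("normal", "moderate_right", "strong"):
        for scalp in ("without_scalp", "with_scalp"):
            lst = []
            for _ in range(config.template_scans_per_category):
                truth = category_truth(spec, cat)
                t = dataclasses.replace(
                    truth,
                    true_affine=_small_misalignment(rng, spec),
                    intensity_scale=float(rng.uniform(*spec.scale_range)),
                )
                scan, _ = simulate_scan(spec, t, scalp_on=(scalp == "with_scalp"), rng=rng)
                lst.append(scan)
            scans_by_label[(cat, scalp)] = lst
    return build_template_set(
        scans_by_label, target0, masks,
        iterations=config.template_iterations,
        reg_opts=config.registration(),
    )


def _small_misalignment(rng: np.random.Generator, spec: PhantomSpec):
    from .registration import AffineTransform12

    return AffineTransform12(
        tuple(rng.uniform(-spec.translation_mm, spec.translation_mm, 3)),
        tuple(np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg, 3))),
        tuple(rng.uniform(*spec.zoom_range, 3)),
        tuple(rng.uniform(-spec.shear_max, spec.shear_max, 3)),
    )


def quantify_cohort(
    scans: list[VolumetricImage],
    templates: TemplateSet,
    masks: ROIMaskSet,
    reg_opts: RegistrationOptions | None = None,
    scan_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Quantify every scan under both template modes; one row per record."""
    scan_ids = scan_ids or [f"scan_{i:05d}" for i in range(len(scans))]
    single = templates.single()
    rows = []
    for sid, scan in zip(scan_ids, scans):
        for mode, tgt in (("single", single), ("multiple", list(templates.templates))):
            records, _ = quantify_scan(
                scan, tgt, masks, template_mode=mode, scan_id=sid, reg_opts=reg_opts
            )
            rows.extend(r.as_row() for r in records)
        log.info("quantified %s", sid)
    return pd.DataFrame(rows)


def cohort_summary(
    results: pd.DataFrame,
    subsample_reps: int = 200,
    subsample_frac: float = 0.9,
    bin_width: float = 0.1,
    seed: int = 0,
) -> dict:
    """Histogram fits per setting, cross-table, kappa, and regressions."""
    fits: dict[str, dict] = {}
    for mode, method, char in SETTINGS:
        sel = results[(results.template_mode == mode) & (results.roi_method == method)]
        vals = sel[f"sbr_{char}"].to_numpy()
        try:
            fit = cs.fit_sbr_values(vals, bin_width)
            fits[f"{mode}_{method}_{char}"] = fit.as_dict()
        except cs.FitError as exc:
            fits[f"{mode}_{method}_{char}"] = {"error": str(exc)}

    summary: dict[str, Any] = {"fits": fits}

    # cross-classification of HV minimum SBR: multiple vs single templates
    key_s, key_m = "single_HV_min", "multiple_HV_min"
    if "c" in fits.get(key_s, {}) and "c" in fits.get(key_m, {}):
        hv = results[results.roi_method == "HV"]
        sv = hv[hv.template_mode == "single"].set_index("scan_id")["sbr_min"]
        mv = hv[hv.template_mode == "multiple"].set_index("scan_id")["sbr_min"]
        common = sv.index.intersection(mv.index)
        lab_s = cs.classify(sv.loc[common].to_numpy(), fits[key_s]["c"])
        lab_m = cs.classify(mv.loc[common].to_numpy(), fits[key_m]["c"])
        tab = cs.cross_tab(lab_m, lab_s)
        kappa, se = cs.cohens_kappa(tab["counts"])
        summary["crosstab"] = {
            "counts": tab["counts"].tolist(),
            "percent": tab["percent"].round(1).tolist(),
            "concordance": tab["concordance"],
            "kappa": kappa,
            "kappa_se": se,
        }
        # subsample stability of d for the headline setting
        try:
            mean_d, sd_d, cov = cs.subsample_stability(
                mv.loc[common].to_numpy(), n_rep=subsample_reps,
                frac=subsample_frac, seed=seed, bin_width=bin_width,
            )
            summary["subsample_d"] = {"mean": mean_d, "sd": sd_d, "cov": cov}
        except (cs.FitError, ValueError) as exc:
            summary["subsample_d"] = {"error": str(exc)}

        # SBR vs DET per mode and label; DET(single) vs DET(multiple)
        regs = {}
        det_s = hv[hv.template_mode == "single"].set_index("scan_id")["det"]
        det_m = hv[hv.template_mode == "multiple"].set_index("scan_id")["det"]
        for mode, vals, dets, c in (
            ("single", sv, det_s, fits[key_s]["c"]),
            ("multiple", mv, det_m, fits[key_m]["c"]),
        ):
            labs = cs.classify(vals.loc[common].to_numpy(), c)
            for group in ("normal", "reduced"):
                m = labs == group
                if m.sum() >= 3 and np.std(dets.loc[common].to_numpy()[m]) > 0:
                    r = cs.regress(
                        vals.loc[common].to_numpy()[m],
                        dets.loc[common].to_numpy()[m],
                        with_constant=True,
                    )
                    regs[f"sbr_vs_det_{mode}_{group}"] = dataclasses.asdict(r)
        agree = lab_s == lab_m
        for group in ("normal", "reduced"):
            m = agree & (lab_m == group)
            if m.sum() >= 3:
                r = cs.regress(
                    det_s.loc[common].to_numpy()[m],
                    det_m.loc[common].to_numpy()[m],
                    with_constant=False,
                )
                regs[f"det_single_vs_multiple_{group}"] = dataclasses.asdict(r)
        summary["regressions"] = regs
        summary["mean_det"] = {
            "single_reduced": float(det_s.loc[common].to_numpy()[lab_m == "reduced"].mean())
            if (lab_m == "reduced").any() else None,
            "multiple_reduced": float(det_m.loc[common].to_numpy()[lab_m == "reduced"].mean())
            if (lab_m == "reduced").any() else None,
        }
    return summary


def run_experiment(config: RunConfig) -> dict:
    """Simulate -> templates -> quantify (both modes) -> cohort statistics.

    Writes the manifest, per-scan results CSV, summary JSON and masks under
    ``config.out_dir``; returns the summary dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = {"config_hash": chash, "seed": config.seed}
    log.info("run_experiment start (hash %s, seed %d)", chash, config.seed)

    spec = config.phantom()
    stage = "anatomy"
    try:
        if config.masks_dir:
            masks = ROIMaskSet.load(config.masks_dir)
        else:
            masks, _ = make_anatomy(spec)
        masks.save(out / "masks")

        stage = "templates"
        templates = obtain_templates(config, spec, masks, config.seed + 1)

        stage = "simulate"
        scans, truths, manifest = simulate_cohort(
            spec, config.n_subjects, config.mixture(),
            seed=config.seed, scalp_fraction=config.scalp_fraction,
        )
        for k, v in stamp.items():
            manifest[k] = v
        manifest.to_csv(out / "manifest.csv", index=False)

        stage = "quantify"
        results = quantify_cohort(
            scans, templates, masks, config.registration(),
            scan_ids=list(manifest.scan_id),
        )
        for k, v in stamp.items():
            results[k] = v
        results.to_csv(out / "results.csv", index=False)

        stage = "cohort_stats"
        summary = cohort_summary(
            results, config.subsample_reps, config.subsample_frac,
            config.bin_width, config.seed,
        )
        summary.update(stamp)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    log.info("run_experiment done -> %s", out)
    return summary
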