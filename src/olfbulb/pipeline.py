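"""End-to-end study orchestration.

``run_study`` chains generate -> volumetry -> scores -> prep -> train ->
evaluate -> saliency -> stats on one phantom cohort, with a single global
seed propagated to every stochastic stage, per-stage toggles, and a JSON
manifest recording each stage's outputs (with content hashes) and wall
time.  ``validate_config`` normalises a nested config dict against the
documented defaults (batch 32, 100 epochs, learning rate 3e-4, momentum 0,
25 augmentations per scan, 150 px crop) and reports every invalid field by
path instead of raising.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import cohort as coh
from . import volumetry as volm
from . import psychophysics as psy
from . import prep as prp
from . import cnn
from . import evaluation as evl
from . import saliency as sal
from . import stats as st

STAGES = ("generate", "volumetry", "scores", "prep", "train",
          "evaluate", "saliency", "stats")

DEFAULTS: dict = {
    "seed": 0,
    "cohort": {
        "n_pd": 15, "n_npod": 15, "n_control": 15,
        "slices_per_subject_range": [5, 9],
        "bulb_volume_means": {"control": 55.0, "PD": 37.0, "NPOD": 37.0},
        "bulb_volume_sd": 8.0, "surround_effect": 1.0, "noise_sd": 6.0,
        "pixel_spacing": 0.2, "slice_thickness": 2.0,
        "raster_shape": [672, 896],
    },
    "prep": {"crop_size": 150, "image_size": None, "n_aug": 25,
             "ratios": [3, 1, 1]},
    "train": {"batch_size": 32, "epochs": 100, "learning_rate": 0.0003,
              "momentum": 0.0, "channels": 3},
    "saliency": {"threshold_quantile": 0.8},
    "stages": {s: True for s in STAGES},
}

_POSITIVE_FIELDS = {
    ("train", "batch_size"), ("train", "epochs"), ("prep", "crop_size"),
    ("prep", "n_aug"), ("cohort", "pixel_spacing"), ("cohort", "slice_thickness"),
}
_NONNEGATIVE_FIELDS = {
    ("train", "learning_rate"), ("train", "momentum"), ("cohort", "noise_sd"),
    ("cohort", "n_pd"), ("cohort", "n_npod"), ("cohort", "n_control"),
}


def validate_config(config: dict | None):
    """Normalise ``config`` against the defaults.

    Returns ``(normalized, errors, warnings)``: every invalid field
    contributes one error string naming its path; unknown keys produce
    warnings, not errors.
    """
    config = config or {}
    normalized = copy.deepcopy(DEFAULTS)
    errors: list[str] = []
    warnings: list[str] = []

    def merge(dst, src, path=""):
        for key, val in src.items():
            here = f"{path}{key}"
            if key not in dst:
                warnings.append(f"unknown key: {here}")
                continue
            if isinstance(dst[key], dict) and isinstance(val, dict):
                merge(dst[key], val, here + ".")
            else:
                dst[key] = val

    merge(normalized, config)

    for section, key in _POSITIVE_FIELDS:
        v = normalized[section][key]
        if not isinstance(v, (int, float)) or v <= 0:
            errors.append(f"{section}.{key}: must be > 0 (got {v!r})")
    for section, key in _NONNEGATIVE_FIELDS:
        v = normalized[section][key]
        if not isinstance(v, (int, float)) or v < 0:
            errors.append(f"{section}.{key}: must be >= 0 (got {v!r})")
    se = normalized["cohort"]["surround_effect"]
    if not isinstance(se, (int, float)) or not (0.0 <= se <= 1.0):
        errors.append(f"cohort.surround_effect: must be in [0, 1] (got {se!r})")
    q = normalized["saliency"]["threshold_quantile"]
    if not isinstance(q, (int, float)) or not (0.0 < q < 1.0):
        errors.append(f"saliency.threshold_quantile: must be in (0, 1) (got {q!r})")
    return normalized, errors, warnings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_study(config: dict | None, out_dir: str | Path) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    config, errors, warnings = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages_on = config["stages"]
    manifest: dict = {"config": config, "warnings": warnings, "stages": {}}
    state: dict = {}

    def record(stage, t0, files):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
        }

    def fail(stage, exc):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if stages_on.get("generate"):
        t0 = time.time()
        try:
            cc = config["cohort"]
            cohort = coh.generate_cohort(coh.CohortConfig(
                n_pd=cc["n_pd"], n_npod=cc["n_npod"], n_control=cc["n_control"],
                slices_per_subject_range=tuple(cc["slices_per_subject_range"]),
                bulb_volume_means=dict(cc["bulb_volume_means"]),
                bulb_volume_sd=cc["bulb_volume_sd"],
                surround_effect=cc["surround_effect"], noise_sd=cc["noise_sd"],
                pixel_spacing=cc["pixel_spacing"],
                slice_thickness=cc["slice_thickness"],
                raster_shape=tuple(cc["raster_shape"]), seed=seed,
            ))
            state["cohort"] = cohort
            coh.write_cohort(cohort, out / "cohort")
            files = [out / "cohort" / "cohort.csv"]
        except Exception as exc:  # noqa: BLE001 - stage boundary
            fail("generate", exc)
        record("generate", t0, files)

    if stages_on.get("volumetry") and "cohort" in state:
        t0 = time.time()
        try:
            vols = volm.subject_volumes(state["cohort"])
            state["volumes"] = vols
            path = out / "volumes.csv"
            vols.to_csv(path, index=False)
        except Exception as exc:
            fail("volumetry", exc)
        record("volumetry", t0, [path])

    if stages_on.get("scores") and "cohort" in state:
        t0 = time.time()
        try:
            scores = psy.score_cohort(state["cohort"], seed=seed)
            state["scores"] = scores
            path = out / "scores.csv"
            scores.to_csv(path, index=False)
        except Exception as exc:
            fail("scores", exc)
        record("scores", t0, [path])

    if stages_on.get("prep") and "cohort" in state:
        t0 = time.time()
        try:
            cohort = state["cohort"]
            pc = config["prep"]
            patients = cohort.subjects_in("PD", "NPOD")
            assignment = prp.subject_split(
                [s.subject_id for s in patients], [s.group for s in patients],
                ratios=tuple(pc["ratios"]), seed=seed)
            aug_cfg = prp.AugmentConfig(n_per_scan=pc["n_aug"], seed=seed)
            state["dataset"] = prp.build_dataset(
                cohort, assignment, crop_size=pc["crop_size"],
                image_size=pc["image_size"], augment_config=aug_cfg,
                channels=config["train"]["channels"])
            state["assignment"] = assignment
            path = out / "split.csv"
            with open(path, "w") as fh:
                fh.write("subject_id,partition\n")
                for sid, part in sorted(assignment.items()):
                    fh.write(f"{sid},{part}\n")
        except Exception as exc:
            fail("prep", exc)
        record("prep", t0, [path])

    if stages_on.get("train") and "dataset" in state:
        t0 = time.time()
        try:
            tc = config["train"]
            xtr, ytr, _ = state["dataset"]["train"]
            xval, yval, _ = state["dataset"]["validation"]
            size = xtr.shape[1]
            model = cnn.SmallCNN(cnn.ArchitectureSpec(
                input_size=(size, size), channels=tc["channels"]), seed=seed)
            history = cnn.train(model, xtr, ytr, cnn.TrainConfig(
                batch_size=tc["batch_size"], epochs=tc["epochs"],
                learning_rate=tc["learning_rate"], momentum=tc["momentum"],
                seed=seed), xval, yval)
            state["model"] = model
            path = out / "history.csv"
            with open(path, "w") as fh:
                fh.write("epoch,loss,accuracy,val_loss,val_accuracy\n")
                for i in range(len(history.loss)):
                    vl = history.val_loss[i] if history.val_loss else ""
                    va = history.val_accuracy[i] if history.val_accuracy else ""
                    fh.write(f"{i + 1},{history.loss[i]:.6f},{history.accuracy[i]:.6f},{vl},{va}\n")
        except Exception as exc:
            fail("train", exc)
        record("train", t0, [path])

    if stages_on.get("evaluate") and "model" in state:
        t0 = time.time()
        try:
            import pandas as pd

            xte, yte, sids = state["dataset"]["test"]
            _, pred = state["model"].predict(xte)
            names = np.where(pred == 1, "PD", "NPOD")
            truth = np.where(yte == 1, "PD", "NPOD")
            table = pd.DataFrame({"subject_id": sids, "true": truth, "predicted": names})
            state["test_table"] = table
            report, errors_by_class = evl.scan_table_report(table)
            path = out / "metrics.csv"
            with open(path, "w") as fh:
                fh.write("metric,value\n")
                for name in ("accuracy", "precision", "recall", "specificity", "f1"):
                    fh.write(f"{name},{getattr(report, name)}\n")
                for klass, cnt in errors_by_class.items():
                    fh.write(f"misdiagnosed_{klass},{cnt}\n")
        except Exception as exc:
            fail("evaluate", exc)
        record("evaluate", t0, [path])

    if stages_on.get("saliency") and "model" in state:
        t0 = time.time()
        try:
            from PIL import Image

            model = state["model"]
            xte, yte, _ = state["dataset"]["test"]
            _, pred = model.predict(xte)
            size = xte.shape[1]
            centre = (size / 2.0, size / 2.0)  # crops are bulb-centred
            maps = [
                sal.gradcam(model, xte[i], int(yte[i]), anchor=centre)
                for i in range(len(xte)) if pred[i] == yte[i]
            ]
            files = []
            if maps:
                group_map = sal.average_saliency(
                    maps, threshold_quantile=config["saliency"]["threshold_quantile"])
                for name, arr in (("saliency_mean.png", group_map.mean),
                                  ("saliency_mask.png", group_map.mask.astype(float))):
                    p = out / name
                    Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(p)
                    files.append(p)
        except Exception as exc:
            fail("saliency", exc)
        record("saliency", t0, files)

    if stages_on.get("stats") and "volumes" in state:
        t0 = time.time()
        try:
            results = st.mixed_anova(state["volumes"])
            path = out / "anova.csv"
            st.anova_table(results).to_csv(path, index=False)
            files = [path]
            if "scores" in state:
                merged = state["volumes"].groupby("subject_id").agg(
                    volume=("volume_mm3", "mean")).join(
                    state["scores"].set_index("subject_id")[["TDI"]])
                corr = st.pearson_bonferroni(merged["volume"], merged["TDI"], m=3)
                cpath = out / "correlations.csv"
                with open(cpath, "w") as fh:
                    fh.write("pair,r,p_raw,p_bonferroni,n\n")
                    fh.write(f"mean_volume~TDI,{corr.r},{corr.p_raw},{corr.p_bonferroni},{corr.n}\n")
                files.append(cpath)
        except Exception as exc:
            fail("stats", exc)
        record("stats", t0, files)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
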