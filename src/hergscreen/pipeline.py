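"""Pipeline orchestration: configuration, staging, provenance.

A single YAML-configurable run executes the whole protocol on a synthetic
(or user-supplied) activity dataset: curate -> split -> descriptors ->
train (+FFD) -> pharmacophore classification -> virtual screen -> report.
Every stage writes CSV outputs into the run directory and is recorded in a
manifest (stage order, seeds, package version) for reproducibility.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chemio import ActivityRecord
from .doseresponse import prediction_report
from .pharmacophore import classify_dataset
from .qsar import ffd_select, fit_pls, loo_stats, pca_domain, predict
from .reference_models import final_model
from .screening import curate, diverse_split, virtual_screen
from .synthetic_data import (SarSpec, embed_pharmacophore_actives, feature_pair_descriptor,
                             make_decoys, make_sar_dataset)

STAGES = ("curate", "split", "descriptors", "train", "pharmacophore", "screen", "report")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Every tunable of the protocol, with its working default."""

    out_dir: str = "hergscreen_run"
    n_compounds: int = 60
    noise_sd: float = 0.3
    active_ic50_max: float = 40e-6  # molar
    lipe_min: float = 4.0
    le_min: float = 0.39
    fq_min: float = 1.0
    tolerance: float = 1.0  # pharmacophore distance tolerance, Angstrom
    cutoff_dry: float = -0.5
    cutoff_o: float = -2.6
    cutoff_n1: float = -4.2
    cutoff_tip: float = -0.75
    bin_width: float = 0.4
    n_lv: int = 2
    ffd_cycles: int = 2
    seed_split: int = 1
    seed_conformers: int = 1
    seed_ffd: int = 1
    seed_simulation: int = 1
    clacc: bool = False
    scale: bool = False
    pooled_cell_lines: bool = True
    train_frac: float = 0.8
    n_screen_actives: int = 10
    n_screen_decoys: int = 40

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(open(path)) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _write_csv(path, header, rows):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest.  A stage failure halts the
    run with the stage name while keeping the outputs written so far."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "stages": [], "seeds": {
        "split": config.seed_split, "conformers": config.seed_conformers,
        "ffd": config.seed_ffd, "simulation": config.seed_simulation}}
    stage = "setup"
    try:
        # synthetic activity data with assay provenance tags
        stage = "curate"
        sar = make_sar_dataset(SarSpec(n_compounds=config.n_compounds,
                                       noise_sd=config.noise_sd,
                                       seed=config.seed_simulation))
        records = []
        for mol, pic in zip(sar.molecules, sar.pic50):
            records.append((mol, ActivityRecord(mol.id, 10.0 ** (-pic),
                                                "patch_clamp", "CHO")))
        retained, report = curate(records)
        _write_csv(out / "curation.csv", ["rule", "count"],
                   list(report.counts.items()))
        manifest["stages"].append({"stage": stage, "retained": len(retained)})

        stage = "split"
        train, test, warn = diverse_split(retained, config.train_frac, config.seed_split)
        _write_csv(out / "split.csv", ["id", "subset"],
                   [(r.compound_id, "train") for _, r in train]
                   + [(r.compound_id, "test") for _, r in test])
        manifest["stages"].append({"stage": stage, "train": len(train),
                                   "test": len(test), "warning": warn})

        stage = "descriptors"
        index = {m.id: i for i, m in enumerate(sar.molecules)}
        X_train = np.array([sar.X[index[r.compound_id]] for _, r in train])
        y_train = np.array([r.pic50 for _, r in train])
        X_test = np.array([sar.X[index[r.compound_id]] for _, r in test])
        y_test = np.array([r.pic50 for _, r in test])
        manifest["stages"].append({"stage": stage, "n_variables": X_train.shape[1]})

        stage = "train"
        ffd = ffd_select(X_train, y_train, n_lv=config.n_lv, cycles=config.ffd_cycles,
                         seed=config.seed_ffd, scale=config.scale)
        mask = ffd.mask
        model = fit_pls(X_train[:, mask], y_train, config.n_lv,
                        labels=[sar.labels[j] for j in np.nonzero(mask)[0]],
                        scale=config.scale)
        q2, sdep = loo_stats(X_train[:, mask], y_train, config.n_lv, scale=config.scale)
        model.q2_per_lv, model.sdep_per_lv = q2, sdep
        (out / "pls_model.json").write_text(model.to_json())
        domain = pca_domain(X_train[:, mask])
        manifest["stages"].append({"stage": stage, "n_kept": int(mask.sum()),
                                   "q2": float(q2[-1]), "r2": model.r2,
                                   "sdep": float(sdep[-1])})

        stage = "pharmacophore"
        pharm = final_model(config.tolerance)
        actives = embed_pharmacophore_actives(pharm, config.n_screen_actives,
                                              seed=config.seed_simulation)
        decoys = make_decoys(config.n_screen_decoys, seed=config.seed_simulation)
        labelled = ([(m, ActivityRecord(m.id, 1e-6, "patch_clamp", "CHO"))
                     for m in actives]
                    + [(m, ActivityRecord(m.id, 1e-3, "patch_clamp", "CHO"))
                       for m in decoys])
        stats, skipped = classify_dataset(labelled, pharm, config.active_ic50_max)
        _write_csv(out / "pharmacophore_stats.csv",
                   ["tp", "tn", "fp", "fn", "mcc", "sensitivity", "specificity"],
                   [[stats.tp, stats.tn, stats.fp, stats.fn,
                     f"{stats.mcc:.3f}", f"{stats.sensitivity:.3f}",
                     f"{stats.specificity:.3f}"]])
        manifest["stages"].append({"stage": stage, "mcc": round(stats.mcc, 3)})

        stage = "screen"
        library = actives + decoys

        def descriptor_fn(mol):
            return feature_pair_descriptor(mol), sar.labels

        hits, audit = virtual_screen(library, pharm, model, domain=domain,
                                     descriptor_fn=descriptor_fn)
        _write_csv(out / "screening.csv",
                   ["id", "stage_reached", "matched", "max_deviation",
                    "lipinski", "predicted_pic50", "in_domain", "rank"],
                   [[h.compound_id, h.stage_reached, h.match_result.matched,
                     f"{h.match_result.max_deviation:.3f}"
                     if np.isfinite(h.match_result.max_deviation) else "",
                     h.lipinski_pass,
                     "" if h.predicted_pic50 is None else f"{h.predicted_pic50:.3f}",
                     h.in_domain, h.rank] for h in audit])
        manifest["stages"].append({"stage": stage, "hits": len(hits)})

        stage = "report"
        y_pred = model.predict(X_test[:, mask])
        rows, unmatched = prediction_report(
            {r.compound_id: float(p) for (_, r), p in zip(test, y_pred)},
            {r.compound_id: r.pic50 for _, r in test})
        _write_csv(out / "prediction_report.csv",
                   ["id", "predicted", "experimental", "difference", "outlier"],
                   [[r["id"], f"{r['predicted_pic50']:.3f}",
                     f"{r['experimental_pic50']:.3f}",
                     f"{r['log_unit_difference']:.3f}", r["outlier"]] for r in rows])
        manifest["stages"].append({
            "stage": stage, "n_test": len(rows),
            "outliers": int(sum(r["outlier"] for r in rows))})
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
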