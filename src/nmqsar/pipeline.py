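"""End-to-end orchestration of the 2D and 3D QSAR stages.

A run is described by one :class:`RunConfig`; each stage writes a JSON
report into the output directory and the combined report collects them.
Reports contain no timestamps and are serialised with sorted keys, so a
rerun with the same config and inputs is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

import nmqsar
from nmqsar import chem_data, comsia3d, descriptors, gep_engine, mlr_heuristic, validation
from nmqsar.comsia3d import FIELD_TYPES


class HMConfig(BaseModel):
    max_size: int = 7
    collinearity_max: float = 0.8
    beam: int = 10
    size_choice_delta: float = 0.02
    chosen_size: Optional[int] = None


class GEPStageConfig(BaseModel):
    population_size: int = 50
    max_generations: int = 200
    head_length: int = 8
    n_genes: int = 3


class CoMSIAConfig(BaseModel):
    spacing: float = 2.0
    margin: float = 4.0
    alpha: float = 0.3
    max_components: int = 10
    template: Optional[str] = None  # default: most active compound


class RunConfig(BaseModel):
    """Everything one pipeline run needs; validated up front."""

    stages: list[str] = Field(default_factory=lambda: ["2d", "3d"])
    activities: str
    descriptors: list[str] = Field(default_factory=list)
    molecules: Optional[str] = None
    candidates: Optional[str] = None
    hm: HMConfig = Field(default_factory=HMConfig)
    gep: GEPStageConfig = Field(default_factory=GEPStageConfig)
    comsia: CoMSIAConfig = Field(default_factory=CoMSIAConfig)
    offset: float = 6.0
    seed: int = 0
    output_dir: str = "results"


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _load_molecules(path: str) -> list[comsia3d.Molecule3D]:
    if path.endswith(".sdf"):
        return comsia3d.read_molecules_sdf(path)
    return comsia3d.read_molecules_json(path)


def run_2d_stage(
    dataset: chem_data.Dataset,
    matrix: descriptors.DescriptorMatrix,
    hm: HMConfig,
    gep: GEPStageConfig,
    seed: int,
) -> dict:
    """Transform → heuristic MLR → GEP → validation on one descriptor table."""
    train = dataset.subset("train")
    test = dataset.subset("test")
    Xtr = matrix.rows(train.ids)
    y_tr = train.activities()

    trace = mlr_heuristic.heuristic_search(
        Xtr,
        y_tr,
        max_size=hm.max_size,
        collinearity_max=hm.collinearity_max,
        beam=hm.beam,
        size_choice_delta=hm.size_choice_delta,
        chosen_size=hm.chosen_size,
    )
    chosen = trace.chosen_model

    report: dict = {
        "hm": {
            "chosen_size": trace.chosen_size,
            "model": chosen.to_dict(),
            "size_table": trace.size_table(),
            "correlation_matrix": {
                "names": list(trace.descriptor_names),
                "values": np.round(trace.correlation_matrix, 6).tolist(),
            },
        }
    }

    gep_cfg = gep_engine.GEPConfig(
        population_size=gep.population_size,
        max_generations=gep.max_generations,
        head_length=gep.head_length,
        n_genes=gep.n_genes,
        seed=seed,
    )
    sel = matrix.select(chosen.descriptor_names)
    X_tr_sel = sel.rows(train.ids).values
    X_te_sel = sel.rows(test.ids).values if test.records else None
    gep_res = gep_engine.evolve(
        X_tr_sel, y_tr, X_te_sel, test.activities() if test.records else None, gep_cfg
    )
    report["gep"] = gep_res.to_dict()

    if test.records:
        Xte = matrix.rows(test.ids).select(chosen.descriptor_names).values
        rep = validation.validation_report(
            y_tr, chosen.predict(X_tr_sel), test.activities(), chosen.predict(Xte),
            q2_loo=chosen.r2_cv,
        )
        report["hm_validation"] = rep.to_dict()
    return report


def run_3d_stage(
    dataset: chem_data.Dataset,
    molecules: Sequence[comsia3d.Molecule3D],
    cfg: CoMSIAConfig,
    candidates: Sequence[comsia3d.Molecule3D] = (),
    offset: float = 6.0,
) -> dict:
    """Fields → PLS/LOO → contours → external validation → prediction."""
    by_id = {m.molecule_id: m for m in molecules}
    missing = [cid for cid in dataset.ids if cid not in by_id]
    if missing:
        raise ValueError(f"molecule(s) missing from the 3D input: {missing}")
    mols = [by_id[cid] for cid in dataset.ids]

    grid = comsia3d.build_grid(
        list(mols) + list(candidates), spacing=cfg.spacing, margin=cfg.margin, alpha=cfg.alpha
    )
    train = dataset.subset("train")
    test = dataset.subset("test")
    X_all, labels = comsia3d.stack_fields(mols, grid)
    idx = {cid: k for k, cid in enumerate(dataset.ids)}
    X_tr = X_all[[idx[c] for c in train.ids]]
    y_tr = train.activities()

    model = comsia3d.pls_loo_onc(X_tr, y_tr, max_components=cfg.max_components, field_labels=labels)
    contours, fractions = comsia3d.contour_and_contrib(model, grid)

    report: dict = {
        "grid": {"origin": list(grid.origin), "spacing": grid.spacing,
                 "counts": list(grid.counts), "alpha": grid.alpha},
        "pls": model.to_dict(),
        "field_fractions": fractions,
        "contour_levels": {f: list(contours.levels[f]) for f in FIELD_TYPES},
    }

    if test.records:
        X_te = X_all[[idx[c] for c in test.ids]]
        val = validation.validation_report(
            y_tr, model.predict(X_tr), test.activities(), model.predict(X_te), q2_loo=model.q2
        )
        report["validation"] = val.to_dict()

    if candidates:
        Xc, _ = comsia3d.stack_fields(candidates, grid)
        preds = model.predict(Xc)
        order = np.argsort(-preds, kind="stable")
        report["predictions"] = [
            {
                "name": candidates[i].molecule_id,
                "predicted_activity": float(preds[i]),
                "predicted_ic50_uM": chem_data.inverse_pic50(float(preds[i]), offset),
            }
            for i in order
        ]
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write all reports."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    dataset = chem_data.read_compound_table(config.activities, offset=config.offset)
    combined: dict = {
        "config": json.loads(config.model_dump_json()),
        "package_version": nmqsar.__version__,
        "n_compounds": len(dataset.records),
        "n_train": dataset.n_train,
        "n_test": dataset.n_test,
    }

    for stage in config.stages:
        if stage == "2d":
            if not config.descriptors:
                raise ValueError("stage '2d' needs at least one descriptor table")
            matrix, drop_log = descriptors.assemble_matrix(dataset, imported=config.descriptors)
            rep = run_2d_stage(dataset, matrix, config.hm, config.gep, config.seed)
            rep["descriptor_screening"] = {"kept": len(matrix.names), "dropped": drop_log}
            _write_json(rep, outdir / "report_2d.json")
            combined["2d"] = rep
        elif stage == "3d":
            if not config.molecules:
                raise ValueError("stage '3d' needs a molecules input")
            molecules = _load_molecules(config.molecules)
            candidates = _load_molecules(config.candidates) if config.candidates else []
            rep = run_3d_stage(dataset, molecules, config.comsia, candidates, config.offset)
            _write_json(rep, outdir / "report_3d.json")
            combined["3d"] = rep
        else:
            raise ValueError(f"unknown stage {stage!r} (expected '2d' or '3d')")

    _write_json(combined, outdir / "report.json")
    return combined
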