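"""End-to-end orchestration: configuration, the subset pipeline, reports.

``run_subset`` wires the stages together for one molecular-weight subset:
template selection → pairwise alignment → grid-ESP descriptors → fivefold
external cross-validation of the regression → validation reports, writing
aligned structures and JSON artifacts along the way.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger("alphaq")


@dataclass
class RunConfig:
    """All tunables of the pipeline; defaults are the production protocol
    values (fine grids, 2000 rotations, margin 2.7 Å, M = 3 hidden neurons,
    convergence at F ≤ 1e-4, five folds)."""

    spacing_descriptor: float = 0.212
    spacing_align: float = 0.106
    margin: float = 2.7
    n_rotamers: int = 2000
    m_hidden: int = 3
    f_tol: float = 1e-4
    max_epochs: int = 20000
    learning_rate: float = 0.5
    n_folds: int = 5
    train_frac: float = 0.80
    pca_components: int | None = None
    pca_variance_target: float = 0.95
    charge_mode: str = "partial_charge"
    alignment_charge_mode: str = "promolecule"
    sigma: float = 0.4
    poisson_mode: str = "freespace"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _content_hash(*paths) -> str:
    digest = hashlib.sha256()
    for p in paths:
        digest.update(Path(p).read_bytes())
    return digest.hexdigest()[:16]


def run_subset(config: RunConfig, sdf_path, logbb_csv, out_dir) -> dict:
    """Run the full subset pipeline and write artifacts.

    Writes to ``out_dir``: resolved config, aligned structures (SDF),
    per-fold and summary reports (JSON).  Returns the report dict.
    """
    from . import align3d, chem_io, espgrid, template, validate
    from .annmodel import TrainConfig

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    mols = chem_io.read_molecules(sdf_path, logbb_csv)
    labeled = [m for m in mols if m.logbb is not None]
    if len(labeled) < 10:
        raise ValueError("need at least 10 labeled molecules")
    log.info("stage=read n=%d labeled=%d t=%.1fs",
             len(mols), len(labeled), time.time() - t0)

    charge = espgrid.ChargeModel(mode=config.alignment_charge_mode,
                                 sigma=config.sigma)
    desc_charge = espgrid.ChargeModel(mode=config.charge_mode,
                                      sigma=config.sigma)
    box = espgrid.build_common_box(labeled, spacing=config.spacing_align,
                                   margin=config.margin)
    desc_box = espgrid.build_common_box(
        labeled, spacing=config.spacing_descriptor, margin=config.margin)
    rotamers = align3d.hopf_rotations(config.n_rotamers)
    log.info("stage=setup box=%s desc_box=%s rotamers=%d",
             box.dims, desc_box.dims, len(rotamers))

    # Template on the full labeled subset (reported); cross-validation
    # re-selects per training fold.
    t1 = time.time()
    dm = template.distance_matrix(labeled, box, rotamers, charge,
                                  poisson_mode=config.poisson_mode)
    centrality = template.betweenness_exact(dm)
    dm.to_csv(out / "distance_matrix.csv")
    (out / "centrality.json").write_text(centrality.to_json())
    log.info("stage=template id=%s t=%.1fs",
             centrality.template_id, time.time() - t1)

    t2 = time.time()
    by_id = {m.id: m for m in labeled}
    tmpl = by_id[centrality.template_id]
    tmpl = tmpl.translated(box.center - tmpl.centroid())
    rho_t = espgrid.density_field(tmpl, box, charge)
    phi_t = espgrid.solve_poisson(rho_t, mode=config.poisson_mode)
    aligned = []
    pair_reports = []
    for m in labeled:
        if m.id == centrality.template_id:
            aligned.append(tmpl)
            continue
        res = align3d.align_pair(tmpl, m, box, rotamers, charge,
                                 template_phi=phi_t,
                                 poisson_mode=config.poisson_mode)
        aligned.append(align3d.apply_alignment(m, box, res))
        pair_reports.append({
            "id": m.id,
            "quaternion": res.quaternion.tolist(),
            "translation": res.translation.tolist(),
            "e_ij": res.e_ij,
        })
    chem_io.write_sdf(aligned, out / "aligned.sdf")
    (out / "alignment.json").write_text(json.dumps(pair_reports, indent=1))
    log.info("stage=align n=%d t=%.1fs", len(aligned), time.time() - t2)

    t3 = time.time()
    from .descriptors import esp_vector

    raw = np.array([
        esp_vector(m, desc_box, desc_charge, poisson_mode=config.poisson_mode)
        for m in aligned
    ])
    ids = [m.id for m in aligned]
    y = np.array([m.logbb for m in aligned])
    cfg = TrainConfig(config.f_tol, config.max_epochs, config.learning_rate,
                      seed=config.seed)
    reports, summary = validate.crossvalidate_descriptors(
        raw, ids, y, n_folds=config.n_folds, train_frac=config.train_frac,
        seed=config.seed, cfg=cfg, n_components=config.pca_components,
        variance_target=config.pca_variance_target)
    log.info("stage=cv folds=%d best_r2_test=%.3f t=%.1fs",
             summary["n_folds"], summary["best_r2_test"], time.time() - t3)

    report = {
        "config": dataclasses.asdict(config),
        "inputs_hash": _content_hash(sdf_path, logbb_csv),
        "template_id": centrality.template_id,
        "folds": [dataclasses.asdict(r) for r in reports],
        "summary": summary,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
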