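"""Model validation: R², external predictivity, applicability domain,
Y-scrambling and fivefold external cross-validation.

Statistics follow the standard QSAR validation toolkit:

* R² = 1 − SS_res/SS_tot with SS_tot about the set's own mean (training or
  test set respectively);
* r²_pred = 1 − SS_res(test)/SS about the *training* mean, the external
  predictivity parameter;
* leverage h(x) = xᵀ(XᵀX)⁻¹x on mean-centred projected descriptors, with
  warning leverage h* = 3p/n; a Williams plot flags molecules with
  |standardized residual| > 3 or h > h*;
* Y-scrambling permutes a fraction of the labels and refits, probing for
  chance correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annmodel import ANNModel, TrainConfig, predict, train
from .descriptors import fit_pca, project


@dataclass
class FitReport:
    r2_train: float
    r2_test: float
    r2_pred: float
    fold: int = 0
    n_train: int = 0
    n_test: int = 0
    pearson_r2_train: float | None = None
    pearson_r2_test: float | None = None


@dataclass
class WilliamsData:
    ids: list[str]
    leverage: np.ndarray
    std_residuals: np.ndarray
    h_star: float
    outlier: np.ndarray  # bool: outside applicability domain
    in_domain_fraction: float

    def to_rows(self):
        return [
            {"id": i, "h": float(h), "std_residual": float(r),
             "flag": bool(o)}
            for i, h, r, o in zip(
                self.ids, self.leverage, self.std_residuals, self.outlier)
        ]


def r2(y, y_hat, baseline_mean: float | None = None) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot.

    ``baseline_mean`` sets the centring of SS_tot; by default the mean of
    ``y`` itself (the training-set or test-set convention).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must be equal-length, size >= 2")
    mean = float(np.mean(y)) if baseline_mean is None else float(baseline_mean)
    ss_tot = float(np.sum((y - mean) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero variance about the baseline mean")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def r2_pred(y_test, y_hat_test, y_train_mean: float) -> float:
    """External predictivity: test-set residuals against the training mean."""
    return r2(y_test, y_hat_test, baseline_mean=y_train_mean)


def squared_pearson(y, y_hat) -> float:
    """Squared Pearson correlation, the auxiliary correlation measure."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    r = np.corrcoef(y, y_hat)[0, 1]
    return float(r * r)


def leverage(X_train: np.ndarray, X_query: np.ndarray) -> np.ndarray:
    """Hat-matrix leverages h(x) = xᵀ(XᵀX)⁻¹x with columns centred on the
    training means.  Singular XᵀX falls back to a 1e-8 ridge with a warning."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    n, p = X_train.shape
    if p >= n:
        raise ValueError(
            f"p={p} >= n={n}: leverage undefined; retain fewer PCA components")
    mean = X_train.mean(axis=0)
    Xc = X_train - mean
    Qc = X_query - mean
    G = Xc.T @ Xc
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        warnings.warn("X'X is singular; applying 1e-8 ridge", stacklevel=2)
        Ginv = np.linalg.inv(G + 1e-8 * np.eye(p))
    return np.einsum("ij,jk,ik->i", Qc, Ginv, Qc)


def warning_leverage(p: int, n_train: int) -> float:
    """h* = 3p/n."""
    return 3.0 * p / n_train


def williams(
    ids,
    X_train: np.ndarray,
    X_query: np.ndarray,
    y: np.ndarray,
    y_hat: np.ndarray,
    p: int,
    train_residual_sd: float | None = None,
) -> WilliamsData:
    """Williams applicability-domain data for the queried molecules.

    Residuals are standardized by the training residual SD (pass it when
    scoring test molecules; defaults to the SD of the given residuals).
    A molecule is out of domain iff |std residual| > 3 or h > h* = 3p/n.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    res = y - y_hat
    sd = float(np.std(res)) if train_residual_sd is None else train_residual_sd
    std_res = res / sd if sd > 0 else np.zeros_like(res)
    h = leverage(X_train, X_query)
    h_star = warning_leverage(p, len(X_train))
    outlier = (np.abs(std_res) > 3.0) | (h > h_star)
    return WilliamsData(
        ids=list(ids),
        leverage=h,
        std_residuals=std_res,
        h_star=h_star,
        outlier=outlier,
        in_domain_fraction=float(np.mean(~outlier)),
    )


@dataclass
class QsarDataset:
    """Descriptors and labels of one subset, with a train/test split.

    ``raw`` holds the K-dimensional ESP vectors; PCA and the network are
    (re)fitted on the training rows only.
    """

    ids: list[str]
    raw: np.ndarray
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError("train and test indices overlap")


def fit_and_report(
    ds: QsarDataset,
    cfg: TrainConfig = TrainConfig(),
    n_components: int | None = None,
    variance_target: float = 0.95,
    fold: int = 0,
    m_hidden: int = 3,
    use_bias: bool = False,
):
    """PCA (training rows) → ANN → FitReport; returns (report, model, pca)."""
    X_tr_raw = ds.raw[ds.train_idx]
    X_te_raw = ds.raw[ds.test_idx]
    y_tr = ds.y[ds.train_idx]
    y_te = ds.y[ds.test_idx]
    pca = fit_pca(X_tr_raw, n_components=n_components,
                  variance_target=variance_target)
    X_tr = project(pca, X_tr_raw)
    X_te = project(pca, X_te_raw)
    model = train(X_tr, y_tr, cfg, m_hidden=m_hidden, use_bias=use_bias)
    yhat_tr = predict(model, X_tr)
    yhat_te = predict(model, X_te)
    report = FitReport(
        r2_train=r2(y_tr, yhat_tr),
        r2_test=r2(y_te, yhat_te),
        r2_pred=r2_pred(y_te, yhat_te, float(np.mean(y_tr))),
        fold=fold,
        n_train=len(y_tr),
        n_test=len(y_te),
        pearson_r2_train=squared_pearson(y_tr, yhat_tr),
        pearson_r2_test=squared_pearson(y_te, yhat_te),
    )
    return report, model, pca


def y_scramble(
    ds: QsarDataset,
    fraction: float = 0.10,
    seed: int = 0,
    cfg: TrainConfig = TrainConfig(),
    n_components: int | None = None,
    variance_target: float = 0.95,
) -> FitReport:
    """Permute a random ⌈fraction·n⌉-subset of the labels among themselves
    (descriptors unchanged), refit, and report the statistics."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(ds.y)
    k = int(np.ceil(fraction * n))
    if k < 2:
        warnings.warn(
            "fewer than 2 labels selected: the identity permutation is "
            "possible", stacklevel=2)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=k, replace=False)
    perm = rng.permutation(k)
    y_scr = ds.y.copy()
    y_scr[chosen] = y_scr[chosen[perm]]
    scrambled = QsarDataset(ds.ids, ds.raw, y_scr, ds.train_idx, ds.test_idx)
    report, _, _ = fit_and_report(
        scrambled, cfg, n_components=n_components,
        variance_target=variance_target)
    return report


def crossvalidate(
    mols,
    box,
    rotamers,
    charge_model,
    descriptor_box=None,
    n_folds: int = 5,
    train_frac: float = 0.80,
    seed: int = 0,
    cfg: TrainConfig = TrainConfig(),
    n_components: int | None = None,
    variance_target: float = 0.95,
    poisson_mode: str = "freespace",
):
    """Fivefold external cross-validation, end to end.

    Per fold: random train/test resample → template selection on the
    training molecules (distance matrix + betweenness) → alignment of every
    molecule to the template → ESP descriptors → PCA (training rows) → ANN →
    FitReport.  Returns (reports, summary); the summary names the best fold
    by r2_test, mirroring the practice of presenting the best of the five
    resamples.
    """
    from .align3d import align_pair, apply_alignment
    from .chem_io import make_folds
    from .descriptors import esp_vector
    from .espgrid import density_field, solve_poisson
    from .template import betweenness_exact, distance_matrix, select_template

    if len(mols) < 10:
        raise ValueError("need at least 10 molecules for cross-validation")
    if any(m.logbb is None for m in mols):
        raise ValueError("all molecules need LogBB labels")
    desc_box = descriptor_box if descriptor_box is not None else box
    by_id = {m.id: m for m in mols}
    ids = [m.id for m in mols]
    y_by_id = {m.id: m.logbb for m in mols}
    reports = []
    for split in make_folds(ids, n_folds=n_folds, train_frac=train_frac,
                            seed=seed):
        y_tr = np.array([y_by_id[i] for i in split.train_ids])
        if np.ptp(y_tr) == 0.0:
            warnings.warn(f"fold {split.fold}: constant training labels, "
                          "skipped", stacklevel=2)
            continue
        train_mols = [by_id[i] for i in split.train_ids]
        dm = distance_matrix(train_mols, box, rotamers, charge_model,
                             poisson_mode=poisson_mode)
        template_id = select_template(betweenness_exact(dm))
        template = by_id[template_id]
        template = template.translated(box.center - template.centroid())
        rho_t = density_field(template, box, charge_model)
        phi_t = solve_poisson(rho_t, mode=poisson_mode)
        aligned = {}
        for mol_id in ids:
            if mol_id == template_id:
                aligned[mol_id] = template
                continue
            res = align_pair(template, by_id[mol_id], box, rotamers,
                             charge_model, template_phi=phi_t,
                             poisson_mode=poisson_mode)
            aligned[mol_id] = apply_alignment(by_id[mol_id], box, res)
        raw = np.array([
            esp_vector(aligned[i], desc_box, charge_model,
                       poisson_mode=poisson_mode)
            for i in ids
        ])
        id_pos = {i: k for k, i in enumerate(ids)}
        ds = QsarDataset(
            ids, raw, np.array([y_by_id[i] for i in ids]),
            np.array([id_pos[i] for i in split.train_ids]),
            np.array([id_pos[i] for i in split.test_ids]),
        )
        fold_cfg = TrainConfig(cfg.f_tol, cfg.max_epochs, cfg.learning_rate,
                               seed=cfg.seed + split.fold)
        report, _, _ = fit_and_report(
            ds, fold_cfg, n_components=n_components,
            variance_target=variance_target, fold=split.fold)
        reports.append(report)
    if not reports:
        raise ValueError("all folds degenerate")
    best = max(reports, key=lambda r: r.r2_test)
    summary = {
        "n_folds": len(reports),
        "best_fold": best.fold,
        "best_r2_test": best.r2_test,
        "mean_r2_test": float(np.mean([r.r2_test for r in reports])),
        "mean_r2_pred": float(np.mean([r.r2_pred for r in reports])),
    }
    return reports, summary


def crossvalidate_descriptors(
    ds_full_raw: np.ndarray,
    ids: list[str],
    y: np.ndarray,
    n_folds: int = 5,
    train_frac: float = 0.80,
    seed: int = 0,
    cfg: TrainConfig = TrainConfig(),
    n_components: int | None = None,
    variance_target: float = 0.95,
):
    """Fivefold external cross-validation on precomputed descriptors.

    Each fold is an independent random resample at ``train_frac``; folds
    with degenerate labels are skipped with a warning.  Returns
    (list of FitReport, summary dict with the best fold by r2_test).
    """
    from .chem_io import make_folds

    if len(y) < 10:
        raise ValueError("need at least 10 molecules for cross-validation")
    id_pos = {i: k for k, i in enumerate(ids)}
    reports = []
    for split in make_folds(ids, n_folds=n_folds, train_frac=train_frac,
                            seed=seed):
        tr = np.array([id_pos[i] for i in split.train_ids])
        te = np.array([id_pos[i] for i in split.test_ids])
        if np.ptp(np.asarray(y)[tr]) == 0.0:
            warnings.warn(f"fold {split.fold}: constant training labels, "
                          "skipped", stacklevel=2)
            continue
        ds = QsarDataset(ids, ds_full_raw, y, tr, te)
        fold_cfg = TrainConfig(cfg.f_tol, cfg.max_epochs, cfg.learning_rate,
                               seed=cfg.seed + split.fold)
        report, _, _ = fit_and_report(
            ds, fold_cfg, n_components=n_components,
            variance_target=variance_target, fold=split.fold)
        reports.append(report)
    if not reports:
        raise ValueError("all folds degenerate")
    best = max(reports, key=lambda r: r.r2_test)
    summary = {
        "n_folds": len(reports),
        "best_fold": best.fold,
        "best_r2_test": best.r2_test,
        "mean_r2_test": float(np.mean([r.r2_test for r in reports])),
        "mean_r2_pred": float(np.mean([r.r2_pred for r in reports])),
    }
    return reports, summary
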