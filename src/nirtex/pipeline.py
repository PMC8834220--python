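"""End-to-end calibration workflow.

Per target parameter (TSS, BS, BH, BCh, BCo) the pipeline runs: replicate
averaging -> pre-treatment selection -> Mahalanobis screen on PCA scores ->
PLS robust-limit screen -> outlier removal -> Kennard-Stone 80/20 split on
min-max data -> full-spectrum PLS, beta-selected PLS and an ANN on the
selected (optionally diameter-augmented) predictors -> R²/RMSE/bias/RPD on
the cross-validated training set and the external test set.

Every fitted constant (pre-treatment constants, min-max ranges, selection,
critical limits) derives from training rows only once the split exists;
screening stages run before the split, on the full sample, as screening
must.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import syndata
from .ann import ANNSpec, build_ann, predict_ann, prepare_inputs, train_ann
from .evalsplit import kennard_stone, metrics
from .outliers import critical_limits, mahalanobis_flag, pca_fit, pls_distances
from .pls_core import fit_simpls, jackknife_beta, loo_cv, predict
from .preprocess import Pretreatment, fit_apply_scaler
from .spectra_io import SpectraSet, average_replicates, write_spectra
from .syndata import (BandLibrary, LinkSpec, NoiseModel, StudyDesign,
                      generate_study, records_to_frame)
from .varsel import augment, beta_select

log = logging.getLogger("nirtex.pipeline")

__all__ = ["PipelineConfig", "select_pretreatment", "calibrate_response",
           "run_calibration", "make_fixture", "DEFAULT_PRETREATMENTS"]

#: Pinned per-response pre-treatment defaults: SNV + mean center for the
#: TSS / springiness / chewiness / cohesiveness models, mean center alone
#: for hardness.
DEFAULT_PRETREATMENTS = {
    "tss": ["snv", "mean_center"],
    "bs": ["snv", "mean_center"],
    "bh": ["mean_center"],
    "bch": ["snv", "mean_center"],
    "bco": ["snv", "mean_center"],
}

#: Texture responses get the equatorial diameter appended as an extra
#: predictor for the ANN; gumminess is generated but never modeled.
AUGMENT_DIAMETER = {"bs", "bh", "bch", "bco"}


@dataclass
class PipelineConfig:
    spectra_csv: str | None = None
    references_csv: str | None = None
    synthetic: bool = True
    design: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    link: dict = field(default_factory=dict)
    responses: tuple = ("tss", "bs")
    pretreatments: dict = field(default_factory=lambda: dict(DEFAULT_PRETREATMENTS))
    candidate_pretreatments: tuple = (("mean_center",), ("snv", "mean_center"))
    mahalanobis_alpha: float = 0.01
    limits_alpha: float = 0.01
    screen_components: int = 5
    a_max: int = 12
    split_fraction: float = 0.8
    selection_p_threshold: float = 0.05
    magnitude_rule: str = "extrema"
    scaler_fit: str = "train"       # 'train' | 'all'
    models: tuple = ("pls_full", "pls_selected", "ann")
    ann_epochs: int = 1000
    ann_l1: float = 1e-4
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.scaler_fit not in ("train", "all"):
            raise ValueError("scaler_fit must be 'train' or 'all'")
        for r in self.responses:
            if r == "bg":
                raise ValueError("gumminess is not modeled; use chewiness (bch)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("responses", "models", "candidate_pretreatments"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(tuple(x) if isinstance(x, list) else x for x in raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["responses"] = list(d["responses"])
        d["models"] = list(d["models"])
        d["candidate_pretreatments"] = [list(c) for c in d["candidate_pretreatments"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def select_pretreatment(raw: SpectraSet, candidates, design_labels,
                        silhouette_threshold: float = 0.25) -> list[dict]:
    """Rank candidate pre-treatments by PC1+PC2 cumulative variance and flag
    any whose first-two-PC scores discriminate the experimental design.

    Discrimination is tested with the mean silhouette of the block labels on
    the PC1-PC2 scores; candidates above the threshold are flagged and
    excluded from the ranking (a pre-treatment that reveals the sampling
    design rather than the chemistry would bias the calibration).
    """
    from sklearn.metrics import silhouette_score

    labels = np.asarray(design_labels)
    if len(candidates) == 0:
        raise ValueError("no candidate pre-treatments")
    results = []
    for cand in candidates:
        pt = cand if isinstance(cand, Pretreatment) else Pretreatment(list(cand))
        fitted = pt.fit(raw)
        treated = fitted.train_result
        X = treated.absorbance if isinstance(treated, SpectraSet) else treated
        pca = pca_fit(X, k=2)
        cumvar = float(pca.cumulative[-1])
        if len(np.unique(labels)) > 1:
            sil = float(silhouette_score(pca.scores, labels))
        else:
            sil = 0.0
        results.append({"pretreatment": pt, "name": pt.name,
                        "cumulative_variance": cumvar, "silhouette": sil,
                        "flagged": sil > silhouette_threshold})
    ok = [r for r in results if not r["flagged"]]
    if not ok:
        sils = {r["name"]: r["silhouette"] for r in results}
        raise ValueError(f"every candidate discriminates the design: {sils}")
    ok.sort(key=lambda r: -r["cumulative_variance"])
    flagged = [r for r in results if r["flagged"]]
    return ok + flagged


def _response_vector(refs: pd.DataFrame, response: str) -> np.ndarray:
    if response not in refs.columns:
        raise ValueError(f"reference table has no column {response!r}")
    return refs[response].to_numpy(dtype=float)


def calibrate_response(
    avg: SpectraSet,
    refs: pd.DataFrame,
    response: str,
    config: PipelineConfig,
) -> dict:
    """Run screening, split, selection and all models for one response.

    ``avg`` holds berry-level (replicate-averaged) spectra; ``refs`` is the
    berry reference table indexed like ``avg.sample_ids``.
    """
    y_all = _response_vector(refs, response)
    n0 = avg.n_samples

    # --- pre-treatment (pinned per response, or ranked selection) ----------
    steps = config.pretreatments.get(response)
    if steps is None:
        ranking = select_pretreatment(
            avg, config.candidate_pretreatments, refs["block"].to_numpy()
        )
        pt = ranking[0]["pretreatment"]
    else:
        pt = Pretreatment(list(steps))
    fitted_screen = pt.fit(avg)
    treated = fitted_screen.train_result
    Xp = treated.absorbance

    # --- screen 1: Mahalanobis on PCA scores -------------------------------
    full_pca = pca_fit(Xp, k=min(Xp.shape[0] - 1, Xp.shape[1], 30))
    k = int(np.searchsorted(full_pca.cumulative, 0.95) + 1)
    k = min(max(k, 2), full_pca.scores.shape[1])
    while k > 1 and full_pca.explained_ratio[k - 1] < 1e-8 * full_pca.explained_ratio[0]:
        k -= 1  # drop numerically null PCs (degenerate at zero noise)
    mflags, d2 = mahalanobis_flag(full_pca.scores[:, :k], alpha=config.mahalanobis_alpha)

    # --- screen 2: PLS residual distances with robust limits ----------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screen_model = fit_simpls(Xp, y_all, config.screen_components)
    dist = pls_distances(screen_model, Xp)
    robust = critical_limits(dist, approach="robust", alpha=config.limits_alpha)
    removed_mask = mflags | robust.flags
    removed_ids = [avg.sample_ids[i] for i in np.flatnonzero(removed_mask)]
    provenance = {
        avg.sample_ids[i]: ("mahalanobis" if mflags[i] else "")
        + ("+" if mflags[i] and robust.flags[i] else "")
        + ("pls_robust" if robust.flags[i] else "")
        for i in np.flatnonzero(removed_mask)
    }
    keep = ~removed_mask
    X_screen = Xp[keep]
    raw_clean = avg.absorbance[keep]
    y = y_all[keep]
    refs_clean = refs.iloc[np.flatnonzero(keep)]
    n_clean = X_screen.shape[0]
    log.info("response=%s n_raw=%d n_after_outliers=%d removed=%d",
             response, n0, n_clean, int(removed_mask.sum()))

    # --- Kennard-Stone split on min-max data --------------------------------
    # distances use the all-row screening pre-treatment under an all-row
    # min-max (a metric choice only; no response labels are involved)
    span = X_screen.max(axis=0) - X_screen.min(axis=0)
    ks_cols = span > 0
    X_ks = (X_screen[:, ks_cols] - X_screen[:, ks_cols].min(axis=0)) / span[ks_cols]
    split = kennard_stone(X_ks, fraction=config.split_fraction)
    tr, te = split.train, split.test

    # --- model-stage constants: fitted on training rows only ----------------
    fit_rows = np.arange(n_clean) if config.scaler_fit == "all" else tr
    model_pt = pt.fit(raw_clean[fit_rows])
    X_model = model_pt.apply(raw_clean)
    span_tr = X_model[fit_rows].max(axis=0) - X_model[fit_rows].min(axis=0)
    cols = span_tr > 0  # drop train-constant columns (possible at zero noise)
    X_model = X_model[:, cols]
    grid_kept = avg.grid[cols]
    _, scaler = fit_apply_scaler(X_model[fit_rows], mode="minmax")
    Xs = scaler.apply(X_model)
    Xtr, Xte = Xs[tr], Xs[te]
    ytr, yte = y[tr], y[te]

    a_max = min(config.a_max, len(tr) - 2, Xtr.shape[1])
    out: dict = {
        "response": response,
        "pretreatment": pt.name,
        "n_raw": n0,
        "n_after_outliers": n_clean,
        "removed_ids": removed_ids,
        "removal_provenance": provenance,
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
        "train_ids": [refs_clean.index[i] for i in tr],
        "models": {},
        "scaler": scaler,
        "model_pretreatment": model_pt,
    }

    # --- model 1: PLS on the full spectrum ----------------------------------
    cv_full = loo_cv(Xtr, ytr, a_max)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls_full = fit_simpls(Xtr, ytr, cv_full.selected)
    dd_limits = critical_limits(pls_distances(pls_full, Xtr),
                                approach="data_driven", alpha=config.limits_alpha)
    if "pls_full" in config.models:
        out["models"]["pls_full"] = {
            "n_components": pls_full.n_components,
            "training_cv": metrics(ytr, cv_full.loo_predictions),
            "external": metrics(yte, predict(pls_full, Xte)),
            "data_driven_limits": dd_limits,
        }

    # --- wavelength selection on the training rows --------------------------
    jk = jackknife_beta(Xtr, ytr, pls_full.n_components)
    try:
        sel = beta_select(jk, pls_full, p_threshold=config.selection_p_threshold,
                          magnitude_rule=config.magnitude_rule)
        out_sel_note = "significant"
    except ValueError:
        # no-signal response (e.g. cohesiveness): nothing passes the
        # significance screen; keep the beta-curve extrema alone so the
        # model comparison can still be reported
        log.warning("response=%s: no coefficient significant at p<%.3g; "
                    "falling back to beta-curve extrema without the p screen",
                    response, config.selection_p_threshold)
        sel = beta_select(jk, pls_full, p_threshold=np.inf,
                          magnitude_rule=config.magnitude_rule)
        out_sel_note = "extrema_only_no_significance"
    sel_idx = sel.indices
    out["selection_note"] = out_sel_note
    out["selected_indices"] = sel_idx
    out["selected_wavenumbers"] = grid_kept[sel_idx]
    out["n_selected"] = int(sel_idx.size)

    # --- model 2: PLS on the selected wavenumbers ---------------------------
    if "pls_selected" in config.models:
        Xtr_s, Xte_s = Xtr[:, sel_idx], Xte[:, sel_idx]
        a_sel = min(a_max, Xtr_s.shape[1])
        cv_sel = loo_cv(Xtr_s, ytr, a_sel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls_sel = fit_simpls(Xtr_s, ytr, cv_sel.selected)
        out["models"]["pls_selected"] = {
            "n_components": pls_sel.n_components,
            "training_cv": metrics(ytr, cv_sel.loo_predictions),
            "external": metrics(yte, predict(pls_sel, Xte_s)),
        }

    # --- model 3: ANN on selected (+ diameter) predictors -------------------
    if "ann" in config.models:
        X_ann = X_model[:, sel_idx]
        if response in AUGMENT_DIAMETER and "diameter" in refs_clean.columns:
            X_ann = augment(X_ann, refs_clean["diameter"].to_numpy(dtype=float))
            out["ann_augmented"] = True
        else:
            out["ann_augmented"] = False
        _, ann_scaler = fit_apply_scaler(X_ann[fit_rows], mode="minmax")
        Xa = ann_scaler.apply(X_ann)
        spec = ANNSpec(
            n_predictors=Xa.shape[1], epochs=config.ann_epochs,
            l1_lambda=config.ann_l1, seed=config.seed,
        )
        net = build_ann(spec)
        Xa_in = prepare_inputs(Xa, spec)
        history = train_ann(net, Xa_in[tr], ytr, spec)
        # inner-validation rows of the training set, at the restored weights
        rng = np.random.default_rng(spec.seed + 1)
        perm = rng.permutation(len(tr))
        n_val = max(int(round(spec.validation_split * len(tr))), 1)
        val_rows = tr[perm[:n_val]]
        out["models"]["ann"] = {
            "widths": (spec.input_width, spec.hidden_width, 1),
            "best_epoch": history.best_epoch,
            "training_cv": metrics(y[val_rows], predict_ann(net, Xa_in[val_rows])),
            "external": metrics(yte, predict_ann(net, Xa_in[te])),
        }
        out["ann_scaler"] = ann_scaler

    return out


def _load_inputs(config: PipelineConfig):
    if config.synthetic or config.spectra_csv is None:
        d = dict(config.design)
        n_grid = d.pop("n_grid", None)
        design = StudyDesign(seed=config.seed, **d)
        noise = NoiseModel(**config.noise)
        link = LinkSpec(**config.link)
        grid = syndata.default_grid(n_grid) if n_grid else None
        spectra, records = generate_study(design, BandLibrary(), noise, link, grid=grid)
        refs = records_to_frame(records)
    else:
        from .spectra_io import read_spectra

        spectra = read_spectra(config.spectra_csv)
        refs = pd.read_csv(config.references_csv, index_col=0)
    return spectra, refs


def run_calibration(config: PipelineConfig) -> dict:
    """Run the full workflow for every configured response.

    Returns the run report: per response the chosen pre-treatment, removed
    outliers with provenance, selected wavenumbers and per-model metrics on
    the cross-validated training set and the external test set.
    """
    spectra, refs = _load_inputs(config)
    avg = average_replicates(spectra, "berry_id")
    refs = refs.loc[avg.sample_ids]
    report = {"seed": config.seed, "n_berries": avg.n_samples,
              "n_face_spectra": spectra.n_samples, "responses": {}}
    for response in config.responses:
        report["responses"][response] = calibrate_response(avg, refs, response, config)
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        config.to_yaml(os.path.join(config.outdir, "config.yaml"))
        with open(os.path.join(config.outdir, "report.json"), "w") as fh:
            json.dump(_jsonable(report), fh, indent=1)
    return report


def _jsonable(obj):
    from .evalsplit import FitMetrics
    from .outliers import CriticalLimits
    from .preprocess import FittedPretreatment, FittedTransform

    if isinstance(obj, FittedPretreatment):
        return "+".join(n for n, _, _ in obj.steps)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, FitMetrics):
        return obj.to_dict()
    if isinstance(obj, CriticalLimits):
        return {"approach": obj.approach, "limit_h": obj.limit_h,
                "limit_q": obj.limit_q, "n_h": obj.n_h, "n_q": obj.n_q,
                "n_flagged": int(obj.flags.sum())}
    if isinstance(obj, FittedTransform):
        return obj.method
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def make_fixture(profile: str, seed: int, outdir: str) -> dict:
    """Write a synthetic file bundle: spectra CSV, reference CSV, config YAML.

    'tiny' is a 24-berry study on a 101-point grid for fast tests;
    'paper_scale' is the full 270-berry study on the 1001-point grid.
    """
    if profile == "tiny":
        design = StudyDesign(n_blocks=2, n_bags_per_block=2, n_berries_per_bag=6,
                             seed=seed)
        grid = syndata.default_grid(101)
    elif profile == "paper_scale":
        design = StudyDesign(seed=seed)
        grid = syndata.default_grid(1001)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    spectra, records = generate_study(design, grid=grid)
    os.makedirs(outdir, exist_ok=True)
    spath = os.path.join(outdir, "spectra.csv")
    rpath = os.path.join(outdir, "references.csv")
    write_spectra(spectra, spath)
    records_to_frame(records).to_csv(rpath, float_format="%.17g")
    cfg = PipelineConfig(spectra_csv=spath, references_csv=rpath,
                         synthetic=False, seed=seed)
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))
    return {"spectra": spath, "references": rpath,
            "config": os.path.join(outdir, "config.yaml"),
            "n_berries": design.n_berries,
            "n_spectra": spectra.n_samples}
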