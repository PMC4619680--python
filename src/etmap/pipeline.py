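"""End-to-end workflows with config, logging and seed management.

Two entry points mirror the two mapping strategies:

* ``run_bivariate_etm`` -- fit the environment -> trait prediction on the
  phenotyped accessions, then run the bivariate mixed-model scan on the
  (observed, predicted) trait pair over all accessions; a constant
  prediction falls back to the univariate scan on the observed trait.
* ``run_univariate_etm`` -- predict the trait for unphenotyped target
  accessions (optionally restricted to the fitted prediction range) and run
  the univariate mixed-model scan on the prediction alone.

Every output directory receives the resolved config, the seed, a per-stage
log and SHA-256 checksums of the inputs, so a run is reproducible from
(inputs, config).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import envpredict as ep
from .io_core import (
    AccessionTable,
    GenotypeMatrix,
    read_genotypes,
    standardize_columns,
    pc1_trait,
)
from .relatedness import (
    KinshipMatrix,
    compute_kinship,
    inflation_factor,
    scan_mtmm,
    scan_univariate,
)

__all__ = ["RunConfig", "run_bivariate_etm", "run_univariate_etm",
           "bivariate_etm_scan", "univariate_etm_scan"]


@dataclass
class RunConfig:
    """Configuration of one ETM run (serialized alongside every output)."""

    genotype_path: str = ""
    genotype_format: str = "delimited"
    map_path: str | None = None
    table_path: str = ""
    trait_cols: list[str] = field(default_factory=list)
    env_cols: list[str] = field(default_factory=list)
    method: str = "cca"  # lm | en | rf | cca
    use_pc1: bool = False
    include_rho_e: bool = False
    maf_min: float = 0.05
    range_filter: bool = True
    n_trees: int = 500
    seed: int = 0
    out_dir: str = "etm_run"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r}: {err}")
        self.stage = stage


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    G = read_genotypes(cfg.genotype_path, cfg.genotype_format, map_path=cfg.map_path)
    df = pd.read_csv(cfg.table_path)
    table = AccessionTable(df, trait_cols=list(cfg.trait_cols), env_cols=list(cfg.env_cols))
    return G, table


def _observed_trait(table: AccessionTable, cfg: RunConfig, fit_mask: np.ndarray, log: list):
    """Single observed trait vector: the declared column, or PC1 of several."""
    Y = table.traits()
    if cfg.use_pc1 and Y.shape[1] >= 2:
        scores, expl = pc1_trait(Y[fit_mask])
        log.append({"stage": "pc1", "explained_fraction": expl})
        y = np.full(len(table.accession_ids), np.nan)
        y[fit_mask] = scores
        return y
    return Y[:, 0]


def bivariate_etm_scan(
    G: GenotypeMatrix,
    K: KinshipMatrix,
    table: AccessionTable,
    cfg: RunConfig,
    log: list | None = None,
):
    """Functional core of the bivariate workflow (no file I/O).

    Returns (results DataFrame, info dict).  Accessions lacking the observed
    trait still contribute through the predicted trait via the
    partially-overlapping bivariate design.
    """
    log = log if log is not None else []
    ids = table.accession_ids
    Y = table.traits()
    fit_mask = ~np.isnan(Y).any(axis=1)
    if not fit_mask.any():
        raise PipelineError("prediction", ValueError("no phenotyped accessions"))
    fit_ids = [a for a, m_ in zip(ids, fit_mask) if m_]
    table_std, _ = standardize_columns(table, list(cfg.env_cols), fit_ids=fit_ids)
    y_obs = _observed_trait(table_std, cfg, fit_mask, log)
    yfit = y_obs[fit_mask]
    yfit = (yfit - yfit.mean()) / yfit.std()
    X = table_std.env_matrix()
    model = ep.fit_prediction(
        cfg.method, yfit, X[fit_mask], seed=cfg.seed, names=list(cfg.env_cols),
        n_trees=cfg.n_trees,
    )
    pred = ep.apply_prediction(model, X, accession_ids=ids)
    log.append({"stage": "prediction", "method": cfg.method,
                "fit_n": int(fit_mask.sum()), "fit_corr": model.fit_corr,
                "constant": pred.constant})
    y1 = np.full(len(ids), np.nan)
    y1[fit_mask] = yfit
    if pred.constant:
        log.append({"stage": "fallback", "reason": "constant prediction",
                    "action": "univariate scan on observed trait"})
        res = scan_univariate(y1[fit_mask], _subset(G, fit_mask), _subset_K(K, fit_mask),
                              maf_min=cfg.maf_min)
        info = {"fallback": True}
    else:
        y2 = pred.y_hat
        y2 = (y2 - y2.mean()) / y2.std()
        res = scan_mtmm(y1, y2, G, K, include_rho_e=cfg.include_rho_e, maf_min=cfg.maf_min)
        info = {"fallback": False}
    pcol = "p" if info["fallback"] else "p_common"
    ok = res[pcol] < 1
    if ok.sum() >= 100:
        lam, _ = inflation_factor(res.loc[ok, pcol].to_numpy())
        log.append({"stage": "gwas", "lambda_gc": lam, "n_snps": int(len(res))})
    res = res.sort_values([pcol, "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return res, info


def univariate_etm_scan(
    G: GenotypeMatrix,
    K: KinshipMatrix,
    table: AccessionTable,
    cfg: RunConfig,
    log: list | None = None,
):
    """Functional core of the univariate workflow (mapping on predictions).

    The prediction model is fit on the phenotyped set; mapping is done on
    the predicted trait of the unphenotyped targets, after the optional
    range filter.
    """
    log = log if log is not None else []
    ids = table.accession_ids
    Y = table.traits()
    fit_mask = ~np.isnan(Y).any(axis=1)
    target_mask = ~fit_mask
    if not target_mask.any():
        raise PipelineError("targets", ValueError("no unphenotyped target accessions"))
    fit_ids = [a for a, m_ in zip(ids, fit_mask) if m_]
    table_std, _ = standardize_columns(table, list(cfg.env_cols), fit_ids=fit_ids)
    y_obs = _observed_trait(table_std, cfg, fit_mask, log)
    yfit = y_obs[fit_mask]
    yfit = (yfit - yfit.mean()) / yfit.std()
    X = table_std.env_matrix()
    model = ep.fit_prediction(
        cfg.method, yfit, X[fit_mask], seed=cfg.seed, names=list(cfg.env_cols),
        n_trees=cfg.n_trees,
    )
    pred = ep.apply_prediction(
        model, X[target_mask],
        accession_ids=[a for a, m_ in zip(ids, target_mask) if m_],
        range_filter=cfg.range_filter,
    )
    keep = pred.in_range if pred.in_range is not None else np.ones(len(pred.y_hat), bool)
    log.append({"stage": "prediction", "method": cfg.method,
                "targets": int(target_mask.sum()), "excluded_out_of_range": int((~keep).sum())})
    if not keep.any():
        raise PipelineError(
            "range_filter",
            ValueError(f"all {len(keep)} targets outside the fitted range"),
        )
    target_idx = np.where(target_mask)[0][keep]
    yhat = pred.y_hat[keep]
    yhat = (yhat - yhat.mean()) / yhat.std()
    Gs = _subset(G, target_idx)
    Ks = _subset_K(K, target_idx)
    res = scan_univariate(yhat, Gs, Ks, maf_min=cfg.maf_min)
    ok = res["p"] < 1
    if ok.sum() >= 100:
        lam, _ = inflation_factor(res.loc[ok, "p"].to_numpy())
        log.append({"stage": "gwas", "lambda_gc": lam, "n_snps": int(len(res))})
    res = res.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return res, {"n_targets_used": int(keep.sum())}


def _subset(G: GenotypeMatrix, idx) -> GenotypeMatrix:
    idx = np.asarray(idx)
    if idx.dtype == bool:
        idx = np.where(idx)[0]
    return GenotypeMatrix(
        [G.accession_ids[i] for i in idx], G.snp_ids, G.chrom, G.pos,
        G.scores[idx], coding=G.coding,
    )


def _subset_K(K: KinshipMatrix, idx) -> KinshipMatrix:
    idx = np.asarray(idx)
    if idx.dtype == bool:
        idx = np.where(idx)[0]
    return KinshipMatrix(K.values[np.ix_(idx, idx)], [K.accession_ids[i] for i in idx])


def _run(cfg: RunConfig, core) -> pd.DataFrame:
    os.makedirs(cfg.out_dir, exist_ok=True)
    log: list = []
    try:
        G, table = _load_inputs(cfg)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load", e) from e
    K = compute_kinship(G)
    res, info = core(G, K, table, cfg, log)
    res.to_csv(os.path.join(cfg.out_dir, "results.csv"), index=False)
    meta = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "info": info,
        "log": log,
        "input_checksums": {
            p: _sha256(p)
            for p in [cfg.genotype_path, cfg.table_path, cfg.map_path]
            if p and os.path.exists(p)
        },
    }
    with open(os.path.join(cfg.out_dir, "run.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return res


def run_bivariate_etm(cfg: RunConfig) -> pd.DataFrame:
    """File-level bivariate ETM run; writes results.csv and run.json."""
    return _run(cfg, bivariate_etm_scan)


def run_univariate_etm(cfg: RunConfig) -> pd.DataFrame:
    """File-level univariate ETM run; writes results.csv and run.json."""
    return _run(cfg, univariate_etm_scan)
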