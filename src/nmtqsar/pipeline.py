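"""End-to-end orchestration: split–select–validate–exchange, and prediction
with the two published five-descriptor models.

The workflow splits the dataset into two equal halves, runs objective
filtering once (unsupervised, on the full pool), selects and fits a model on
one half, validates it externally on the other, then exchanges the halves
and repeats — so every molecule serves once for selection and once for
external validation. Both arms are pushed through the full rule-based
acceptance check and a consensus note lists the descriptors the two top
models share.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .descriptors import DescriptorMatrix
from .feature_selection import GAConfig, ModelCandidate, ga_mlr_search, ofs_filter
from . import validation as mv
from .validation import (ADReport, AcceptanceResult, MLRModel, ValidationReport,
                         acceptance_check, leverage_cutoff)

log = logging.getLogger(__name__)

__all__ = [
    "SplitScheme", "WorkflowConfig", "ArmResult", "ExchangeResult",
    "make_split", "run_exchange_workflow", "MODEL_1", "MODEL_2",
    "published_model", "predict_with_published", "report",
]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitScheme:
    set_a_ids: list[str]
    set_b_ids: list[str]
    seed: int = 0
    method: str = "activity_sorted_alternating"

    def __post_init__(self) -> None:
        if set(self.set_a_ids) & set(self.set_b_ids):
            raise ValueError("split halves overlap")
        if abs(len(self.set_a_ids) - len(self.set_b_ids)) > 1:
            raise ValueError("split halves differ by more than one molecule")


def make_split(ids: list[str], pic50, method: str = "activity_sorted_alternating",
               seed: int = 0) -> SplitScheme:
    """Split molecules into two near-equal halves.

    The default sorts by activity and alternates assignment, so both halves
    span the full pIC50 range; a seeded random split is also available.
    """
    ids = [str(i) for i in ids]
    if method == "activity_sorted_alternating":
        order = np.argsort(np.asarray(pic50, dtype=float))[::-1]
    elif method == "random":
        order = np.random.default_rng(seed).permutation(len(ids))
    else:
        raise ValueError(f"unknown split method {method!r}")
    a = [ids[i] for i in order[0::2]]
    b = [ids[i] for i in order[1::2]]
    return SplitScheme(set_a_ids=a, set_b_ids=b, seed=seed, method=method)


# ---------------------------------------------------------------------------
# workflow
# ---------------------------------------------------------------------------

@dataclass
class WorkflowConfig:
    """Every knob of the exchange workflow."""

    model_size: int = 5
    ga: GAConfig = field(default_factory=GAConfig)
    near_const_frac: float = 0.95
    corr_cut: float = 0.90
    split_method: str = "activity_sorted_alternating"
    split_seed: int = 0
    lmo_frac_out: float = 0.30
    lmo_reps: int = 2000
    yscramble_reps: int = 2000
    lof_d: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ga = GAConfig(**raw.pop("ga", {}))
        return cls(ga=ga, **raw)


@dataclass
class ArmResult:
    candidate: ModelCandidate
    model: MLRModel
    report: ValidationReport
    acceptance: AcceptanceResult
    ad: ADReport
    train_ids: list[str]
    ext_ids: list[str]
    obs_pred: pd.DataFrame  # id, set, observed, predicted


@dataclass
class ExchangeResult:
    arms: list[ArmResult]
    consensus_descriptors: list[str]
    ofs_surviving: list[str]


def _validate_arm(Xtr: pd.DataFrame, ytr: np.ndarray, Xex: pd.DataFrame,
                  yex: np.ndarray, candidate: ModelCandidate,
                  config: WorkflowConfig, train_ids, ext_ids) -> ArmResult:
    names = candidate.descriptor_names
    model = mv.fit_ols(Xtr[names], ytr, names=names, ids=list(train_ids))
    rep = mv.basic_fit_stats(model, Xtr[names], ytr, lof_d=config.lof_d)
    loo = mv.q2_loo(Xtr[names], ytr)
    rep.q2_loo, rep.press_cv = loo.q2, loo.press
    rep.rmse_cv, rep.mae_cv, rep.ccc_cv = loo.rmse_cv, loo.mae_cv, loo.ccc_cv
    rep.q2_lmo = mv.q2_lmo(Xtr[names], ytr, frac_out=config.lmo_frac_out,
                           reps=config.lmo_reps, seed=config.seed)
    rep.r2_yscr, rep.q2_yscr = mv.y_scramble(Xtr[names], ytr,
                                             reps=config.yscramble_reps,
                                             seed=config.seed)
    if len(names) >= 2:
        rep.kxx, rep.delta_k = mv.kxx_delta_k(Xtr[names], ytr)
    rep.merge(mv.external_stats(model, Xex[names], yex))
    yhat_ex = mv.predict_many(model, Xex[names])
    rep.gt = mv.golbraikh_tropsha(yex, yhat_ex)
    ad = mv.williams_ad(model, Xtr[names], ytr, Xex[names], yex,
                        ids_train=list(train_ids), ids_ext=list(ext_ids))
    obs_pred = pd.DataFrame({
        "id": list(train_ids) + list(ext_ids),
        "set": ["train"] * len(train_ids) + ["ext"] * len(ext_ids),
        "observed": np.concatenate([ytr, yex]),
        "predicted": np.concatenate([mv.predict_many(model, Xtr[names]), yhat_ex]),
    })
    try:
        acc = acceptance_check(rep)
    except ValueError as e:  # e.g. single-descriptor model: no Kxx/ΔK rule
        acc = AcceptanceResult(passed=False,
                               rules={"incomplete report": {"passed": False,
                                                            "value": str(e)}})
    return ArmResult(candidate=candidate, model=model, report=rep,
                     acceptance=acc, ad=ad,
                     train_ids=list(train_ids), ext_ids=list(ext_ids),
                     obs_pred=obs_pred)


def run_exchange_workflow(X: DescriptorMatrix, y, config: WorkflowConfig | None = None,
                          split: SplitScheme | None = None) -> ExchangeResult:
    """Run the two-arm exchange strategy on a descriptor matrix + response.

    Arm 1 selects and fits on half A and validates on half B; arm 2 swaps the
    halves. Objective filtering runs once on the full pool (it is
    unsupervised, so no response information leaks across the split).
    """
    config = config or WorkflowConfig()
    y = pd.Series(np.asarray(y, dtype=float), index=[str(i) for i in X.ids])
    X_f, _ofs = ofs_filter(X)
    df = X_f.to_frame()
    if len(_ofs.surviving) <= config.model_size:
        raise ValueError("surviving pool is not larger than the model size")
    if split is None:
        split = make_split(list(df.index), y.to_numpy(),
                           method=config.split_method, seed=config.split_seed)
    half_ids = [split.set_a_ids, split.set_b_ids]
    min_n = min(len(h) for h in half_ids)
    if min_n <= config.model_size + 2:
        raise ValueError("half too small for the requested model size")
    arms = []
    for tr_ids, ex_ids in [(half_ids[0], half_ids[1]), (half_ids[1], half_ids[0])]:
        Xtr, Xex = df.loc[tr_ids], df.loc[ex_ids]
        ga = GAConfig(**{**config.ga.__dict__, "model_size": config.model_size})
        candidates = ga_mlr_search(Xtr, y.loc[tr_ids].to_numpy(), ga)
        arms.append(_validate_arm(Xtr, y.loc[tr_ids].to_numpy(),
                                  Xex, y.loc[ex_ids].to_numpy(),
                                  candidates[0], config, tr_ids, ex_ids))
    consensus = sorted(set(arms[0].candidate.descriptor_names)
                       & set(arms[1].candidate.descriptor_names))
    if consensus == sorted(arms[0].candidate.descriptor_names):
        log.info("both arms selected identical descriptor sets: %s", consensus)
    return ExchangeResult(arms=arms, consensus_descriptors=consensus,
                          ofs_surviving=_ofs.surviving)


# ---------------------------------------------------------------------------
# published models
# ---------------------------------------------------------------------------

def _published(intercept: float, half0: float, coefs: dict[str, tuple[float, float]],
               n_train: int) -> MLRModel:
    return MLRModel(
        intercept=intercept,
        coefficients={k: v[0] for k, v in coefs.items()},
        coef_halfwidths={"intercept": half0, **{k: v[1] for k, v in coefs.items()}},
        n_train=n_train,
        p=len(coefs),
    )


MODEL_1 = _published(0.928, 0.703, {
    "C_AbSA": (0.028, 0.008),
    "all_HASA2": (0.009, 0.001),
    "fNH4B": (-0.142, 0.069),
    "fringNH2A": (0.554, 0.311),
    "flipoH3B": (-0.241, 0.133),
}, n_train=155)

MODEL_2 = _published(1.574, 0.618, {
    "C_AbSA": (0.026, 0.008),
    "all_HASA2": (0.008, 0.001),
    "fNH4B": (-0.19, 0.068),
    "fringNH2A": (0.772, 0.336),
    "flipoH3B": (-0.287, 0.139),
}, n_train=154)

# fixture integrity: the shipped equations carry the published intercepts
assert MODEL_1.intercept == 0.928 and MODEL_2.intercept == 1.574


def published_model(which: str) -> MLRModel:
    try:
        return {"model1": MODEL_1, "model2": MODEL_2}[which.lower()]
    except KeyError:
        raise ValueError(f"unknown published model {which!r}; use 'model1' or 'model2'")


def predict_with_published(x, model: str = "model1",
                           leverage: float | None = None) -> tuple[float, bool | None]:
    """Predict pIC50 with a shipped published equation.

    ``x`` maps the five descriptor names to values. If a leverage against the
    original training design is supplied, the in-domain flag compares it with
    h* = 3(p+1)/n of that model; otherwise the flag is None.
    """
    m = published_model(model)
    pred = mv.predict(m, x)
    in_domain = None
    if leverage is not None:
        in_domain = bool(leverage <= leverage_cutoff(m.p, m.n_train))
    return pred, in_domain


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _arm_dict(arm: ArmResult) -> dict:
    return {
        "descriptors": arm.candidate.descriptor_names,
        "fitness_q2loo": arm.candidate.fitness_q2loo,
        "intercept": arm.model.intercept,
        "coefficients": arm.model.coefficients,
        "coef_halfwidths": arm.model.coef_halfwidths,
        "n_train": arm.model.n_train,
        "n_ext": len(arm.ext_ids),
        "statistics": arm.report.to_dict(),
        "acceptance": {
            "passed": arm.acceptance.passed,
            "rules": {k: v["passed"] for k, v in arm.acceptance.rules.items()},
        },
        "applicability_domain": {
            "h_star": arm.ad.h_star,
            "outliers": arm.ad.outliers,
            "influential": arm.ad.influential,
        },
    }


def report(results: ExchangeResult, out_dir: str | Path | None = None
           ) -> tuple[dict, str]:
    """Machine- and human-readable summaries of an exchange run.

    Returns (dict, markdown). With ``out_dir`` set, writes report.json,
    report.md and per-arm Williams / observed-vs-predicted CSVs; output is
    deterministic, so regeneration is byte-identical.
    """
    d = {
        "arms": [_arm_dict(a) for a in results.arms],
        "consensus_descriptors": results.consensus_descriptors,
        "n_surviving_descriptors": len(results.ofs_surviving),
    }
    lines = ["# GA-MLR QSAR exchange workflow report", ""]
    for i, arm in enumerate(results.arms, start=1):
        eq = " + ".join(
            [f"{arm.model.intercept:.3f}"]
            + [f"{b:+.3f}*{nm}" for nm, b in arm.model.coefficients.items()])
        lines += [f"## Arm {i}", "",
                  f"pIC50 = {eq}", "",
                  f"n_train = {arm.model.n_train}, n_ext = {len(arm.ext_ids)}", ""]
        stats = arm.report.to_dict()
        stat_line = ", ".join(f"{k} = {v:.3f}" for k, v in stats.items()
                              if isinstance(v, float))
        lines += [stat_line, ""]
        verdicts = ", ".join(f"{k}: {'pass' if v['passed'] else 'FAIL'}"
                             for k, v in arm.acceptance.rules.items())
        lines += [f"Acceptance: {'PASS' if arm.acceptance.passed else 'FAIL'} ({verdicts})", ""]
    lines += [f"Consensus descriptors: {', '.join(results.consensus_descriptors) or 'none'}", ""]
    md = "\n".join(lines)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(d, indent=2, sort_keys=True))
        (out / "report.md").write_text(md)
        for i, arm in enumerate(results.arms, start=1):
            pd.DataFrame({
                "id": arm.ad.ids,
                "leverage": arm.ad.leverages,
                "std_residual": arm.ad.std_residuals,
                "set": arm.ad.sets,
            }).to_csv(out / f"williams_arm{i}.csv", index=False)
            arm.obs_pred.to_csv(out / f"obs_pred_arm{i}.csv", index=False)
    return d, md
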