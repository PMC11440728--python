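"""End-to-end orchestration: simulate -> extract -> filter -> select -> train -> evaluate.

One config and one master seed determine every artifact. The three standard
model variants mirror the clinical / +intratumoral / +vasculature comparison:
``clinical``, ``clinical+tumor``, ``clinical+tumor+vessel`` — all evaluated on
the identical test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate, tumor_features, vessel_features
from .image_core import resample_isotropic, zscore_standardize
from .metrics import concordance_index, log_rank, timed_roc_report
from .selection import CoxChi2Screener, SequentialForwardSelector, split_cohort
from .simulate import CohortSpec, to_structured
from .survival_net import NetworkSpec, SurvivalNet, stratify
from .vessel_features import OutlierFeatureFilter

#: Stage-seed offsets fanned out from the master seed (all below 2**31).
SEED_OFFSETS = {"simulate": 11, "split": 23, "train": 37, "evaluate": 53}


@dataclass
class PipelineConfig:
    n_subjects: int = 60
    use_images: bool = False  # phantom-image extraction vs tabular ground truth
    grid_shape: tuple[int, int, int] = (72, 72, 72)
    cohort: CohortSpec | None = None
    fractions: tuple[float, float, float] = (0.55, 0.15, 0.30)
    alpha: float = 0.05
    max_features: int = 15
    network: NetworkSpec | None = None
    evaluation_times: tuple[float, ...] = (1.0, 2.0, 3.0, 6.0)
    stratification_months: float = 3.3
    stratification_cut: float = 0.5
    seed: int = 0


def _stage_seed(master: int, stage: str) -> int:
    return (master * 1009 + SEED_OFFSETS[stage]) % (2**31 - 1)


def _encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix from the clinical table (one-hot minus reference)."""
    out = pd.DataFrame(index=clinical.index)
    out["age"] = clinical["age"].astype(float)
    for col in clinical.columns:
        if col == "age":
            continue
        levels = sorted(clinical[col].unique())
        for lv in levels[1:]:
            out[f"{col}_{lv}"] = (clinical[col] == lv).astype(float)
    return out


def extract_image_features(phantoms: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both radiomics extractors on each phantom (tumor 593, vessel 91)."""
    tumor_rows, vessel_rows = [], []
    for ph in phantoms:
        vol = zscore_standardize(resample_isotropic(ph["volume"]))
        tmask = ph["tumor_mask"]
        tumor_rows.append(tumor_features.extract_intratumoral(vol, tmask))
        vessel_rows.append(vessel_features.extract_peritumoral(
            vol, tmask, lung_mask=ph.get("lung_mask"),
            vessel_mask=ph.get("vessel_mask")))
    return pd.DataFrame(tumor_rows), pd.DataFrame(vessel_rows)


def _fit_variant(X: pd.DataFrame, y_struct, idx_train, idx_val,
                 alpha, max_features, net_spec, seed):
    """Screen -> SFS -> network for one feature-set variant."""
    y_train = y_struct[idx_train]
    screener = CoxChi2Screener(alpha=alpha).fit(X.iloc[idx_train], y_train)
    candidates = screener.selected_features_
    trace = None
    if len(candidates) > 1:
        pvals = screener.result_.table["p_value"].to_dict()
        sfs = SequentialForwardSelector(max_features=max_features)
        sfs.fit(X.iloc[idx_train], y_train, X.iloc[idx_val], y_struct[idx_val],
                candidates=candidates, screening_p=pvals)
        selected = sfs.selected_features_ or candidates[:1]
        trace = sfs.trace_
    else:
        selected = candidates
    if not selected:
        # fall back to the single lowest-p feature so the variant stays comparable
        tab = screener.result_.table.dropna(subset=["p_value"])
        selected = [tab["p_value"].idxmin()] if len(tab) else list(X.columns[:1])
    spec = net_spec or NetworkSpec()
    spec = NetworkSpec(**{**asdict(spec), "seed": seed})
    model = SurvivalNet(spec).fit(X.iloc[idx_train][selected], y_train,
                                  X.iloc[idx_val][selected], y_struct[idx_val])
    return {"screener": screener, "trace": trace, "selected": selected, "model": model}


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline; optionally write artifacts to ``out_dir``.

    Returns a dict with per-variant models, test metrics, the stratification
    log-rank result, and the seed manifest.
    """
    master = config.seed
    cohort = config.cohort or CohortSpec(n_subjects=config.n_subjects,
                                         seed=_stage_seed(master, "simulate"))

    if config.use_images:
        phantoms, clinical, outcome, truth_lp = simulate.generate_image_cohort(
            config.n_subjects, seed=_stage_seed(master, "simulate"),
            grid_shape=config.grid_shape, cohort_spec=cohort)
        tumor_tab, vessel_tab = extract_image_features(phantoms)
        tumor_tab.index = clinical.index
        vessel_tab.index = clinical.index
        vessel_tab = vessel_tab.drop(columns=["empty_tree"], errors="ignore")
    else:
        features, clinical, outcome, truth_lp = simulate.generate_cohort(cohort)
        tumor_tab = features[["tumor_radius_mm", "heterogeneity"]].copy()
        vessel_tab = features[["vessel_tortuosity"]].copy()
        noise = features[[c for c in features.columns if c.startswith("noise_")]]
        tumor_tab = pd.concat([tumor_tab, noise], axis=1)

    clin_X = _encode_clinical(clinical)
    y = to_structured(outcome)
    idx_train, idx_val, idx_test = split_cohort(
        len(clinical), config.fractions, seed=_stage_seed(master, "split"))

    # outlier filter on radiomic blocks: reference = training rows,
    # fraction counted over the whole dataset
    filt_t = OutlierFeatureFilter().fit(tumor_tab, reference_index=tumor_tab.index[idx_train])
    tumor_tab = filt_t.transform(tumor_tab)
    filt_v = OutlierFeatureFilter().fit(vessel_tab, reference_index=vessel_tab.index[idx_train])
    vessel_tab = filt_v.transform(vessel_tab)

    variants = {
        "clinical": clin_X,
        "clinical+tumor": pd.concat([clin_X, tumor_tab], axis=1),
        "clinical+tumor+vessel": pd.concat([clin_X, tumor_tab, vessel_tab], axis=1),
    }
    results: dict = {"config": config, "splits": {"train": idx_train.tolist(),
                                                  "validation": idx_val.tolist(),
                                                  "test": idx_test.tolist()},
                     "models": {}, "outcome": outcome, "truth_lp": truth_lp}
    y_test = y[idx_test]
    for vi, (name, X) in enumerate(variants.items()):
        fitted = _fit_variant(X, y, idx_train, idx_val, config.alpha,
                              config.max_features, config.network,
                              seed=_stage_seed(master, "train") + vi)
        model = fitted["model"]
        risk_test = model.predict(X.iloc[idx_test][fitted["selected"]])
        entry = {**fitted, "risk_test": risk_test}
        try:
            entry["c_index_test"] = concordance_index(y_test, risk_test).c_index
        except ValueError:
            entry["c_index_test"] = np.nan
        try:
            entry["roc"] = timed_roc_report(y_test, risk_test,
                                            times=config.evaluation_times,
                                            n_boot=0)
        except ValueError:
            entry["roc"] = None
        curves = model.predict_survival_function(X.iloc[idx_test][fitted["selected"]])
        strat = stratify(curves, config.stratification_months, config.stratification_cut)
        entry["stratification"] = strat
        hi = strat.groups == "high"
        if hi.any() and (~hi).any():
            t_test = np.asarray(outcome["time"])[idx_test]
            e_test = np.asarray(outcome["event"])[idx_test]
            entry["logrank"] = log_rank(
                {"time": t_test[hi], "event": e_test[hi]},
                {"time": t_test[~hi], "event": e_test[~hi]})
        else:
            entry["logrank"] = (np.nan, np.nan)
        results["models"][name] = entry

    if out_dir is not None:
        _write_artifacts(results, variants, clinical, outcome, Path(out_dir))
    return results


def _write_artifacts(results, variants, clinical, outcome, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(out / "clinical.csv")
    outcome.to_csv(out / "outcome.csv")
    for name, X in variants.items():
        X.to_csv(out / f"features_{name.replace('+', '_')}.csv")
    manifest = {"seed": results["config"].seed,
                "splits": results["splits"],
                "models": {}}
    for name, entry in results["models"].items():
        safe = name.replace("+", "_")
        (out / f"model_{safe}.json").write_text(entry["model"].to_json())
        manifest["models"][name] = {
            "selected": entry["selected"],
            "c_index_test": float(entry["c_index_test"]),
            "logrank_p": float(entry["logrank"][1]),
            "auc": ({str(k): float(v) for k, v in entry["roc"].auc.items()}
                    if entry["roc"] else None),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
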