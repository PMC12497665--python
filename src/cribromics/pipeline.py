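"""End-to-end driver: simulate -> IVIM maps -> erode -> extract -> train -> evaluate.

The pipeline streams phantom cases one at a time (a case's volumes are
discarded once its region features are extracted), so memory stays flat in
cohort size.  Every stage's parameters and derived seeds are captured in
the run log; given the same config the whole run is reproducible.
"""

from __future__ import annotations

import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import ExtractionSettings, extract_region_features
from .grids import RegionMask
from .ivim import DwiStack, fit_segmented_ivim
from .metrics import MetricReport, bootstrap_metrics
from .model import (
    Hyperparams,
    LogisticModel,
    MrmrRanking,
    fit_logistic,
    mrmr_rank,
    predict_probability,
    select_feature_count_cv,
    split_dataset,
    target_from_label,
    tune_hyperparameters,
)
from .phantom import PhantomSpec, generate_phantom_case
from .regions import REASON_LOST_ON_GRID, ErosionSpec, erode_region, filter_regions

META_COLS = ("region_id", "case_id", "label", "volume_cc", "split")


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    extraction: ExtractionSettings = field(default_factory=ExtractionSettings)
    erosion: bool = True
    # acquisition in-plane voxel size driving the erosion radius; defaults
    # to the simulated DWI in-plane size (radius 1 on the map grid).
    acquisition_inplane_mm: float | None = None
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    grid_search: bool = False
    k_max: int = 20
    cv_pool: str = "pooled"  # "pooled" (train+validation) or "validation_only"
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_boot: int = 1000
    seed: int = 0

    def derived_seeds(self) -> dict[str, int]:
        return {
            "phantom": self.phantom.seed,
            "split": self.seed + 1,
            "cv": self.seed + 2,
            "bootstrap": self.seed + 3,
        }


def config_from_yaml(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Recognized top-level keys: ``phantom`` (PhantomSpec fields except
    tissue_params/protocol, plus ``noise_sigma`` and ``b_values`` which go
    to the protocol), ``extraction`` (ExtractionSettings fields), and any
    direct PipelineConfig scalar field (seed, erosion, n_boot, cv_pool,
    k_max, grid_search, acquisition_inplane_mm, fractions).
    """
    import yaml

    from .phantom import AcquisitionProtocol

    raw = yaml.safe_load(open(path)) or {}
    phantom_kw = dict(raw.pop("phantom", {}) or {})
    proto_kw = {}
    for key in ("b_values", "noise_sigma", "dwi_spacing", "t2w_spacing", "field_label"):
        if key in phantom_kw:
            proto_kw[key] = phantom_kw.pop(key)
    if "b_values" in proto_kw:
        proto_kw["b_values"] = tuple(float(b) for b in proto_kw["b_values"])
    phantom = PhantomSpec(
        **phantom_kw,
        **({"protocol": AcquisitionProtocol(**proto_kw)} if proto_kw else {}),
    )
    extraction_kw = raw.pop("extraction", {}) or {}
    for key in ("t2w_resample_mm", "adc_fbv_resample_mm"):
        if key in extraction_kw:
            extraction_kw[key] = tuple(extraction_kw[key])
    extraction = ExtractionSettings(**extraction_kw)
    if "fractions" in raw:
        raw["fractions"] = tuple(raw["fractions"])
    return PipelineConfig(phantom=phantom, extraction=extraction, **raw)


@dataclass
class RunResult:
    features: pd.DataFrame            # kept regions with split assignments
    dropped: pd.DataFrame             # region_id, label, reason
    ranking: MrmrRanking
    cv_trace: list[float]
    n_features: int
    model: LogisticModel
    report: MetricReport
    test_probabilities: pd.DataFrame  # region_id, label, target, probability
    log: dict


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def extract_cohort_features(config: PipelineConfig, progress: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stages simulate -> ivim -> erode -> filter -> extract for the whole cohort.

    Returns (features table, dropped-region table).
    """
    spec = config.phantom
    acq = config.acquisition_inplane_mm or spec.protocol.dwi_spacing[0]
    rows, drops = [], []
    for i in range(spec.n_cases):
        case = generate_phantom_case(spec, i)
        maps = fit_segmented_ivim(DwiStack(volumes=case.dwi, mask=case.prostate_mask))
        regions = case.regions
        if config.erosion:
            espec = ErosionSpec(
                acquisition_inplane_mm=acq,
                grid_inplane_mm=maps.adc.geometry.spacing[0],
            )
            regions = [erode_region(r, espec) for r in regions]
        kept, dropped = filter_regions(regions)
        for reg, reason in dropped:
            drops.append({"region_id": reg.region_id, "case_id": reg.case_id,
                          "label": reg.label, "reason": reason})
        for reg in kept:
            try:
                feats = extract_region_features(case.t2w, maps.adc, maps.fbv, reg,
                                                config.extraction)
            except ValueError:
                # thin regions can alias away under nearest-neighbour
                # resampling onto a coarser extraction grid
                drops.append({"region_id": reg.region_id, "case_id": reg.case_id,
                              "label": reg.label, "reason": REASON_LOST_ON_GRID})
                continue
            rows.append({"region_id": reg.region_id, "case_id": reg.case_id,
                         "label": reg.label, "volume_cc": reg.volume_cc, **feats})
        if progress and (i + 1) % 25 == 0:
            print(f"  processed {i + 1}/{spec.n_cases} cases", file=sys.stderr)
    features = pd.DataFrame(rows)
    dropped_df = pd.DataFrame(drops, columns=["region_id", "case_id", "label", "reason"])
    return features, dropped_df


def train_and_evaluate(features: pd.DataFrame, config: PipelineConfig) -> RunResult:
    """Stages split -> mRMR -> CV feature count -> fit -> bootstrap evaluation."""
    seeds = config.derived_seeds()
    table = split_dataset(features, fractions=config.fractions, seed=seeds["split"])
    feat_cols = _feature_columns(table)
    y_all = target_from_label(table["label"])

    train_mask = (table["split"] == "train").to_numpy()
    if config.cv_pool == "validation_only":
        cv_mask = (table["split"] == "validation").to_numpy()
    else:
        cv_mask = (table["split"] != "test").to_numpy()

    # drop constant features: they carry no information and break binning
    X_train = table.loc[train_mask, feat_cols]
    usable = [c for c in feat_cols if X_train[c].nunique() > 1]
    ranking = mrmr_rank(X_train[usable], y_all[train_mask], max_features=config.k_max)

    X_cv = table.loc[cv_mask, ranking.features]
    y_cv = y_all[cv_mask]
    hp = config.hyperparams
    if config.grid_search:
        hp = tune_hyperparameters(X_cv[ranking.top(1)], y_cv, seed=seeds["cv"])
    k, trace = select_feature_count_cv(
        X_cv, y_cv, ranking, k_max=config.k_max, hyperparams=hp, seed=seeds["cv"]
    )
    chosen = ranking.top(k)

    fit_mask = (table["split"] != "test").to_numpy()
    model = fit_logistic(table.loc[fit_mask, chosen], y_all[fit_mask], hp)

    test = table[table["split"] == "test"]
    probs = predict_probability(model, test[chosen])
    y_test = target_from_label(test["label"])
    report = bootstrap_metrics(y_test, probs, n_boot=config.n_boot,
                               seed=seeds["bootstrap"], threshold=model.threshold)
    test_probabilities = pd.DataFrame({
        "region_id": test["region_id"].to_numpy(),
        "label": test["label"].to_numpy(),
        "target": y_test,
        "probability": probs,
    })
    log = {
        "version": __version__,
        "seeds": seeds,
        "erosion": config.erosion,
        "cv_pool": config.cv_pool,
        "hyperparams": hp.to_jsonable(),
        "n_regions_kept": int(len(features)),
        "split_sizes": table["split"].value_counts().to_dict(),
        "ranking": ranking.features,
        "cv_trace": trace,
        "n_features_selected": k,
        "selected_features": chosen,
    }
    return RunResult(
        features=table, dropped=pd.DataFrame(), ranking=ranking, cv_trace=trace,
        n_features=k, model=model, report=report,
        test_probabilities=test_probabilities, log=log,
    )


def run_pipeline(config: PipelineConfig, out_dir=None, progress: bool = False) -> RunResult:
    """Execute the full pipeline; optionally write all artifacts to ``out_dir``."""
    features, dropped = extract_cohort_features(config, progress=progress)
    if len(features) < 10:
        raise RuntimeError(
            f"only {len(features)} regions survived erosion/filtering; "
            "increase n_cases"
        )
    result = train_and_evaluate(features, config)
    result.dropped = dropped
    result.log["n_regions_dropped"] = int(len(dropped))
    result.log["drop_reasons"] = dropped["reason"].value_counts().to_dict() if len(dropped) else {}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.features.to_csv(out / "features.csv", index=False)
        dropped.to_csv(out / "drop_report.csv", index=False)
        (out / "model.json").write_text(result.model.to_json())
        (out / "report.json").write_text(json.dumps(result.report.to_dict(), indent=2))
        result.test_probabilities.to_csv(out / "test_predictions.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(result.log, indent=2, default=str))
    return result
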