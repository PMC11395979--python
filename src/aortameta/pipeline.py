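"""End-to-end metamodel pipeline.

One call wires the whole protocol together on a cohort table that carries
morphometry, hemodynamics and labels:

1. stratified 80:20 split (the *same* split serves every classifier);
2. surrogate regressions fitted on the training records only (fitting them
   on all records would leak test information into the comparison);
3. chained surrogate prediction of the five predictable responses for all
   records;
4. three logistic classifiers fitted on the training set — diameters,
   observed hemodynamics, predicted hemodynamics;
5. evaluation of all three on the identical held-out test records, plus
   the observed-vs-predicted correlation report.

The direct and metamodel classifiers use the feature set the surrogates
can predict, so their accuracies are a like-for-like comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import (
    HEMO_FEATURES_PREDICTABLE,
    MORPHO_FEATURES,
    LogisticClassifier,
    SeparationWarning,
    SplitPlan,
    accuracy,
    fit_logistic,
    split_80_20,
)
from .config import PRESSURE_COLUMNS, VELOCITY_COLUMNS, RunConfig, _stage_seed
from .surrogate import (
    PUBLISHED_MODELS,
    SurrogateModel,
    chain_predict,
    correlation_report,
    fit_all_surrogates,
)

__all__ = ["PipelineResult", "run_pipeline", "compare_report"]

_ALL_HEMO = (*VELOCITY_COLUMNS, *PRESSURE_COLUMNS)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, with provenance."""

    split: SplitPlan
    surrogates: Mapping[str, SurrogateModel]
    classifiers: dict[str, LogisticClassifier]
    accuracies: dict[str, float]
    confusions: dict[str, dict]
    misclassified: dict[str, list[str]]
    correlations: pd.DataFrame
    predictions: pd.DataFrame
    seed: int
    config_hash: str

    def to_dict(self) -> dict:
        return {
            "split": {"train": list(self.split.train),
                      "test": list(self.split.test),
                      "seed": self.split.seed},
            "surrogates": {k: m.to_dict() for k, m in self.surrogates.items()},
            "classifiers": {k: c.to_dict() for k, c in self.classifiers.items()},
            "accuracies": self.accuracies,
            "confusions": self.confusions,
            "misclassified": self.misclassified,
            "correlations": {k: float(v)
                             for k, v in self.correlations["r"].items()},
            "seed": self.seed,
            "config_hash": self.config_hash,
        }


def run_pipeline(cohort: pd.DataFrame, config: RunConfig) -> PipelineResult:
    """Run the full split / fit / predict / classify / evaluate protocol."""
    required = set(MORPHO_FEATURES) | set(HEMO_FEATURES_PREDICTABLE) | {"label"}
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    cohort = cohort.reset_index(drop=True)

    split = split_80_20(cohort["label"], seed=_stage_seed(config.seed, "split"),
                        test_fraction=config.test_fraction)
    train = cohort.iloc[list(split.train)]
    test = cohort.iloc[list(split.test)]

    if config.model_mode == "fitted":
        surrogates = fit_all_surrogates(train)
    else:
        surrogates = dict(PUBLISHED_MODELS)
    predicted = chain_predict(cohort, surrogates)

    hemo_features = (_ALL_HEMO if config.all_features_ablation
                     else HEMO_FEATURES_PREDICTABLE)
    feature_tables = {
        "morpho": cohort[list(MORPHO_FEATURES)],
        "hemo": cohort[list(hemo_features)],
        "meta": predicted[list(predicted.columns)],
    }

    classifiers: dict[str, LogisticClassifier] = {}
    accuracies: dict[str, float] = {}
    confusions: dict[str, dict] = {}
    misclassified: dict[str, list[str]] = {}
    pred_frame = pd.DataFrame({
        "patient_id": cohort.get("patient_id", pd.Series(cohort.index.astype(str))),
        "label": cohort["label"],
        "in_test": [i in set(split.test) for i in cohort.index],
    })

    test_ids = list(split.test)
    with warnings.catch_warnings():
        # quasi-separation is expected on well-separated synthetic cohorts
        warnings.simplefilter("ignore", SeparationWarning)
        for name, table in feature_tables.items():
            clf = fit_logistic(table.iloc[list(split.train)],
                               train["label"].to_numpy(),
                               standardize=config.standardize,
                               threshold=config.threshold)
            classifiers[name] = clf
            # the same-split guarantee is asserted, not assumed
            assert list(table.iloc[test_ids].index) == test_ids
            pred = clf.predict(table.iloc[test_ids])
            res = accuracy(pred, test["label"].to_numpy())
            accuracies[name] = res["accuracy"]
            confusions[name] = res["confusion"]
            wrong = np.asarray(test_ids)[pred != test["label"].to_numpy()]
            misclassified[name] = [str(pred_frame["patient_id"].iloc[i])
                                   for i in wrong]
            pred_frame[f"p_coa_{name}"] = clf.predict_proba(table)
            pred_frame[f"pred_{name}"] = clf.predict(table)

    correlations = correlation_report(cohort[list(predicted.columns)], predicted)
    return PipelineResult(
        split=split, surrogates=surrogates, classifiers=classifiers,
        accuracies=accuracies, confusions=confusions,
        misclassified=misclassified, correlations=correlations,
        predictions=pred_frame, seed=config.seed, config_hash=config.hash())


def compare_report(res: PipelineResult) -> dict:
    """JSON-ready comparison of the three classifiers.

    Accuracies are recomputed from the stored confusion matrices so the
    summary is internally consistent by construction.
    """
    out: dict = {"seed": res.seed, "config_hash": res.config_hash,
                 "n_test": len(res.split.test), "classifiers": {}}
    for name in res.accuracies:
        conf = res.confusions[name]
        n = sum(conf.values())
        acc = (conf["tp"] + conf["tn"]) / n
        if abs(acc - res.accuracies[name]) > 1e-12:
            raise AssertionError(
                f"stored accuracy for {name} disagrees with its confusion matrix")
        out["classifiers"][name] = {
            "accuracy": acc,
            "confusion": conf,
            "misclassified": res.misclassified[name],
        }
    out["correlation_r"] = {k: float(v)
                            for k, v in res.correlations["r"].items()}
    out["best_predicted"] = str(res.correlations["r"].idxmax())
    return out
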