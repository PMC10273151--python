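"""End-to-end study replication: modeling arm, validation arm, fixture arm.

``replicate_study`` runs the whole pipeline under one seed:

1. generate a modeling cohort (default 116 specimens = 1,160 groups),
   split each specimen's groups 9:1, train the scoring CNN and measure
   held-out ROC/AUC, accuracy at cutoff 0.500 and Youden cutoffs;
2. generate a validation cohort (default 40 specimens = 400 groups) with
   simulated frozen-section calls, then score spectral-alone, FS-alone
   and spectral-assisted-FS (fused) diagnosis, with PPV/NPV and AUCs;
3. evaluate the shipped 12-case FS-indeterminate worked example at the
   strict threshold.

Every metric in the report traces to the run's seed and config hash.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import time
from typing import Sequence

import numpy as np

from . import decision, evaluation
from .data import BinaryLabel, Specimen, cohort_summary
from .fixtures import load_indeterminate_cases
from .io import StudyConfig, config_hash
from .model import InvasionClassifier, InvasionClassifierResults
from .synthetic import sample_cohort

__all__ = [
    "StudyReport",
    "replicate_study",
    "validation_metrics",
    "seeded_replication_metrics",
]

log = logging.getLogger("specdx.study")


@dataclasses.dataclass
class StudyReport:
    modeling: dict
    validation: dict
    fixture: dict
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _specimen_seeds(seed: int, n: int) -> list[int]:
    """Derive independent child seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def validation_metrics(
    cohort: Sequence[Specimen],
    results: InvasionClassifierResults,
    threshold: float | str,
) -> dict:
    """Specimen-level spectral / FS-alone / fused diagnostics for a cohort.

    FS-alone accuracy counts indeterminate calls as incorrect (the
    rater gave no answer); the fused arm resolves them spectrally.
    ROC scores: infiltration index / 5 for the spectral arm, the
    three-level FS score for the FS arm, and for the fused arm the FS
    score where definite, else the scaled index.
    """
    scores = results.score_cohort(cohort)
    fs_map = {s.specimen_id: s.fs_call for s in cohort}
    diags = decision.diagnose_cohort(scores, fs_map, threshold)
    truth = {s.specimen_id: s.binary_label for s in cohort}

    y, spectral_calls, fused_calls, fs_ok, idx_scores, fs_scores, fused_scores = (
        [], [], [], [], [], [], []
    )
    for d in diags:
        label = truth[d.specimen_id]
        y.append(label)
        spectral_calls.append(d.spectral_call)
        fused_calls.append(d.fused_call)
        fs_binary = decision.fused_call(d.fs_score, None) if d.fs_score in (0.0, 1.0) else None
        fs_ok.append(fs_binary is not None and fs_binary is label)
        idx_scores.append(d.infiltration_index.value / 5.0)
        fs_scores.append(d.fs_score)
        fused_scores.append(
            d.fs_score if d.fs_score in (0.0, 1.0) else d.infiltration_index.value / 5.0
        )

    spectral = evaluation.diagnostic_metrics(spectral_calls, y)
    fused = evaluation.diagnostic_metrics(fused_calls, y)
    n = len(y)
    n_indeterminate = sum(1 for s in fs_scores if s == 0.5)
    fs_accuracy = sum(fs_ok) / n

    y_bin = [1 if v is BinaryLabel.IAC else 0 for v in y]
    aucs = {}
    for name, s in (("spectral", idx_scores), ("fs", fs_scores), ("fused", fused_scores)):
        try:
            aucs[name] = evaluation.auc(evaluation.roc_curve(s, y_bin))
        except ValueError:
            aucs[name] = None

    return {
        "n_specimens": n,
        "n_fs_indeterminate": n_indeterminate,
        "threshold": decision.THRESHOLD_PROFILES.get(threshold, threshold)
        if isinstance(threshold, str)
        else threshold,
        "spectral_accuracy_pct": round(100 * spectral.accuracy, 2),
        "fs_accuracy_pct": round(100 * fs_accuracy, 2),
        "fused_accuracy_pct": round(100 * fused.accuracy, 2),
        "fused_ppv_pct": None if fused.ppv is None else round(100 * fused.ppv, 2),
        "fused_npv_pct": None if fused.npv is None else round(100 * fused.npv, 2),
        "auc": aucs,
    }


def _fixture_metrics(threshold: float | str) -> dict:
    df = load_indeterminate_cases()
    if isinstance(threshold, str):
        threshold = decision.THRESHOLD_PROFILES[threshold]
    calls = [decision.spectral_call(v, threshold) for v in df["infiltration_index"]]
    labels = [t.binary_label for t in df["truth"]]
    m = evaluation.diagnostic_metrics(calls, labels)
    under = sum(
        1
        for c, t in zip(calls, labels)
        if t is BinaryLabel.IAC and c is BinaryLabel.NON_IAC
    )
    over = sum(
        1
        for c, t in zip(calls, labels)
        if t is BinaryLabel.NON_IAC and c is BinaryLabel.IAC
    )
    return {
        "n_cases": len(df),
        "threshold": threshold,
        "spectral_accuracy_pct": round(100 * m.accuracy, 2),
        "n_correct": m.tp + m.tn,
        "n_underestimates": under,
        "n_overestimates": over,
    }


def seeded_replication_metrics(
    config: StudyConfig | None = None,
    seed: int = 1,
    validation_n: int | None = None,
) -> dict:
    """One seeded modeling+validation run; the unit the medians are taken over.

    Generates a modeling cohort, fits the scoring CNN on the
    within-specimen 9:1 split, measures held-out AUC and accuracy at
    cutoff 0.500, then generates a validation cohort with simulated FS
    calls and measures the spectral / FS-alone / fused specimen
    accuracies.  Returns the metrics plus the fitted results object.
    """
    config = config or StudyConfig()
    seeds = _specimen_seeds(seed, 4)
    cohort = sample_cohort(config.generator, seed=seeds[0])
    split = dataclasses.replace(config.split, seed=seeds[1])
    model = InvasionClassifier.from_cohort(cohort, split, config.model)
    results = model.fit(seed=seeds[2])
    vgen = dataclasses.replace(
        config.generator,
        n_specimens=config.validation_n if validation_n is None else validation_n,
    )
    vcohort = sample_cohort(vgen, seed=seeds[3], with_fs=True)
    validation = validation_metrics(vcohort, results, config.validation_threshold)
    return {
        "seed": seed,
        "n_modeling_specimens": len(cohort),
        "test_auc": results.auc,
        "test_accuracy_pct": 100.0 * results.accuracy(0.5),
        "validation": validation,
        "results": results,
    }


def replicate_study(config: StudyConfig | None = None) -> StudyReport:
    """Run the full seeded replication and return the report."""
    config = config or StudyConfig()
    chash = config_hash(config)
    seeds = _specimen_seeds(config.seed, 4)
    t0 = time.time()

    # --- modeling arm ------------------------------------------------------
    modeling_cohort = sample_cohort(config.generator, seed=seeds[0])
    log.info(
        "stage=modeling-cohort seed=%d %s elapsed=%.1fs",
        seeds[0], cohort_summary(modeling_cohort), time.time() - t0,
    )
    split = dataclasses.replace(config.split, seed=seeds[1])
    model = InvasionClassifier.from_cohort(modeling_cohort, split, config.model)
    results = model.fit(seed=seeds[2])
    log.info(
        "stage=train n_train=%d n_test=%d final_loss=%.4f elapsed=%.1fs",
        len(model.train_records), len(model.test_records),
        results.history[-1], time.time() - t0,
    )

    def auc_stat(idx: np.ndarray) -> float | None:
        sids = np.array([r.specimen_id for r in model.test_records])
        probs = results.test_probabilities
        labels = results.test_labels
        unique = sids[np.sort(np.unique(sids, return_index=True)[1])]
        take = np.concatenate([np.flatnonzero(sids == unique[i]) for i in idx])
        if len(set(labels[take])) < 2:
            return None
        return evaluation.auc(evaluation.roc_curve(probs[take], labels[take]))

    n_test_specimens = len({r.specimen_id for r in model.test_records})
    auc_lo, auc_hi, _ = evaluation.bootstrap_ci(
        auc_stat, n_test_specimens, b=max(100, config.bootstrap_b), seed=seeds[2]
    )
    youden = results.youden_table(2)
    modeling = {
        "n_specimens": len(modeling_cohort),
        "n_groups": sum(len(s.groups) for s in modeling_cohort),
        "n_train_groups": len(model.train_records),
        "n_test_groups": len(model.test_records),
        "test_auc": round(results.auc, 3),
        "test_auc_ci95": [round(auc_lo, 3), round(auc_hi, 3)],
        "test_accuracy_pct_at_0.500": round(100 * results.accuracy(0.5), 2),
        "youden_cutoffs": [
            {
                "cutoff": round(float(r.cutoff), 3),
                "sensitivity": round(float(r.sensitivity), 3),
                "specificity": round(float(r.specificity), 3),
                "youden_j": round(float(r.youden_j), 3),
            }
            for _, r in youden.iterrows()
        ],
        "final_train_loss": round(results.history[-1], 4),
    }
    log.info("stage=modeling-metrics auc=%.3f acc=%.2f%%",
             results.auc, modeling["test_accuracy_pct_at_0.500"])

    # --- validation arm ----------------------------------------------------
    vgen = dataclasses.replace(config.generator, n_specimens=config.validation_n)
    validation_cohort = sample_cohort(vgen, seed=seeds[3], with_fs=True)
    log.info("stage=validation-cohort seed=%d %s",
             seeds[3], cohort_summary(validation_cohort))
    validation = validation_metrics(
        validation_cohort, results, config.validation_threshold
    )
    log.info("stage=validation-metrics %s", validation)

    # --- fixture arm --------------------------------------------------------
    fixture = _fixture_metrics(config.fixture_threshold)

    from . import __version__

    provenance = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": chash,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "runtime_seconds": round(time.time() - t0, 1),
    }
    return StudyReport(modeling, validation, fixture, provenance)
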