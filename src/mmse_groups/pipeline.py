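"""End-to-end replication pipeline.

Chains the stages — dialect inference, normalization, train/validation split,
Ward clustering of the training set, Kruskal–Wallis category selection,
centroid computation, validation-set classification, longitudinal transition
matrices and association tests — behind one entry point with explicit seeds.

Cluster indices coming out of Ward are anonymous; they are given group names
by Hungarian matching of the cluster centroids (registration/attention/recall)
to the packaged published centroids, or to generator truth where available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import __version__ as _pkg_version
from .associations import (
    apoe_group_association,
    genotype_from_alleles,
    harmonize_drugs,
    medication_transition_scan,
)
from .centroids import (
    CentroidModel,
    agreement,
    classify_frame,
    compute_centroids,
    kruskal_wallis_by_category,
    paper_model,
    select_categories,
)
from .clustering import distance_matrix, ward_cluster
from .errors import ConfigurationError, ValidationError
from .scoring import CATEGORIES, builtin_systems, infer_scoring_systems, normalize_frame
from .synthetic import GROUPS, SyntheticCohort, SyntheticCohortConfig, generate_cohort
from .transitions import DEFAULT_WINDOW, pair_visits, transition_matrix


@dataclass
class PipelineConfig:
    """Configuration of :func:`run_replication`."""

    synthetic: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    split_fraction: float = 0.5
    split_seed: int = 12345
    k: int = 5
    n_categories_keep: int = 3
    window: tuple[int, int] = DEFAULT_WINDOW
    last_rule: str = "earliest"
    outdir: Optional[str] = None

    def validate(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigurationError("split_fraction must be in (0, 1)")
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        self.synthetic.validate()


def split_cohort(
    patient_ids: Sequence[str], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Random disjoint, exhaustive split into training and validation ids.

    Training receives ``floor(n * fraction)`` patients — with an odd cohort at
    fraction 0.5 the extra patient lands in validation, matching the published
    1858/1859 split of 3717 patients.  Deterministic per seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must be in (0, 1)")
    ids = sorted(str(p) for p in patient_ids)
    if len(ids) < 2:
        raise ValidationError("need at least two patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(len(ids) * fraction))
    train = sorted(ids[i] for i in perm[:n_train])
    valid = sorted(ids[i] for i in perm[n_train:])
    return train, valid


def match_cluster_labels(
    predicted: Mapping[str, object], truth: Mapping[str, str]
) -> dict[object, str]:
    """Map anonymous cluster labels onto true group names.

    Hungarian assignment maximising the confusion-matrix diagonal; every
    predicted label gets a distinct group name.
    """
    pred = pd.Series(predicted)
    tr = pd.Series(truth)
    pred.index = pred.index.astype(str)
    tr.index = tr.index.astype(str)
    conf = pd.crosstab(pred, tr.reindex(pred.index))
    row_ind, col_ind = linear_sum_assignment(-conf.to_numpy())
    return {
        conf.index[i]: str(conf.columns[j]) for i, j in zip(row_ind, col_ind)
    }


def name_clusters_by_model(
    cluster_model: CentroidModel, reference: Optional[CentroidModel] = None
) -> dict[str, str]:
    """Name anonymous clusters after the nearest reference centroids (1-to-1).

    Matching uses the categories common to both models; the packaged
    published model is the default reference.
    """
    ref = reference if reference is not None else paper_model()
    cats = [c for c in ref.categories if c in cluster_model.categories]
    if not cats:
        raise ValidationError("no categories shared with the reference model")
    A = np.array([[cluster_model.centroids[g][c] for c in cats] for g in cluster_model.groups])
    B = np.array([[ref.centroids[g][c] for c in cats] for g in ref.groups])
    cost = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    row_ind, col_ind = linear_sum_assignment(cost)
    return {
        str(cluster_model.groups[i]): str(ref.groups[j])
        for i, j in zip(row_ind, col_ind)
    }


def first_visit_rates(rates: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: the earliest visit in a success-rate table."""
    df = rates.sort_values(["patient_id", "visit_day"], kind="stable")
    return df.groupby("patient_id", as_index=False, sort=True).first()


@dataclass
class RecoveryResult:
    """Outcome of the pipeline-recovery experiment on one synthetic cohort."""

    selected_categories: tuple[str, ...]
    model: CentroidModel  # cluster centroids over the selected categories
    full_model: CentroidModel  # cluster centroids over all five categories
    truth_agreement: float  # fraction of patients whose matched cluster equals truth
    n: int


def recovery_experiment(
    config: SyntheticCohortConfig, k: int = 5, n_keep: int = 3
) -> RecoveryResult:
    """Generate a cohort, recluster it blind, and recover the signature.

    Runs Ward (k clusters) on the first-visit success rates of the full
    cohort, selects the top ``n_keep`` categories by Kruskal–Wallis over the
    cluster labels, computes cluster centroids, and names clusters by
    Hungarian matching against generator truth.  Used to check that the
    pipeline recovers the configured group structure.
    """
    cohort = generate_cohort(config)
    systems = {t: inf.system for t, inf in infer_scoring_systems(cohort.visits).items()}
    rates = normalize_frame(cohort.visits, systems)
    first = first_visit_rates(rates)

    dm = distance_matrix(first, CATEGORIES)
    clust = ward_cluster(dm, k)
    truth = dict(zip(cohort.truth["patient_id"], cohort.truth["first_group"]))
    rename = match_cluster_labels(clust.labels, truth)
    named = {pid: rename[lab] for pid, lab in clust.labels.items()}

    kw = kruskal_wallis_by_category(first, named)
    selected = select_categories(kw, n_keep)
    model = compute_centroids(first, named, selected, provenance="pipeline recovery")
    full_model = compute_centroids(first, named, CATEGORIES, provenance="pipeline recovery, all categories")
    agree = float(np.mean([named[p] == truth[p] for p in named]))
    return RecoveryResult(selected, model, full_model, agree, len(named))


def run_replication(config: PipelineConfig) -> dict:
    """Full replication on a synthetic cohort; returns a structured report.

    When ``config.outdir`` is set, writes labels, the fitted model, agreement
    figures, transition matrices, association tables and a run manifest.
    """
    config.validate()
    cohort = generate_cohort(config.synthetic)
    n_patients = cohort.truth["patient_id"].nunique()

    inference = infer_scoring_systems(cohort.visits)
    ambiguous = sorted(t for t, inf in inference.items() if inf.ambiguous)
    systems = {t: inf.system for t, inf in inference.items() if inf.system is not None}
    visits = cohort.visits[cohort.visits["trial_id"].isin(systems)]
    rates = normalize_frame(visits, systems)
    first = first_visit_rates(rates)

    train_ids, valid_ids = split_cohort(
        first["patient_id"], config.split_fraction, config.split_seed
    )
    first_train = first[first["patient_id"].isin(train_ids)].reset_index(drop=True)
    first_valid = first[first["patient_id"].isin(valid_ids)].reset_index(drop=True)

    # --- training: cluster, select, fit ---
    dm = distance_matrix(first_train, CATEGORIES)
    clust = ward_cluster(dm, config.k)
    kw = kruskal_wallis_by_category(first_train, clust.labels)
    selected = select_categories(kw, config.n_categories_keep)
    raw_model = compute_centroids(
        first_train, clust.labels, selected, provenance="training-set Ward clusters"
    )
    rename = name_clusters_by_model(raw_model)
    named_labels = {pid: rename[str(lab)] for pid, lab in clust.labels.items()}
    model = CentroidModel(
        categories=raw_model.categories,
        centroids={rename[str(g)]: dict(raw_model.centroids[g]) for g in raw_model.groups},
        provenance=raw_model.provenance,
    )
    model.centroids = {
        g: model.centroids[g] for g in GROUPS if g in model.centroids
    }

    # --- agreement between cluster labels and centroid classification ---
    model5 = compute_centroids(
        first_train, named_labels, CATEGORIES, provenance="all five categories"
    )
    agree3 = agreement(named_labels, classify_frame(first_train, model).to_dict())
    agree5 = agreement(named_labels, classify_frame(first_train, model5).to_dict())

    labels_valid = classify_frame(first_valid, model)

    # --- longitudinal transitions ---
    pairs = pair_visits(rates, config.window, last_rule=config.last_rule)
    pairs_train = pairs[pairs["patient_id"].isin(train_ids)]
    pairs_valid = pairs[pairs["patient_id"].isin(valid_ids)]
    tm_train = transition_matrix(pairs_train, model)
    tm_valid = transition_matrix(pairs_valid, model)

    # --- associations ---
    genotypes = genotype_from_alleles(cohort.apoe)
    all_labels = dict(named_labels)
    all_labels.update(labels_valid.to_dict())
    apoe_train = apoe_group_association(genotypes, pd.Series(named_labels))
    apoe_valid = apoe_group_association(genotypes, labels_valid)

    meds = harmonize_drugs(cohort.medications)
    per_patient = {}
    for subset, prs in (("training", pairs_train), ("validation", pairs_valid)):
        firstg = classify_frame(
            prs[["patient_id"] + [f"first_{c}" for c in model.categories]].rename(
                columns={f"first_{c}": c for c in model.categories}
            ),
            model,
        )
        lastg = classify_frame(
            prs[["patient_id"] + [f"last_{c}" for c in model.categories]].rename(
                columns={f"last_{c}": c for c in model.categories}
            ),
            model,
        )
        per_patient[subset] = pd.DataFrame(
            {
                "patient_id": firstg.index,
                "first_group": firstg.values,
                "last_group": lastg.values,
            }
        )
    med_tests = {
        subset: medication_transition_scan(meds, per_patient[subset])
        for subset in per_patient
    }

    report = {
        "n_patients": int(n_patients),
        "n_training": len(train_ids),
        "n_validation": len(valid_ids),
        "ambiguous_trials": ambiguous,
        "k": int(clust.k),
        "selected_categories": list(selected),
        "kruskal_wallis": {
            c: {"H": r.statistic, "p": r.pvalue, "log10_p": r.log10_pvalue}
            for c, r in kw.items()
        },
        "centroids": model.centroids,
        "agreement_3cat": {"percent": agree3.percent_agreement, "kappa": agree3.kappa},
        "agreement_5cat": {"percent": agree5.percent_agreement, "kappa": agree5.kappa},
        "validation_group_sizes": labels_valid.value_counts().to_dict(),
        "transitions_training_total": tm_train.grand_total,
        "transitions_validation_total": tm_valid.grand_total,
        "apoe_p_training": apoe_train.pvalue,
        "apoe_p_validation": apoe_valid.pvalue,
        "seeds": {"cohort": config.synthetic.seed, "split": config.split_seed},
        "version": _pkg_version,
    }

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.Series(named_labels, name="group").rename_axis("patient_id").to_csv(
            out / "labels_training.csv"
        )
        labels_valid.rename_axis("patient_id").to_csv(out / "labels_validation.csv")
        model.to_json(out / "model.json")
        tm_train.to_table().to_csv(out / "transitions_training.csv")
        tm_valid.to_table().to_csv(out / "transitions_validation.csv")
        apoe_train.rates.to_csv(out / "apoe_training.csv", index=False)
        apoe_valid.rates.to_csv(out / "apoe_validation.csv", index=False)
        for subset, table in med_tests.items():
            table.to_csv(out / f"medication_tests_{subset}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(report, indent=2, default=str))

    report["medication_tests"] = med_tests
    report["transition_matrices"] = {"training": tm_train, "validation": tm_valid}
    report["model"] = model
    return report
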