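"""Split, cluster the training half, and fit the centroid signature.

Half the cohort is Ward-clustered (k=5) on its five-category success rates;
the Kruskal-Wallis test ranks categories by how strongly they separate the
clusters; the three best form the signature over which per-group centroids
are computed.  Reports the agreement between cluster labels and
nearest-centroid classification (3-category and 5-category models) and
writes labels, the fitted model and diagnostics under results/signature/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mmse_groups.centroids import (
    agreement,
    classify_frame,
    compute_centroids,
    kruskal_wallis_by_category,
    select_categories,
)
from mmse_groups.clustering import distance_matrix, ward_cluster
from mmse_groups.pipeline import first_visit_rates, name_clusters_by_model, split_cohort
from mmse_groups.scoring import CATEGORIES

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--rates", type=Path, default=ROOT / "results" / "rates.csv")
    ap.add_argument("--split-seed", type=int, default=12345)
    ap.add_argument("--k", type=int, default=5)
    ap.add_argument("--keep", type=int, default=3)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "signature")
    args = ap.parse_args()

    rates = pd.read_csv(args.rates, dtype={"patient_id": str})
    first = first_visit_rates(rates)
    train_ids, valid_ids = split_cohort(first["patient_id"], 0.5, args.split_seed)
    train = first[first["patient_id"].isin(train_ids)].reset_index(drop=True)
    valid = first[first["patient_id"].isin(valid_ids)].reset_index(drop=True)
    print(f"split: {len(train)} training / {len(valid)} validation")

    clust = ward_cluster(distance_matrix(train, CATEGORIES), args.k)
    kw = kruskal_wallis_by_category(train, clust.labels)
    for c in CATEGORIES:
        print(f"  {c:<12} H = {kw[c].statistic:8.1f}   log10 p = {kw[c].log10_pvalue:8.1f}")
    selected = select_categories(kw, args.keep)
    print(f"selected categories: {', '.join(selected)}")

    raw_model = compute_centroids(train, clust.labels, selected,
                                  provenance="training-set Ward clusters")
    rename = name_clusters_by_model(raw_model)
    labels = {p: rename[str(l)] for p, l in clust.labels.items()}
    model = compute_centroids(train, labels, selected,
                              provenance="training-set Ward clusters")
    print("recovered centroids (%):")
    for g, cent in model.centroids.items():
        vals = "  ".join(f"{c}={v:5.1f}" for c, v in cent.items())
        print(f"  {g:<12} {vals}")

    model5 = compute_centroids(train, labels, CATEGORIES)
    agr3 = agreement(labels, classify_frame(train, model).to_dict())
    agr5 = agreement(labels, classify_frame(train, model5).to_dict())
    print(f"cluster vs 3-category centroid labels: {agr3.percent_agreement:.1f}% "
          f"(kappa {agr3.kappa:.3f})")
    print(f"cluster vs 5-category centroid labels: {agr5.percent_agreement:.1f}% "
          f"(kappa {agr5.kappa:.3f})")

    labels_valid = classify_frame(valid, model)
    print("validation group sizes:")
    print(labels_valid.value_counts().to_string())

    args.out.mkdir(parents=True, exist_ok=True)
    model.to_json(args.out / "model.json")
    pd.Series(labels, name="group").rename_axis("patient_id").to_csv(
        args.out / "labels_training.csv")
    labels_valid.rename_axis("patient_id").to_csv(args.out / "labels_validation.csv")
    (args.out / "diagnostics.json").write_text(json.dumps({
        "kruskal_wallis_log10_p": {c: kw[c].log10_pvalue for c in CATEGORIES},
        "selected_categories": list(selected),
        "agreement_3cat": {"percent": agr3.percent_agreement, "kappa": agr3.kappa},
        "agreement_5cat": {"percent": agr5.percent_agreement, "kappa": agr5.kappa},
    }, indent=2))
    print(f"model and labels written to {args.out}")


if __name__ == "__main__":
    main()
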