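"""Association tests: APOE genotype composition and medication-transition links.

Tests whether the APOE risk genotypes (e3/e4, e4/e4) are unevenly
distributed across the five groups (k-group proportion test) and scans every
(transition, drug) stratum with a two-sided binomial test against the pooled
other destinations.  Writes tidy tables under results/associations/.
"""

import argparse
from pathlib import Path

import pandas as pd

from mmse_groups.associations import (
    apoe_group_association,
    genotype_from_alleles,
    harmonize_drugs,
    medication_transition_scan,
)
from mmse_groups.centroids import CentroidModel, classify_frame
from mmse_groups.transitions import pair_visits

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--rates", type=Path, default=ROOT / "results" / "rates.csv")
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--signature", type=Path, default=ROOT / "results" / "signature")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "associations")
    args = ap.parse_args()

    rates = pd.read_csv(args.rates, dtype={"patient_id": str})
    model = CentroidModel.from_json(args.signature / "model.json")
    genotypes = genotype_from_alleles(pd.read_csv(args.cohort / "apoe.csv", dtype=str))
    args.out.mkdir(parents=True, exist_ok=True)

    for subset in ("training", "validation"):
        labels = pd.read_csv(args.signature / f"labels_{subset}.csv",
                             dtype=str).set_index("patient_id")["group"]
        res = apoe_group_association(genotypes, labels)
        print(f"{subset}: APOE risk-genotype rates by group "
              f"(proportion test p = {res.pvalue:.3g}, n = {res.rates['n'].sum()})")
        print(res.rates.to_string(index=False))
        res.rates.to_csv(args.out / f"apoe_{subset}.csv", index=False)

    meds = harmonize_drugs(pd.read_csv(args.cohort / "medications.csv", dtype=str))
    pairs = pair_visits(rates)
    firstg = classify_frame(
        pairs[["patient_id"] + [f"first_{c}" for c in model.categories]].rename(
            columns={f"first_{c}": c for c in model.categories}), model)
    lastg = classify_frame(
        pairs[["patient_id"] + [f"last_{c}" for c in model.categories]].rename(
            columns={f"last_{c}": c for c in model.categories}), model)
    trans = pd.DataFrame({"patient_id": firstg.index,
                          "first_group": firstg.values,
                          "last_group": lastg.values})
    scan = medication_transition_scan(meds, trans)
    scan.to_csv(args.out / "medication_tests.csv", index=False)
    hits = scan[scan["p_value"] < 0.05]
    print(f"\n{len(scan)} (transition, drug) strata tested; "
          f"{len(hits)} below p = 0.05:")
    if len(hits):
        print(hits.head(10).to_string(index=False))
    print(f"\ntables written to {args.out}")


if __name__ == "__main__":
    main()
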