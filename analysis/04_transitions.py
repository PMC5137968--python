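"""Tabulate group transitions between first and last visits.

Pairs each patient's baseline with the earliest follow-up 183-1461 days
later, classifies both ends with the fitted signature model, and writes the
training and validation transition matrices (counts with row percentages)
under results/transitions/.
"""

import argparse
from pathlib import Path

import pandas as pd

from mmse_groups.centroids import CentroidModel
from mmse_groups.transitions import pair_visits, transition_matrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--rates", type=Path, default=ROOT / "results" / "rates.csv")
    ap.add_argument("--signature", type=Path, default=ROOT / "results" / "signature")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "transitions")
    args = ap.parse_args()

    rates = pd.read_csv(args.rates, dtype={"patient_id": str})
    model = CentroidModel.from_json(args.signature / "model.json")
    pairs = pair_visits(rates)
    print(f"{len(pairs)} patients have a qualifying follow-up visit")

    args.out.mkdir(parents=True, exist_ok=True)
    for subset in ("training", "validation"):
        ids = set(pd.read_csv(args.signature / f"labels_{subset}.csv",
                              dtype=str)["patient_id"])
        sub = pairs[pairs["patient_id"].isin(ids)]
        tm = transition_matrix(sub, model)
        print(f"\n{subset} transitions ({tm.grand_total} patients):")
        print(tm.to_table().to_string())
        retention = {g: int(tm.proportions_rounded.loc[g, g]) for g in tm.groups}
        print(f"retention (%): {retention}")
        tm.to_table().to_csv(args.out / f"{subset}.csv")
    print(f"\nmatrices written to {args.out}")


if __name__ == "__main__":
    main()
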