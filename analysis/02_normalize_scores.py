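"""Infer each trial's scoring dialect and normalize scores to success rates.

Raw category points are only comparable within a dialect; this step
attributes every trial to the 30-, 56- or 51-point system by candidate
elimination on the observed score distributions, then rescales each category
to a 0-100% success rate.  Writes results/rates.csv.
"""

import argparse
from pathlib import Path

from mmse_groups.scoring import infer_scoring_systems, normalize_frame, read_visits_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--visits", type=Path, default=ROOT / "results" / "cohort" / "visits.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "rates.csv")
    args = ap.parse_args()

    visits = read_visits_csv(args.visits)
    inferred = infer_scoring_systems(visits)
    for trial, res in sorted(inferred.items()):
        tag = "AMBIGUOUS" if res.ambiguous else res.system.name
        print(f"trial {trial}: {tag}  (survivors: {', '.join(s.name for s in res.survivors)})")

    systems = {t: r.system for t, r in inferred.items() if r.system is not None}
    kept = visits[visits["trial_id"].isin(systems)]
    dropped = visits["patient_id"].nunique() - kept["patient_id"].nunique()
    if dropped:
        print(f"excluded {dropped} patients from ambiguous trials")
    rates = normalize_frame(kept, systems)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    rates.to_csv(args.out, index=False)
    print(f"wrote {len(rates)} normalized visit rows to {args.out}")


if __name__ == "__main__":
    main()
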