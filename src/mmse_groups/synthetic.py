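"""Synthetic CAMD-like cohort generator.

The real multi-trial Alzheimer's cohort behind this analysis is
access-restricted, so the pipeline is exercised on synthetic cohorts that
emulate its published statistical structure:

* five latent cognitive groups (cognisant, inattentive, forgetful, distant,
  absent) with per-category mean success rates equal to the published
  training-set centroids (orientation/language means, which were not
  published, default to values consistent with the verbal group
  descriptions);
* three scoring dialects (30-, 56- and 51-point) mixed across trials;
* one follow-up visit per patient 6 months to 4 years after baseline, with
  the follow-up group drawn from the published first-to-last transition
  proportions;
* APOE genotypes for roughly a third of patients, with the risk genotypes
  (e3/e4, e4/e4) enriched in the more impaired groups;
* sparse medication records with brand/generic synonym noise and intake
  rates that can differ by group transition.

Per-category dispersion around the group centroid is a censored normal:
a Gaussian of standard deviation ``noise_sd`` clipped to [0, 100], then
discretised to the integer point scale of the patient's dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scoring import CATEGORIES, ScoringSystem, builtin_systems

#: Canonical group order, best to worst overall cognitive performance.
GROUPS: tuple[str, ...] = ("cognisant", "inattentive", "forgetful", "distant", "absent")

#: Published signature means for registration/attention/recall; the
#: orientation/language means are package defaults chosen to match the verbal
#: group descriptions while remaining far less group-discriminating than the
#: three signature categories (see docs/methods.md).
DEFAULT_CENTROIDS: dict[str, dict[str, float]] = {
    "cognisant":   {"orientation": 75.0, "registration": 100.0, "attention": 98.0, "recall": 83.3, "language": 88.0},
    "inattentive": {"orientation": 70.0, "registration": 93.3,  "attention": 44.0, "recall": 83.3, "language": 84.0},
    "forgetful":   {"orientation": 70.0, "registration": 93.3,  "attention": 94.0, "recall": 13.3, "language": 84.0},
    "distant":     {"orientation": 62.0, "registration": 100.0, "attention": 21.0, "recall": 6.7,  "language": 78.0},
    "absent":      {"orientation": 50.0, "registration": 43.3,  "attention": 18.0, "recall": 0.0,  "language": 62.0},
}

#: Published training-set group sizes.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "cognisant": 194,
    "inattentive": 261,
    "forgetful": 632,
    "distant": 589,
    "absent": 182,
}

#: Published training-set transition counts (first visit row, last visit column).
TRAINING_TRANSITION_COUNTS: dict[str, dict[str, int]] = {
    "cognisant":   {"cognisant": 60, "inattentive": 35, "forgetful": 33,  "distant": 9,   "absent": 1},
    "inattentive": {"cognisant": 33, "inattentive": 68, "forgetful": 22,  "distant": 44,  "absent": 10},
    "forgetful":   {"cognisant": 65, "inattentive": 28, "forgetful": 218, "distant": 86,  "absent": 24},
    "distant":     {"cognisant": 13, "inattentive": 25, "forgetful": 57,  "distant": 218, "absent": 67},
    "absent":      {"cognisant": 1,  "inattentive": 4,  "forgetful": 6,   "distant": 23,  "absent": 47},
}

#: Published validation-set transition counts.
VALIDATION_TRANSITION_COUNTS: dict[str, dict[str, int]] = {
    "cognisant":   {"cognisant": 76, "inattentive": 53, "forgetful": 30,  "distant": 9,   "absent": 6},
    "inattentive": {"cognisant": 35, "inattentive": 56, "forgetful": 19,  "distant": 48,  "absent": 18},
    "forgetful":   {"cognisant": 63, "inattentive": 28, "forgetful": 225, "distant": 89,  "absent": 25},
    # The published table prints 18 for distant->cognisant, but its own row
    # total (316), percentage (3%) and cognisant column total (183) all
    # require 8; the printed 18 is a typo.
    "distant":     {"cognisant": 8,   "inattentive": 23, "forgetful": 35,  "distant": 191, "absent": 59},
    "absent":      {"cognisant": 1,  "inattentive": 5,  "forgetful": 5,   "distant": 25,  "absent": 40},
}


def _rows_to_proportions(counts: Mapping[str, Mapping[str, float]]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for g, row in counts.items():
        total = float(sum(row.values()))
        out[g] = {h: row[h] / total for h in row}
    return out


DEFAULT_TRANSITIONS: dict[str, dict[str, float]] = _rows_to_proportions(
    TRAINING_TRANSITION_COUNTS
)

#: Genotype distributions per group; risk genotypes (e3/e4, e4/e4) are most
#: common in the distant group and least in cognisant/inattentive, and e2/e2
#: does not occur — matching the published qualitative pattern.
DEFAULT_APOE_FREQS: dict[str, dict[str, float]] = {
    "cognisant":   {"e2/e3": 0.08, "e2/e4": 0.02, "e3/e3": 0.45, "e3/e4": 0.37, "e4/e4": 0.08},
    "inattentive": {"e2/e3": 0.06, "e2/e4": 0.02, "e3/e3": 0.45, "e3/e4": 0.38, "e4/e4": 0.09},
    "forgetful":   {"e2/e3": 0.05, "e2/e4": 0.02, "e3/e3": 0.38, "e3/e4": 0.43, "e4/e4": 0.12},
    "distant":     {"e2/e3": 0.03, "e2/e4": 0.02, "e3/e3": 0.30, "e3/e4": 0.47, "e4/e4": 0.18},
    "absent":      {"e2/e3": 0.04, "e2/e4": 0.02, "e3/e3": 0.32, "e3/e4": 0.45, "e4/e4": 0.17},
}

#: Brand/generic synonyms; every raw name carries its generic as a tag so the
#: harmonization step can merge them.
DRUG_SYNONYMS: dict[str, tuple[str, ...]] = {
    "donepezil": ("donepezil", "Aricept"),
    "memantine": ("memantine", "Namenda"),
    "galantamine": ("galantamine", "Razadyne"),
    "rivastigmine": ("rivastigmine", "Exelon"),
    "citalopram": ("citalopram", "Celexa"),
    "sertraline": ("sertraline", "Zoloft"),
    "aspirin": ("aspirin", "acetylsalicylic acid"),
    "lorazepam": ("lorazepam", "Ativan"),
    "multivitamins": ("multivitamins", "multivitamin complex"),
    "ginkgo biloba": ("ginkgo biloba", "ginkgo extract"),
}

#: Baseline intake probabilities, with transition-specific overrides mirroring
#: the published medication-transition associations (higher multivitamin
#: intake among stable cognisant patients; higher citalopram intake on
#: inattentive->absent; higher ginkgo intake on distant->absent).
DEFAULT_MEDICATION_RATES: dict = {
    "default": {
        "donepezil": 0.30,
        "memantine": 0.15,
        "galantamine": 0.08,
        "rivastigmine": 0.08,
        "citalopram": 0.05,
        "sertraline": 0.05,
        "aspirin": 0.15,
        "lorazepam": 0.06,
        "multivitamins": 0.04,
        "ginkgo biloba": 0.04,
    },
    "overrides": {
        ("cognisant", "cognisant"): {"multivitamins": 0.12},
        ("inattentive", "absent"): {"citalopram": 0.15},
        ("distant", "absent"): {"ginkgo biloba": 0.12},
    },
}

DEFAULT_DIALECT_MIX: dict[str, float] = {"mmse30": 0.60, "mmse56": 0.25, "mmse51": 0.15}


@dataclass
class SyntheticCohortConfig:
    """All knobs of the generator; defaults are the published cohort structure."""

    group_names: tuple[str, ...] = GROUPS
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    centroids: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CENTROIDS.items()}
    )
    noise_sd: float = 8.0
    dialect_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DIALECT_MIX))
    transition_matrix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_TRANSITIONS.items()}
    )
    followup_day_range: tuple[int, int] = (183, 1461)
    apoe_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_APOE_FREQS.items()}
    )
    apoe_coverage: float = 1.0 / 3.0
    medication_rates: dict = field(
        default_factory=lambda: {
            "default": dict(DEFAULT_MEDICATION_RATES["default"]),
            "overrides": {k: dict(v) for k, v in DEFAULT_MEDICATION_RATES["overrides"].items()},
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.group_names:
            raise ConfigurationError("group_names is empty")
        sizes = {g: int(self.group_sizes.get(g, 0)) for g in self.group_names}
        if any(v < 0 for v in sizes.values()):
            raise ConfigurationError("group sizes must be non-negative")
        if sum(sizes.values()) == 0:
            raise ConfigurationError("all group sizes are zero")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if abs(sum(self.dialect_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("dialect_mix proportions must sum to 1")
        known = set(builtin_systems())
        if not set(self.dialect_mix) <= known:
            raise ConfigurationError(f"unknown dialects in mix: {set(self.dialect_mix) - known}")
        for g in self.group_names:
            row = self.transition_matrix.get(g)
            if row is None or abs(sum(row.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"transition row for {g!r} is not stochastic")
            cent = self.centroids.get(g)
            if cent is None or set(CATEGORIES) - set(cent):
                raise ConfigurationError(f"centroid for {g!r} missing categories")
            if any(not 0 <= cent[c] <= 100 for c in CATEGORIES):
                raise ConfigurationError(f"centroid for {g!r} outside [0, 100]")
            freqs = self.apoe_freqs.get(g)
            if freqs is None or abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"APOE frequencies for {g!r} do not sum to 1")
        lo, hi = self.followup_day_range
        if not (0 < lo <= hi):
            raise ConfigurationError("followup_day_range must satisfy 0 < min <= max")
        if not 0 <= self.apoe_coverage <= 1:
            raise ConfigurationError("apoe_coverage must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """Generated cohort: visit table plus ancillary tables and ground truth."""

    visits: pd.DataFrame
    apoe: pd.DataFrame
    medications: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticCohortConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.visits.to_csv(outdir / "visits.csv", index=False)
        self.apoe.to_csv(outdir / "apoe.csv", index=False)
        self.medications.to_csv(outdir / "medications.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


def _rates_to_raw(rates: np.ndarray, system: ScoringSystem) -> np.ndarray:
    """Discretise percent rates onto the dialect's integer point scale."""
    mx = np.array([system.max_points[c] for c in CATEGORIES], dtype=float)
    return np.rint(rates * mx / 100.0).astype(int)


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic given ``config.seed``.

    A single RNG stream is consumed in patient order with a fixed number of
    draws per patient, so extending ``group_sizes`` leaves earlier patients'
    records unchanged.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    systems = builtin_systems()
    dialect_names = sorted(config.dialect_mix)
    dialect_probs = np.array([config.dialect_mix[d] for d in dialect_names])
    groups = list(config.group_names)
    drugs = sorted(config.medication_rates["default"])
    overrides = config.medication_rates.get("overrides", {})

    patients: list[str] = []
    first_groups: list[str] = []
    for g in groups:
        n_g = int(config.group_sizes.get(g, 0))
        first_groups.extend([g] * n_g)
    n = len(first_groups)
    patients = [f"P{i:05d}" for i in range(n)]

    visit_rows: list[dict] = []
    truth_rows: list[dict] = []
    apoe_rows: list[dict] = []
    med_rows: list[dict] = []
    lo, hi = config.followup_day_range

    for pid, g_first in zip(patients, first_groups):
        dialect = dialect_names[int(rng.choice(len(dialect_names), p=dialect_probs))]
        system = systems[dialect]

        mu_first = np.array([config.centroids[g_first][c] for c in CATEGORIES])
        rates_first = np.clip(rng.normal(mu_first, config.noise_sd), 0.0, 100.0)

        row = config.transition_matrix[g_first]
        probs = np.array([row.get(h, 0.0) for h in groups])
        g_last = groups[int(rng.choice(len(groups), p=probs))]
        followup_day = int(rng.integers(lo, hi + 1))

        mu_last = np.array([config.centroids[g_last][c] for c in CATEGORIES])
        rates_last = np.clip(rng.normal(mu_last, config.noise_sd), 0.0, 100.0)

        for day, rates in ((0, rates_first), (followup_day, rates_last)):
            raw = _rates_to_raw(rates, system)
            rec = {
                "patient_id": pid,
                "trial_id": f"trial-{dialect}",
                "visit_day": day,
            }
            rec.update({c: int(v) for c, v in zip(CATEGORIES, raw)})
            rec["total"] = int(raw.sum())
            visit_rows.append(rec)

        # Fixed draw count per patient: genotype draws happen regardless of coverage.
        has_apoe = rng.random() < config.apoe_coverage
        freqs = config.apoe_freqs[g_first]
        genos = sorted(freqs)
        geno = genos[int(rng.choice(len(genos), p=np.array([freqs[x] for x in genos])))]
        if has_apoe:
            a1, a2 = geno.split("/")
            apoe_rows.append({"patient_id": pid, "allele1": a1, "allele2": a2})

        trans_over = overrides.get((g_first, g_last), {})
        for drug in drugs:
            p_take = trans_over.get(drug, config.medication_rates["default"][drug])
            take = rng.random() < p_take
            synonyms = DRUG_SYNONYMS.get(drug, (drug,))
            raw_name = synonyms[int(rng.integers(len(synonyms)))]
            if take:
                med_rows.append(
                    {"patient_id": pid, "raw_name": raw_name, "tags": drug}
                )

        truth_rows.append(
            {
                "patient_id": pid,
                "first_group": g_first,
                "last_group": g_last,
                "dialect": dialect,
            }
        )

    visits = pd.DataFrame(
        visit_rows,
        columns=["patient_id", "trial_id", "visit_day", *CATEGORIES, "total"],
    )
    apoe = pd.DataFrame(apoe_rows, columns=["patient_id", "allele1", "allele2"])
    medications = pd.DataFrame(med_rows, columns=["patient_id", "raw_name", "tags"])
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "first_group", "last_group", "dialect"]
    )
    return SyntheticCohort(visits, apoe, medications, truth, config)


def generate_transition_labels(
    n: int,
    matrix: Mapping[str, Mapping[str, float]],
    seed: int,
    first_group_probs: Optional[Mapping[str, float]] = None,
) -> list[tuple[str, str]]:
    """Draw ``n`` (first_group, last_group) pairs from a row-stochastic matrix.

    ``first_group_probs`` gives the marginal over first-visit groups
    (uniform over the matrix rows by default).  Empirical row proportions
    converge to the matrix rows as ``n`` grows.
    """
    groups = list(matrix)
    for g in groups:
        if abs(sum(matrix[g].values()) - 1.0) > 1e-9:
            raise ConfigurationError(f"transition row for {g!r} is not stochastic")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    if first_group_probs is None:
        p_first = np.full(len(groups), 1.0 / len(groups))
    else:
        p_first = np.array([first_group_probs.get(g, 0.0) for g in groups])
        if abs(p_first.sum() - 1.0) > 1e-9:
            raise ConfigurationError("first_group_probs must sum to 1")
    firsts = rng.choice(len(groups), size=n, p=p_first)
    out: list[tuple[str, str]] = []
    for gi in firsts:
        row = matrix[groups[gi]]
        probs = np.array([row.get(h, 0.0) for h in groups])
        li = int(rng.choice(len(groups), p=probs))
        out.append((groups[gi], groups[li]))
    return out


def scaled_config(scale: float, seed: int = 0, **kwargs) -> SyntheticCohortConfig:
    """A paper-structured config with group sizes scaled by ``scale`` (for fast tests)."""
    sizes = {g: max(1, int(round(v * scale))) for g, v in DEFAULT_GROUP_SIZES.items()}
    return replace(SyntheticCohortConfig(seed=seed, **kwargs), group_sizes=sizes)
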