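"""APOE-group association, drug-name harmonization, medication-transition tests.

Three loosely related pieces of the downstream analysis:

* a k-group test of equal proportions (chi-square, Yates-corrected in the
  two-group case) used for APOE risk-genotype composition across groups;
* harmonization of free-text drug names into canonical titles by merging
  names that share a category tag (brand vs generic);
* a binomial test comparing a drug's intake rate in one group transition
  against the rate among comparator transitions, labelling the direction
  "beneficial" when higher intake accompanies the relatively better outcome
  and "adverse" otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .synthetic import GROUPS

#: Risk alleles combination considered "poor prognosis" genotypes.
DEFAULT_RISK_SET: frozenset[str] = frozenset({"e3/e4", "e4/e4"})

#: Outcome ranking, best to worst.  Inattentive and forgetful share virtually
#: the same total-score level and are ranked equal.
GROUP_RANK: dict[str, int] = {
    "cognisant": 0,
    "inattentive": 1,
    "forgetful": 1,
    "distant": 2,
    "absent": 3,
}


def proportion_test(
    successes: Sequence[int], totals: Sequence[int]
) -> tuple[float, float]:
    """Chi-square test that k groups share one success proportion.

    Yates continuity correction is applied in the two-group case, matching
    the behaviour of the standard R proportion test.
    """
    succ = np.asarray(successes, dtype=int)
    tot = np.asarray(totals, dtype=int)
    if len(succ) < 2:
        raise ValidationError("need at least two groups")
    if (tot <= 0).any():
        raise ValidationError("all group totals must be positive")
    if ((succ < 0) | (succ > tot)).any():
        raise ValidationError("successes must lie in [0, total]")
    table = np.vstack([succ, tot - succ])
    if np.all(succ == 0) or np.all(succ == tot):
        return 0.0, 1.0  # degenerate: identical proportions at a boundary
    res = stats.chi2_contingency(table, correction=(len(succ) == 2))
    return float(res.statistic), float(res.pvalue)


@dataclass
class ApoeAssociation:
    """Per-group risk-genotype incidence and the k-group proportion test."""

    rates: pd.DataFrame  # columns: group, n, risk_carriers, risk_rate
    statistic: float
    pvalue: float


def apoe_group_association(
    genotypes: Mapping[str, str] | pd.Series,
    labels: Mapping[str, str] | pd.Series,
    risk_set: Iterable[str] = DEFAULT_RISK_SET,
) -> ApoeAssociation:
    """Compare the incidence of risk genotypes across patient groups.

    Only genotyped patients enter; groups with no genotyped patient are
    dropped.  Raises if fewer than two groups remain.
    """
    geno = pd.Series(genotypes).astype(str)
    lab = pd.Series(labels).astype(str)
    geno.index = geno.index.astype(str)
    lab.index = lab.index.astype(str)
    common = geno.index.intersection(lab.index)
    if len(common) == 0:
        raise ValidationError("no genotyped, labelled patients")
    risk = frozenset(risk_set)
    df = pd.DataFrame({"genotype": geno.loc[common], "group": lab.loc[common]})
    df["is_risk"] = df["genotype"].isin(risk)
    order = [g for g in GROUPS if g in set(df["group"])] or sorted(set(df["group"]))
    rows = []
    for g in order:
        sub = df.loc[df["group"] == g]
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "risk_carriers": int(sub["is_risk"].sum()),
                "risk_rate": float(sub["is_risk"].mean()),
            }
        )
    rates = pd.DataFrame(rows)
    if len(rates) < 2:
        raise ValidationError("need at least two groups with genotyped patients")
    stat, p = proportion_test(rates["risk_carriers"].tolist(), rates["n"].tolist())
    return ApoeAssociation(rates, stat, p)


def genotype_from_alleles(apoe: pd.DataFrame) -> pd.Series:
    """Collapse allele1/allele2 columns into a sorted genotype string (e.g. 'e3/e4')."""
    alleles = apoe[["allele1", "allele2"]].astype(str)
    geno = alleles.apply(lambda r: "/".join(sorted((r["allele1"], r["allele2"]))), axis=1)
    return pd.Series(geno.values, index=apoe["patient_id"].astype(str), name="genotype")


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", str(name).strip().casefold())


def _tag_set(tags: object) -> frozenset[str]:
    if tags is None or (isinstance(tags, float) and np.isnan(tags)):
        return frozenset()
    if isinstance(tags, str):
        parts = [t for t in (p.strip().casefold() for p in tags.split(";")) if t]
        return frozenset(parts)
    return frozenset(_normalize_name(t) for t in tags)


def harmonize_drugs(records: pd.DataFrame) -> pd.DataFrame:
    """Merge drug names that share at least one category tag.

    Names (case-folded, whitespace-normalized) are nodes of a graph with an
    edge between any two names sharing a tag; each connected component is one
    drug, canonically named by its lexicographically smallest member.
    Untagged names remain singletons.  Returns the input with ``canonical_name``
    added; empty input passes through.
    """
    if records.empty:
        out = records.copy()
        out["canonical_name"] = pd.Series(dtype=str)
        return out
    if (records["raw_name"].astype(str).str.strip() == "").any():
        raise ValidationError("empty raw_name in medication records")
    df = records.copy()
    df["_name"] = df["raw_name"].map(_normalize_name)
    df["_tags"] = df["tags"].map(_tag_set) if "tags" in df else [frozenset()] * len(df)

    g = nx.Graph()
    tag_to_names: dict[str, set[str]] = {}
    for name, tags in zip(df["_name"], df["_tags"]):
        g.add_node(name)
        for t in tags:
            tag_to_names.setdefault(t, set()).add(name)
    for names in tag_to_names.values():
        names = sorted(names)
        for other in names[1:]:
            g.add_edge(names[0], other)

    canonical = {}
    for comp in nx.connected_components(g):
        rep = min(comp)
        for name in comp:
            canonical[name] = rep
    df["canonical_name"] = df["_name"].map(canonical)
    return df.drop(columns=["_name", "_tags"])


@dataclass
class MedicationTestResult:
    """Outcome of one drug-vs-transition binomial test."""

    drug: str
    from_group: str
    to_group: str
    comparator: str
    n_focal: int
    n_comparator: int
    intake_focal: int
    intake_comparator: int
    effect: str  # "beneficial" | "adverse" | "none" | "not-testable"
    pvalue: Optional[float]
    testable: bool


def medication_transition_test(
    medications: pd.DataFrame,
    transitions: pd.DataFrame,
    drug: str,
    from_group: str,
    to_group: str,
    comparator: str = "others",
) -> MedicationTestResult:
    """Binomial test of a drug's intake rate in one transition stratum.

    Parameters
    ----------
    medications:
        Harmonized records with ``patient_id`` and ``canonical_name``.
    transitions:
        One row per patient with ``patient_id, first_group, last_group``.
    drug:
        Canonical drug name to test.
    from_group, to_group:
        The focal transition stratum.
    comparator:
        ``"others"`` — all other destinations from ``from_group`` combined;
        ``"better"`` / ``"worse"`` — only destinations ranked above/below
        ``to_group`` in the outcome ordering.

    The focal intake count is tested against the comparator intake rate with
    a two-sided binomial test.  No multiple-testing correction is applied
    here; see :func:`medication_transition_scan`.
    """
    if comparator not in ("others", "better", "worse"):
        raise ValidationError(f"unknown comparator {comparator!r}")
    trans = transitions.copy()
    trans["patient_id"] = trans["patient_id"].astype(str)
    origin = trans.loc[trans["first_group"] == from_group]
    focal = origin.loc[origin["last_group"] == to_group]
    rank_to = GROUP_RANK[to_group]
    if comparator == "others":
        comp = origin.loc[origin["last_group"] != to_group]
    elif comparator == "better":
        comp = origin.loc[origin["last_group"].map(GROUP_RANK) < rank_to]
    else:
        comp = origin.loc[origin["last_group"].map(GROUP_RANK) > rank_to]
    if focal.empty:
        raise ValidationError(f"empty focal stratum {from_group}->{to_group}")
    if comp.empty:
        raise ValidationError(
            f"empty {comparator!r} comparator stratum for {from_group}->{to_group}"
        )

    takers = set(
        medications.loc[
            medications["canonical_name"] == drug, "patient_id"
        ].astype(str)
    )
    k_focal = int(focal["patient_id"].isin(takers).sum())
    k_comp = int(comp["patient_id"].isin(takers).sum())
    n_focal, n_comp = len(focal), len(comp)
    if k_focal == 0 and k_comp == 0:
        return MedicationTestResult(
            drug, from_group, to_group, comparator, n_focal, n_comp,
            0, 0, "not-testable", None, False,
        )
    p0 = k_comp / n_comp
    if 0.0 < p0 < 1.0:
        pvalue = float(stats.binomtest(k_focal, n_focal, p0, alternative="two-sided").pvalue)
    else:
        pvalue = 0.0 if (k_focal > 0) != (p0 > 0.0) or (0 < k_focal < n_focal) else 1.0

    rate_focal = k_focal / n_focal
    # Which stratum is the relatively better outcome? Compare destination ranks.
    comp_rank = float(comp["last_group"].map(GROUP_RANK).mean())
    focal_better = rank_to < comp_rank
    if rate_focal == p0:
        effect = "none"
    elif (rate_focal > p0) == focal_better:
        effect = "beneficial"
    else:
        effect = "adverse"
    return MedicationTestResult(
        drug, from_group, to_group, comparator, n_focal, n_comp,
        k_focal, k_comp, effect, pvalue, True,
    )


def medication_transition_scan(
    medications: pd.DataFrame,
    transitions: pd.DataFrame,
    comparator: str = "others",
    min_stratum: int = 10,
    adjust: bool = False,
) -> pd.DataFrame:
    """Test every (transition, drug) combination with enough patients.

    Returns a tidy table with columns ``from, to, treatment, effect, p_value``
    (plus counts).  ``adjust=True`` appends Benjamini–Hochberg adjusted
    p-values; the default reports raw p-values.
    """
    drugs = sorted(medications["canonical_name"].dropna().unique())
    rows = []
    for (f, t), grp in transitions.groupby(["first_group", "last_group"]):
        if len(grp) < min_stratum:
            continue
        for drug in drugs:
            try:
                res = medication_transition_test(
                    medications, transitions, drug, str(f), str(t), comparator
                )
            except ValidationError:
                continue
            if not res.testable:
                continue
            rows.append(
                {
                    "from": f,
                    "to": t,
                    "treatment": drug,
                    "effect": res.effect,
                    "p_value": res.pvalue,
                    "n_focal": res.n_focal,
                    "n_comparator": res.n_comparator,
                    "intake_focal": res.intake_focal,
                    "intake_comparator": res.intake_comparator,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "from", "to", "treatment", "effect", "p_value",
            "n_focal", "n_comparator", "intake_focal", "intake_comparator",
        ],
    )
    if adjust and len(out):
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"].to_numpy())
    return out.sort_values("p_value").reset_index(drop=True)
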