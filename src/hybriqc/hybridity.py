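"""F1 hybridity classification and cohort summaries.

A putative F1 is authenticated at the loci that are *informative* for its
cross — markers where the two parents are opposite homozygotes. Its
hybridity score is

    hybridity% = 100 * L_het / n_evaluable

where L_het counts heterozygous F1 calls among the evaluable informative
loci (informative loci with a non-missing F1 call; missing calls are
dropped from numerator and denominator alike). Classification:

* no informative loci at all (Pm == 0)      -> UNDETERMINED_NO_POLYMORPHISM
* fewer than ``min_informative`` evaluable  -> UNDETERMINED_MISSING
* hybridity% >= threshold (default 20)      -> TRUE_HYBRID
* otherwise                                 -> SELF

A selfed offspring of a homozygous female is homozygous for the female
allele at every informative locus, so its expected score is 0%; a true
hybrid's is 100%. The threshold absorbs genotyping error. A male-allele
homozygote at an informative locus counts as non-het (towards SELF) but
is flagged separately: it is inconsistent with selfing and suggests
pollen contamination or an outcross.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (CrossDesign, GenotypeMatrix, HET, HOM1, HOM2,
                          MISSING)
from .polymorphism import NA_SCORE, pair_polymorphism_table, score_parental_pair

__all__ = [
    "Category", "HybridityResult", "classify_f1", "hybridity_table",
    "cross_success_table", "success_distribution", "cohort_summary",
    "summarize_counts", "heterozygosity_contrast", "round_half_up",
]


class Category(str, enum.Enum):
    TRUE_HYBRID = "TRUE_HYBRID"
    SELF = "SELF"
    UNDETERMINED_MISSING = "UNDETERMINED_MISSING"
    UNDETERMINED_NO_POLYMORPHISM = "UNDETERMINED_NO_POLYMORPHISM"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 -> 1), as used in reported percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HybridityResult:
    f1_id: str
    cross_id: str
    L_het: int
    Pm: int                      # informative loci for the parents
    n_evaluable: int             # informative loci with a non-missing F1 call
    n_missing_informative: int
    hybridity_percent: float     # NaN when undetermined
    category: Category
    male_hom_count: int = 0      # evaluable loci where the F1 is the male homozygote
    outcross_flag: bool = False


def classify_f1(f1_calls: np.ndarray, pair_scores: np.ndarray,
                threshold: float = 20.0, min_informative: int = 1,
                male_calls: np.ndarray | None = None,
                f1_id: str = "", cross_id: str = "") -> HybridityResult:
    """Classify one putative F1 against its cross's marker scores.

    ``pair_scores`` is the 1/0/NA vector from
    :func:`hybriqc.polymorphism.score_parental_pair`. The boundary goes to
    TRUE_HYBRID: a score exactly at ``threshold`` is a hybrid. When
    ``male_calls`` is supplied, male-homozygote F1 calls at informative
    loci are counted and flagged as a possible outcross signal.
    """
    f1 = np.asarray(f1_calls, dtype=np.int8)
    scores = np.asarray(pair_scores, dtype=np.int8)
    if f1.shape != scores.shape:
        raise ValueError("f1_calls and pair_scores have different lengths")
    informative = scores == 1
    pm = int(informative.sum())
    evaluable = informative & (f1 != MISSING)
    n_eval = int(evaluable.sum())
    l_het = int((f1[evaluable] == HET).sum())
    male_hom = 0
    if male_calls is not None and n_eval:
        m = np.asarray(male_calls, dtype=np.int8)
        male_hom = int((f1[evaluable] == m[evaluable]).sum())
    if pm == 0:
        category, percent = Category.UNDETERMINED_NO_POLYMORPHISM, np.nan
    elif n_eval < min_informative:
        category, percent = Category.UNDETERMINED_MISSING, np.nan
    else:
        percent = 100.0 * l_het / n_eval
        category = Category.TRUE_HYBRID if percent >= threshold else Category.SELF
    return HybridityResult(
        f1_id=f1_id, cross_id=cross_id, L_het=l_het, Pm=pm,
        n_evaluable=n_eval, n_missing_informative=pm - n_eval,
        hybridity_percent=percent, category=category,
        male_hom_count=male_hom,
        outcross_flag=male_hom > 0 and category is Category.SELF)


def hybridity_table(matrix: GenotypeMatrix, design: CrossDesign,
                    threshold: float = 20.0, min_informative: int = 1,
                    het_parent_policy: str = "na",
                    pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Classify every designed F1; one row per F1.

    F1s listed in the design but absent from the genotype table are
    reported as UNDETERMINED_MISSING with a note. ``pairs`` (from
    :func:`pair_polymorphism_table`) is recomputed when not supplied.
    """
    n_markers = matrix.n_markers
    rows = []
    for cross in design.crosses:
        genotyped = cross.female_id in matrix and cross.male_id in matrix
        if genotyped:
            male = matrix.calls_for(cross.male_id)
            scores = score_parental_pair(matrix.calls_for(cross.female_id),
                                         male, het_parent_policy)
        else:
            male = None
            scores = np.full(n_markers, NA_SCORE, dtype=np.int8)
        for f1_id in cross.f1_ids:
            if f1_id in matrix:
                res = classify_f1(matrix.calls_for(f1_id), scores,
                                  threshold=threshold,
                                  min_informative=min_informative,
                                  male_calls=male, f1_id=f1_id,
                                  cross_id=cross.cross_id)
                note = ""
            else:
                pm = int((scores == 1).sum())
                cat = (Category.UNDETERMINED_NO_POLYMORPHISM if pm == 0
                       else Category.UNDETERMINED_MISSING)
                res = HybridityResult(f1_id=f1_id, cross_id=cross.cross_id,
                                      L_het=0, Pm=pm, n_evaluable=0,
                                      n_missing_informative=pm,
                                      hybridity_percent=np.nan, category=cat)
                note = "not genotyped"
            rows.append({
                "f1_id": res.f1_id, "cross_id": res.cross_id,
                "L_het": res.L_het, "Pm": res.Pm,
                "n_evaluable": res.n_evaluable,
                "n_missing_informative": res.n_missing_informative,
                "hybridity_percent": res.hybridity_percent,
                "category": res.category.value,
                "male_hom_count": res.male_hom_count,
                "outcross_flag": res.outcross_flag,
                "note": note,
            })
    return pd.DataFrame(rows)


def cross_success_table(results: pd.DataFrame, design: CrossDesign,
                        include_undetermined: bool = False) -> pd.DataFrame:
    """Per-cross hybridity success rate: 100 * n_true / n_total.

    By default undetermined F1s are excluded from n_total; with
    ``include_undetermined`` they count against the cross. Crosses where
    every F1 is undetermined get NaN success and undetermined=True.
    """
    unknown = set(results["cross_id"]) - {c.cross_id for c in design.crosses}
    if unknown:
        raise KeyError(f"results reference unknown crosses: {sorted(unknown)}")
    rows = []
    grouped = dict(list(results.groupby("cross_id")))
    for cross in design.crosses:
        sub = grouped.get(cross.cross_id)
        if sub is None:
            rows.append({"cross_id": cross.cross_id, "n_true": 0, "n_self": 0,
                         "n_undetermined": 0, "n_total": 0,
                         "success_rate": np.nan, "undetermined": True})
            continue
        n_true = int((sub["category"] == Category.TRUE_HYBRID.value).sum())
        n_self = int((sub["category"] == Category.SELF.value).sum())
        n_undet = len(sub) - n_true - n_self
        n_total = len(sub) if include_undetermined else n_true + n_self
        rows.append({
            "cross_id": cross.cross_id, "n_true": n_true, "n_self": n_self,
            "n_undetermined": n_undet, "n_total": n_total,
            "success_rate": np.nan if n_total == 0 else 100.0 * n_true / n_total,
            "undetermined": n_total == 0,
        })
    return pd.DataFrame(rows)


def success_distribution(cross_table: pd.DataFrame) -> dict[str, float]:
    """Share of crosses at 100% / 0% / intermediate / undetermined success."""
    n = len(cross_table)
    rate = cross_table["success_rate"]
    full = int((rate == 100.0).sum())
    zero = int((rate == 0.0).sum())
    undet = int(cross_table["undetermined"].sum())
    inter = n - full - zero - undet
    out = {"n_crosses": n, "n_full_success": full, "n_zero_success": zero,
           "n_intermediate": inter, "n_undetermined": undet}
    if n:
        out.update({
            "pct_full_success": 100.0 * full / n,
            "pct_zero_success": 100.0 * zero / n,
            "pct_intermediate": 100.0 * inter / n,
            "pct_undetermined": 100.0 * undet / n,
        })
    return out


def summarize_counts(counts: Mapping[str, int]) -> dict:
    """Counts -> percentages (unrounded and half-up integer) over their total.

    Keys are category names; any key starting with 'UNDETERMINED' also
    feeds an aggregated 'UNDETERMINED_TOTAL' entry.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("at least one counted result is required")
    pct = {k: 100.0 * v / total for k, v in counts.items()}
    undet = sum(v for k, v in counts.items() if k.startswith("UNDETERMINED"))
    out = {
        "counts": dict(counts),
        "total": total,
        "percent_unrounded": pct,
        "percent": {k: int(round_half_up(v)) for k, v in pct.items()},
    }
    out["counts"]["UNDETERMINED_TOTAL"] = undet
    out["percent_unrounded"]["UNDETERMINED_TOTAL"] = 100.0 * undet / total
    out["percent"]["UNDETERMINED_TOTAL"] = int(round_half_up(100.0 * undet / total))
    return out


def cohort_summary(results: pd.DataFrame) -> dict:
    """Four-way category breakdown of a classified F1 cohort."""
    counts = {c.value: int((results["category"] == c.value).sum())
              for c in Category}
    return summarize_counts(counts)


_HET_BINS = ["0%", ">0-<6%", "6-10%", ">10%", "filtered_out"]


def _het_bin(pr_het: float, pr_missing: float, missing_filter: float) -> str:
    if pr_missing > missing_filter or not np.isfinite(pr_het):
        return "filtered_out"
    if pr_het == 0.0:
        return "0%"
    if pr_het < 0.06:
        return ">0-<6%"
    if pr_het <= 0.10:
        return "6-10%"
    return ">10%"


def heterozygosity_contrast(matrix: GenotypeMatrix, design: CrossDesign,
                            missing_filter: float = 0.10,
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample heterozygosity split into parent vs F1 groups.

    Returns (per_sample, inset, bins): per-sample pr_het/pr_missing with a
    group label; min/mean/max pr_het per group (samples passing the
    missingness filter); and counts per heterozygosity bin (0%, >0-<6%,
    6-10%, >10%, filtered_out) per group. Samples exceeding the
    missingness filter land in the filtered_out bin and are excluded from
    the inset.
    """
    parents = set(design.parent_ids)
    f1s = set(design.f1_ids)
    pr_het = matrix.pr_het_per_sample()
    pr_miss = matrix.pr_missing_per_sample()
    rows = []
    for s in matrix.sample_ids:
        group = ("parent" if s in parents
                 else "F1" if s in f1s else "unassigned")
        rows.append({"sample_id": s, "group": group,
                     "pr_het": float(pr_het[s]), "pr_missing": float(pr_miss[s]),
                     "het_bin": _het_bin(pr_het[s], pr_miss[s], missing_filter)})
    per_sample = pd.DataFrame(rows)
    kept = per_sample[per_sample["het_bin"] != "filtered_out"]
    inset = (kept.groupby("group")["pr_het"].agg(["min", "mean", "max"])
             if not kept.empty else pd.DataFrame(columns=["min", "mean", "max"]))
    bins = (per_sample.groupby(["group", "het_bin"]).size()
            .unstack(fill_value=0)
            .reindex(columns=_HET_BINS, fill_value=0))
    return per_sample, inset, bins
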