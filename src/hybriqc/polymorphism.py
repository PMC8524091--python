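"""Per-cross marker polymorphism and per-marker efficiency.

For each cross, every panel marker is scored against the two parents:

* 1  — the parents are opposite homozygotes (the marker is *informative*
  for hybridity testing in this cross),
* 0  — the parents carry the same homozygous genotype,
* NA — either parental call is missing (and, under the default policy,
  either parent is heterozygous, since a het parent makes the locus
  undiagnostic for hybridity).

Percent parental polymorphism of a cross is 100 * Pm / Tm with Pm the
number of markers scored 1 and Tm the number scored non-NA. Marker
efficiency of marker j is 100 * fm / Tc with fm the number of crosses
where j scored 1 and Tc the number of crosses where j scored non-NA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import (CrossDesign, GenotypeMatrix, HET, HOM1, HOM2,
                          MISSING, MarkerDef)

__all__ = [
    "NA_SCORE", "score_parental_pair", "percent_parental_polymorphism",
    "pair_polymorphism_table", "marker_efficiency_table",
    "informative_marker_distribution",
]

NA_SCORE = np.int8(-1)  # sentinel inside int8 score vectors


def score_parental_pair(female_calls: np.ndarray, male_calls: np.ndarray,
                        het_parent_policy: str = "na") -> np.ndarray:
    """Score each marker 1 / 0 / NA for one parental pair.

    ``het_parent_policy`` is 'na' (heterozygous parent makes the locus
    uninformative; the default) or 'zero' (scored not-polymorphic).
    Symmetric in its two arguments.
    """
    f = np.asarray(female_calls, dtype=np.int8)
    m = np.asarray(male_calls, dtype=np.int8)
    if f.shape != m.shape:
        raise ValueError(
            f"call vectors have different lengths ({f.size} vs {m.size})")
    if het_parent_policy not in ("na", "zero"):
        raise ValueError(f"unknown het_parent_policy {het_parent_policy!r}")
    scores = np.zeros(f.shape, dtype=np.int8)
    opposite = ((f == HOM1) & (m == HOM2)) | ((f == HOM2) & (m == HOM1))
    scores[opposite] = 1
    na = (f == MISSING) | (m == MISSING)
    if het_parent_policy == "na":
        na |= (f == HET) | (m == HET)
    scores[na] = NA_SCORE
    return scores


def percent_parental_polymorphism(pm: int, tm: int) -> float:
    """100 * Pm / Tm; NaN (cross flagged upstream) when Tm == 0."""
    if tm < 0 or pm < 0 or pm > tm:
        raise ValueError(f"invalid counts Pm={pm}, Tm={tm}")
    return np.nan if tm == 0 else 100.0 * pm / tm


def pair_polymorphism_table(matrix: GenotypeMatrix, design: CrossDesign,
                            het_parent_policy: str = "na") -> pd.DataFrame:
    """Score every designed cross against the panel.

    Returns one row per cross: cross_id, female_id, male_id, one score
    column per marker (1.0 / 0.0 / NaN), Pm, Tm, percent_polymorphic
    (NaN with no_informative_data=True when Tm == 0), and
    parents_genotyped. Crosses whose parents are absent from the
    genotype table are retained with all-NA scores.
    """
    marker_ids = matrix.marker_ids
    rows = []
    for cross in design.crosses:
        genotyped = cross.female_id in matrix and cross.male_id in matrix
        if genotyped:
            scores = score_parental_pair(matrix.calls_for(cross.female_id),
                                         matrix.calls_for(cross.male_id),
                                         het_parent_policy)
        else:
            scores = np.full(len(marker_ids), NA_SCORE, dtype=np.int8)
        pm = int((scores == 1).sum())
        tm = int((scores != NA_SCORE).sum())
        row = {"cross_id": cross.cross_id, "female_id": cross.female_id,
               "male_id": cross.male_id}
        row.update({mid: (np.nan if s == NA_SCORE else float(s))
                    for mid, s in zip(marker_ids, scores)})
        row.update({"Pm": pm, "Tm": tm,
                    "percent_polymorphic": percent_parental_polymorphism(pm, tm),
                    "no_informative_data": tm == 0,
                    "parents_genotyped": genotyped})
        rows.append(row)
    return pd.DataFrame(rows)


def marker_efficiency_table(pairs: pd.DataFrame, marker_ids: list[str],
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker efficiency across all scored crosses, plus the inset.

    Returns
    -------
    per_marker : DataFrame with marker_id, fm (crosses scored 1),
        Tc (crosses scored non-NA), percent_efficiency (NaN when Tc == 0),
        defined.
    inset : min/mean/max of percent_efficiency over defined markers.
    """
    if pairs.empty:
        raise ValueError("at least one scored cross is required")
    rows = []
    for mid in marker_ids:
        col = pairs[mid]
        fm = int((col == 1.0).sum())
        tc = int(col.notna().sum())
        rows.append({"marker_id": mid, "fm": fm, "Tc": tc,
                     "percent_efficiency": np.nan if tc == 0 else 100.0 * fm / tc,
                     "defined": tc > 0})
    table = pd.DataFrame(rows)
    eff = table.loc[table["defined"], "percent_efficiency"]
    inset = pd.DataFrame({"percent_efficiency":
                          {"min": eff.min(), "mean": eff.mean(), "max": eff.max()}})
    return table, inset


def informative_marker_distribution(pairs: pd.DataFrame,
                                    low_threshold: int = 2,
                                    ) -> tuple[pd.Series, list[str]]:
    """Distribution of informative-marker counts across crosses.

    Returns the histogram of Pm values (index = Pm, values = number of
    crosses) and the cross IDs in the left tail (Pm <= ``low_threshold``),
    i.e. crosses where hybridity will be hard or impossible to call.
    """
    counts = pairs["Pm"].value_counts().sort_index()
    counts.index.name = "Pm"
    counts.name = "n_crosses"
    low = pairs.loc[pairs["Pm"] <= low_threshold, "cross_id"].tolist()
    return counts, low
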