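"""Per-marker genetic summaries, panel screening, dataset filtering and
parental fingerprint reports.

Allele frequencies use gene counting: each homozygote contributes two
copies of its allele, each heterozygote one copy of each; missing calls
are excluded from the denominator. The polymorphism information content
of marker *j* is

    PIC_j = 1 - sum_i p_i^2

over its allele frequencies p_i, with a maximum of 0.5 at a biallelic
locus (p = q = 0.5). MAF/MnAF denote the major/minor allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import (GenotypeMatrix, GenotypeValidationError, HET, HOM1,
                          HOM2, MISSING, STATE_NAMES)

__all__ = [
    "allele_frequencies", "compute_pic", "marker_summary_table",
    "ScreenVerdict", "screen_marker", "screen_panel",
    "FilterResult", "filter_dataset", "fingerprint_report",
]

_STATE_LETTER = {int(HOM1): "A", int(HET): "H", int(HOM2): "B", int(MISSING): "-"}


def allele_frequencies(matrix: GenotypeMatrix, marker_id: str) -> tuple[float, float]:
    """Gene-count frequencies (freq_allele1, freq_allele2) at one marker."""
    j = matrix.marker_ids.index(marker_id)
    col = matrix.calls[:, j]
    n1 = 2 * int((col == HOM1).sum()) + int((col == HET).sum())
    n2 = 2 * int((col == HOM2).sum()) + int((col == HET).sum())
    total = n1 + n2
    if total == 0:
        raise GenotypeValidationError(
            f"marker {marker_id!r}: all calls missing, allele frequencies undefined")
    return n1 / total, n2 / total


def compute_pic(freqs: Sequence[float]) -> float:
    """Polymorphism information content 1 - sum(p_i^2) of an allele-frequency vector."""
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {p.sum()!r}, not 1")
    return float(1.0 - np.sum(p ** 2))


def marker_summary_table(matrix: GenotypeMatrix,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker summary statistics plus the panel-level inset.

    Returns
    -------
    per_marker : DataFrame with columns marker_id, maf, mnaf, pr_het,
        pr_missing, pic, n_called, defined. Markers with no non-missing
        calls have NaN maf/mnaf/pic, pr_missing 1.0 and defined=False.
    inset : DataFrame indexed {min, mean, max} over defined markers for
        each statistic.
    """
    calls = matrix.calls
    n = matrix.n_samples
    n_hom1 = (calls == HOM1).sum(axis=0)
    n_hom2 = (calls == HOM2).sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    n_called = n_hom1 + n_hom2 + n_het
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = (2 * n_hom1 + n_het) / (2 * n_called)
        f2 = (2 * n_hom2 + n_het) / (2 * n_called)
        pr_het = n_het / n_called
    maf = np.maximum(f1, f2)
    mnaf = np.minimum(f1, f2)
    pic = 1.0 - (f1 ** 2 + f2 ** 2)
    pr_missing = (calls == MISSING).sum(axis=0) / n
    per_marker = pd.DataFrame({
        "marker_id": matrix.marker_ids,
        "maf": maf, "mnaf": mnaf, "pr_het": pr_het,
        "pr_missing": pr_missing, "pic": pic,
        "n_called": n_called, "defined": n_called > 0,
    })
    stats = per_marker.loc[per_marker["defined"],
                           ["maf", "mnaf", "pr_het", "pr_missing", "pic"]]
    inset = pd.DataFrame({"min": stats.min(), "mean": stats.mean(),
                          "max": stats.max()}).T
    return per_marker, inset


@dataclass(frozen=True)
class ScreenVerdict:
    """Panel-screening outcome for one marker.

    A marker is *biased* when one allele is called more than
    ``bias_threshold`` of the time across a diverse set of accessions;
    it fails the heterozygosity screen when its heterozygous-call
    proportion reaches ``het_threshold``. Only unbiased, low-het markers
    pass into a QC panel.
    """

    marker_id: str
    biased: bool
    het_fail: bool

    @property
    def passed(self) -> bool:
        return not self.biased and not self.het_fail


def screen_marker(summary, bias_threshold: float = 0.75,
                  het_threshold: float = 0.04) -> ScreenVerdict:
    """Apply the neutrality and heterozygosity screening criteria.

    ``summary`` is any mapping/record with maf, pr_het and marker_id
    (e.g. a row of :func:`marker_summary_table`).
    """
    get = (summary.get if hasattr(summary, "get")
           else lambda k: getattr(summary, k))
    maf, pr_het = float(get("maf")), float(get("pr_het"))
    if not np.isfinite(maf):
        raise GenotypeValidationError(
            f"marker {get('marker_id')!r}: undefined frequencies, cannot screen")
    return ScreenVerdict(marker_id=str(get("marker_id")),
                         biased=maf > bias_threshold,
                         het_fail=pr_het >= het_threshold)


def screen_panel(per_marker: pd.DataFrame, bias_threshold: float = 0.75,
                 het_threshold: float = 0.04) -> pd.DataFrame:
    verdicts = [screen_marker(row, bias_threshold, het_threshold)
                for row in per_marker[per_marker["defined"]].to_dict("records")]
    return pd.DataFrame([{"marker_id": v.marker_id, "biased": v.biased,
                          "het_fail": v.het_fail, "passed": v.passed}
                         for v in verdicts])


@dataclass
class FilterResult:
    matrix: GenotypeMatrix
    removed_samples: list[tuple[str, float]]   # (sample_id, pr_missing)
    removed_markers: list[tuple[str, float]]   # (marker_id, mnaf; NaN if undefined)
    log: list[str] = field(default_factory=list)


def filter_dataset(matrix: GenotypeMatrix, max_missing_per_sample: float = 0.10,
                   min_mnaf: float = 0.0) -> FilterResult:
    """Remove high-missingness samples, then low-MnAF markers.

    Samples with pr_missing strictly greater than ``max_missing_per_sample``
    are removed first; markers whose minor allele frequency (recomputed on
    the surviving samples) is strictly below ``min_mnaf`` — or undefined —
    are removed second. Row/column order is preserved. Idempotent.
    """
    for name, t in (("max_missing_per_sample", max_missing_per_sample),
                    ("min_mnaf", min_mnaf)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    pr_miss = matrix.pr_missing_per_sample()
    keep_samples = [s for s in matrix.sample_ids
                    if pr_miss[s] <= max_missing_per_sample]
    removed_samples = [(s, float(pr_miss[s])) for s in matrix.sample_ids
                       if s not in set(keep_samples)]
    if not keep_samples:
        raise GenotypeValidationError(
            f"all {matrix.n_samples} samples exceed "
            f"{max_missing_per_sample:.0%} missingness; empty result")
    sub = matrix.subset(sample_ids=keep_samples)
    per_marker, _ = marker_summary_table(sub)
    mnaf = per_marker.set_index("marker_id")["mnaf"]
    keep_markers, removed_markers = [], []
    for m in sub.marker_ids:
        v = mnaf[m]
        if np.isfinite(v) and (v >= min_mnaf):
            keep_markers.append(m)
        elif not np.isfinite(v) and min_mnaf == 0.0:
            # undefined frequency but no MnAF requirement: retain
            keep_markers.append(m)
        else:
            removed_markers.append((m, float(v)))
    out = sub.subset(marker_ids=keep_markers)
    log = [
        f"sample filter (pr_missing > {max_missing_per_sample}): "
        f"removed {len(removed_samples)} of {matrix.n_samples} samples",
        f"marker filter (mnaf < {min_mnaf}): "
        f"removed {len(removed_markers)} of {matrix.n_markers} markers",
    ]
    return FilterResult(matrix=out, removed_samples=removed_samples,
                        removed_markers=removed_markers, log=log)


def fingerprint_report(matrix: GenotypeMatrix,
                       sample_ids: Sequence[str] | None = None,
                       reliability_threshold: float = 0.55) -> pd.DataFrame:
    """Per-sample marker fingerprints with reliability flags.

    The call string encodes one character per panel marker
    (A = homozygous allele 1, B = homozygous allele 2, H = heterozygous,
    '-' = missing). A fingerprint is *reliable* when its missing-call
    proportion does not exceed ``reliability_threshold`` (default: more
    than 55% missing is unreliable).
    """
    ids = list(matrix.sample_ids) if sample_ids is None else list(sample_ids)
    rows = []
    for s in ids:
        calls = matrix.calls_for(s)  # raises KeyError for unknown IDs
        pr_missing = float((calls == MISSING).mean())
        called = calls != MISSING
        pr_het = float((calls == HET).sum() / called.sum()) if called.any() else np.nan
        rows.append({
            "sample_id": s,
            "call_string": "".join(_STATE_LETTER[int(c)] for c in calls),
            "genotype": " ".join(m.genotype_text(c, sep=":")
                                 for m, c in zip(matrix.panel, calls)),
            "pr_missing": pr_missing,
            "pr_het": pr_het,
            "reliable": pr_missing <= reliability_threshold,
        })
    return pd.DataFrame(rows)
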