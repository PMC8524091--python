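"""Synthetic genotype cohorts with ground truth for pipeline validation.

The generator emulates the structure a KASP-based hybridity QC assay
sees in a self-pollinating crop's crossing block:

* near-homozygous inbred female parents, each locus drawn homozygous for
  allele 1 with a configurable per-marker frequency and flipped to
  heterozygous at a small residual rate;
* two near-identical "sister line" males (male B is a copy of male A
  differing at a configurable number of loci);
* crosses of females onto the males, each producing a small F1 cohort in
  which every putative F1 is a true hybrid with probability (1 - s) and
  a female selfing otherwise — hybrids receive one gamete from each
  parent, selfings two independent gametes from the female (so a
  heterozygous female locus segregates 1:2:1 under selfing);
* per-call genotyping error (uniform swap to another called state) and
  per-call missingness, applied after truth is recorded.

Defaults mirror the cohort scale this package targets: 220 females and 2
males forming 225 crosses (five females crossed to both males, 17
crosses involving male B) with 1,436 F1s in total, selfing rate 0.15,
per-marker allele-1 frequency 0.75, residual heterozygosity 0.02 per
locus, missingness 0.03 per call, and identical sister males. See
docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import (Cross, CrossDesign, GenotypeMatrix, HET, HOM1,
                          HOM2, MISSING, MarkerDef, default_panel)
from .hybridity import Category

__all__ = [
    "MALE_A", "MALE_B", "SimConfig", "SimBundle",
    "make_cross_design", "study_cross_design",
    "simulate_parents", "simulate_f1_cohort", "corrupt_calls",
    "simulate_study", "recovery_report",
]

MALE_A = "MALE-A"
MALE_B = "MALE-B"

# study-scale design structure: (group, n_lines, n_reused, n_maleB_crosses)
_STUDY_GROUPS = (("IET", 89, 3, 15), ("PYT", 31, 2, 2),
                 ("AYT", 85, 0, 0), ("landrace", 15, 0, 0))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated crossing-block scenario."""

    n_females: int = 220
    n_f1_total: int = 1436
    selfing_rate: float = 0.15
    allele1_freq: float | Sequence[float] = 0.75
    residual_het_rate: float = 0.02
    missing_rate: float = 0.03
    genotyping_error_rate: float = 0.0
    sister_male_divergence: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("selfing_rate", "residual_het_rate", "missing_rate",
                     "genotyping_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_females < 1 or self.n_f1_total < 0:
            raise ValueError("n_females >= 1 and n_f1_total >= 0 required")

    def freq_vector(self, n_markers: int) -> np.ndarray:
        p = np.asarray(self.allele1_freq, dtype=float)
        if p.ndim == 0:
            p = np.full(n_markers, float(p))
        if p.size != n_markers:
            raise ValueError(
                f"allele1_freq has length {p.size}, panel has {n_markers} markers")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("allele frequencies must be in [0, 1]")
        return p


@dataclass
class SimBundle:
    """Everything one simulated scenario produced."""

    config: SimConfig
    panel: list[MarkerDef]
    design: CrossDesign
    parents_true: GenotypeMatrix   # uncorrupted parent genotypes
    parents: GenotypeMatrix        # observed (error + missingness applied)
    f1: GenotypeMatrix             # observed F1 calls
    truth: pd.DataFrame            # f1_id, cross_id, true_status

    @property
    def combined(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            sample_ids=self.parents.sample_ids + self.f1.sample_ids,
            panel=self.parents.panel,
            calls=np.vstack([self.parents.calls, self.f1.calls]))


def _female_ids(n: int) -> list[tuple[str, str]]:
    """(female_id, source_group) pairs; study groups when n == 220."""
    if n == 220:
        out = []
        for group, n_lines, _, _ in _STUDY_GROUPS:
            out += [(f"{group}-{k + 1:03d}", group) for k in range(n_lines)]
        return out
    return [(f"F-{k + 1:03d}", None) for k in range(n)]


def _distribute(total: int, n_bins: int) -> list[int]:
    base, extra = divmod(total, n_bins)
    return [base + 1 if k < extra else base for k in range(n_bins)]


def make_cross_design(female_ids: Sequence[str], n_f1_total: int,
                      male_id: str = MALE_A,
                      groups: Sequence[str | None] | None = None,
                      ) -> CrossDesign:
    """One cross per female to a single male, F1s distributed evenly."""
    counts = _distribute(n_f1_total, len(female_ids))
    crosses = []
    for k, (fid, n_f1) in enumerate(zip(female_ids, counts)):
        cid = f"C{k + 1:03d}"
        crosses.append(Cross(
            cross_id=cid, female_id=fid, male_id=male_id,
            f1_ids=tuple(f"{cid}-P{i + 1:02d}" for i in range(n_f1)),
            source_group=groups[k] if groups is not None else None))
    return CrossDesign(crosses=crosses)


def study_cross_design(n_f1_total: int = 1436) -> CrossDesign:
    """The study-scale crossing structure.

    220 females in four source groups; five females (three IET, two PYT)
    are crossed to both males, the rest once; male B receives 17 crosses
    (15 IET + 2 PYT); 225 crosses in total.
    """
    crosses: list[Cross] = []
    k = 0
    for group, n_lines, n_reused, n_male_b in _STUDY_GROUPS:
        fids = [f"{group}-{i + 1:03d}" for i in range(n_lines)]
        # reused lines cross to both males; then enough single crosses to
        # male B to reach the group's male-B total; the rest to male A
        extra_b = n_male_b - n_reused
        for i, fid in enumerate(fids):
            if i < n_reused:
                males = [MALE_A, MALE_B]
            elif i < n_reused + extra_b:
                males = [MALE_B]
            else:
                males = [MALE_A]
            for male in males:
                k += 1
                crosses.append(Cross(cross_id=f"C{k:03d}", female_id=fid,
                                     male_id=male, f1_ids=(),
                                     source_group=group))
    counts = _distribute(n_f1_total, len(crosses))
    crosses = [replace_f1s(c, counts[i]) for i, c in enumerate(crosses)]
    return CrossDesign(crosses=crosses)


def replace_f1s(cross: Cross, n_f1: int) -> Cross:
    return Cross(cross_id=cross.cross_id, female_id=cross.female_id,
                 male_id=cross.male_id,
                 f1_ids=tuple(f"{cross.cross_id}-P{i + 1:02d}"
                              for i in range(n_f1)),
                 source_group=cross.source_group)


def simulate_parents(config: SimConfig, panel: list[MarkerDef] | None = None,
                     rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw true (uncorrupted) parent genotypes.

    Each locus of each parent is HOM1 with probability p_j, else HOM2,
    then flipped to HET with ``residual_het_rate``. Male B is a copy of
    male A made homozygous-opposite at ``sister_male_divergence`` loci.
    """
    panel = default_panel() if panel is None else panel
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_markers = len(panel)
    p = config.freq_vector(n_markers)
    females = _female_ids(config.n_females)
    n = len(females)
    calls = np.where(rng.random((n + 1, n_markers)) < p[None, :], HOM1, HOM2
                     ).astype(np.int8)  # females + male A
    het = rng.random((n + 1, n_markers)) < config.residual_het_rate
    calls[het] = HET
    male_a = calls[-1]
    male_b = male_a.copy()
    k = min(config.sister_male_divergence, n_markers)
    if k:
        loci = rng.choice(n_markers, size=k, replace=False)
        male_b[loci] = np.where(male_b[loci] == HOM1, HOM2, HOM1)
    sample_ids = [fid for fid, _ in females] + [MALE_A, MALE_B]
    return GenotypeMatrix(sample_ids=sample_ids, panel=list(panel),
                          calls=np.vstack([calls[:-1], male_a[None, :],
                                           male_b[None, :]]))


def _gamete(calls: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete (0 = allele1, 1 = allele2 per locus) from a true genotype."""
    g = np.where(calls == HOM2, 1, 0).astype(np.int8)
    het = calls == HET
    g[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return g


def corrupt_calls(calls: np.ndarray, config: SimConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply genotyping error then missingness, per call."""
    out = calls.copy()
    if config.genotyping_error_rate > 0:
        err = (rng.random(out.shape) < config.genotyping_error_rate) \
            & (out != MISSING)
        # uniform swap to one of the two other called states
        shift = rng.integers(1, 3, size=out.shape, dtype=np.int8)
        out[err] = (out[err] + shift[err]) % 3
    if config.missing_rate > 0:
        out[rng.random(out.shape) < config.missing_rate] = MISSING
    return out


def simulate_f1_cohort(parents_true: GenotypeMatrix, design: CrossDesign,
                       config: SimConfig,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw F1 genotypes for every designed cross, then corrupt the calls.

    Returns the observed F1 matrix and the truth table
    (f1_id, cross_id, true_status in {HYBRID, SELF}).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_markers = parents_true.n_markers
    f1_ids, rows, truth = [], [], []
    for cross in design.crosses:
        try:
            female = parents_true.calls_for(cross.female_id)
            male = parents_true.calls_for(cross.male_id)
        except KeyError as exc:
            raise KeyError(
                f"cross {cross.cross_id!r} references an unsimulated parent: "
                f"{exc}") from None
        for f1_id in cross.f1_ids:
            is_hybrid = rng.random() >= config.selfing_rate
            if is_hybrid:
                geno = _gamete(female, rng) + _gamete(male, rng)
            else:
                geno = _gamete(female, rng) + _gamete(female, rng)
            # dosage sum 0/1/2 -> call state
            calls = np.select([geno == 0, geno == 1], [HOM1, HET], HOM2
                              ).astype(np.int8)
            f1_ids.append(f1_id)
            rows.append(calls)
            truth.append({"f1_id": f1_id, "cross_id": cross.cross_id,
                          "true_status": "HYBRID" if is_hybrid else "SELF"})
    calls = (np.vstack(rows) if rows
             else np.empty((0, n_markers), dtype=np.int8))
    observed = corrupt_calls(calls, config, rng)
    matrix = GenotypeMatrix(sample_ids=f1_ids, panel=list(parents_true.panel),
                            calls=observed)
    return matrix, pd.DataFrame(truth, columns=["f1_id", "cross_id",
                                                "true_status"])


def simulate_study(config: SimConfig | None = None,
                   panel: list[MarkerDef] | None = None,
                   design: CrossDesign | None = None) -> SimBundle:
    """Run the whole generator: parents, design, F1 cohort, corruption."""
    config = SimConfig() if config is None else config
    panel = default_panel() if panel is None else panel
    rng = np.random.default_rng(config.seed)
    parents_true = simulate_parents(config, panel=panel, rng=rng)
    if design is None:
        if config.n_females == 220:
            design = study_cross_design(config.n_f1_total)
        else:
            females = [fid for fid, _ in _female_ids(config.n_females)]
            design = make_cross_design(females, config.n_f1_total)
    f1, truth = simulate_f1_cohort(parents_true, design, config, rng=rng)
    parents = GenotypeMatrix(sample_ids=parents_true.sample_ids,
                             panel=list(panel),
                             calls=corrupt_calls(parents_true.calls, config, rng))
    return SimBundle(config=config, panel=panel, design=design,
                     parents_true=parents_true, parents=parents, f1=f1,
                     truth=truth)


def recovery_report(results: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Confusion matrix of classified vs simulated F1 status.

    Restricted to determined F1s (TRUE_HYBRID or SELF). Also returns the
    estimated selfing rate (classified-SELF fraction among determined),
    sensitivity for SELF detection and specificity (hybrids kept).
    """
    merged = results.merge(truth, on=["f1_id", "cross_id"], how="outer",
                           indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", "f1_id"].tolist()
        raise ValueError(f"results/truth ID mismatch: {bad[:5]}...")
    determined = merged[merged["category"].isin(
        [Category.TRUE_HYBRID.value, Category.SELF.value])]
    pred_self = determined["category"] == Category.SELF.value
    true_self = determined["true_status"] == "SELF"
    confusion = {
        ("HYBRID", "TRUE_HYBRID"): int((~true_self & ~pred_self).sum()),
        ("HYBRID", "SELF"): int((~true_self & pred_self).sum()),
        ("SELF", "TRUE_HYBRID"): int((true_self & ~pred_self).sum()),
        ("SELF", "SELF"): int((true_self & pred_self).sum()),
    }
    n = len(determined)
    n_true_self = int(true_self.sum())
    n_true_hyb = n - n_true_self
    return {
        "n_total": len(merged),
        "n_determined": n,
        "confusion": confusion,
        "s_hat": float(pred_self.sum() / n) if n else float("nan"),
        "sensitivity_self": (confusion[("SELF", "SELF")] / n_true_self
                             if n_true_self else float("nan")),
        "specificity": (confusion[("HYBRID", "TRUE_HYBRID")] / n_true_hyb
                        if n_true_hyb else float("nan")),
        "discordant": confusion[("HYBRID", "SELF")]
                      + confusion[("SELF", "TRUE_HYBRID")],
    }
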