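"""Pipeline orchestration: run every QC stage in order and emit the
study-style report bundle (CSV + JSON + newick), a run manifest and a log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import CrossDesign, GenotypeMatrix, MarkerDef
from . import hybridity as hy
from . import marker_stats as ms
from . import polymorphism as po
from . import relatedness as rel

__all__ = ["Thresholds", "run_pipeline", "write_bundle", "summarize_design"]


@dataclass(frozen=True)
class Thresholds:
    """Every numeric QC rule in one place (defaults are the standard ones)."""

    hybridity: float = 20.0          # % het at informative loci to call a hybrid
    min_informative: int = 1         # evaluable informative loci to classify
    parent_missing: float = 0.10     # sample missingness filter for relatedness
    fingerprint: float = 0.55        # missingness above which a fingerprint is unreliable
    related_pair: float = 2.0        # distance below which a pair is "related"
    bias: float = 0.75               # allele-frequency screening bound
    het_screen: float = 0.04         # heterozygous-call screening bound
    min_mnaf: float = 0.0            # marker MnAF filter
    het_parent_policy: str = "na"


def summarize_design(design: CrossDesign) -> pd.DataFrame:
    """Crossing-structure summary per source group, with a Total row.

    Counts unique female lines, lines used in more than one cross,
    crosses, and F1s.
    """
    rows = []
    groups: dict[str, list] = {}
    for c in design.crosses:
        groups.setdefault(c.source_group or "unassigned", []).append(c)
    for group, crosses in groups.items():
        females = [c.female_id for c in crosses]
        counts = pd.Series(females).value_counts()
        rows.append({
            "source_group": group,
            "n_lines": counts.size,
            "n_lines_used_twice": int((counts > 1).sum()),
            "n_crosses": len(crosses),
            "n_f1": sum(len(c.f1_ids) for c in crosses),
        })
    table = pd.DataFrame(rows, columns=["source_group", "n_lines",
                                        "n_lines_used_twice", "n_crosses",
                                        "n_f1"])
    all_females = pd.Series([c.female_id for c in design.crosses]).value_counts()
    total = {
        "source_group": "Total",
        "n_lines": int(all_females.size) if len(design.crosses) else 0,
        "n_lines_used_twice": int((all_females > 1).sum()) if len(design.crosses) else 0,
        "n_crosses": len(design.crosses),
        "n_f1": sum(len(c.f1_ids) for c in design.crosses),
    }
    return pd.concat([table, pd.DataFrame([total])], ignore_index=True)


def run_pipeline(matrix: GenotypeMatrix, design: CrossDesign,
                 thresholds: Thresholds | None = None) -> dict:
    """Execute the four analysis stages and return the in-memory bundle.

    Stages, in order: per-marker statistics and screening; parental
    fingerprints; per-cross polymorphism and marker efficiency; per-F1
    hybridity with cross/cohort summaries and the parent-vs-F1
    heterozygosity contrast; relatedness (distances, NJ tree, related
    pairs on missingness-filtered parents; PCA with marker contributions
    on all filtered samples). Deterministic for identical inputs.
    """
    t = thresholds or Thresholds()
    log: list[str] = []
    bundle: dict = {"thresholds": t, "log": log}

    validation = design.validate_against(matrix)
    bundle["validation"] = validation
    log.append(f"inputs: {matrix.n_samples} samples x {matrix.n_markers} "
               f"markers, {len(design)} crosses, {len(design.f1_ids)} F1s")
    for w in validation["warnings"]:
        log.append(f"warning: {w}")

    # stage 1: marker statistics + screening
    per_marker, inset = ms.marker_summary_table(matrix)
    bundle["marker_summary"] = per_marker
    bundle["marker_summary_inset"] = inset
    bundle["screen"] = ms.screen_panel(per_marker, bias_threshold=t.bias,
                                       het_threshold=t.het_screen)
    log.append(f"marker stats: {int(per_marker['defined'].sum())} of "
               f"{matrix.n_markers} markers with defined frequencies")

    # stage 2: parental fingerprints
    parents_in_matrix = [p for p in design.parent_ids if p in matrix]
    bundle["fingerprints"] = ms.fingerprint_report(
        matrix, parents_in_matrix, reliability_threshold=t.fingerprint)
    n_unreliable = int((~bundle["fingerprints"]["reliable"]).sum())
    log.append(f"fingerprints: {len(parents_in_matrix)} parents, "
               f"{n_unreliable} unreliable (> {t.fingerprint:.0%} missing)")

    # stage 3: polymorphism + marker efficiency
    pairs = po.pair_polymorphism_table(matrix, design,
                                       het_parent_policy=t.het_parent_policy)
    bundle["pair_polymorphism"] = pairs
    eff, eff_inset = po.marker_efficiency_table(pairs, matrix.marker_ids)
    bundle["marker_efficiency"] = eff
    bundle["marker_efficiency_inset"] = eff_inset
    pm_counts, low = po.informative_marker_distribution(pairs)
    bundle["pm_distribution"] = pm_counts
    bundle["low_polymorphism_crosses"] = low
    log.append(f"polymorphism: mean efficiency "
               f"{eff_inset.loc['mean', 'percent_efficiency']:.2f}%, "
               f"{len(low)} crosses with <= 2 informative markers")

    # stage 4: hybridity
    results = hy.hybridity_table(matrix, design, threshold=t.hybridity,
                                 min_informative=t.min_informative,
                                 het_parent_policy=t.het_parent_policy)
    bundle["hybridity_results"] = results
    cross_table = hy.cross_success_table(results, design)
    bundle["cross_success"] = cross_table
    bundle["success_distribution"] = hy.success_distribution(cross_table)
    bundle["cohort_summary"] = hy.cohort_summary(results)
    per_sample, het_inset, het_bins = hy.heterozygosity_contrast(
        matrix, design, missing_filter=t.parent_missing)
    bundle["heterozygosity_contrast"] = per_sample
    bundle["heterozygosity_inset"] = het_inset
    bundle["heterozygosity_bins"] = het_bins
    pct = bundle["cohort_summary"]["percent"]
    log.append(f"hybridity: {pct.get('TRUE_HYBRID', 0)}% true / "
               f"{pct.get('SELF', 0)}% self / "
               f"{pct.get('UNDETERMINED_TOTAL', 0)}% undetermined")

    # stage 5: relatedness (parents only for distances/NJ, per convention)
    parent_matrix = matrix.subset(sample_ids=parents_in_matrix)
    filt = ms.filter_dataset(parent_matrix,
                             max_missing_per_sample=t.parent_missing,
                             min_mnaf=t.min_mnaf)
    bundle["relatedness_filter"] = filt
    log.append(f"relatedness: {filt.matrix.n_samples} of "
               f"{parent_matrix.n_samples} parents pass the "
               f"{t.parent_missing:.0%} missingness filter")
    numeric_parents = rel.encode_numeric(filt.matrix)
    dist = rel.pairwise_distance(numeric_parents)
    bundle["distance"] = dist
    bundle["related_pairs"] = rel.flag_related_pairs(dist,
                                                     threshold=t.related_pair)
    finite = dist.values[np.triu_indices(len(dist.sample_ids), k=1)]
    finite = finite[np.isfinite(finite)]
    log.append(f"distances: range {finite.min():.2f}-{finite.max():.2f}, "
               f"mean {finite.mean():.2f}; "
               f"{len(bundle['related_pairs'])} pairs < {t.related_pair}")
    if filt.matrix.n_samples >= 3 and not dist.undefined_pairs:
        bundle["nj_tree"] = rel.neighbor_joining(dist)
    else:
        bundle["nj_tree"] = None
        log.append("warning: NJ tree skipped (undefined distances or < 3 samples)")

    # PCA on all samples passing the missingness filter (parents + F1s)
    all_filt = ms.filter_dataset(matrix,
                                 max_missing_per_sample=t.parent_missing,
                                 min_mnaf=t.min_mnaf)
    pca_res = rel.pca(rel.encode_numeric(all_filt.matrix))
    bundle["pca"] = pca_res
    bundle["marker_contributions"] = rel.marker_contributions(pca_res, dims=2)
    log.append(f"pca: PC1+PC2 explain "
               f"{pca_res.variance_explained[:2].sum():.1f}% of variance "
               f"({all_filt.matrix.n_samples} samples)")
    return bundle


def write_bundle(bundle: dict, outdir: str | Path) -> list[Path]:
    """Write every machine-readable artifact of a pipeline run.

    Output is deterministic for identical inputs (no timestamps in
    machine outputs; the log carries run narrative only).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        df.to_csv(p, **kw)
        written.append(p)

    def _json(name: str, obj) -> None:
        p = outdir / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable)
                     + "\n")
        written.append(p)

    _csv("marker_stats.csv", bundle["marker_summary"], index=False)
    _json("marker_stats_summary.json",
          bundle["marker_summary_inset"].to_dict())
    _csv("marker_screen.csv", bundle["screen"], index=False)
    _csv("fingerprints.csv", bundle["fingerprints"], index=False)
    _csv("pair_polymorphism.csv", bundle["pair_polymorphism"], index=False)
    _csv("marker_efficiency.csv", bundle["marker_efficiency"], index=False)
    _json("marker_efficiency_summary.json",
          bundle["marker_efficiency_inset"].to_dict())
    _csv("pm_distribution.csv", bundle["pm_distribution"].reset_index(),
         index=False)
    _csv("hybridity_results.csv", bundle["hybridity_results"], index=False)
    _csv("cross_success.csv", bundle["cross_success"], index=False)
    _json("cohort_summary.json", {
        "categories": bundle["cohort_summary"],
        "success_distribution": bundle["success_distribution"],
    })
    _csv("heterozygosity_contrast.csv", bundle["heterozygosity_contrast"],
         index=False)
    _csv("heterozygosity_bins.csv", bundle["heterozygosity_bins"])
    _csv("distance_matrix.csv", bundle["distance"].to_frame())
    _csv("related_pairs.csv", bundle["related_pairs"], index=False)
    if bundle["nj_tree"] is not None:
        p = outdir / "nj_tree.nwk"
        p.write_text(rel.tree_to_newick(bundle["nj_tree"]) + "\n")
        written.append(p)
    pca_dir = outdir / "pca"
    pca_dir.mkdir(exist_ok=True)
    for name, df in (("scores", bundle["pca"].scores),
                     ("loadings", bundle["pca"].loadings),
                     ("contributions", bundle["marker_contributions"])):
        p = pca_dir / f"{name}.csv"
        df.to_csv(p)
        written.append(p)
    _json("pca/variance.json", {
        "eigenvalues": bundle["pca"].eigenvalues.tolist(),
        "variance_explained": bundle["pca"].variance_explained.tolist(),
    })
    _json("manifest.json", {
        "tool": "hybriqc",
        "version": __version__,
        "thresholds": asdict(bundle["thresholds"]),
        "artifacts": sorted(str(p.relative_to(outdir)) for p in written),
        "validation": bundle["validation"],
    })
    (outdir / "run.log").write_text("\n".join(bundle["log"]) + "\n")
    written.append(outdir / "run.log")
    return written


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
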