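"""Readers, writers and the canonical in-memory containers for biallelic
KASP-style genotype calls.

A genotype call at a biallelic SNP is one of four states relative to the
marker's two panel alleles:

* ``HOM1`` — homozygous for allele 1 (e.g. ``T:T`` at a T/C marker),
* ``HOM2`` — homozygous for allele 2 (``C:C``),
* ``HET``  — heterozygous; the pair is unordered (``T:C`` == ``C:T``),
* ``MISSING`` — no call.

Calls are stored as an ``int8`` sample x marker grid (codes below), which
keeps a cohort of a few thousand samples x a low-density panel trivially
small and makes every downstream statistic a vectorized numpy expression.

Supported on-disk dialects:

* call-grid CSV/TSV — samples as rows, markers as columns, cells are
  allele pairs ("T:T", "T/C") or a missing token;
* HapMap — markers as rows with the 11 standard leading columns, samples
  as columns, two-letter genotype cells ("TC"), missing "NN".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOM1", "HET", "HOM2", "MISSING", "STATE_NAMES",
    "GenotypeValidationError", "MarkerDef", "GenotypeMatrix",
    "Cross", "CrossDesign",
    "read_marker_panel", "default_panel",
    "read_genotype_table", "write_call_grid", "write_hapmap",
    "read_cross_design", "write_cross_design",
]

# call-state codes; MISSING is negative so "state >= 0" selects called loci
HOM1 = np.int8(0)
HET = np.int8(1)
HOM2 = np.int8(2)
MISSING = np.int8(-1)

STATE_NAMES = {int(HOM1): "HOM1", int(HET): "HET", int(HOM2): "HOM2",
               int(MISSING): "MISSING"}

MISSING_TOKENS = {"?", "-", "--", "NA", "N", "NN", "", "?:?", "-:-", "-/-"}
_PAIR_SEPARATORS = (":", "/")

# HapMap leading columns (TASSEL-style)
HAPMAP_COLUMNS = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
                  "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]


class GenotypeValidationError(ValueError):
    """An input file or call grid violates a structural invariant."""


@dataclass(frozen=True)
class MarkerDef:
    """Definition of one biallelic SNP marker in a QC panel."""

    marker_id: str
    chromosome: int
    pos_start: int
    pos_end: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise GenotypeValidationError(
                f"marker {self.marker_id!r}: allele1 == allele2 ({self.allele1!r})")
        for a in (self.allele1, self.allele2):
            if len(a) != 1 or a.upper() not in "ACGT":
                raise GenotypeValidationError(
                    f"marker {self.marker_id!r}: invalid allele {a!r}")
        if self.pos_start > self.pos_end:
            raise GenotypeValidationError(
                f"marker {self.marker_id!r}: pos_start > pos_end")

    def call_from_alleles(self, a: str, b: str) -> np.int8:
        """Map an unordered allele pair to a call state code."""
        pair = {a, b}
        if not pair <= {self.allele1, self.allele2}:
            bad = sorted(pair - {self.allele1, self.allele2})
            raise GenotypeValidationError(
                f"allele(s) {bad} not in panel alleles "
                f"{self.allele1}/{self.allele2} of marker {self.marker_id!r}")
        if len(pair) == 2:
            return HET
        return HOM1 if a == self.allele1 else HOM2

    def genotype_text(self, state: int, sep: str = "") -> str:
        """Render a call state as allele text ('TT', 'T:C', 'NN'/'-:-')."""
        if state == MISSING:
            return f"-{sep}-" if sep else "NN"
        if state == HOM1:
            return f"{self.allele1}{sep}{self.allele1}"
        if state == HOM2:
            return f"{self.allele2}{sep}{self.allele2}"
        return f"{self.allele1}{sep}{self.allele2}"


@dataclass
class GenotypeMatrix:
    """Validated sample x marker grid of biallelic call states."""

    sample_ids: list[str]
    panel: list[MarkerDef]
    calls: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.panel)):
            raise GenotypeValidationError(
                f"call grid shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.panel)} markers")
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise GenotypeValidationError(f"duplicate sample IDs: {dupes}")
        dupes = _duplicates([m.marker_id for m in self.panel])
        if dupes:
            raise GenotypeValidationError(f"duplicate marker IDs: {dupes}")
        bad = set(np.unique(self.calls)) - {-1, 0, 1, 2}
        if bad:
            raise GenotypeValidationError(f"invalid call codes: {sorted(bad)}")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    # -- conveniences -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.panel)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.panel]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def calls_for(self, sample_id: str) -> np.ndarray:
        """Call-state vector (length n_markers) for one sample."""
        try:
            return self.calls[self._index[sample_id]]
        except KeyError:
            raise KeyError(f"unknown sample ID {sample_id!r}") from None

    def subset(self, sample_ids: Sequence[str] | None = None,
               marker_ids: Sequence[str] | None = None) -> "GenotypeMatrix":
        rows = (list(range(self.n_samples)) if sample_ids is None
                else [self._index[s] for s in sample_ids])
        if marker_ids is None:
            cols = list(range(self.n_markers))
        else:
            midx = {m.marker_id: j for j, m in enumerate(self.panel)}
            cols = [midx[m] for m in marker_ids]
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            panel=[self.panel[j] for j in cols],
            calls=self.calls[np.ix_(rows, cols)].copy(),
        )

    def pr_missing_per_sample(self) -> pd.Series:
        return pd.Series((self.calls == MISSING).mean(axis=1),
                         index=self.sample_ids, name="pr_missing")

    def pr_het_per_sample(self) -> pd.Series:
        """HET fraction among non-missing calls per sample (NaN if all missing)."""
        called = self.calls != MISSING
        with np.errstate(invalid="ignore"):
            vals = (self.calls == HET).sum(axis=1) / called.sum(axis=1)
        return pd.Series(vals, index=self.sample_ids, name="pr_het")

    def to_frame(self, sep: str = ":") -> pd.DataFrame:
        """Text rendering (index = sample_id, columns = marker_id)."""
        data = {
            m.marker_id: [m.genotype_text(s, sep) for s in self.calls[:, j]]
            for j, m in enumerate(self.panel)
        }
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"))


# ---------------------------------------------------------------------------
# marker panel


def read_marker_panel(path: str | Path) -> list[MarkerDef]:
    """Read a panel definition CSV.

    Required columns: marker_id, chromosome, pos_start, pos_end, allele1,
    allele2. A single 'position' column of the form 'start-end' is also
    accepted in place of pos_start/pos_end.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if "position" in df.columns and "pos_start" not in df.columns:
        pos = df["position"].str.replace("–", "-", regex=False)
        parts = pos.str.split("-", n=1, expand=True)
        df["pos_start"], df["pos_end"] = parts[0], parts[1].fillna(parts[0])
    required = ["marker_id", "chromosome", "pos_start", "pos_end",
                "allele1", "allele2"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise GenotypeValidationError(f"panel file missing columns: {missing_cols}")
    panel = [
        MarkerDef(
            marker_id=row.marker_id.strip(),
            chromosome=int(row.chromosome),
            pos_start=int(row.pos_start),
            pos_end=int(row.pos_end),
            allele1=row.allele1.strip().upper(),
            allele2=row.allele2.strip().upper(),
        )
        for row in df.itertuples()
    ]
    dupes = _duplicates([m.marker_id for m in panel])
    if dupes:
        raise GenotypeValidationError(f"duplicate marker IDs in panel: {dupes}")
    return panel


def default_panel() -> list[MarkerDef]:
    """The packaged 17-SNP cowpea QC panel (one to two markers per chromosome)."""
    ref = resources.files("hybriqc") / "panels" / "cowpea_qc17.csv"
    with resources.as_file(ref) as path:
        return read_marker_panel(path)


# ---------------------------------------------------------------------------
# genotype tables


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


def _parse_pair_cell(cell: str, marker: MarkerDef, sample_id: str) -> np.int8:
    token = cell.strip()
    if token in MISSING_TOKENS or token.upper() in MISSING_TOKENS:
        return MISSING
    for sep in _PAIR_SEPARATORS:
        if sep in token:
            a, b = (p.strip().upper() for p in token.split(sep, 1))
            break
    else:
        if len(token) == 2:  # bare two-letter cell, HapMap style
            a, b = token[0].upper(), token[1].upper()
        else:
            raise GenotypeValidationError(
                f"sample {sample_id!r}, marker {marker.marker_id!r}: "
                f"cannot parse genotype cell {cell!r}")
    if {a, b} & {"-", "?", "N"}:
        return MISSING
    try:
        return marker.call_from_alleles(a, b)
    except GenotypeValidationError as exc:
        raise GenotypeValidationError(
            f"sample {sample_id!r}, marker {marker.marker_id!r}: {exc}") from None


def _read_rows(path: str | Path) -> list[list[str]]:
    text = Path(path).read_text()
    first_line = text.splitlines()[0] if text else ""
    delim = "\t" if first_line.count("\t") >= first_line.count(",") else ","
    rows = [row for row in csv.reader(text.splitlines(), delimiter=delim)]
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise GenotypeValidationError(f"{path}: empty genotype table")
    width = len(rows[0])
    for i, r in enumerate(rows[1:], start=2):
        if len(r) != width:
            raise GenotypeValidationError(
                f"{path}: ragged row {i} ({len(r)} fields, header has {width})")
    return rows


def read_genotype_table(path: str | Path, dialect: str = "auto",
                        panel: Sequence[MarkerDef] | None = None,
                        ) -> GenotypeMatrix:
    """Read a genotype call table and normalize it against a marker panel.

    Parameters
    ----------
    path : file path
    dialect : {'auto', 'call-grid', 'hapmap'}
        'auto' detects HapMap by its 'rs#' header field.
    panel : marker definitions; required for 'call-grid', optional for
        'hapmap' (where the file itself carries alleles/positions).
    """
    rows = _read_rows(path)
    if dialect == "auto":
        dialect = "hapmap" if rows[0][0].strip() == "rs#" else "call-grid"
    if dialect == "call-grid":
        if panel is None:
            raise GenotypeValidationError(
                "call-grid dialect requires a marker panel to resolve alleles")
        return _from_call_grid(rows, list(panel), path)
    if dialect == "hapmap":
        return _from_hapmap(rows, list(panel) if panel is not None else None, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _from_call_grid(rows: list[list[str]], panel: list[MarkerDef],
                    path: str | Path) -> GenotypeMatrix:
    header = [c.strip() for c in rows[0][1:]]
    by_id = {m.marker_id: m for m in panel}
    unknown = [m for m in header if m not in by_id]
    if unknown:
        raise GenotypeValidationError(
            f"{path}: marker columns not in panel: {unknown}")
    missing = [m.marker_id for m in panel if m.marker_id not in header]
    if missing:
        raise GenotypeValidationError(
            f"{path}: panel markers absent from table: {missing}")
    col_of = {m: j for j, m in enumerate(header)}
    sample_ids = [r[0].strip() for r in rows[1:]]
    dupes = _duplicates(sample_ids)
    if dupes:
        raise GenotypeValidationError(f"{path}: duplicate sample IDs: {dupes}")
    calls = np.full((len(sample_ids), len(panel)), MISSING, dtype=np.int8)
    for i, r in enumerate(rows[1:]):
        cells = r[1:]
        for j, marker in enumerate(panel):
            calls[i, j] = _parse_pair_cell(cells[col_of[marker.marker_id]],
                                           marker, sample_ids[i])
    return GenotypeMatrix(sample_ids=sample_ids, panel=panel, calls=calls)


def _from_hapmap(rows: list[list[str]], panel: list[MarkerDef] | None,
                 path: str | Path) -> GenotypeMatrix:
    header = rows[0]
    if len(header) < 12:
        raise GenotypeValidationError(f"{path}: HapMap file has no sample columns")
    sample_ids = [c.strip() for c in header[11:]]
    dupes = _duplicates(sample_ids)
    if dupes:
        raise GenotypeValidationError(f"{path}: duplicate sample IDs: {dupes}")
    by_id = {m.marker_id: m for m in panel} if panel is not None else {}
    markers: list[MarkerDef] = []
    grid: list[list[np.int8]] = []  # marker-major
    for r in rows[1:]:
        marker_id = r[0].strip()
        alleles = r[1].strip().upper().split("/")
        if marker_id in by_id:
            marker = by_id[marker_id]
            if set(alleles) != {marker.allele1, marker.allele2}:
                raise GenotypeValidationError(
                    f"{path}: alleles {r[1]!r} of {marker_id!r} disagree with panel")
        else:
            if panel is not None:
                raise GenotypeValidationError(
                    f"{path}: marker {marker_id!r} not in supplied panel")
            marker = MarkerDef(marker_id=marker_id, chromosome=int(r[2]),
                               pos_start=int(r[3]), pos_end=int(r[3]),
                               allele1=alleles[0], allele2=alleles[1])
        markers.append(marker)
        grid.append([_parse_pair_cell(cell, marker, sample_ids[k])
                     for k, cell in enumerate(r[11:])])
    dupes = _duplicates([m.marker_id for m in markers])
    if dupes:
        raise GenotypeValidationError(f"{path}: duplicate marker rows: {dupes}")
    matrix = GenotypeMatrix(sample_ids=sample_ids, panel=markers,
                            calls=np.asarray(grid, dtype=np.int8).T)
    if panel is not None:  # restore panel column order
        matrix = matrix.subset(marker_ids=[m.marker_id for m in panel])
    return matrix


def write_call_grid(matrix: GenotypeMatrix, path: str | Path,
                    sep: str = ",") -> None:
    """Write the call-grid dialect (samples x markers, 'T:C' cells, 'NA' missing)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["sample_id"] + matrix.marker_ids)
        for i, sid in enumerate(matrix.sample_ids):
            row = [m.genotype_text(matrix.calls[i, j], sep=":")
                   if matrix.calls[i, j] != MISSING else "NA"
                   for j, m in enumerate(matrix.panel)]
            w.writerow([sid] + row)


def write_hapmap(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a HapMap-dialect file (two-letter genotype cells, 'NN' missing).

    Round-trips through :func:`read_genotype_table` with the same panel
    bit-identically at the call-state level.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(HAPMAP_COLUMNS + matrix.sample_ids)
        for j, m in enumerate(matrix.panel):
            meta = [m.marker_id, f"{m.allele1}/{m.allele2}", str(m.chromosome),
                    str(m.pos_start), "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            cells = [m.genotype_text(matrix.calls[i, j])
                     for i in range(matrix.n_samples)]
            w.writerow(meta + cells)


# ---------------------------------------------------------------------------
# cross design


@dataclass(frozen=True)
class Cross:
    """One cross: a female parent, a male parent, and its putative F1s."""

    cross_id: str
    female_id: str
    male_id: str
    f1_ids: tuple[str, ...]
    source_group: str | None = None

    def __post_init__(self) -> None:
        if self.female_id == self.male_id:
            raise GenotypeValidationError(
                f"cross {self.cross_id!r}: female and male parent are the same "
                f"sample ({self.female_id!r})")


@dataclass
class CrossDesign:
    """A validated set of crosses (cross IDs unique, F1 IDs disjoint)."""

    crosses: list[Cross]

    def __post_init__(self) -> None:
        dupes = _duplicates([c.cross_id for c in self.crosses])
        if dupes:
            raise GenotypeValidationError(f"duplicate cross IDs: {dupes}")
        all_f1 = [f for c in self.crosses for f in c.f1_ids]
        dupes = _duplicates(all_f1)
        if dupes:
            raise GenotypeValidationError(
                f"F1 IDs assigned to more than one cross: {dupes}")
        self._by_id = {c.cross_id: c for c in self.crosses}
        self._cross_of_f1 = {f: c.cross_id for c in self.crosses for f in c.f1_ids}

    def __len__(self) -> int:
        return len(self.crosses)

    def __getitem__(self, cross_id: str) -> Cross:
        return self._by_id[cross_id]

    @property
    def f1_ids(self) -> list[str]:
        return [f for c in self.crosses for f in c.f1_ids]

    @property
    def parent_ids(self) -> list[str]:
        """Unique parent sample IDs in first-appearance order (females then males)."""
        out: list[str] = []
        seen: set[str] = set()
        for c in self.crosses:
            if c.female_id not in seen:
                out.append(c.female_id); seen.add(c.female_id)
        for c in self.crosses:
            if c.male_id not in seen:
                out.append(c.male_id); seen.add(c.male_id)
        return out

    def cross_of_f1(self, f1_id: str) -> str:
        try:
            return self._cross_of_f1[f1_id]
        except KeyError:
            raise KeyError(f"F1 {f1_id!r} is not assigned to any cross") from None

    def validate_against(self, matrix: GenotypeMatrix) -> dict[str, list[str]]:
        """Cross-reference the design with a genotype table.

        Returns a report dict; referenced-but-ungenotyped samples are
        warnings (the cross is retained), genotyped-but-undesigned samples
        are listed as 'unassigned'.
        """
        designed = set(self.parent_ids) | set(self.f1_ids)
        missing_parents = sorted({p for c in self.crosses
                                  for p in (c.female_id, c.male_id)
                                  if p not in matrix})
        missing_f1s = sorted(f for f in self.f1_ids if f not in matrix)
        unassigned = [s for s in matrix.sample_ids if s not in designed]
        warnings = [f"parent {p!r} referenced by the design is not genotyped"
                    for p in missing_parents]
        warnings += [f"F1 {f!r} referenced by the design is not genotyped"
                     for f in missing_f1s]
        return {"warnings": warnings, "missing_parents": missing_parents,
                "missing_f1s": missing_f1s, "unassigned_samples": unassigned}


def read_cross_design(path: str | Path) -> CrossDesign:
    """Read a cross-design CSV.

    Columns: cross_id, female_id, male_id, f1_ids (';'-delimited list,
    may be empty), optional source_group.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["cross_id", "female_id", "male_id", "f1_ids"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise GenotypeValidationError(f"design file missing columns: {missing_cols}")
    crosses = []
    for row in df.itertuples():
        f1s = tuple(t.strip() for t in row.f1_ids.replace("|", ";").split(";")
                    if t.strip())
        group = getattr(row, "source_group", "") or None
        crosses.append(Cross(cross_id=row.cross_id.strip(),
                             female_id=row.female_id.strip(),
                             male_id=row.male_id.strip(),
                             f1_ids=f1s, source_group=group))
    return CrossDesign(crosses=crosses)


def write_cross_design(design: CrossDesign, path: str | Path) -> None:
    rows = [{"cross_id": c.cross_id, "female_id": c.female_id,
             "male_id": c.male_id, "f1_ids": ";".join(c.f1_ids),
             "source_group": c.source_group or ""}
            for c in design.crosses]
    pd.DataFrame(rows).to_csv(path, index=False)
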