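"""Dominant-marker (RAPD/AFLP-style) presence/absence matrices.

A marker matrix holds one row per specimen and one column per scored band
(locus).  Cells are strictly binary: 1 = band present, 0 = band absent;
missing data is not modelled because dominant-marker scoring has no
missing state in this pipeline.  Specimens are assigned to roles through a
metadata table (parental group A, parental group B, query, or outgroup),
and band-category definitions (monomorphic, polymorphic, unique,
diagnostic) follow the standard dominant-marker conventions:

* monomorphic — present in every scored specimen;
* polymorphic — present in at least one but not all scored specimens;
* unique to a taxon — present in >= 1 specimen of that taxon and in no
  specimen of the other taxon;
* diagnostic (species-specific) — present in *every* specimen of one
  parental group and absent from every specimen of the other.

Query specimens never influence unique/diagnostic calls, so adding
putative hybrids to a matrix leaves the diagnostic sets unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ClassificationError, FormatError, MergeError, MetadataError

GROUPS = ("parent_A", "parent_B", "query", "outgroup")


@dataclass
class SpecimenMeta:
    """Role assignment of one specimen."""

    specimen_id: str
    group: str
    label: str = ""

    def __post_init__(self):
        if self.group not in GROUPS:
            raise MetadataError(
                f"unknown group {self.group!r} for specimen {self.specimen_id!r}; "
                f"expected one of {GROUPS}"
            )


MetaTable = Mapping[str, SpecimenMeta]


@dataclass
class MarkerMatrix:
    """Specimens x loci binary band matrix with per-locus provenance labels."""

    specimen_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray
    locus_source: list[str] | None = None
    locus_size_bp: list[int] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.specimen_ids), len(self.locus_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.specimen_ids)} specimens x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"non-binary cell at specimen {self.specimen_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}"
            )
        if len(set(self.specimen_ids)) != len(self.specimen_ids):
            raise FormatError("duplicate specimen ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise FormatError("duplicate locus ids")
        if self.locus_source is not None and len(self.locus_source) != len(self.locus_ids):
            raise FormatError("locus_source length mismatch")
        if self.locus_size_bp is not None and len(self.locus_size_bp) != len(self.locus_ids):
            raise FormatError("locus_size_bp length mismatch")

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def row(self, specimen_id: str) -> np.ndarray:
        try:
            i = self.specimen_ids.index(specimen_id)
        except ValueError:
            raise MetadataError(f"specimen {specimen_id!r} not in matrix") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.specimen_ids, columns=self.locus_ids)

    def subset_specimens(self, ids: Sequence[str]) -> "MarkerMatrix":
        idx = [self.specimen_ids.index(s) for s in ids]
        return MarkerMatrix(
            list(ids), list(self.locus_ids), self.values[idx],
            locus_source=self.locus_source,
            locus_size_bp=self.locus_size_bp,
        )

    def subset_loci(self, loci: Sequence[str]) -> "MarkerMatrix":
        idx = [self.locus_ids.index(l) for l in loci]
        return MarkerMatrix(
            list(self.specimen_ids), list(loci), self.values[:, idx],
            locus_source=[self.locus_source[i] for i in idx] if self.locus_source else None,
            locus_size_bp=[self.locus_size_bp[i] for i in idx] if self.locus_size_bp else None,
        )


def _detect_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_matrix(path, meta_path=None):
    """Read a marker matrix (and optionally its specimen metadata).

    The matrix file has a header row of locus ids (first column = specimen
    id) and one 0/1 row per specimen.  Comma or tab delimiting is
    auto-detected from the header.  Returns ``matrix`` or
    ``(matrix, meta)`` when ``meta_path`` is given.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file")
    sep = _detect_delimiter(header)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    specimen_ids = [str(s) for s in df.index]
    locus_ids = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell not in ("0", "1"):
                raise FormatError(
                    f"{path}: non-binary value {cell!r} at row {i + 1} "
                    f"(specimen {specimen_ids[i]!r}), column {j + 1} (locus {locus_ids[j]!r})"
                )
            values[i, j] = int(cell)
    matrix = MarkerMatrix(specimen_ids, locus_ids, values)
    if meta_path is None:
        return matrix
    meta = read_meta(meta_path)
    missing = [s for s in specimen_ids if s not in meta]
    if missing:
        raise MetadataError(f"specimens missing from metadata: {missing}")
    return matrix, meta


def read_meta(path) -> dict[str, SpecimenMeta]:
    """Read a specimen metadata table (columns: specimen_id, group, label)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = _detect_delimiter(header)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"specimen_id", "group"}
    if not required.issubset(df.columns):
        raise MetadataError(f"{path}: metadata needs columns {sorted(required)}")
    meta: dict[str, SpecimenMeta] = {}
    for _, rec in df.iterrows():
        sid = str(rec["specimen_id"])
        if sid in meta:
            raise MetadataError(f"{path}: duplicate specimen_id {sid!r}")
        meta[sid] = SpecimenMeta(sid, str(rec["group"]), str(rec.get("label", "")))
    return meta


def write_matrix(matrix: MarkerMatrix, path) -> None:
    """Write the canonical comma-delimited form (stored row/column order)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(["specimen_id", *matrix.locus_ids]) + "\n")
        for sid, row in zip(matrix.specimen_ids, matrix.values):
            fh.write(",".join([sid, *(str(int(v)) for v in row)]) + "\n")


def write_meta(meta: MetaTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("specimen_id,group,label\n")
        for m in meta.values():
            fh.write(f"{m.specimen_id},{m.group},{m.label}\n")


def merge_matrices(matrices: Sequence[MarkerMatrix]) -> MarkerMatrix:
    """Column-concatenate matrices scored on the same specimens.

    Locus-id collisions between inputs are resolved by prefixing with the
    locus source ("src:locus"); specimen order follows the first input.
    """
    if not matrices:
        raise MergeError("no matrices to merge")
    first = matrices[0]
    if len(matrices) == 1:
        return first
    base = set(first.specimen_ids)
    for m in matrices[1:]:
        if set(m.specimen_ids) != base:
            only_a = sorted(base - set(m.specimen_ids))
            only_b = sorted(set(m.specimen_ids) - base)
            raise MergeError(
                f"specimen sets differ: only in first={only_a}, only in other={only_b}"
            )
    seen: set[str] = set()
    locus_ids: list[str] = []
    sources: list[str] = []
    blocks = []
    for m in matrices:
        reordered = m.subset_specimens(first.specimen_ids)
        src = m.locus_source or [""] * m.n_loci
        for lid, s in zip(m.locus_ids, src):
            name = lid if lid not in seen else f"{s}:{lid}" if s else f"dup:{lid}"
            if name in seen:
                raise MergeError(f"cannot disambiguate duplicated locus id {lid!r}")
            seen.add(name)
            locus_ids.append(name)
            sources.append(s)
        blocks.append(reordered.values)
    return MarkerMatrix(
        list(first.specimen_ids), locus_ids, np.hstack(blocks), locus_source=sources
    )


@dataclass
class BandClassification:
    """Per-locus band categories and diagnostic/unique flags."""

    category: dict[str, str]              # locus -> monomorphic | polymorphic
    unique_to_A: set[str] = field(default_factory=set)
    unique_to_B: set[str] = field(default_factory=set)
    diagnostic_A: set[str] = field(default_factory=set)
    diagnostic_B: set[str] = field(default_factory=set)
    novel_in_query: set[str] = field(default_factory=set)
    excluded_outgroup_only: set[str] = field(default_factory=set)

    @property
    def counts(self) -> dict[str, int]:
        cats = list(self.category.values())
        return {
            "scored_loci": len(cats),
            "monomorphic": cats.count("monomorphic"),
            "polymorphic": cats.count("polymorphic"),
            "unique_to_A": len(self.unique_to_A),
            "unique_to_B": len(self.unique_to_B),
            "diagnostic_A": len(self.diagnostic_A),
            "diagnostic_B": len(self.diagnostic_B),
            "novel_in_query": len(self.novel_in_query),
            "excluded_outgroup_only": len(self.excluded_outgroup_only),
        }

    def to_json(self, path=None) -> str:
        payload = {
            "counts": self.counts,
            "monomorphic": sorted(l for l, c in self.category.items() if c == "monomorphic"),
            "polymorphic": sorted(l for l, c in self.category.items() if c == "polymorphic"),
            "unique_to_A": sorted(self.unique_to_A),
            "unique_to_B": sorted(self.unique_to_B),
            "diagnostic_A": sorted(self.diagnostic_A),
            "diagnostic_B": sorted(self.diagnostic_B),
            "novel_in_query": sorted(self.novel_in_query),
            "excluded_outgroup_only": sorted(self.excluded_outgroup_only),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _group_ids(meta: MetaTable, group: str, ids: Iterable[str]) -> list[str]:
    return [s for s in ids if s in meta and meta[s].group == group]


def classify_bands(
    matrix: MarkerMatrix,
    meta: MetaTable,
    exclude_groups: Iterable[str] = ("outgroup",),
    diagnostic_tolerance: int = 0,
) -> BandClassification:
    """Categorise every scored locus and flag unique/diagnostic bands.

    Outgroup specimens are excluded by default; loci carried only by
    excluded specimens are dropped before categorisation (and reported in
    ``excluded_outgroup_only``).  ``diagnostic_tolerance`` relaxes strict
    fixation: a locus may violate the all-present / all-absent rule in at
    most that many specimens per parental group (default 0 = strict).
    """
    exclude = set(exclude_groups)
    unknown = [s for s in matrix.specimen_ids if s not in meta]
    if unknown:
        raise MetadataError(f"specimens without metadata: {unknown}")
    kept_ids = [s for s in matrix.specimen_ids if meta[s].group not in exclude]
    a_ids = _group_ids(meta, "parent_A", kept_ids)
    b_ids = _group_ids(meta, "parent_B", kept_ids)
    q_ids = _group_ids(meta, "query", kept_ids)
    if not a_ids or not b_ids:
        raise ClassificationError(
            f"need >=1 specimen per parental group after exclusions "
            f"(parent_A={len(a_ids)}, parent_B={len(b_ids)})"
        )

    df = matrix.to_frame()
    kept = df.loc[kept_ids]
    dropped = df.drop(index=kept_ids)
    # loci present only in excluded (e.g. outgroup) specimens are removed
    outgroup_only = set()
    if len(dropped):
        outgroup_only = {
            l for l in matrix.locus_ids
            if kept[l].sum() == 0 and dropped[l].sum() > 0
        }
    scored = [l for l in matrix.locus_ids if l not in outgroup_only]

    A = kept.loc[a_ids, scored].to_numpy()
    B = kept.loc[b_ids, scored].to_numpy()
    Q = kept.loc[q_ids, scored].to_numpy() if q_ids else np.zeros((0, len(scored)), np.int8)
    total = kept[scored].to_numpy()

    present_all = total.all(axis=0)
    present_any = total.any(axis=0)
    # loci with no band in any kept specimen are not scored at all
    category = {
        l: ("monomorphic" if present_all[j] else "polymorphic")
        for j, l in enumerate(scored)
        if present_any[j]
    }

    a_pres = A.sum(axis=0)
    b_pres = B.sum(axis=0)
    q_pres = Q.sum(axis=0)
    nA, nB = len(a_ids), len(b_ids)
    tol = int(diagnostic_tolerance)

    res = BandClassification(category=category, excluded_outgroup_only=outgroup_only)
    for j, l in enumerate(scored):
        if l not in category:
            continue
        if a_pres[j] >= 1 and b_pres[j] == 0:
            res.unique_to_A.add(l)
            if a_pres[j] >= nA - tol and b_pres[j] <= tol:
                res.diagnostic_A.add(l)
        if b_pres[j] >= 1 and a_pres[j] == 0:
            res.unique_to_B.add(l)
            if b_pres[j] >= nB - tol and a_pres[j] <= tol:
                res.diagnostic_B.add(l)
        if a_pres[j] == 0 and b_pres[j] == 0 and q_pres[j] >= 1:
            res.novel_in_query.add(l)
    return res


def novel_bands(matrix: MarkerMatrix, meta: MetaTable) -> set[str]:
    """Loci present in >=1 query specimen and absent from both parental groups."""
    import warnings

    q_ids = _group_ids(meta, "query", matrix.specimen_ids)
    if not q_ids:
        warnings.warn("no query specimens; novel band set is empty", stacklevel=2)
        return set()
    a_ids = _group_ids(meta, "parent_A", matrix.specimen_ids)
    b_ids = _group_ids(meta, "parent_B", matrix.specimen_ids)
    df = matrix.to_frame()
    q_any = df.loc[q_ids].any(axis=0)
    par_any = df.loc[a_ids + b_ids].any(axis=0) if a_ids + b_ids else pd.Series(False, index=df.columns)
    return set(df.columns[q_any & ~par_any])
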