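"""Diagnostic-marker hybrid index and hybrid-class calls.

The index measures a specimen's position between two parental species on
a 0-1 scale using species-diagnostic dominant markers: loci fixed-present
in one parental group and fixed-absent in the other.  With m_A markers
diagnostic for parent A and m_B for parent B, a specimen is scored for

* ``c_present`` — how many parent-B diagnostic bands it carries, and
* ``a_absent`` — how many parent-A diagnostic bands it lacks.

Two index variants are computed:

* raw:        (c_present + a_absent) / (m_A + m_B)
* normalized: 1/2 * (c_present/m_B + a_absent/m_A)

Both are 0 for a pure parent A and 1 for a pure parent B.  They differ
whenever m_A != m_B: the normalized variant equals exactly 0.5 for a
fully additive F1 (all bands of both parents present), while the raw
variant weights each marker equally regardless of which side it came
from.  Both are reported because field practice uses both conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, HybridDetectError
from .io_matrix import BandClassification, MarkerMatrix, MetaTable

CLASS_CALLS = ("pure_A", "backcross_A", "F1_type", "backcross_B", "pure_B", "ambiguous")


@dataclass
class DiagnosticMarkerSet:
    """Per-parent lists of species-diagnostic loci."""

    loci_A: list[str]
    loci_B: list[str]

    def __post_init__(self):
        if set(self.loci_A) & set(self.loci_B):
            raise ConfigError("diagnostic sets must be disjoint")
        if not self.loci_A or not self.loci_B:
            raise ConfigError("each parental diagnostic set needs >=1 locus")

    @property
    def m_A(self) -> int:
        return len(self.loci_A)

    @property
    def m_B(self) -> int:
        return len(self.loci_B)

    @classmethod
    def from_classification(cls, bc: BandClassification) -> "DiagnosticMarkerSet":
        return cls(sorted(bc.diagnostic_A), sorted(bc.diagnostic_B))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding used for display values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def score_specimen_markers(
    matrix: MarkerMatrix, dset: DiagnosticMarkerSet, specimen_id: str
) -> tuple[int, int]:
    """Count parent-B diagnostic bands present and parent-A bands absent."""
    missing = [l for l in dset.loci_A + dset.loci_B if l not in matrix.locus_ids]
    if missing:
        raise HybridDetectError(f"diagnostic loci absent from matrix: {missing}")
    row = pd.Series(matrix.row(specimen_id), index=matrix.locus_ids)
    c_present = int(row[dset.loci_B].sum())
    a_absent = int(dset.m_A - row[dset.loci_A].sum())
    return c_present, a_absent


def hybrid_index(
    c_present: int, a_absent: int, m_A: int, m_B: int, variant: str = "raw"
) -> float:
    """Hybrid index in [0,1]; 0 = pure parent A, 1 = pure parent B."""
    if not (0 <= c_present <= m_B):
        raise HybridDetectError(f"c_present={c_present} out of range [0, {m_B}]")
    if not (0 <= a_absent <= m_A):
        raise HybridDetectError(f"a_absent={a_absent} out of range [0, {m_A}]")
    if variant == "raw":
        return (c_present + a_absent) / (m_A + m_B)
    if variant == "normalized":
        return 0.5 * (c_present / m_B + a_absent / m_A)
    raise ConfigError(f"unknown variant {variant!r}; use 'raw' or 'normalized'")


@dataclass
class ClassThresholds:
    """Interval configuration for hybrid-class calls on the index scale.

    ``pure_max``/``pure_min`` bound the pure ranges near 0 and 1 (a pure
    call additionally requires zero opposite-parent markers; otherwise
    the specimen is flagged introgressed), and ``f1_low``..``f1_high``
    is the F1 window (requires >=1 marker from each parent).
    """

    pure_max: float = 0.2
    f1_low: float = 0.4
    f1_high: float = 0.6
    pure_min: float = 0.8
    variant: str = "normalized"

    def __post_init__(self):
        if not (0 <= self.pure_max < self.f1_low <= self.f1_high < self.pure_min <= 1):
            raise ConfigError(
                "class thresholds overlap or are out of order: require "
                "0 <= pure_max < f1_low <= f1_high < pure_min <= 1, got "
                f"{self.pure_max}, {self.f1_low}, {self.f1_high}, {self.pure_min}"
            )


@dataclass
class HybridIndexResult:
    """Per-specimen diagnostic-marker counts, index values and class call."""

    specimen_id: str
    c_present: int
    a_absent: int
    m_A: int
    m_B: int
    index_raw: float
    index_normalized: float
    class_call: str
    introgressed: bool = False
    foreign_marker_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "specimen": self.specimen_id,
            "c_present": self.c_present,
            "a_absent": self.a_absent,
            "m_A": self.m_A,
            "m_B": self.m_B,
            "index_raw": self.index_raw,
            "index_normalized": self.index_normalized,
            "class_call": self.class_call,
            "introgressed": self.introgressed,
            "foreign_marker_ids": self.foreign_marker_ids,
        }


def _call_class(
    idx: float, c_present: int, a_present: int, thresholds: ClassThresholds
) -> tuple[str, bool]:
    """Class call plus introgression flag from index and marker counts.

    ``a_present`` is the count of parent-A diagnostic bands carried.  A
    pure-range index combined with any opposite-parent marker is flagged
    introgressed (a nearly pure genome carrying foreign bands).
    """
    t = thresholds
    if idx <= t.pure_max:
        return ("pure_A", c_present > 0)
    if idx >= t.pure_min:
        return ("pure_B", a_present > 0)
    if t.f1_low <= idx <= t.f1_high:
        if c_present >= 1 and a_present >= 1:
            return ("F1_type", False)
        return ("ambiguous", False)
    if idx < t.f1_low:
        return ("backcross_A", False)
    return ("backcross_B", False)


def classify_specimens(
    results: list[HybridIndexResult], thresholds: ClassThresholds | None = None
) -> list[HybridIndexResult]:
    """Attach deterministic class calls to hybrid-index results (in place)."""
    t = thresholds or ClassThresholds()
    for r in results:
        idx = r.index_normalized if t.variant == "normalized" else r.index_raw
        a_present = r.m_A - r.a_absent
        r.class_call, r.introgressed = _call_class(idx, r.c_present, a_present, t)
    return results


def hybrid_index_table(
    matrix: MarkerMatrix,
    meta: MetaTable,
    dset: DiagnosticMarkerSet,
    thresholds: ClassThresholds | None = None,
    specimens: list[str] | None = None,
) -> list[HybridIndexResult]:
    """Score specimens (default: all query specimens) against a diagnostic set."""
    if specimens is None:
        specimens = [s for s in matrix.specimen_ids if meta[s].group == "query"]
    loci_idx = {l: i for i, l in enumerate(matrix.locus_ids)}
    results = []
    for sid in specimens:
        c, a = score_specimen_markers(matrix, dset, sid)
        row = matrix.row(sid)
        foreign = [l for l in dset.loci_B if row[loci_idx[l]] == 1]
        results.append(
            HybridIndexResult(
                specimen_id=sid,
                c_present=c,
                a_absent=a,
                m_A=dset.m_A,
                m_B=dset.m_B,
                index_raw=hybrid_index(c, a, dset.m_A, dset.m_B, "raw"),
                index_normalized=hybrid_index(c, a, dset.m_A, dset.m_B, "normalized"),
                class_call="ambiguous",
                foreign_marker_ids=foreign,
            )
        )
    return classify_specimens(results, thresholds)


def marker_report(
    matrix: MarkerMatrix,
    meta: MetaTable,
    dset: DiagnosticMarkerSet,
    thresholds: ClassThresholds | None = None,
) -> pd.DataFrame:
    """Query-specimen x diagnostic-locus presence grid with counts and indices.

    One row per query specimen: presence/absence at every diagnostic locus
    (parent-A loci first), then counts and both index variants (displayed
    half-up at 2 decimals in the exported text; full precision kept here).
    """
    results = hybrid_index_table(matrix, meta, dset, thresholds)
    loci = dset.loci_A + dset.loci_B
    rows = []
    for r in results:
        row = pd.Series(matrix.row(r.specimen_id), index=matrix.locus_ids)
        rec = {l: int(row[l]) for l in loci}
        rec.update(
            specimen_id=r.specimen_id,
            c_present=r.c_present,
            a_absent=r.a_absent,
            index_raw=r.index_raw,
            index_normalized=r.index_normalized,
            class_call=r.class_call,
            introgressed=r.introgressed,
        )
        rows.append(rec)
    cols = ["specimen_id", *loci, "c_present", "a_absent",
            "index_raw", "index_normalized", "class_call", "introgressed"]
    return pd.DataFrame(rows, columns=cols)


def write_report(
    report: pd.DataFrame, results: list[HybridIndexResult], out_prefix
) -> None:
    """Export the marker report as delimited text and JSON."""
    out_prefix = Path(out_prefix)
    disp = report.copy()
    for col in ("index_raw", "index_normalized"):
        disp[col] = [round_half_up(v, 2) for v in disp[col]]
    disp.to_csv(out_prefix.with_suffix(".csv"), index=False)
    payload = [r.to_dict() for r in results]
    out_prefix.with_suffix(".json").write_text(
        json.dumps(payload, indent=2), encoding="utf-8"
    )
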