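"""Diagnostic sites between parental sequence groups and in-silico PCR-RFLP.

Works on pre-computed multiple alignments of a nuclear region (e.g. ITS
or a low-copy gene fragment) in which every sequence is assigned to
parental group A, parental group B, or query.  Alignment columns are the
coordinate frame: positions are 0-based internally and 1-based in all
exported reports.

A diagnostic SNP is a column where the parental groups are each fixed
for a different non-gap state; a diagnostic indel is a maximal run of
columns that is all-gap in every sequence of one group and gap-free in
every sequence of the other.  Query sequences never influence discovery.
Cloned query sequences are scored per diagnostic site as matching the
A state, the B state, or neither (novel).

The PCR-RFLP part digests unaligned plastid amplicons in silico with a
panel of ten restriction enzymes and groups specimens into haplotypes by
their multi-enzyme fragment-length profiles, which supports maternal-
parent inference for hybrids (plastids are maternally inherited in most
angiosperms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, DigestError, HybridDetectError

GAP = "-"

# name -> (recognition sequence, cut offset from 5' end of the site).
# All ten are palindromic cutters, so forward-strand matching covers both
# strands.  N in a recognition site matches A/C/G/T in the sequence; N in
# the sequence never matches (conservative digestion).
ENZYME_PANEL: dict[str, tuple[str, int]] = {
    "AluI": ("AGCT", 2),
    "DraI": ("TTTAAA", 3),
    "HindIII": ("AAGCTT", 1),
    "HinfI": ("GANTC", 1),
    "MboI": ("GATC", 0),
    "MseI": ("TTAA", 1),
    "MspI": ("CCGG", 1),
    "PstI": ("CTGCAG", 5),
    "TaqI": ("TCGA", 1),
    "XbaI": ("TCTAGA", 1),
}


# ---------------------------------------------------------------- FASTA I/O

def read_fasta(path, require_alignment: bool = False) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if require_alignment and len({len(s) for _, s in records}) > 1:
        lengths = {i: len(s) for i, s in records}
        raise AlignmentError(f"records differ in length: {lengths}")
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=i, description="") for i, s in records],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------- alignment types

@dataclass
class GroupedAlignment:
    """Equal-length aligned sequences, each assigned to a group."""

    ids: list[str]
    seqs: list[str]
    groups: dict[str, str]  # id -> parent_A | parent_B | query

    def __post_init__(self):
        self.seqs = [s.upper() for s in self.seqs]
        if len({len(s) for s in self.seqs}) > 1:
            raise AlignmentError("aligned sequences must share one length")
        for i in self.ids:
            if i not in self.groups:
                raise AlignmentError(f"sequence {i!r} has no group assignment")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def group_seqs(self, group: str) -> list[str]:
        return [s for i, s in zip(self.ids, self.seqs) if self.groups[i] == group]

    @classmethod
    def from_fasta(cls, path, groups: dict[str, str]) -> "GroupedAlignment":
        records = read_fasta(path, require_alignment=True)
        return cls([i for i, _ in records], [s for _, s in records], groups)


@dataclass
class DiagnosticSites:
    """Fixed differences between parental groups."""

    snp_sites: list[tuple[int, str, str]] = field(default_factory=list)
    # (start, length, carrier) where carrier is the group WITH the gap run
    indel_sites: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.snp_sites) + len(self.indel_sites)

    def to_json(self, path=None) -> str:
        payload = {
            "snp_sites": [
                {"position_1based": p + 1, "state_A": a, "state_B": b}
                for p, a, b in self.snp_sites
            ],
            "indel_sites": [
                {"start_1based": s + 1, "length": l, "gap_carrier": c}
                for s, l, c in self.indel_sites
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _parental(aln: GroupedAlignment) -> tuple[list[str], list[str]]:
    a = aln.group_seqs("parent_A")
    b = aln.group_seqs("parent_B")
    if not a or not b:
        raise AlignmentError(
            f"need >=1 sequence per parental group (A={len(a)}, B={len(b)})"
        )
    return a, b


def _modal_state(column: list[str], min_fixation: float) -> str | None:
    """Modal non-gap state if it reaches the fixation fraction, else None."""
    best, n_best = None, 0
    for state in set(column):
        n = column.count(state)
        if n > n_best:
            best, n_best = state, n
    if best == GAP or best is None:
        return None
    return best if n_best / len(column) >= min_fixation else None


def find_diagnostic_snps(
    aln: GroupedAlignment, min_group_fixation: float = 1.0
) -> DiagnosticSites:
    """Columns fixed for different non-gap states in the two parental groups.

    ``min_group_fixation`` relaxes strict fixation: the modal non-gap
    state must reach at least that fraction within each group (1.0 =
    every sequence).  Gapped sequences at a column count against
    fixation.  Query sequences are ignored.
    """
    if not 0.5 < min_group_fixation <= 1.0:
        raise HybridDetectError("min_group_fixation must be in (0.5, 1.0]")
    a_seqs, b_seqs = _parental(aln)
    sites = DiagnosticSites()
    for pos in range(aln.length):
        col_a = [s[pos] for s in a_seqs]
        col_b = [s[pos] for s in b_seqs]
        state_a = _modal_state(col_a, min_group_fixation)
        state_b = _modal_state(col_b, min_group_fixation)
        if state_a and state_b and state_a != state_b:
            sites.snp_sites.append((pos, state_a, state_b))
    return sites


def find_diagnostic_indels(aln: GroupedAlignment) -> DiagnosticSites:
    """Maximal gap runs fixed-present in one group and fixed-absent in the other.

    A column qualifies when every sequence of one parental group has a gap
    and every sequence of the other group has a base; runs of columns with
    the same carrier group are merged and reported with their length.
    Columns with partial (within-group polymorphic) gaps never qualify.
    """
    a_seqs, b_seqs = _parental(aln)
    carrier_per_col: list[str | None] = []
    for pos in range(aln.length):
        gap_a = [s[pos] == GAP for s in a_seqs]
        gap_b = [s[pos] == GAP for s in b_seqs]
        if all(gap_a) and not any(gap_b):
            carrier_per_col.append("parent_A")
        elif all(gap_b) and not any(gap_a):
            carrier_per_col.append("parent_B")
        else:
            carrier_per_col.append(None)
    sites = DiagnosticSites()
    pos = 0
    while pos < len(carrier_per_col):
        carrier = carrier_per_col[pos]
        if carrier is None:
            pos += 1
            continue
        start = pos
        while pos < len(carrier_per_col) and carrier_per_col[pos] == carrier:
            pos += 1
        sites.indel_sites.append((start, pos - start, carrier))
    return sites


@dataclass
class CloneScore:
    """Per-site parental-state calls for one cloned query sequence."""

    clone_id: str
    calls: list[tuple[str, str]]  # (site description, call in {A, B, novel})
    n_A: int
    n_B: int
    n_novel: int

    def to_dict(self) -> dict:
        return {
            "clone": self.clone_id,
            "n_A": self.n_A,
            "n_B": self.n_B,
            "n_novel": self.n_novel,
            "calls": [{"site": s, "call": c} for s, c in self.calls],
        }


def score_clone(
    clone_id: str, clone_seq: str, sites: DiagnosticSites, aln_length: int | None = None
) -> CloneScore:
    """Call each diagnostic site in a clone as A-state, B-state, or novel."""
    clone_seq = clone_seq.upper()
    if aln_length is not None and len(clone_seq) != aln_length:
        raise AlignmentError(
            f"clone length {len(clone_seq)} != alignment length {aln_length}"
        )
    calls: list[tuple[str, str]] = []
    for pos, state_a, state_b in sites.snp_sites:
        if pos >= len(clone_seq):
            raise AlignmentError(f"SNP position {pos + 1} beyond clone length")
        obs = clone_seq[pos]
        call = "A" if obs == state_a else "B" if obs == state_b else "novel"
        calls.append((f"snp@{pos + 1}", call))
    for start, length, carrier in sites.indel_sites:
        if start + length > len(clone_seq):
            raise AlignmentError(f"indel at {start + 1} beyond clone length")
        run = clone_seq[start:start + length]
        has_gap_run = all(ch == GAP for ch in run)
        gap_free = all(ch != GAP for ch in run)
        if has_gap_run:
            call = "A" if carrier == "parent_A" else "B"
        elif gap_free:
            call = "B" if carrier == "parent_A" else "A"
        else:
            call = "novel"
        calls.append((f"indel@{start + 1}+{length}", call))
    n_a = sum(1 for _, c in calls if c == "A")
    n_b = sum(1 for _, c in calls if c == "B")
    return CloneScore(clone_id, calls, n_a, n_b, len(calls) - n_a - n_b)


# ---------------------------------------------------------------- RFLP

_IUPAC_MATCH = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT",
                "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC"}


def _site_matches(seq: str, start: int, recognition: str) -> bool:
    for off, pat in enumerate(recognition):
        base = seq[start + off]
        if base not in _IUPAC_MATCH.get(pat, pat):
            return False
    return True


def restriction_digest(
    seq: str, enzyme: str, panel: dict[str, tuple[str, int]] | None = None
) -> list[int]:
    """Fragment lengths from digesting a linear sequence with one enzyme.

    Cuts at every exact occurrence of the recognition site at the
    enzyme's cut offset; ambiguity codes in the sequence never match
    (conservative digestion).  Fragments are returned 5'->3' and always
    sum to the sequence length.
    """
    panel = panel or ENZYME_PANEL
    if enzyme not in panel:
        raise DigestError(f"unknown enzyme {enzyme!r}; panel: {sorted(panel)}")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise DigestError(f"sequence contains non-nucleotide symbols: {sorted(bad)}")
    recognition, offset = panel[enzyme]
    cuts = sorted(
        {
            start + offset
            for start in range(len(seq) - len(recognition) + 1)
            if _site_matches(seq, start, recognition)
        }
    )
    cuts = [c for c in cuts if 0 < c < len(seq)]
    bounds = [0, *cuts, len(seq)]
    return [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]


@dataclass
class RflpProfile:
    """Multi-enzyme restriction fragment-length profile of one specimen."""

    specimen_id: str
    fragments: dict[str, tuple[int, ...]]  # enzyme -> ordered lengths
    haplotype: str | None = None

    @classmethod
    def from_sequence(
        cls, specimen_id: str, seq: str, enzymes: list[str] | None = None,
        panel: dict[str, tuple[str, int]] | None = None,
    ) -> "RflpProfile":
        enzymes = enzymes or sorted(ENZYME_PANEL)
        return cls(
            specimen_id,
            {e: tuple(restriction_digest(seq, e, panel)) for e in enzymes},
        )


def _profiles_match(a: RflpProfile, b: RflpProfile, tol: int) -> bool:
    for enz in a.fragments:
        fa, fb = a.fragments[enz], b.fragments[enz]
        if len(fa) != len(fb):
            return False
        if any(abs(x - y) > tol for x, y in zip(fa, fb)):
            return False
    return True


def rflp_haplotypes(
    profiles: list[RflpProfile], tolerance: int = 0
) -> dict[str, str]:
    """Group specimens with matching fragment-length profiles into haplotypes.

    Profiles match when every enzyme yields the same number of fragments
    and corresponding lengths differ by at most ``tolerance`` bp.
    Haplotype ids (H1, H2, ...) are assigned in a canonical order of the
    profiles themselves, so they are stable under specimen reordering.
    Sets each profile's ``haplotype`` and returns specimen -> haplotype.
    """
    if not profiles:
        return {}
    panels = {tuple(sorted(p.fragments)) for p in profiles}
    if len(panels) != 1:
        raise DigestError(f"specimens digested with different enzyme panels: {panels}")
    representatives: list[RflpProfile] = []
    membership: dict[str, int] = {}
    for p in profiles:
        for gi, rep in enumerate(representatives):
            if _profiles_match(p, rep, tolerance):
                membership[p.specimen_id] = gi
                break
        else:
            membership[p.specimen_id] = len(representatives)
            representatives.append(p)
    # canonical ordering: sort representative profiles by their fragment tables
    keys = [tuple(sorted(rep.fragments.items())) for rep in representatives]
    rank = {gi: r for r, gi in enumerate(sorted(range(len(keys)), key=lambda g: keys[g]))}
    result = {sid: f"H{rank[gi] + 1}" for sid, gi in membership.items()}
    for p in profiles:
        p.haplotype = result[p.specimen_id]
    return result


def haplotype_group_table(
    haplotypes: dict[str, str], groups: dict[str, str]
) -> dict[str, dict[str, int]]:
    """Haplotype -> {specimen group -> count} concordance table."""
    table: dict[str, dict[str, int]] = {}
    for sid, hap in haplotypes.items():
        grp = groups.get(sid, "unknown")
        table.setdefault(hap, {})
        table[hap][grp] = table[hap].get(grp, 0) + 1
    return table
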