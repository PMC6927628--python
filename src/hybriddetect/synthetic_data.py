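"""Simulators for marker matrices, parental alignments, and plastid sequences.

The marker simulator emulates a two-species hybridization study scored
with dominant fingerprint markers.  Each species carries a set of
diagnostic loci fixed for the band-presence allele (and fixed-null in the
other species); the default diagnostic counts are 51 for parent A and 44
for parent B, the configuration of the motivating study system.
Background loci draw independent band-allele frequencies per species
from a configurable range.  Specimens are diploid with genotypes in
Hardy-Weinberg proportions; F1s receive one gamete from each species and
first backcrosses an F1 gamete plus a recurrent-parent gamete, so
non-recurrent-parent diagnostic presence alleles segregate 1:1.  Band
phenotypes follow strict dominance (band shown iff >= 1 presence
allele).  Hybrid-specific "novel" bands — seen in real fingerprints of
hybrids and attributed to heteroduplex formation or meiotic
rearrangement — are modelled phenomenologically: a configurable fraction
of background loci is reserved as hybrid-novel (absent in both parental
pools, shown by each hybrid with high probability).  Optional scoring
errors flip cells uniformly at random.

The alignment simulator plants an exact number of fixed SNP differences
and group-specific gap runs between two parental sequence groups, plus
decoy within-group polymorphism, and builds cloned query sequences as
parental mosaics.  The plastid simulator hands each specimen its
maternal lineage's haplotype sequence verbatim (strict maternal
inheritance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .io_matrix import MarkerMatrix, SpecimenMeta
from .seq_diagnostics import GroupedAlignment

_NOVEL_BAND_PENETRANCE = 0.8  # chance each hybrid shows a given novel band


@dataclass
class SimConfig:
    """Study design for one simulated dominant-marker dataset."""

    n_parent_A: int = 10
    n_parent_B: int = 10
    n_F1: int = 5
    n_BC1_A: int = 0
    n_BC1_B: int = 0
    n_loci: int = 595
    n_diag_A: int = 51
    n_diag_B: int = 44
    background_presence_freq_range: tuple[float, float] = (0.1, 0.9)
    novel_band_rate: float = 0.05
    scoring_error_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_diag_A + self.n_diag_B > self.n_loci:
            raise ConfigError(
                f"diagnostic loci ({self.n_diag_A}+{self.n_diag_B}) exceed n_loci={self.n_loci}"
            )
        if min(self.n_parent_A, self.n_parent_B) < 1:
            raise ConfigError("need >=1 specimen per parental pool")
        if min(self.n_diag_A, self.n_diag_B) < 1:
            raise ConfigError("need >=1 diagnostic locus per species")
        lo, hi = self.background_presence_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError(
                "background_presence_freq_range must lie strictly inside (0, 1) "
                "so background loci cannot be fixed"
            )
        for name in ("novel_band_rate", "scoring_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

    @property
    def n_background(self) -> int:
        return self.n_loci - self.n_diag_A - self.n_diag_B


@dataclass
class SimTruth:
    """Ground truth for a simulated marker dataset."""

    true_class: dict[str, str]            # specimen -> pure_A|pure_B|F1|BC1_A|BC1_B
    fraction_A: dict[str, float]          # expected parent-A genome fraction
    genotypes: np.ndarray                 # specimens x loci x 2 presence alleles
    diag_A_loci: list[str]
    diag_B_loci: list[str]
    novel_loci: list[str]


_FRACTION_A = {"pure_A": 1.0, "pure_B": 0.0, "F1": 0.5, "BC1_A": 0.75, "BC1_B": 0.25}


def simulate_marker_dataset(
    config: SimConfig,
) -> tuple[MarkerMatrix, dict[str, SpecimenMeta], SimTruth]:
    """Simulate a marker matrix with metadata and ground truth.

    Parental specimens are assigned to groups parent_A/parent_B; all
    hybrid classes are labelled "query" so the analysis chain sees them
    exactly as a field study would see putative hybrids.
    """
    rng = np.random.default_rng(config.seed)
    c = config
    L = c.n_loci

    # per-species band-presence allele frequencies
    freq_A = np.empty(L)
    freq_B = np.empty(L)
    sl_diag_A = slice(0, c.n_diag_A)
    sl_diag_B = slice(c.n_diag_A, c.n_diag_A + c.n_diag_B)
    sl_bg = slice(c.n_diag_A + c.n_diag_B, L)
    freq_A[sl_diag_A], freq_B[sl_diag_A] = 1.0, 0.0
    freq_A[sl_diag_B], freq_B[sl_diag_B] = 0.0, 1.0
    lo, hi = c.background_presence_freq_range
    freq_A[sl_bg] = rng.uniform(lo, hi, c.n_background)
    freq_B[sl_bg] = rng.uniform(lo, hi, c.n_background)

    # reserve a fraction of background loci as hybrid-novel bands
    bg_idx = np.arange(sl_bg.start, sl_bg.stop)
    novel_mask = rng.random(c.n_background) < c.novel_band_rate
    novel_idx = bg_idx[novel_mask]
    freq_A[novel_idx] = 0.0
    freq_B[novel_idx] = 0.0

    locus_ids = (
        [f"dA{i + 1:03d}" for i in range(c.n_diag_A)]
        + [f"dB{i + 1:03d}" for i in range(c.n_diag_B)]
        + [f"bg{i + 1:04d}" for i in range(c.n_background)]
    )

    def gametes(freq: np.ndarray, n: int) -> np.ndarray:
        return (rng.random((n, L)) < freq).astype(np.int8)

    specs: list[tuple[str, str, str]] = []   # (id, group, class)
    genotype_blocks: list[np.ndarray] = []

    def add(prefix: str, group: str, klass: str, g1: np.ndarray, g2: np.ndarray):
        for _ in range(g1.shape[0]):
            specs.append((prefix, group, klass))
        genotype_blocks.append(np.stack([g1, g2], axis=2))

    add("A", "parent_A", "pure_A", gametes(freq_A, c.n_parent_A), gametes(freq_A, c.n_parent_A))
    add("B", "parent_B", "pure_B", gametes(freq_B, c.n_parent_B), gametes(freq_B, c.n_parent_B))
    if c.n_F1:
        add("F", "query", "F1", gametes(freq_A, c.n_F1), gametes(freq_B, c.n_F1))
    if c.n_BC1_A:
        # F1 gamete: one allele per locus picked uniformly from an F1 genotype
        f1_a, f1_b = gametes(freq_A, c.n_BC1_A), gametes(freq_B, c.n_BC1_A)
        pick = rng.random((c.n_BC1_A, L)) < 0.5
        f1_gam = np.where(pick, f1_a, f1_b)
        add("BA", "query", "BC1_A", gametes(freq_A, c.n_BC1_A), f1_gam)
    if c.n_BC1_B:
        f1_a, f1_b = gametes(freq_A, c.n_BC1_B), gametes(freq_B, c.n_BC1_B)
        pick = rng.random((c.n_BC1_B, L)) < 0.5
        f1_gam = np.where(pick, f1_a, f1_b)
        add("BB", "query", "BC1_B", gametes(freq_B, c.n_BC1_B), f1_gam)

    genotypes = np.concatenate(genotype_blocks, axis=0)
    counters: dict[str, int] = {}
    ids: list[str] = []
    for prefix, group, klass in specs:
        counters[prefix] = counters.get(prefix, 0) + 1
        ids.append(f"{prefix}{counters[prefix]:02d}")
    groups = [g for _, g, _ in specs]
    classes = [k for _, _, k in specs]

    phenotype = genotypes.any(axis=2).astype(np.int8)

    # hybrid-novel bands
    hybrid_rows = [i for i, k in enumerate(classes) if k in ("F1", "BC1_A", "BC1_B")]
    if len(hybrid_rows) and len(novel_idx):
        show = rng.random((len(hybrid_rows), len(novel_idx))) < _NOVEL_BAND_PENETRANCE
        phenotype[np.ix_(hybrid_rows, novel_idx)] |= show.astype(np.int8)

    if c.scoring_error_rate > 0:
        flips = rng.random(phenotype.shape) < c.scoring_error_rate
        phenotype = np.where(flips, 1 - phenotype, phenotype).astype(np.int8)

    matrix = MarkerMatrix(
        ids, locus_ids, phenotype,
        locus_source=["sim"] * L,
    )
    meta = {
        sid: SpecimenMeta(sid, grp, label=klass)
        for sid, grp, klass in zip(ids, groups, classes)
    }
    truth = SimTruth(
        true_class=dict(zip(ids, classes)),
        fraction_A={sid: _FRACTION_A[k] for sid, k in zip(ids, classes)},
        genotypes=genotypes,
        diag_A_loci=locus_ids[sl_diag_A],
        diag_B_loci=locus_ids[sl_diag_B],
        novel_loci=[locus_ids[j] for j in novel_idx],
    )
    return matrix, meta, truth


# ---------------------------------------------------------------- alignments

_BASES = "ACGT"


def _other_base(rng, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[rng.integers(len(choices))]


def simulate_alignment(
    n_A: int = 3,
    n_B: int = 3,
    length: int = 550,
    n_diag_snps: int = 9,
    indel_lengths: Sequence[tuple[str, int]] = (),
    within_group_poly_rate: float = 0.0,
    clone_origins: Sequence[Sequence[str]] = (),
    clone_novel_sites: Mapping[int, Sequence[int]] | None = None,
    seed: int | None = None,
) -> tuple[GroupedAlignment, dict]:
    """Simulate a grouped alignment with planted diagnostic features.

    ``indel_lengths`` lists (carrier_group, length) pairs, the carrier
    being the group whose sequences have the gap run ("A" or "B").
    ``clone_origins`` gives, per clone, the parental origin ("A"/"B") at
    each diagnostic site in order (SNP sites first, then indels);
    ``clone_novel_sites`` maps a clone index to diagnostic-site indices
    replaced by a state found in neither parent.  Returns the alignment
    and a truth dict with the planted coordinates.
    """
    rng = np.random.default_rng(seed)
    indel_lengths = list(indel_lengths)
    n_features = n_diag_snps + len(indel_lengths)
    total_indel = sum(l for _, l in indel_lengths)
    if n_diag_snps + total_indel + n_features >= length:
        raise ConfigError("planted features do not fit into the alignment length")

    base = rng.choice(list(_BASES), size=length)

    # choose non-overlapping feature positions: lay features left to right
    # with random spacing
    slots = n_diag_snps + len(indel_lengths)
    feature_span = n_diag_snps + total_indel
    gaps_budget = length - feature_span
    cuts = np.sort(rng.choice(np.arange(1, gaps_budget), size=slots, replace=False))
    spacings = np.diff(np.concatenate([[0], cuts]))
    order = list(rng.permutation(
        [("snp", None)] * n_diag_snps + [("indel", i) for i in range(len(indel_lengths))]
    ))

    snp_positions: list[int] = []
    snp_states: list[tuple[str, str]] = []
    indel_runs: list[tuple[int, int, str]] = []
    pos = 0
    for spacing, (kind, idx) in zip(spacings, order):
        pos += int(spacing)
        if kind == "snp":
            snp_positions.append(pos)
            a_state = base[pos]
            snp_states.append((a_state, _other_base(rng, a_state)))
            pos += 1
        else:
            carrier, ln = indel_lengths[int(idx)]
            indel_runs.append((pos, ln, f"parent_{carrier}"))
            pos += ln

    def build_parent(which: str) -> str:
        seq = base.copy().astype(object)
        for p, (a_state, b_state) in zip(snp_positions, snp_states):
            seq[p] = a_state if which == "A" else b_state
        for start, ln, carrier in indel_runs:
            if carrier == f"parent_{which}":
                seq[start:start + ln] = "-"
        return "".join(seq)

    parent_a = build_parent("A")
    parent_b = build_parent("B")
    ids = [f"A_{i + 1}" for i in range(n_A)] + [f"B_{i + 1}" for i in range(n_B)]
    seqs = [parent_a] * n_A + [parent_b] * n_B
    groups = {i: ("parent_A" if i.startswith("A_") else "parent_B") for i in ids}

    # decoy within-group polymorphism at non-planted columns
    planted = set(snp_positions)
    for start, ln, _ in indel_runs:
        planted.update(range(start, start + ln))
    seqs = [list(s) for s in seqs]
    poly_columns = []
    for col in range(length):
        if col in planted or rng.random() >= within_group_poly_rate:
            continue
        group_rows = (
            list(range(n_A)) if rng.random() < 0.5 else list(range(n_A, n_A + n_B))
        )
        if len(group_rows) < 2:
            continue
        n_flip = int(rng.integers(1, len(group_rows)))
        rows = rng.choice(group_rows, size=n_flip, replace=False)
        new = _other_base(rng, seqs[group_rows[0]][col])
        for r in rows:
            seqs[r][col] = new
        poly_columns.append(col)
    seqs = ["".join(s) for s in seqs]

    # clones: parental mosaics over the diagnostic sites
    clone_novel_sites = dict(clone_novel_sites or {})
    site_order = [("snp", i) for i in range(len(snp_positions))] + [
        ("indel", i) for i in range(len(indel_runs))
    ]
    for ci, origins in enumerate(clone_origins):
        if len(origins) != len(site_order):
            raise ConfigError(
                f"clone {ci}: origin vector length {len(origins)} != "
                f"{len(site_order)} diagnostic sites"
            )
        clone = list(parent_a)
        # start from parent A, then overwrite per-site state
        for (kind, idx), origin in zip(site_order, origins):
            if kind == "snp":
                p = snp_positions[idx]
                a_state, b_state = snp_states[idx]
                clone[p] = a_state if origin == "A" else b_state
            else:
                start, ln, carrier = indel_runs[idx]
                gapped = carrier == f"parent_{origin}"
                for p in range(start, start + ln):
                    clone[p] = "-" if gapped else base[p]
        for si in clone_novel_sites.get(ci, ()):
            kind, idx = site_order[si]
            if kind != "snp":
                raise ConfigError("novel states are planted at SNP sites only")
            p = snp_positions[idx]
            a_state, b_state = snp_states[idx]
            novel = next(b for b in _BASES if b not in (a_state, b_state))
            clone[p] = novel
        cid = f"H_{ci + 1}"
        ids.append(cid)
        seqs.append("".join(clone))
        groups[cid] = "query"

    aln = GroupedAlignment(ids, seqs, groups)
    truth = {
        "snp_positions": snp_positions,
        "snp_states": snp_states,
        "indel_runs": indel_runs,
        "poly_columns": poly_columns,
    }
    return aln, truth


# ---------------------------------------------------------------- plastid

def simulate_cpdna(
    length: int = 1200,
    haplotype_edits: Mapping[str, Sequence[tuple[int, str]]] | None = None,
    inheritance: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Simulate plastid amplicons under strict maternal inheritance.

    ``haplotype_edits`` maps a haplotype name to (position, new base)
    edits applied to a shared random backbone; the edits are chosen by
    the caller to create or destroy restriction sites.  ``inheritance``
    maps each specimen to its maternal lineage's haplotype name; every
    specimen receives that haplotype sequence verbatim.  Returns
    (specimen -> sequence, haplotype -> sequence).
    """
    rng = np.random.default_rng(seed)
    backbone = "".join(rng.choice(list(_BASES), size=length))
    haplotype_edits = dict(haplotype_edits or {"hap1": []})
    hap_seqs: dict[str, str] = {}
    for name, edits in haplotype_edits.items():
        seq = list(backbone)
        for pos, new in edits:
            if not 0 <= pos < length:
                raise ConfigError(f"edit position {pos} outside sequence of length {length}")
            seq[pos] = new.upper()
        hap_seqs[name] = "".join(seq)
    inheritance = dict(inheritance or {})
    specimen_seqs: dict[str, str] = {}
    for sid, hap in inheritance.items():
        if hap not in hap_seqs:
            raise ConfigError(f"specimen {sid!r} inherits unknown haplotype {hap!r}")
        specimen_seqs[sid] = hap_seqs[hap]
    return specimen_seqs, hap_seqs
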