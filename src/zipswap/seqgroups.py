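"""Grouped-alignment conservation analysis and differentially conserved residue (DCR) scanning.

A DCR is an alignment column that is conserved *within* each of two (or more)
homolog groups with distinct substrate specificities, but occupied by
*different* residues *across* the groups.  Such columns are candidate
specificity determinants: swapping the target-group residue for the
reference-group residue is the elementary move of rational transporter
re-engineering.

The module works on an externally produced multiple sequence alignment
(Clustal Omega, MAFFT, ...).  Only pairwise identity computes an alignment
internally (Needleman-Wunsch via Biopython, BLOSUM62, affine gaps), because
ortholog selection by an identity cutoff operates on unaligned sequences.

Alignment columns are 0-based internally; residue positions are reported in
1-based numbering of a designated reference sequence (e.g. "Q180" means
reference residue 180).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_CHARS = frozenset(AMINO_ACIDS) | {"X", GAP}

#: Residue classes treated as interchangeable when the "non-conservative
#: replacement" filter is switched on.  S/T is included because a Thr->Ser
#: swap is a conservative replacement in this sense.
CONSERVATIVE_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("ILVM"),
    frozenset("ST"),
    frozenset("DE"),
    frozenset("KR"),
    frozenset("FYW"),
    frozenset("NQ"),
)


class AllGapOverlapError(ValueError):
    """Two aligned sequences share no column where both are non-gap."""


@dataclass(frozen=True)
class SeqRecord:
    """A protein sequence with an accession-like identifier.

    The alphabet is the 20 standard amino acids plus 'X' (unknown) and '-'
    (gap, only meaningful in aligned context).  Stop symbols '*' must be
    stripped at I/O time.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_gapped(self) -> bool:
        return GAP in self.seq

    def ungapped(self) -> "SeqRecord":
        return replace(self, seq=self.seq.replace(GAP, "")) if self.is_gapped else self


@dataclass
class SeqGroup:
    """A labelled set of homologs assumed to share substrate specificity."""

    label: str
    members: list[SeqRecord]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.label!r} has no members")
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate ids in group {self.label!r}")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# pairwise identity & ortholog selection
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: SeqRecord, b: SeqRecord, *, aligned: bool | None = None) -> float:
    """Percent identity between two sequences, in [0, 100].

    Identity = matches / (columns where neither sequence is a gap) * 100,
    the most common convention.  If the inputs are not already aligned
    (``aligned=None`` auto-detects by the presence of gap characters), a
    global Needleman-Wunsch alignment (BLOSUM62, gap open -11, extend -1)
    is computed internally.  Symmetric in its arguments by construction.
    """
    if aligned is None:
        aligned = a.is_gapped or b.is_gapped
    if aligned:
        if len(a.seq) != len(b.seq):
            raise ValueError("aligned sequences must have equal length")
        pairs = [
            (x, y) for x, y in zip(a.seq, b.seq) if x != GAP and y != GAP
        ]
        if not pairs:
            raise AllGapOverlapError(
                f"{a.id} and {b.id} have no overlapping non-gap columns"
            )
        matches = sum(x == y for x, y in pairs)
        return 100.0 * matches / len(pairs)
    # canonical argument order guarantees exact symmetry even when the
    # optimal alignment is degenerate
    s1, s2 = sorted([a.ungapped().seq, b.ungapped().seq])
    alignment = _ALIGNER.align(s1, s2)[0]
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches
    if aligned_cols == 0:
        raise AllGapOverlapError(f"{a.id} and {b.id} align with no residue overlap")
    return 100.0 * counts.identities / aligned_cols


def select_orthologs(
    query: SeqRecord,
    candidates: list[SeqRecord],
    cutoff_percent: float = 50.0,
    *,
    label: str | None = None,
) -> SeqGroup:
    """Group the query with every candidate at >= ``cutoff_percent`` identity.

    Mirrors ortholog selection by a sequence-identity threshold (default 50%).
    Membership is order-independent.  An empty candidate list produces a
    singleton group with a warning.
    """
    if not 0.0 < cutoff_percent <= 100.0:
        raise ValueError("cutoff_percent must be in (0, 100]")
    members = [query]
    for cand in candidates:
        if pairwise_identity(query, cand) >= cutoff_percent:
            members.append(cand)
    if len(members) == 1 and candidates:
        warnings.warn(
            f"no candidate reached {cutoff_percent}% identity to {query.id}",
            stacklevel=2,
        )
    elif not candidates:
        warnings.warn("no candidates supplied; group contains only the query",
                      stacklevel=2)
    return SeqGroup(label=label or f"orthologs_of_{query.id}", members=members)


# ---------------------------------------------------------------------------
# grouped MSA
# ---------------------------------------------------------------------------

@dataclass
class GroupedMsa:
    """An alignment whose rows are partitioned into labelled specificity groups.

    ``colmap`` maps 1-based reference residue numbers to 0-based alignment
    columns; ``col_to_ref`` is its inverse over non-gap reference columns.
    """

    records: list[SeqRecord]
    group_of: dict[str, str]
    ref_id: str
    colmap: dict[int, int] = field(init=False, repr=False)
    col_to_ref: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no rows")
        width = len(self.records[0].seq)
        for rec in self.records:
            if len(rec.seq) != width:
                raise ValueError(f"ragged alignment: row {rec.id!r} has length "
                                 f"{len(rec.seq)}, expected {width}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        missing = [i for i in ids if i not in self.group_of]
        if missing:
            raise ValueError(f"members without group assignment: {missing}")
        by_id = {r.id: r for r in self.records}
        if self.ref_id not in by_id:
            raise ValueError(f"reference id {self.ref_id!r} not in alignment")
        refseq = by_id[self.ref_id].seq
        colmap: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(refseq):
            if ch != GAP:
                pos += 1
                colmap[pos] = col
        self.colmap = colmap
        self.col_to_ref = {c: p for p, c in colmap.items()}

    @property
    def width(self) -> int:
        return len(self.records[0].seq)

    @property
    def group_labels(self) -> list[str]:
        # sorted so downstream defaults are invariant to row order
        return sorted({self.group_of[r.id] for r in self.records})

    def rows_of(self, group: str) -> list[SeqRecord]:
        return [r for r in self.records if self.group_of[r.id] == group]

    def column(self, col: int, group: str | None = None) -> str:
        rows = self.records if group is None else self.rows_of(group)
        return "".join(r.seq[col] for r in rows)


def build_grouped_msa(
    records: list[SeqRecord],
    group_assignments: dict[str, str],
    ref_id: str,
) -> GroupedMsa:
    """Assemble a :class:`GroupedMsa` from aligned records and a group map."""
    return GroupedMsa(records=list(records), group_of=dict(group_assignments),
                      ref_id=ref_id)


# ---------------------------------------------------------------------------
# conservation profile
# ---------------------------------------------------------------------------

@dataclass
class GroupColumnStats:
    consensus: str | None      # modal non-gap residue; None if all-gap
    fraction: float            # modal count / non-gap count; nan if all-gap
    n_nongap: int
    gap_fraction: float
    tie: bool                  # modal residue chosen lexicographically

    @property
    def is_invariant(self) -> bool:
        return self.n_nongap > 0 and self.fraction == 1.0


@dataclass
class ConservationProfile:
    """Per-column, per-group consensus and conservation fractions."""

    group_labels: list[str]
    stats: dict[str, list[GroupColumnStats]]   # label -> per-column stats
    col_to_ref: dict[int, int]                 # alignment col -> ref position

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.stats.values())))


def _column_stats(column: str) -> GroupColumnStats:
    residues = [c for c in column if c != GAP]
    n = len(column)
    if not residues:
        return GroupColumnStats(None, float("nan"), 0, 1.0, False)
    counts = Counter(residues)
    top = max(counts.values())
    modal = sorted(r for r, c in counts.items() if c == top)
    return GroupColumnStats(
        consensus=modal[0],
        fraction=top / len(residues),
        n_nongap=len(residues),
        gap_fraction=(n - len(residues)) / n,
        tie=len(modal) > 1,
    )


def conservation_profile(msa: GroupedMsa) -> ConservationProfile:
    """Modal-residue consensus and conservation fraction per column per group.

    Gaps never count toward the consensus; an all-gap column for a group is
    flagged (consensus ``None``, fraction NaN).  Modal ties break
    lexicographically and are recorded.
    """
    labels = msa.group_labels
    if len(labels) < 2:
        raise ValueError("conservation_profile requires >= 2 groups")
    stats = {
        g: [_column_stats(msa.column(c, g)) for c in range(msa.width)]
        for g in labels
    }
    return ConservationProfile(group_labels=labels, stats=stats,
                               col_to_ref=dict(msa.col_to_ref))


# ---------------------------------------------------------------------------
# DCR scanning
# ---------------------------------------------------------------------------

@dataclass
class DcrParams:
    """Criteria for flagging a column as differentially conserved.

    min_within_conservation
        Minimum modal fraction every group must reach (1.0 = strictly
        invariant).
    non_conservative_only
        If true, drop hits whose target/reference consensus pair falls inside
        a conservative residue class (see :data:`CONSERVATIVE_CLASSES`).
    max_group_gap_fraction
        Columns where any group exceeds this gap fraction are excluded.
    """

    min_within_conservation: float = 1.0
    require_cross_group_difference: bool = True
    non_conservative_only: bool = False
    conservative_classes: tuple[frozenset[str], ...] = CONSERVATIVE_CLASSES
    max_group_gap_fraction: float = 0.5
    target_group: str | None = None
    reference_group: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.min_within_conservation <= 1.0:
            raise ValueError("min_within_conservation must be in (0, 1]")
        if not 0.0 <= self.max_group_gap_fraction <= 1.0:
            raise ValueError("max_group_gap_fraction must be in [0, 1]")


@dataclass
class DcrHit:
    """One differentially conserved column, with its proposed swap mutation."""

    column: int                      # 0-based alignment column
    ref_position: int                # 1-based reference numbering
    residues_by_group: dict[str, str]
    fractions_by_group: dict[str, float]
    swap: str                        # e.g. "Q180H"
    class_tag: str = "unassigned"    # pore / entrance / lipid / unassigned


def _is_conservative(x: str, y: str,
                     classes: tuple[frozenset[str], ...]) -> bool:
    return any(x in cls and y in cls for cls in classes)


def scan_dcrs(profile: ConservationProfile,
              params: DcrParams | None = None) -> list[DcrHit]:
    """Scan every alignment column for differential conservation.

    A column is a hit iff every group meets ``min_within_conservation`` and
    stays under the gap ceiling, the target and reference group consensuses
    differ, and (optionally) that consensus pair is a non-conservative
    replacement.  Columns where the reference sequence is gapped carry no
    reference numbering and are skipped.  Hits are sorted by reference
    position and are invariant to row order and member relabelling.
    """
    params = params or DcrParams()
    labels = profile.group_labels
    target = params.target_group or labels[0]
    reference = params.reference_group or labels[1]
    for g in (target, reference):
        if g not in labels:
            raise ValueError(f"unknown group {g!r}; have {labels}")

    hits: list[DcrHit] = []
    for col in range(profile.n_columns):
        if col not in profile.col_to_ref:
            continue
        per_group = {g: profile.stats[g][col] for g in labels}
        if any(s.n_nongap == 0 for s in per_group.values()):
            continue
        if any(s.gap_fraction > params.max_group_gap_fraction
               for s in per_group.values()):
            continue
        if any(s.fraction < params.min_within_conservation
               for s in per_group.values()):
            continue
        t_res = per_group[target].consensus
        r_res = per_group[reference].consensus
        if params.require_cross_group_difference and t_res == r_res:
            continue
        if t_res == "X" or r_res == "X":
            continue
        if params.non_conservative_only and _is_conservative(
                t_res, r_res, params.conservative_classes):
            continue
        pos = profile.col_to_ref[col]
        hits.append(DcrHit(
            column=col,
            ref_position=pos,
            residues_by_group={g: per_group[g].consensus for g in labels},
            fractions_by_group={g: per_group[g].fraction for g in labels},
            swap=f"{t_res}{pos}{r_res}",
        ))
    hits.sort(key=lambda h: h.ref_position)
    return hits


def dcr_table(hits: list[DcrHit]) -> pd.DataFrame:
    """Tidy DataFrame view of a hit list (one row per DCR)."""
    rows = []
    for h in hits:
        row: dict[str, object] = {
            "ref_position": h.ref_position,
            "column": h.column,
            "swap": h.swap,
            "class_tag": h.class_tag,
        }
        for g, res in h.residues_by_group.items():
            row[f"consensus_{g}"] = res
            row[f"fraction_{g}"] = h.fractions_by_group[g]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subfamily column composition
# ---------------------------------------------------------------------------

def column_composition(
    msas_by_subfamily: dict[str, GroupedMsa],
    ref_positions: list[int],
) -> pd.DataFrame:
    """Amino-acid frequency vectors at shared reference positions.

    For each subfamily alignment (each carrying its own mapping to the shared
    reference numbering) and each queried position, returns the frequency of
    every standard amino acid among non-gap residues (vector sums to 1), plus
    the gap fraction reported separately ('X' counts as gap-like unknown).
    Positions absent from a subfamily's colmap are omitted with a warning.
    """
    rows = []
    for family, msa in msas_by_subfamily.items():
        for pos in ref_positions:
            col = msa.colmap.get(pos)
            if col is None:
                warnings.warn(
                    f"position {pos} absent from reference mapping of "
                    f"subfamily {family!r}; row omitted", stacklevel=2)
                continue
            column = msa.column(col)
            residues = [c for c in column if c in AMINO_ACIDS]
            n_excluded = len(column) - len(residues)
            freqs = Counter(residues)
            total = len(residues)
            row: dict[str, object] = {"subfamily": family, "ref_position": pos}
            for aa in AMINO_ACIDS:
                row[aa] = freqs.get(aa, 0) / total if total else float("nan")
            row["gap_fraction"] = n_excluded / len(column)
            row["n_sequences"] = len(column)
            rows.append(row)
    return pd.DataFrame(rows)
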