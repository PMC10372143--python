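"""Structural mapping of candidate specificity residues.

Elevator-type transporters alternate between an inward-facing (IFC) and an
outward-facing (OFC) conformation; a residue pair that is far apart in one
conformation can approach in the other and assemble a *conditional*
selectivity filter.  This module measures Calpha-Calpha distances in
PDB-format models of distinct conformations, classifies residues by their
geometric relation to the transport pathway, and cross-checks residue pairs
against an evolutionary-covariance contact table produced externally.

Conformations are distinct input files carrying labels; no interpolation is
performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .seqgroups import DcrHit


@dataclass(frozen=True)
class Residue:
    name: str
    ca: np.ndarray  # (3,) Angstrom


@dataclass
class StructureModel:
    """Per-residue Calpha coordinates for one conformation of one chain."""

    conformation: str
    chain: str
    residues: dict[int, Residue]

    def __post_init__(self) -> None:
        for num, res in self.residues.items():
            if not np.all(np.isfinite(res.ca)):
                raise ValueError(f"non-finite coordinates at residue {num}")

    def __len__(self) -> int:
        return len(self.residues)

    def ca(self, pos: int) -> np.ndarray:
        try:
            return self.residues[pos].ca
        except KeyError:
            raise KeyError(
                f"residue {pos} not present in {self.conformation} model "
                f"(chain {self.chain})"
            ) from None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Apply a rigid-body transform (used by invariance tests)."""
        return StructureModel(
            conformation=self.conformation,
            chain=self.chain,
            residues={
                n: Residue(r.name, rotation @ r.ca + translation)
                for n, r in self.residues.items()
            },
        )


@dataclass(frozen=True)
class PairDistance:
    pos_i: int
    pos_j: int
    distance: float
    conformation: str


def read_structure(pdb_text: str, chain: str | None = None,
                   conformation_label: str = "model") -> StructureModel:
    """Parse Calpha coordinates from PDB text (ATOM/HETATM records).

    One Calpha per residue: among altlocs the highest-occupancy one is kept
    (ties resolved toward altloc 'A').  Residues with insertion codes are
    rejected; residues lacking a CA atom are skipped with a warning; residue
    numbering is taken verbatim from the file.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("PDB text contains no models")
    model = structure[0]
    if chain is None:
        if len(model) == 0:
            raise ValueError("PDB model contains no chains")
        gchain = model[0]
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise ValueError(f"chain {chain!r} not found in PDB")
    residues: dict[int, Residue] = {}
    for res in gchain:
        if res.seqid.icode not in (" ", "\x00", ""):
            raise ValueError(
                f"residue {res.seqid.num}{res.seqid.icode.strip()} carries an "
                "insertion code; renumber the model first"
            )
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            warnings.warn(
                f"residue {res.name} {res.seqid.num} has no CA atom; skipped",
                stacklevel=2,
            )
            continue
        # altloc resolution: highest occupancy, tie -> lowest altloc letter
        best = sorted(cas, key=lambda a: (-a.occ, a.altloc or "A"))[0]
        residues[res.seqid.num] = Residue(
            name=res.name,
            ca=np.array([best.pos.x, best.pos.y, best.pos.z], dtype=float),
        )
    if not residues:
        raise ValueError("no CA atoms found in the requested chain")
    return StructureModel(conformation=conformation_label,
                          chain=gchain.name, residues=residues)


def ca_distance(model: StructureModel, pos_i: int, pos_j: int) -> PairDistance:
    """Euclidean Calpha-Calpha distance between two residues (Angstrom)."""
    d = float(np.linalg.norm(model.ca(pos_i) - model.ca(pos_j)))
    return PairDistance(pos_i=pos_i, pos_j=pos_j, distance=d,
                        conformation=model.conformation)


def pair_distance_table(models: list[StructureModel],
                        pairs: list[tuple[int, int]]) -> pd.DataFrame:
    """Distances for each residue pair across all conformations."""
    rows = [
        {"conformation": m.conformation, "pos_i": i, "pos_j": j,
         "distance_A": ca_distance(m, i, j).distance}
        for m in models for (i, j) in pairs
    ]
    return pd.DataFrame(rows)


def classify_pore_proximity(
    model: StructureModel,
    positions: list[int],
    axis: tuple[int, int] | np.ndarray,
    radius_cutoff: float = 8.0,
    *,
    origin: np.ndarray | None = None,
) -> dict[int, str]:
    """Tag residues as pore / entrance / lipid relative to the pathway axis.

    The axis runs from an intracellular anchor residue to an extracellular
    anchor residue (``axis=(intra_pos, extra_pos)``), or is given as an
    explicit vector with ``origin``.  A residue within ``radius_cutoff`` of
    the axis is "pore" when its axial coordinate falls inside the anchor
    span and "entrance" when it lies beyond either anchor (the pathway
    mouths); anything farther out radially is "lipid".  Swapping the anchors
    flips the sign of the axial coordinate but not the tags.
    """
    if isinstance(axis, tuple):
        a = model.ca(axis[0])
        b = model.ca(axis[1])
        direction = b - a
        span = float(np.linalg.norm(direction))
    else:
        if origin is None:
            raise ValueError("explicit axis vector requires an origin")
        a = np.asarray(origin, dtype=float)
        direction = np.asarray(axis, dtype=float)
        span = float(np.linalg.norm(direction))
    if span < 1e-9:
        raise ValueError("degenerate pathway axis (anchors coincide)")
    if radius_cutoff <= 0:
        raise ValueError("radius_cutoff must be positive")
    u = direction / span

    tags: dict[int, str] = {}
    for pos in positions:
        v = model.ca(pos) - a
        axial = float(v @ u)
        perp = float(np.linalg.norm(v - axial * u))
        if perp > radius_cutoff:
            tags[pos] = "lipid"
        elif 0.0 <= axial <= span:
            tags[pos] = "pore"
        else:
            tags[pos] = "entrance"
    return tags


def annotate_dcr_hits(hits: list[DcrHit], tags: dict[int, str]) -> list[DcrHit]:
    """Fill ``class_tag`` on DCR hits from a pore-proximity classification."""
    for h in hits:
        h.class_tag = tags.get(h.ref_position, h.class_tag)
    return hits


def read_contact_table(source) -> pd.DataFrame:
    """CSV with header columns (i, j, score), as covariance tools export."""
    df = pd.read_csv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"i", "j", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"contact table must have columns {sorted(required)}")
    if not np.all(np.isfinite(df["score"])):
        raise ValueError("contact table contains non-finite scores")
    return df[["i", "j", "score"]].astype({"i": int, "j": int})


def check_contacts(
    table: pd.DataFrame,
    query_pairs: list[tuple[int, int]],
    score_threshold: float | None = None,
    sequence_separation_min: int = 0,
) -> pd.DataFrame:
    """Look up residue pairs in a coupling-score contact table.

    Matching is order-insensitive in (i, j).  Rows failing the sequence
    separation or score threshold are dropped before ranking; rank 1 is the
    highest surviving score.  Returns one row per query with columns
    (pos_i, pos_j, present, score, rank).
    """
    if table.empty:
        raise ValueError("contact table is empty")
    df = table.copy()
    df = df[(df["i"] - df["j"]).abs() >= sequence_separation_min]
    if score_threshold is not None:
        df = df[df["score"] >= score_threshold]
    if df.empty:
        warnings.warn("no contact rows survive the filters", stacklevel=2)
    df = df.sort_values("score", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    lookup = {frozenset((r.i, r.j)): (r.score, r.rank)
              for r in df.itertuples(index=False)}
    rows = []
    for i, j in query_pairs:
        hit = lookup.get(frozenset((i, j)))
        rows.append({
            "pos_i": i, "pos_j": j,
            "present": hit is not None,
            "score": hit[0] if hit else float("nan"),
            "rank": hit[1] if hit else pd.NA,
        })
    return pd.DataFrame(rows)
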