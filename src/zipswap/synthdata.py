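"""Ground-truth generators for every input class the pipeline consumes.

Each generator is deterministic given (seed, parameters), emits only
standard plain-text formats (FASTA, PDB, CSV) so the outputs flow through
the public interfaces unchanged, and records its ground truth in a JSON
sidecar that a verify pass can re-check against the written files.

The defaults encode the study conditions the analysis is built for: two
specificity groups of homologs with invariant planted columns over an
i.i.d. drifting background; 65Zn/109Cd two-window gamma counts with Poisson
noise, a 0.235 Zn->Cd crosstalk fraction and empty-vector background wells;
Hill-kinetic uptake with 10% multiplicative noise; and paired IFC/OFC
coordinate models in which the designated residue pair closes from 14.9 to
7.5 Angstrom.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .io import write_fasta
from .isotope import DEFAULT_CROSSTALK_SLOPE
from .kinetics import hill
from .seqgroups import AMINO_ACIDS, GroupedMsa, SeqRecord, build_grouped_msa

#: Per-construct (Zn, Cd) activity multipliers relative to wild type.
#: "2M" suppresses Cd 4-fold (a ~4x selectivity gain); "4M" suppresses Cd
#: ~7.5-fold for a 7-8x selectivity gain, the double/quadruple-variant
#: phenotype scales the assay is designed to resolve.
DEFAULT_CONSTRUCT_MULTIPLIERS: dict[str, tuple[float, float]] = {
    "WT": (1.0, 1.0),
    "2M": (1.2, 0.30),
    "4M": (1.1, 0.147),
}

#: Hill parameters (Vmax, K, n) per (construct, metal).  Vmax is in percent
#: of the wild-type Vmax, K in uM.  The 4M entries encode the measured fold
#: changes: Zn Vmax ~4x up / K ~2x up, Cd K 6x up with Vmax unchanged,
#: Fe Vmax 7x down / K 2x up.
DEFAULT_HILL_PARAMS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("WT", "Zn"): (100.0, 3.0, 1.5),
    ("4M", "Zn"): (390.0, 7.0, 1.5),
    ("WT", "Cd"): (100.0, 4.0, 1.5),
    ("4M", "Cd"): (95.0, 24.0, 1.5),
    ("WT", "Fe"): (100.0, 5.0, 1.5),
    ("4M", "Fe"): (14.3, 10.0, 1.5),
}

STANDARD_CONCS_UM = (0.0, 2.5, 5.0, 10.0, 20.0)


def _write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    seed: int
    group_labels: list[str]
    length: int
    n_seqs_per_group: int
    background_mut_prob: float
    planted: dict[int, dict[str, str]]   # column -> group -> residue
    ref_id: str

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["planted"] = {str(k): v for k, v in self.planted.items()}
        d["kind"] = "families"
        _write_json(d, path)


def gen_families(
    n_groups: int = 2,
    n_seqs: int = 8,
    length: int = 200,
    planted: list[tuple[int, dict[str, str] | tuple[str, ...]]] | None = None,
    background_mut_prob: float = 0.3,
    seed: int = 0,
    group_labels: list[str] | None = None,
) -> tuple[GroupedMsa, FamilyTruth]:
    """Simulate aligned homolog groups with planted differential columns.

    All groups share one ancestral sequence.  At planted columns every group
    member carries that group's planted residue exactly (invariant within,
    differing across groups); at background columns each member independently
    mutates away from the ancestor with ``background_mut_prob`` to a uniform
    other residue.  No tree-structured evolution is simulated -- i.i.d.
    column drift is sufficient to exercise the DCR scanner.
    """
    labels = group_labels or [f"group{i + 1}" for i in range(n_groups)]
    if len(labels) != n_groups or len(set(labels)) != n_groups:
        raise ValueError("group labels must be unique and match n_groups")
    planted = planted or []
    planted_map: dict[int, dict[str, str]] = {}
    for col, residues in planted:
        if not 0 <= col < length:
            raise ValueError(f"planted column {col} outside [0, {length})")
        if not isinstance(residues, dict):
            residues = dict(zip(labels, residues))
        if set(residues) != set(labels):
            raise ValueError(f"planted column {col} must name every group")
        if len(set(residues.values())) != len(labels):
            raise ValueError(
                f"planted column {col}: residues must differ between groups")
        if col in planted_map:
            raise ValueError(f"conflicting plant at column {col}")
        planted_map[col] = dict(residues)

    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    ancestor = rng.choice(aa, size=length)

    records: list[SeqRecord] = []
    group_of: dict[str, str] = {}
    for label in labels:
        for k in range(n_seqs):
            row = ancestor.copy()
            mutate = rng.random(length) < background_mut_prob
            for col in np.flatnonzero(mutate):
                choices = aa[aa != row[col]]
                row[col] = rng.choice(choices)
            for col, residues in planted_map.items():
                row[col] = residues[label].encode()
            rid = f"{label}_seq{k + 1}"
            records.append(SeqRecord(id=rid, seq=b"".join(row).decode()))
            group_of[rid] = label

    ref_id = records[0].id
    msa = build_grouped_msa(records, group_of, ref_id)
    truth = FamilyTruth(seed=seed, group_labels=labels, length=length,
                        n_seqs_per_group=n_seqs,
                        background_mut_prob=background_mut_prob,
                        planted=planted_map, ref_id=ref_id)
    return msa, truth


def write_family_bundle(outdir: str | Path, msa: GroupedMsa,
                        truth: FamilyTruth) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(msa.records, outdir / "alignment.fasta")
    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("id\tgroup\n")
        for rec in msa.records:
            fh.write(f"{rec.id}\t{msa.group_of[rec.id]}\n")
    truth.to_json(outdir / "truth_families.json")


# ---------------------------------------------------------------------------
# two-window gamma assay
# ---------------------------------------------------------------------------

@dataclass
class AssayTruth:
    seed: int
    crosstalk_slope: float
    background_cpm: float
    base_zn_cpm: float
    base_cd_cpm: float
    multipliers: dict[str, tuple[float, float]]
    n_experiments: int
    n_replicates: int
    expected_relative_selectivity_pct: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        wt_zn, wt_cd = self.multipliers["WT"]
        wt_ratio = wt_zn / wt_cd
        self.expected_relative_selectivity_pct = {
            c: 100.0 * (zn / cd) / wt_ratio
            for c, (zn, cd) in self.multipliers.items() if cd > 0
        }

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["kind"] = "assay"
        _write_json(d, path)


def gen_standards(
    concs_uM: tuple[float, ...] = STANDARD_CONCS_UM,
    cpm_per_uM: float = 5000.0,
    slope: float = DEFAULT_CROSSTALK_SLOPE,
    seed: int = 0,
    *,
    poisson: bool = True,
) -> pd.DataFrame:
    """Zn-only calibration standards with Poisson-noised two-window counts.

    The Zn window expects ``cpm_per_uM * conc`` counts; the Cd window sees
    only the crosstalk fraction ``slope`` of that.  The default series spans
    0-20 uM with non-zero wells at >= 1.25e4 expected counts.
    """
    rng = np.random.default_rng(seed)
    zn_mean = np.asarray(concs_uM, dtype=float) * cpm_per_uM
    cd_mean = slope * zn_mean
    zn = rng.poisson(zn_mean).astype(float) if poisson else zn_mean
    cd = rng.poisson(cd_mean).astype(float) if poisson else cd_mean
    return pd.DataFrame({
        "standard_conc_uM": concs_uM,
        "zn_window_cpm": zn,
        "cd_window_cpm": cd,
    })


def gen_assay(
    multipliers: dict[str, tuple[float, float]] | None = None,
    slope: float = DEFAULT_CROSSTALK_SLOPE,
    background_cpm: float = 150.0,
    base_zn_cpm: float = 20000.0,
    base_cd_cpm: float = 15000.0,
    n_experiments: int = 5,
    n_replicates: int = 3,
    seed: int = 0,
    expression_cv: float = 0.15,
    well_cv: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, AssayTruth]:
    """Simulate standards plus transfected/empty-vector wells.

    Expected Zn-window counts per well are ``background + f * zn_mult *
    base_zn_cpm`` where ``f`` is a lognormal nuisance factor combining
    per-transfection expression variation and per-well cell-number
    variation (the factor the internal-competition ratio cancels).  The Cd
    window receives its own signal plus ``slope`` times the Zn-window
    expectation.  Counts are Poisson.  Empty-vector wells (label
    ``empty_vector``) carry zero transporter signal.
    """
    multipliers = dict(multipliers or DEFAULT_CONSTRUCT_MULTIPLIERS)
    if any(zn <= 0 or cd < 0 for zn, cd in multipliers.values()):
        raise ValueError("activity multipliers must be positive")
    rng = np.random.default_rng(seed)
    standards = gen_standards(slope=slope, seed=int(rng.integers(2**31)))

    rows = []
    constructs = list(multipliers) + ["empty_vector"]
    for e in range(1, n_experiments + 1):
        for construct in constructs:
            zn_mult, cd_mult = multipliers.get(construct, (0.0, 0.0))
            expr = float(np.exp(rng.normal(0.0, expression_cv)))
            for r in range(1, n_replicates + 1):
                f = expr * float(np.exp(rng.normal(0.0, well_cv)))
                zn_mean = background_cpm + f * zn_mult * base_zn_cpm
                cd_mean = background_cpm + f * cd_mult * base_cd_cpm \
                    + slope * zn_mean
                rows.append({
                    "experiment_id": f"exp{e}",
                    "well_id": f"exp{e}_{construct}_r{r}",
                    "construct": construct,
                    "zn_window_cpm": float(rng.poisson(zn_mean)),
                    "cd_window_cpm": float(rng.poisson(cd_mean)),
                })
    wells = pd.DataFrame(rows)
    truth = AssayTruth(seed=seed, crosstalk_slope=slope,
                       background_cpm=background_cpm,
                       base_zn_cpm=base_zn_cpm, base_cd_cpm=base_cd_cpm,
                       multipliers=multipliers,
                       n_experiments=n_experiments,
                       n_replicates=n_replicates)
    return standards, wells, truth


def write_assay_bundle(outdir: str | Path, standards: pd.DataFrame,
                       wells: pd.DataFrame, truth: AssayTruth) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    standards.to_csv(outdir / "standards.csv", index=False)
    wells.to_csv(outdir / "wells.csv", index=False)
    truth.to_json(outdir / "truth_assay.json")


# ---------------------------------------------------------------------------
# uptake curves
# ---------------------------------------------------------------------------

@dataclass
class CurveTruth:
    seed: int
    params: dict[str, tuple[float, float, float]]  # "construct|metal" -> V,K,n
    concs_uM: list[float]
    noise_cv: float
    n_replicates: int

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["kind"] = "curves"
        _write_json(d, path)


def gen_curves(
    params: dict[tuple[str, str], tuple[float, float, float]] | None = None,
    concs_uM: tuple[float, ...] = (1.0, 2.5, 5.0, 10.0, 20.0, 40.0),
    noise_cv: float = 0.10,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, CurveTruth]:
    """Hill-kinetic uptake series with multiplicative Gaussian noise.

    Rates are ``hill(S; V, K, n) * (1 + cv * eps)`` truncated at zero, with
    3 replicates per concentration by default.
    """
    params = dict(params or DEFAULT_HILL_PARAMS)
    rng = np.random.default_rng(seed)
    rows = []
    for (construct, metal), (vmax, k, n) in sorted(params.items()):
        for conc in concs_uM:
            mean = float(hill(conc, vmax, k, n))
            for r in range(1, n_replicates + 1):
                rate = mean * (1.0 + noise_cv * rng.standard_normal())
                rows.append({
                    "construct": construct, "metal": metal,
                    "conc_uM": conc, "rate": max(rate, 0.0),
                    "replicate": r,
                })
    curves = pd.DataFrame(rows)
    truth = CurveTruth(seed=seed,
                       params={f"{c}|{m}": v for (c, m), v in params.items()},
                       concs_uM=list(concs_uM), noise_cv=noise_cv,
                       n_replicates=n_replicates)
    return curves, truth


def write_curves_bundle(outdir: str | Path, curves: pd.DataFrame,
                        truth: CurveTruth) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves.to_csv(outdir / "curves.csv", index=False)
    truth.to_json(outdir / "truth_curves.json")


# ---------------------------------------------------------------------------
# two-conformation structures
# ---------------------------------------------------------------------------

@dataclass
class StructureTruth:
    seed: int
    pair: tuple[int, int]
    d_ifc: float
    d_ofc: float
    n_residues: int

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["kind"] = "structures"
        _write_json(d, path)


def _random_walk(rng: np.random.Generator, n: int, step: float = 3.8
                 ) -> np.ndarray:
    steps = rng.standard_normal((n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.cumsum(steps * step, axis=0)


def _pdb_string(numbers: list[int], coords: np.ndarray,
                names: dict[int, str]) -> str:
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    for num, xyz in zip(numbers, coords):
        res = gemmi.Residue()
        res.name = names.get(num, "ALA")
        res.seqid = gemmi.SeqId(num, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def gen_structures(
    n_residues: int = 80,
    pair: tuple[int, int] = (180, 343),
    d_ifc: float = 14.9,
    d_ofc: float = 7.5,
    seed: int = 0,
) -> tuple[str, str, StructureTruth]:
    """Toy IFC/OFC coordinate models in which one residue pair approaches.

    A Calpha random walk provides the shared scaffold; the second pair
    residue is placed at exactly ``d_ifc`` (inward-facing) or ``d_ofc``
    (outward-facing) Angstrom from the first along a fixed, randomly chosen
    signed coordinate axis, emulating an elevator-type conformational change
    closing a selectivity filter (defaults: 14.9 -> 7.5).  Coordinates are
    snapped to the 0.001 Angstrom PDB precision grid, so any requested
    distance with at most three decimals survives the PDB round-trip
    exactly.  Residue numbering is a contiguous block around the first pair
    position plus the second pair position.  Returns two PDB strings and the
    ground truth.
    """
    pos_i, pos_j = pair
    if pos_i == pos_j:
        raise ValueError("pair positions must differ")
    if d_ifc <= 0 or d_ofc <= 0:
        raise ValueError("pair distances must be positive")
    rng = np.random.default_rng(seed)
    start = pos_i - n_residues // 2
    numbers = sorted(set(range(start, start + n_residues)) | {pos_i, pos_j})
    coords = np.round(_random_walk(rng, len(numbers)), 3)
    direction = np.zeros(3)
    direction[rng.integers(3)] = rng.choice([-1.0, 1.0])
    names = {pos_i: "GLN", pos_j: "GLU"}

    idx_i = numbers.index(pos_i)
    idx_j = numbers.index(pos_j)
    pdbs = []
    for d in (d_ifc, d_ofc):
        c = coords.copy()
        c[idx_j] = np.round(c[idx_i] + d * direction, 3)
        pdbs.append(_pdb_string(numbers, c, names))
    truth = StructureTruth(seed=seed, pair=(pos_i, pos_j), d_ifc=d_ifc,
                           d_ofc=d_ofc, n_residues=len(numbers))
    return pdbs[0], pdbs[1], truth


def write_structure_bundle(outdir: str | Path, pdb_ifc: str, pdb_ofc: str,
                           truth: StructureTruth) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "model_ifc.pdb").write_text(pdb_ifc)
    (outdir / "model_ofc.pdb").write_text(pdb_ofc)
    truth.to_json(outdir / "truth_structures.json")


# ---------------------------------------------------------------------------
# covariance contact table
# ---------------------------------------------------------------------------

def gen_contacts(
    n_positions: int = 460,
    n_random: int = 100,
    planted_pairs: list[tuple[int, int]] | None = None,
    planted_score: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic coupling-score table: low-score random pairs + planted hits."""
    planted_pairs = planted_pairs or []
    rng = np.random.default_rng(seed)
    planted_set = {frozenset(p) for p in planted_pairs}
    rows = []
    while len(rows) < n_random:
        i, j = sorted(rng.integers(1, n_positions + 1, size=2))
        if i == j or frozenset((i, j)) in planted_set:
            continue
        rows.append({"i": int(i), "j": int(j),
                     "score": float(rng.uniform(0.0, 0.5))})
    for i, j in planted_pairs:
        rows.append({"i": i, "j": j,
                     "score": planted_score + float(rng.uniform(0, 0.1))})
    return pd.DataFrame(rows).drop_duplicates(subset=["i", "j"])


# ---------------------------------------------------------------------------
# full bundle + verification
# ---------------------------------------------------------------------------

def write_full_bundle(outdir: str | Path, seed: int = 0) -> Path:
    """Write one coherent synthetic input set for the end-to-end pipeline."""
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=4)
    msa, ftruth = gen_families(
        planted=[(10, ("Q", "H")), (40, ("E", "H")), (90, ("C", "G")),
                 (130, ("N", "H")), (170, ("D", "K"))],
        seed=int(seeds[0]),
        group_labels=["multi_metal", "zn_preferring"],
    )
    write_family_bundle(outdir, msa, ftruth)
    standards, wells, atruth = gen_assay(seed=int(seeds[1]))
    write_assay_bundle(outdir, standards, wells, atruth)
    curves, ctruth = gen_curves(seed=int(seeds[2]))
    write_curves_bundle(outdir, curves, ctruth)
    ifc, ofc, struth = gen_structures(seed=int(seeds[3]))
    write_structure_bundle(outdir, ifc, ofc, struth)
    return outdir


def verify_bundle(outdir: str | Path) -> dict[str, str]:
    """Re-read generator outputs and assert consistency with their truths.

    Returns a per-bundle status map; raises AssertionError on the first
    inconsistency found.
    """
    from . import structmap
    from .io import read_fasta, read_groups_tsv
    from .seqgroups import DcrParams, conservation_profile, scan_dcrs

    outdir = Path(outdir)
    report: dict[str, str] = {}

    fpath = outdir / "truth_families.json"
    if fpath.exists():
        truth = json.loads(fpath.read_text())
        records = read_fasta(outdir / "alignment.fasta")
        groups = read_groups_tsv(outdir / "groups.tsv")
        msa = build_grouped_msa(records, groups, truth["ref_id"])
        hits = scan_dcrs(conservation_profile(msa), DcrParams())
        planted_cols = {int(c) for c in truth["planted"]}
        hit_cols = {h.column for h in hits}
        assert planted_cols <= hit_cols, (
            f"planted columns {sorted(planted_cols - hit_cols)} not recovered")
        for h in hits:
            if h.column in planted_cols:
                expect = truth["planted"][str(h.column)]
                assert h.residues_by_group == expect, (
                    f"column {h.column}: {h.residues_by_group} != {expect}")
        report["families"] = "ok"

    spath = outdir / "truth_structures.json"
    if spath.exists():
        truth = json.loads(spath.read_text())
        pos_i, pos_j = truth["pair"]
        for label, key in (("ifc", "d_ifc"), ("ofc", "d_ofc")):
            model = structmap.read_structure(
                (outdir / f"model_{label}.pdb").read_text(),
                conformation_label=label.upper())
            d = structmap.ca_distance(model, pos_i, pos_j).distance
            assert abs(d - truth[key]) < 1e-6, (
                f"{label} pair distance {d} != {truth[key]}")
        report["structures"] = "ok"

    apath = outdir / "truth_assay.json"
    if apath.exists():
        truth = json.loads(apath.read_text())
        from .isotope import fit_crosstalk
        standards = pd.read_csv(outdir / "standards.csv")
        calib = fit_crosstalk(standards)
        se = 3 * crosstalk_check_se(standards, calib.slope)
        assert abs(calib.slope - truth["crosstalk_slope"]) < max(se, 0.01), (
            f"recovered slope {calib.slope} far from {truth['crosstalk_slope']}")
        wells = pd.read_csv(outdir / "wells.csv")
        assert set(wells["construct"]) == set(truth["multipliers"]) | {
            "empty_vector"}
        report["assay"] = "ok"

    cpath = outdir / "truth_curves.json"
    if cpath.exists():
        truth = json.loads(cpath.read_text())
        curves = pd.read_csv(outdir / "curves.csv")
        assert (curves["rate"] >= 0).all()
        keys = {f"{c}|{m}" for c, m in
                curves.groupby(["construct", "metal"]).groups}
        assert keys == set(truth["params"])
        report["curves"] = "ok"

    if not report:
        raise FileNotFoundError(f"no truth sidecars found under {outdir}")
    return report


def crosstalk_check_se(standards: pd.DataFrame, slope: float) -> float:
    from .isotope import crosstalk_slope_se
    return crosstalk_slope_se(standards, slope)
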