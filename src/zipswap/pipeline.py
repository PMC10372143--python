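"""End-to-end orchestration: sequences -> DCRs -> structure -> assay -> kinetics.

Stages communicate only through files in the output directory so any stage
can be re-run or inspected in isolation; the report records software
version, a config hash and input-file hashes for provenance.  The report
body is deterministic for a fixed config and seed (no timestamps); wall
times go to the log only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, structmap
from .io import read_fasta, read_groups_tsv
from .isotope import (CalibrationModel, compute_activity, fit_crosstalk,
                      selectivity)
from .kinetics import fit_curves
from .seqgroups import (DcrParams, conservation_profile, dcr_table, scan_dcrs)

log = logging.getLogger("zipswap")


class ConfigError(ValueError):
    """A run configuration problem detected before any stage executes."""


@dataclass
class RunConfig:
    """Validated inputs and thresholds for a pipeline run.

    Stage sections are plain mappings (mirroring the YAML layout); only the
    ``sequences`` stage is mandatory, later stages run when configured.
    """

    output_dir: str = "zipswap_out"
    seed: int = 0
    sequences: dict = field(default_factory=dict)
    structure: dict | None = None
    assay: dict | None = None
    kinetics: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.sequences:
            raise ConfigError("config must define the 'sequences' stage")
        self._require_files("sequences", self.sequences,
                            ["alignment", "groups"])
        if "ref_id" not in self.sequences:
            raise ConfigError("sequences stage requires 'ref_id'")
        if self.structure:
            models = self.structure.get("models") or []
            if not models:
                raise ConfigError("structure stage requires 'models'")
            for m in models:
                self._require_files("structure", m, ["path"])
            if "contact_table" in self.structure:
                self._require_files("structure", self.structure,
                                    ["contact_table"])
        if self.assay:
            self._require_files("assay", self.assay, ["measurements"])
            if ("standards" not in self.assay
                    and "slope_override" not in self.assay):
                raise ConfigError(
                    "assay stage requires 'standards' or 'slope_override'")
            if "standards" in self.assay:
                self._require_files("assay", self.assay, ["standards"])
        if self.kinetics:
            self._require_files("kinetics", self.kinetics, ["curves"])

    @staticmethod
    def _require_files(stage: str, section: dict, keys: list[str]) -> None:
        for key in keys:
            if key not in section:
                raise ConfigError(f"{stage} stage requires {key!r}")
            if not Path(section[key]).is_file():
                raise ConfigError(
                    f"{stage} input {key!r} not found: {section[key]}")

    def input_paths(self) -> list[Path]:
        paths: list[Path] = []
        for key in ("alignment", "groups"):
            paths.append(Path(self.sequences[key]))
        if self.structure:
            paths += [Path(m["path"]) for m in self.structure.get("models", [])]
            if "contact_table" in self.structure:
                paths.append(Path(self.structure["contact_table"]))
        if self.assay:
            paths.append(Path(self.assay["measurements"]))
            if "standards" in self.assay:
                paths.append(Path(self.assay["standards"]))
        if self.kinetics:
            paths.append(Path(self.kinetics["curves"]))
        return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(report: dict, name: str):
    class _StageCtx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: started", name)
            return report["stages"].setdefault(name, {"status": "running"})

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                report["stages"][name]["status"] = "ok"
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                report["stages"][name]["status"] = "error"
                report["stages"][name]["error"] = str(exc)
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False
    return _StageCtx()


def run_engineering_report(config: RunConfig) -> dict:
    """Run all configured stages in dependency order and write the report.

    Each stage's outputs land in ``output_dir`` even when later stages are
    skipped or fail; the first stage error propagates after the report is
    written (the CLI converts it into a non-zero exit).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_dict = asdict(config)
    report: dict = {
        "software": {"name": "zipswap", "version": __version__},
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "inputs": {str(p): _sha256(p) for p in config.input_paths()},
        "stages": {},
    }
    error: Exception | None = None

    hits = []
    try:
        with _stage(report, "sequences") as st:
            seq = config.sequences
            records = read_fasta(seq["alignment"])
            groups = read_groups_tsv(seq["groups"])
            from .seqgroups import build_grouped_msa
            msa = build_grouped_msa(records, groups, seq["ref_id"])
            params = DcrParams(
                min_within_conservation=seq.get("min_conservation", 1.0),
                max_group_gap_fraction=seq.get("max_gap_fraction", 0.5),
                non_conservative_only=seq.get("non_conservative_only", False),
                target_group=seq.get("target_group"),
                reference_group=seq.get("reference_group"),
            )
            profile = conservation_profile(msa)
            hits = scan_dcrs(profile, params)
            st["n_dcrs"] = len(hits)
            st["dcr_positions"] = [h.ref_position for h in hits]
            st["swaps"] = [h.swap for h in hits]
    except Exception as exc:  # first failing stage aborts the rest
        error = exc

    if error is None and config.structure:
        try:
            with _stage(report, "structure") as st:
                sc = config.structure
                models = [
                    structmap.read_structure(
                        Path(m["path"]).read_text(),
                        chain=m.get("chain"),
                        conformation_label=m.get("conformation", "model"),
                    )
                    for m in sc["models"]
                ]
                pairs = [tuple(p) for p in sc.get("pairs", [])]
                if pairs:
                    dist = structmap.pair_distance_table(models, pairs)
                    dist.to_csv(outdir / "pair_distances.tsv", sep="\t",
                                index=False)
                    st["pair_distances"] = dist.to_dict("records")
                anchors = sc.get("anchors")
                if anchors:
                    model = models[0]
                    positions = [h.ref_position for h in hits
                                 if h.ref_position in model.residues]
                    tags = structmap.classify_pore_proximity(
                        model, positions, tuple(anchors),
                        radius_cutoff=sc.get("radius_cutoff", 8.0))
                    structmap.annotate_dcr_hits(hits, tags)
                    st["class_tags"] = {str(k): v for k, v in tags.items()}
                if "contact_table" in sc:
                    table = structmap.read_contact_table(sc["contact_table"])
                    qpairs = [tuple(p) for p in sc.get(
                        "query_pairs", sc.get("pairs", []))]
                    if qpairs:
                        rep = structmap.check_contacts(
                            table, qpairs,
                            score_threshold=sc.get("score_threshold"),
                            sequence_separation_min=sc.get(
                                "sequence_separation_min", 0))
                        rep.to_csv(outdir / "contacts.tsv", sep="\t",
                                   index=False)
                        st["contacts_present"] = int(rep["present"].sum())
        except Exception as exc:
            error = exc
    elif config.structure is None:
        report["stages"]["structure"] = {"status": "skipped"}

    # DCR table (with any class tags) is written after the structure stage
    if hits:
        table = dcr_table(hits)
        table.to_csv(outdir / "dcr.tsv", sep="\t", index=False)
        table.to_json(outdir / "dcr.json", orient="records", indent=1)

    if error is None and config.assay:
        try:
            with _stage(report, "assay") as st:
                ac = config.assay
                if "slope_override" in ac:
                    calib = CalibrationModel(
                        slope=float(ac["slope_override"]), intercept=0.0,
                        r_squared=float("nan"), n_points=2,
                        free_slope=float("nan"), free_intercept=float("nan"))
                else:
                    calib = fit_crosstalk(pd.read_csv(ac["standards"]))
                (outdir / "calibration.json").write_text(json.dumps(
                    {k: v for k, v in asdict(calib).items()},
                    indent=1, sort_keys=True) + "\n")
                wells = pd.read_csv(ac["measurements"])
                acts = compute_activity(
                    wells, calib,
                    wt_label=ac.get("wt_label", "WT"),
                    empty_label=ac.get("empty_label", "empty_vector"))
                acts.to_csv(outdir / "activity.tsv", sep="\t", index=False)
                sel = selectivity(acts, wt_label=ac.get("wt_label", "WT"))
                sel.per_experiment.to_csv(
                    outdir / "selectivity_per_experiment.tsv", sep="\t",
                    index=False)
                sel.summary.to_csv(outdir / "selectivity.tsv", sep="\t",
                                   index=False)
                st["calibration_slope"] = calib.slope
                st["relative_selectivity_pct"] = dict(zip(
                    sel.summary["construct"],
                    sel.summary["relative_selectivity_pct"]))
        except Exception as exc:
            error = exc
    elif config.assay is None:
        report["stages"]["assay"] = {"status": "skipped"}

    if error is None and config.kinetics:
        try:
            with _stage(report, "kinetics") as st:
                kc = config.kinetics
                curves = pd.read_csv(kc["curves"])
                fits = fit_curves(curves)
                fits.to_csv(outdir / "hill_fits.tsv", sep="\t", index=False)
                baseline = kc.get("baseline", "WT")
                folds = []
                base = fits[fits["construct"] == baseline].set_index("metal")
                for _, row in fits.iterrows():
                    if row["construct"] == baseline:
                        continue
                    if row["metal"] not in base.index:
                        continue
                    b = base.loc[row["metal"]]
                    folds.append({
                        "construct": row["construct"],
                        "metal": row["metal"],
                        "vmax_fold_vs_baseline": row["vmax"] / b["vmax"],
                        "km_fold_vs_baseline": row["km"] / b["km"],
                        "specificity_fold_reduction":
                            b["vmax_over_km"] / row["vmax_over_km"],
                    })
                fold_df = pd.DataFrame(folds)
                fold_df.to_csv(outdir / "specificity_folds.tsv", sep="\t",
                               index=False)
                st["n_fits"] = len(fits)
                st["folds"] = folds
        except Exception as exc:
            error = exc
    elif config.kinetics is None:
        report["stages"]["kinetics"] = {"status": "skipped"}

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str) + "\n")
    if error is not None:
        raise error
    return report
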