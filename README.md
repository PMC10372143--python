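# zipswap

Computational toolkit for rationally re-engineering the substrate
specificity of metal transporters, built around the workflow that converted
the multi-metal human transporter ZIP8 into a Zn-preferring variant:

1. **Find candidate specificity determinants.**  Align homologs of a target
   transporter and of a reference transporter with a different substrate
   spectrum, partition the alignment into specificity groups, and scan for
   *differentially conserved residues* (DCRs) — columns conserved within
   each group but occupied by different residues across groups.  Each DCR
   yields a swap mutation (e.g. `Q180H`: replace the target residue with
   the reference consensus).
2. **Map them onto structure.**  Measure Cα–Cα distances of candidate pairs
   across inward-facing (IFC) and outward-facing (OFC) conformational
   models, classify residues as pore / entrance / lipid relative to the
   transport pathway axis, and cross-check pairs against an evolutionary
   covariance contact table.  A pair that approaches only in the OFC is a
   candidate *conditional selectivity filter*.
3. **Quantify the phenotype.**  Analyse dual-isotope internal-competition
   transport assays — ⁶⁵Zn and ¹⁰⁹Cd counted simultaneously in two gamma
   windows from the same well — including the Zn→Cd-window crosstalk
   calibration (zero-intercept slope of Cd-window on Zn-window counts from
   Zn-only standards), empty-vector background subtraction, per-experiment
   Zn/Cd selectivity relative to wild type, Student's t statistics, Hill
   kinetics v = Vmax·Sⁿ/(Kⁿ+Sⁿ) with specificity constants Vmax/K_M,
   single-dose competition inhibition, and ICP-MS Mn/P molar ratios.

A synthetic-data module generates every input class (grouped FASTA
families, two-window count tables, uptake curves, two-conformation PDB
models) with serialized ground truth, so the full pipeline is testable
end-to-end without downloads.  See `docs/methods.md` for models, defaults
and limitations.

## Worked example

Simulate a coherent input bundle and run the stages through the CLI:

```console
$ zipswap simulate --what all --out-dir demo --seed 11
synthetic all written to demo

$ zipswap -q dcr --alignment demo/alignment.fasta --groups demo/groups.tsv \
    --ref multi_metal_seq1 --out demo/dcr.tsv
5 DCRs -> demo/dcr.tsv

$ zipswap -q assay --measurements demo/wells.csv --standards demo/standards.csv \
    --out-dir demo
slope=0.2333; wrote activity.tsv, selectivity.tsv in demo

$ cut -f1-3 demo/selectivity.tsv
construct  zn_cd_ratio         relative_selectivity_pct
2M         5.313126580081311   398.86256632153174
4M         9.927842559237897   745.3866961599149
WT         1.332068347651046   100.0

$ zipswap -q structmap --pdb demo/model_ifc.pdb --pdb demo/model_ofc.pdb \
    --conformation IFC --conformation OFC --pair 180:343 --out demo/dist.tsv
$ cat demo/dist.tsv
conformation  pos_i  pos_j  distance_A
IFC           180    343    14.899999999999999
OFC           180    343    7.5
```

Reading the numbers: the scan recovered all five planted DCR swaps; the
fitted crosstalk slope (0.2333) matches the generator's 0.235 truth within
Poisson noise; the double variant's Zn/Cd selectivity is ~4× wild type
(399%) and the quadruple variant's ~7.5× (745%), i.e. the engineered
constructs progressively favour Zn over Cd; and the designated residue pair
closes from 14.9 Å to 7.5 Å between conformations — the geometry of a
filter that only assembles in the outward-facing state.

The same stages run as one pipeline from a YAML config
(`zipswap run --config run.yaml`), writing per-stage tables plus a
`report.json` with software version, config hash and input hashes.
`zipswap verify --dir demo` re-reads generated outputs and asserts
consistency with their ground-truth sidecars.

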