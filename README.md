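# tloopsrm

Most protein kinases switch into their active state when the activation
loop (T-loop) of the kinase domain — the stretch between the conserved
DFG and APE motifs — is phosphorylated. Measuring T-loop phosphorylation
directly by targeted mass spectrometry (SRM on a triple quadrupole, with
heavy-isotope-labeled internal standard peptides) therefore gives a
readout of kinase activation itself, rather than inferring it from
substrate phosphorylation.

`tloopsrm` is the computational backbone for building and running such a
kinome-wide assay:

* **Target design** — parse kinase sequences from FASTA, locate the
  activation segment (DFG…APE, configurable motifs and length bounds),
  enumerate phosphorylatable S/T/Y residues, digest in silico with
  trypsin and/or LysC, and keep the phosphopeptides accessible to SRM.
* **Assay building** — monoisotopic precursor/fragment m/z for light and
  heavy (C-terminal K +8.014199 Da / R +10.008269 Da) phospho-forms,
  y/b ions with optional −H₃PO₄ neutral-loss variants, site-determining
  ions for positional isomers, and charge-dependent collision energies
  (CE = 0.03·m/z + 2.905 for 2+; CE = 0.038·m/z + 2.281 for ≥3+).
* **Scheduling** — survey mode (≈3 transitions/precursor, 4 min windows,
  4 s cycles) and quantification mode (≤7 transitions including
  site-determining ions, 6–10 min windows, 2.5–3 s cycles), iRT-based
  retention-time mapping, and an exact concurrency sweep that reports
  the worst-point dwell time.
* **Quantification** — peak integration of light/heavy chromatograms,
  transition-pattern similarity (rdotp > 0.9), co-elution checks,
  on/off noise substitution, and analyte/internal-standard ratios.
* **Calibration & statistics** — dilution-series regression with
  LOD = 3·S_a/b and LOQ = 10·S_a/b (slope b, intercept SD S_a),
  normalization to a control condition, and per-peptide differential
  testing of log₂ ratios (significance at p ≤ 0.05).
* **Kinase grouping** — shared T-loop peptides are resolved by the
  protein-grouping principle into kinase groups (e.g. one peptide shared
  by three receptor kinases yields one three-member group).
* **Synthetic data** — seed-deterministic generators for kinomes with
  known activation segments and ambiguity classes, Gaussian-peak SRM
  chromatograms with known ratios, and dilution series with known slope
  and intercept spread, so every stage is testable end to end.

## Worked example

```python
from tloopsrm import (build_assay, build_peptide_kinase_map, design_targets,
                      fit_calibration, resolve_groups)
from tloopsrm.simulate import (KinomeSimParams, generate_kinome,
                               simulate_dilution_series)

# a 12-kinase synthetic kinome where three kinases share one T-loop peptide
records, truth = generate_kinome(
    12, seed=17, params=KinomeSimParams(shared_groups=(3, 2)))
targets, skipped = design_targets(records)
mapping = build_peptide_kinase_map(
    targets, {r.kinase_id: r.gene for r in records})
detected = [(i["target_peptide"], frozenset({i["local_sites"][0]}))
            for i in truth.kinases.values()]
result = resolve_groups(detected, mapping)
print(result.n_sites, result.n_groups, result.n_kinases)
# 9 9 12   (12 kinases -> 9 distinct sites -> 9 groups, incl. one trio, one pair)

assay = build_assay(targets[0], mode="quantification")
print(len(assay.channel("light", 2)))   # 7 transitions per precursor

series, _ = simulate_dilution_series(b_true=2.0, intercept_sd=0.5,
                                     noise_sd=0.0, seed=1)
fit = fit_calibration(series)
print(fit.summary())
```

The calibration summary prints the fitted sensitivity `b`, the intercept
spread `S_a`, and the derived limits — for the series above the slope is
2.0 and LOD/LOQ follow `3·S_a/b` and `10·S_a/b` (their ratio is always
10/3).

The same pipeline is scriptable from the shell:

```bash
tloopsrm simulate kinome --n 12 --seed 7 --shared 3 -o kinome.fasta
tloopsrm design kinome.fasta -o targets.csv
tloopsrm group targets.csv -o groups.csv
tloopsrm assay targets.csv --mode quantification -o transitions.csv
```

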