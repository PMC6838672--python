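# Methods

This note documents the models, estimators and numerical conventions the
package implements, the parameters that matter, and what the synthetic
data do and do not emulate.

## Activation-segment annotation

The activation segment (T-loop) is defined as the interval from the
first residue of the DFG motif to the last residue of the APE motif,
1-based and inclusive. Motifs are regular expressions (defaults: exact
`DFG` and `APE`, falling back to the degenerate `D[FWL]G` / `AP[ED]`
when the exact pair finds nothing), and a valid pair must enclose
15–40 intervening residues (`SegmentParams.min_gap/max_gap`). DFG
occurrences are scanned left to right and, for each, APE occurrences
left to right; the first pair satisfying the bounds wins, which makes
the location position-equivariant and deterministic. Externally supplied
segment annotations (sidecar TSV) always override the motif search.
Sequences without a valid pair are skipped with a log entry, never a
crash — real kinomes contain atypical kinases.

## Digestion and target accessibility

Cleavage rules: trypsin cuts after K or R except before proline; LysC
cuts after K unconditionally; a combined digest uses the union of cut
points. Peptides with 0..`max_missed` internal missed cleavages are
enumerated directly from the cut-point list (default `max_missed=2`).
A digest peptide is an *accessible* target when it covers at least one
S/T/Y of the activation segment and is 6–30 residues long — the typical
SRM-measurable tryptic range; both bounds are configurable. One target
is emitted per distinct (backbone, phospho-position set); identical
peptides from different kinases merge, with the kinase-id set recording
the ambiguity. Singly and doubly phosphorylated forms are generated by
default (`multiplicities=(1, 2)`), since several T-loops carry two
sites on one tryptic peptide. Peptides ending on a residue other than
K/R (protein C-terminus) are retained but flagged: they cannot take the
heavy C-terminal label and are excluded from assay building.

## Masses and transitions

All masses are monoisotopic. Residue masses come from pyteomics; the
fixed constants are proton 1.007276 Da, water 18.010565 Da, phospho
(HPO₃) 79.966331 Da, phosphoric-acid neutral loss 97.976896 Da, and
heavy labels +8.014199 Da (K) / +10.008269 Da (R), the standard
SILAC-style C-terminal chemistry for synthetic standards. The heavy
label therefore appears in precursor and y-ion masses but never in
b ions. Neutral-loss (−98) fragment variants exist only for fragments
containing at least one phosphosite and are generated as selectable
candidates, not force-included.

Candidate ions are all theoretical y/b fragments of index ≥2. Without a
spectral library the ranking is: y before b, longer ions first, no-loss
before loss, 1+ before 2+ — y ions dominate tryptic CID spectra. When
library intensities are supplied they take precedence. Survey mode keeps
the top 3 per precursor; quantification mode keeps up to 7 and
force-includes site-determining ions (fragments covering a proper,
non-empty subset of the candidate S/T/Y positions), evicting the
worst-ranked non-discriminating picks when the budget is full. Precursor
charge is 2+ always, plus 3+ for backbones ≥15 residues or with an
internal H/K/R. Collision energy is the charge-branched linear form
(2+: 0.03·m/z + 2.905; ≥3+: 0.038·m/z + 2.281) with an optional
constant offset for empirical per-transition stepping.

## Scheduling

Expected retention times may be given directly in minutes or mapped
from a reference (iRT) scale through a least-squares line fitted to
paired standards. Mode presets: survey 4 min windows / 4 s cycles;
quantification 6–10 min windows / 2.5–3 s cycles (defaults 6 min,
2.75 s). Concurrency is computed by an exact event sweep over window
boundaries (equivalent to evaluating a fine RT grid in the limit);
windows are treated as closed, so windows that merely touch count as
concurrent — the conservative choice for dwell. The worst-point dwell is
`cycle_time / max_concurrent`; a method is feasible when it stays at or
above the dwell floor (default 10 ms). Infeasibility is a reported
state, not an exception, so methods can be split or re-windowed.

## Peak integration and acceptance

The apex is the maximum of the summed transition trace inside the
scheduling window. Apex and boundary search run on a Savitzky-Golay
smoothed copy (window 11 points, order 2) of the summed trace; areas are
always integrated on the raw traces. Boundaries are the nearest flanking
local minima, or the first points below 0.5% of the apex, whichever
comes first; a local minimum only counts once the trace has dropped
below half the apex, so noise wiggles on the peak top cannot truncate
integration. The 0.5% floor keeps the systematic clip of a clean
Gaussian peak (tail loss plus boundary-mean baseline subtraction) under
2%. Each transition's area is the trapezoidal integral between the
boundaries minus its boundary-mean baseline, clipped at zero, reported
in counts·s. The noise area is the median absolute summed intensity
outside the boundaries times the window width.

A light/heavy pair is **accepted** when rdotp (normalized dot product of
matched transition areas; a zero vector gives 0 by definition) exceeds
0.9, the apexes co-elute within 0.2 min, and the light summed area
exceeds the noise area. The RT tolerance stands in for what an analyst
would judge visually; 0.2 min is well inside one scheduling window and
several peak widths. A failing pair is **rejected** — unless the
replicate context shows the peptide confidently accepted in another
condition, in which case it is an **on/off** observation and the noise
area becomes a censored readout (so a clean biological absence is not
discarded as a bad signal). Ratios are light/heavy for accepted
peptides, noise/heavy (flagged censored) for on/off, missing for
rejected.

## Calibration (LOD/LOQ)

The dilution-series model is `response = b·amount + a`. The sensitivity
`b` comes from an ordinary least-squares fit to all replicates combined;
a separate line is fitted per replicate and `S_a` is the standard
deviation across the per-replicate intercepts. With triplicates, the
plain sample SD underestimates the true intercept spread by the
well-known c₄(3) ≈ 0.886 factor, so `S_a` is bias-corrected by default
(`bias_correct=True`), making the LOD estimator mean-unbiased; the
alternative reading of `S_a` as the combined-fit intercept standard
error is available as `sa_method="stderr"`. Then LOD = 3·S_a/b and
LOQ = 10·S_a/b, so LOQ/LOD = 10/3 identically. Spike amounts below the
current LOD are excluded iteratively — all but the highest such level —
and the fit repeated until the excluded set stabilizes (bounded by the
number of levels); this prevents noise-floor points from flattening the
line. Non-positive slopes flag the fit invalid rather than producing
negative limits. Default levels mirror a seven-point series from 10 amol
to 100 fmol in triplicate.

## Differential testing

Analyte/standard ratios are divided by the mean ratio of the reference
(control) condition per peptide (idempotent; peptides with no reference
values are flagged, not normalized), log₂-transformed, and technical
replicates are averaged within each biological replicate. Each peptide
is then tested with a fixed-effects condition comparison on the
biological-replicate means — for two conditions an equal-variance
two-sample t-test, which is what a linear mixed-effects analysis reduces
to for a balanced design once technical replicates are collapsed. This
keeps the test deterministic and dependency-light. Significance uses
p ≤ 0.05 by default; Benjamini-Hochberg adjustment is computed on
request but reported alongside rather than replacing the raw cutoff.
Conditions with fewer than two biological replicates get a fold change
but no p-value (with a warning). Degenerate zero-variance comparisons
return p = 1 when the means agree and p = 0 otherwise.

## Synthetic data: what it emulates, and what not

The kinome generator embeds one DFG…APE segment per protein (length
300–600 residues, gap 15–40) whose 1–3 S/T/Y sites sit inside a single
tryptic peptide with enforced K/R termini; filler alphabets exclude
K/R/P (no stray cut points) and S/T/Y (no stray sites) inside the
segment, and flanks are redrawn if a spurious motif pair would shadow
the true segment. Shared groups reuse one tryptic core across several
kinases, creating exactly the ambiguity classes the grouping module
must resolve. Chromatograms are Gaussian peaks (width 3–8 s) on a shared
grid with a per-peptide transition pattern common to light and heavy
channels, light amplitude = heavy × true ratio, and additive Gaussian
baseline noise (default SD 2% of the tallest transition apex — a
moderate-noise regime); interference is simulated by re-drawing the
light pattern, absence by zeroing it. Dilution series follow the
calibration model with per-replicate intercept draws.

None of this reproduces real LC-MS behavior — tailing peaks, correlated
noise, matrix interferences, retention-time drift, ionization
suppression, or missing transitions. Passing the closed-loop tests shows
the estimators are correct under their stated model, not that real
chromatograms will be this clean; the acceptance thresholds (rdotp,
co-elution, noise floor) exist precisely because real data are not.

## Problem sizes

The shipped acceptance run uses a 12-kinase synthetic kinome (one trio
and one pair sharing segments), 500 simulated dilution series for
slope/LOD recovery, 1000 null and 200 two-fold simulations for the
error rates, 1000 random cases for each mass/digestion oracle sweep,
and an 8-peptide closed-loop quantification — sizes at which every
Monte-Carlo summary is stable to well within the asserted tolerances
while the whole run completes in seconds.

## Known limitations

* Segment location is motif-based, not homology-model-based; kinases
  with non-canonical activation segments need external annotations.
* Only trypsin and LysC are implemented; no other proteases.
* Product ions are y/b (plus −98 variants); no a-ions or internal
  fragments.
* The grouping module treats each peptide's exact kinase set as the
  group identity; it does not compute parsimony-minimal protein lists.
* The differential model supports condition + biological/technical
  replicates only, not multi-factor designs or repeated-measures
  covariance structures.
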