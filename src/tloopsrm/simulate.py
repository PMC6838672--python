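"""Synthetic data with known ground truth for every pipeline stage.

Generates (1) synthetic kinomes whose activation segments, T-loop sites
and tryptic target peptides are known by construction, including shared
segments that force kinase-group ambiguity; (2) SRM chromatograms as
Gaussian peaks over baseline noise with known light/heavy ratios; and
(3) dilution series with known slope, intercept spread and noise. Every
generator is deterministic in its seed and emits a truth record from
which the expected output of each downstream module can be computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import AssayDefinition
from .calibration import DEFAULT_LEVELS, DilutionSeries
from .kinome import KinaseRecord, SegmentParams, locate_activation_segment

_FILLER = "ACEFGHILMNQVW"       # no K/R/P (cleavage), no S/T/Y (sites), no D
_CORE_ALPHABET = "ACEFGHILMNQVW"


class SimulationError(ValueError):
    pass


@dataclass
class KinomeSimParams:
    """Shape of the synthetic kinome.

    ``shared_groups`` lists sizes of kinase subsets that share one T-loop
    tryptic peptide (creating ambiguity classes); remaining kinases get
    unique segments. Defaults mirror typical kinase-domain geometry:
    proteins of 300-600 residues, 15-40 residues between DFG and APE,
    1-3 phosphorylatable sites inside one tryptic peptide.
    """

    length_range: tuple[int, int] = (300, 600)
    gap_range: tuple[int, int] = (15, 40)
    n_sites_range: tuple[int, int] = (1, 3)
    core_length_range: tuple[int, int] = (6, 12)
    shared_groups: tuple[int, ...] = ()


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    seed: int
    kinases: dict = field(default_factory=dict)
    ratios: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "kinases": self.kinases,
                       "ratios": self.ratios, "calibration": self.calibration},
                      fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], kinases=d.get("kinases", {}),
                   ratios=d.get("ratios", {}),
                   calibration=d.get("calibration", {}))


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n > 0 else ""


def _make_loop_insert(rng: np.random.Generator, params: KinomeSimParams
                      ) -> tuple[str, list[int]]:
    """A 'K' + core + 'R' insert; returns (insert, site offsets in core)."""
    lo, hi = params.core_length_range
    core_len = int(rng.integers(lo - 1, hi))         # target peptide = core+R
    n_sites = int(rng.integers(params.n_sites_range[0],
                               params.n_sites_range[1] + 1))
    n_sites = min(n_sites, core_len)
    core = list(_draw(rng, _CORE_ALPHABET, core_len))
    site_offsets = sorted(rng.choice(core_len, size=n_sites, replace=False))
    for off in site_offsets:
        core[off] = str(rng.choice(list("STY")))
    return "K" + "".join(core) + "R", [int(o) for o in site_offsets]


def generate_kinome(n_kinases: int, seed: int,
                    params: KinomeSimParams | None = None
                    ) -> tuple[list[KinaseRecord], SimulationTruth]:
    """Synthesize kinase sequences with embedded DFG...APE segments.

    Each protein carries exactly one activation segment whose S/T/Y sites
    sit inside one tryptic peptide; members of a shared group reuse the
    same tryptic target peptide so that downstream grouping must merge
    them. Every record is verified to locate at its truth span (flanks
    are redrawn when a spurious motif pair would shadow the real one).
    """
    if n_kinases < 1:
        raise SimulationError("n_kinases must be >= 1")
    params = params or KinomeSimParams()
    if sum(params.shared_groups) > n_kinases:
        raise SimulationError("shared groups exceed n_kinases")
    if any(g < 2 for g in params.shared_groups):
        raise SimulationError("shared group sizes must be >= 2")
    min_len, max_len = params.length_range
    rng = np.random.default_rng(seed)

    # Assign each kinase a loop insert; shared groups reuse one insert.
    inserts: list[tuple[str, list[int], int | None]] = []
    group_no = 0
    for size in params.shared_groups:
        ins, offs = _make_loop_insert(rng, params)
        inserts.extend((ins, offs, group_no) for _ in range(size))
        group_no += 1
    while len(inserts) < n_kinases:
        ins, offs = _make_loop_insert(rng, params)
        inserts.append((ins, offs, None))

    truth = SimulationTruth(seed=seed)
    records: list[KinaseRecord] = []
    for i, (insert, offsets, group) in enumerate(inserts):
        kinase_id = f"KIN{i + 1:03d}"
        gene = f"GN{i + 1:03d}"
        gap_lo, gap_hi = params.gap_range
        if len(insert) > gap_hi:
            raise SimulationError(
                "contradictory params: loop insert longer than the maximum "
                "DFG-APE gap")
        if len("DFG" + insert + "APE") + 40 > min_len:
            raise SimulationError(
                "contradictory params: segment does not fit in the protein")
        gap = int(rng.integers(max(gap_lo, len(insert)), gap_hi + 1))
        pad = gap - len(insert)
        pre = _draw(rng, _FILLER, int(rng.integers(0, pad + 1)) if pad else 0)
        post = _draw(rng, _FILLER, pad - len(pre))
        segment = "DFG" + pre + insert + post + "APE"
        total = int(rng.integers(min_len, max_len + 1))
        flank_total = max(total - len(segment), 40)
        n_left = int(rng.integers(10, flank_total - 9))

        for _attempt in range(50):
            left = _draw(rng, "ACDEFGHIKLMNPQRSTVWY", n_left)
            right = _draw(rng, "ACDEFGHIKLMNPQRSTVWY", flank_total - n_left)
            seq = left + segment + right
            seg_start = len(left) + 1
            seg_end = len(left) + len(segment)
            rec = KinaseRecord(kinase_id, gene, seq)
            try:
                found = locate_activation_segment(rec, SegmentParams())
            except LookupError:
                continue
            if found == (seg_start, seg_end):
                break
        else:
            raise SimulationError(f"{kinase_id}: could not embed a unique "
                                  "activation segment")

        core_start = seg_start + 3 + len(pre) + 1   # first residue after the K
        sites = [core_start + off for off in offsets]
        target_peptide = insert[1:]                 # core + R
        truth.kinases[kinase_id] = {
            "gene": gene,
            "segment": [seg_start, seg_end],
            "sites": sites,
            "target_peptide": target_peptide,
            "local_sites": [off + 1 for off in offsets],
            "shared_group": group,
        }
        records.append(rec)
    return records, truth


def write_fasta(records: list[KinaseRecord], path) -> None:
    """Plain FASTA with ``>id gene`` headers, 60-column wrapped."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.kinase_id} {rec.gene}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


@dataclass
class ChromatogramSimParams:
    """Peak shape and noise of simulated SRM traces.

    Peaks are Gaussian with widths of 3-8 s; baseline noise is additive
    Gaussian with a standard deviation of ``noise_frac`` times the
    heaviest transition apex (clipped at zero).
    """

    rt_range_min: tuple[float, float] = (10.0, 100.0)
    sigma_range_s: tuple[float, float] = (3.0, 8.0)
    heavy_total: float = 1.0e5
    noise_frac: float = 0.02
    grid_halfwidth_min: float = 1.5
    grid_step_min: float = 0.005


def simulate_chromatograms(
    assays: list[AssayDefinition],
    ratios: dict[str, float],
    seed: int,
    params: ChromatogramSimParams | None = None,
    interference: set[str] | None = None,
    off_peptides: set[str] | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate light/heavy traces for each assay at known true ratios.

    ``ratios`` maps a peptide id (``assay.peptide_id``, or the plain
    backbone when unambiguous) -> true light/heavy ratio. Peptides in
    ``off_peptides`` get zero light amplitude (a clean absence); peptides
    in ``interference`` get an independently drawn light transition
    pattern, which should fail the rdotp acceptance check. Light and
    heavy channels of one peptide share RT, width and (unless interfered)
    transition pattern. Returns a tidy table with columns peptide,
    channel, ion, time, intensity plus the truth record; the peptide
    column carries the phospho-form id so that positional isomers of one
    backbone stay distinct.
    """
    params = params or ChromatogramSimParams()
    interference = interference or set()
    off_peptides = off_peptides or set()
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed)
    frames = []
    for assay in sorted(assays, key=lambda a: a.peptide_id):
        pep = assay.peptide_id
        backbone = assay.target.backbone
        if pep in ratios:
            ratio = float(ratios[pep])
        elif backbone in ratios:
            ratio = float(ratios[backbone])
        else:
            raise SimulationError(f"no true ratio supplied for {pep}")
        is_off = pep in off_peptides or backbone in off_peptides
        is_interfered = pep in interference or backbone in interference
        rt = (assay.expected_rt if assay.expected_rt is not None
              else float(rng.uniform(*params.rt_range_min)))
        sigma_min = float(rng.uniform(*params.sigma_range_s)) / 60.0
        ions = sorted({t.annotation for t in assay.transitions
                       if t.precursor_charge == 2})
        weights = rng.uniform(0.2, 1.0, size=len(ions))
        weights /= weights.sum()
        heavy_amps = dict(zip(ions, params.heavy_total * weights))
        if is_interfered:
            w2 = rng.uniform(0.2, 1.0, size=len(ions))
            # force a genuinely different pattern (reversed ranking)
            w2 = np.sort(w2)[np.argsort(np.argsort(-weights))]
            w2 /= w2.sum()
            light_amps = {ion: params.heavy_total * ratio * w
                          for ion, w in zip(ions, w2)}
        elif is_off:
            light_amps = {ion: 0.0 for ion in ions}
        else:
            light_amps = {ion: a * ratio for ion, a in heavy_amps.items()}

        grid = np.arange(rt - params.grid_halfwidth_min,
                         rt + params.grid_halfwidth_min + 1e-12,
                         params.grid_step_min)
        noise_sd = params.noise_frac * max(heavy_amps.values())
        for channel, amps in (("light", light_amps), ("heavy", heavy_amps)):
            for ion in ions:
                clean = amps[ion] * np.exp(-0.5 * ((grid - rt) / sigma_min) ** 2)
                noisy = np.clip(
                    clean + rng.normal(0.0, noise_sd, size=grid.size), 0.0, None)
                frames.append(pd.DataFrame({
                    "peptide": pep, "channel": channel, "ion": ion,
                    "time": grid, "intensity": noisy,
                }))
        truth.ratios[pep] = {
            "ratio": ratio, "rt": rt, "sigma_min": sigma_min,
            "off": is_off, "interference": is_interfered,
        }
    return pd.concat(frames, ignore_index=True), truth


def simulate_dilution_series(
    b_true: float,
    intercept_sd: float,
    noise_sd: float,
    seed: int,
    levels=DEFAULT_LEVELS,
    n_replicates: int = 3,
    noise_floor: float | None = None,
    peptide: str = "SYNTHETIC",
) -> tuple[DilutionSeries, SimulationTruth]:
    """Simulate a spike-in dilution series.

    ``response = b_true * amount + intercept_rep + eps`` with one
    intercept draw per replicate (Normal(0, intercept_sd)) and
    point-level noise Normal(0, noise_sd). When a ``noise_floor`` is
    given, responses below it are replaced by draws around the floor —
    the synthetic counterpart of reading a representative noise area for
    spike-ins below detection.
    """
    if b_true <= 0:
        raise SimulationError("b_true must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    intercepts = rng.normal(0.0, intercept_sd, size=n_replicates)
    for rep in range(1, n_replicates + 1):
        for amount in levels:
            resp = (b_true * amount + intercepts[rep - 1]
                    + rng.normal(0.0, noise_sd))
            if noise_floor is not None and resp < noise_floor:
                resp = abs(rng.normal(noise_floor, 0.2 * noise_floor))
            rows.append({"amount_fmol": float(amount), "replicate": rep,
                         "response": float(resp)})
    truth = SimulationTruth(seed=seed, calibration={
        "b_true": b_true, "intercept_sd": intercept_sd, "noise_sd": noise_sd,
        "levels": list(levels), "n_replicates": n_replicates,
        "intercepts": [float(x) for x in intercepts],
    })
    return DilutionSeries(peptide, pd.DataFrame(rows)), truth
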