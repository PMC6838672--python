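"""SRM assay construction: masses, transitions, collision energy, scheduling.

Builds light/heavy transition sets for phosphopeptide targets in two
acquisition modes:

* *survey* — broad screening, ~3 transitions per precursor, short
  scheduling windows and long cycle times;
* *quantification* — up to 7 transitions per precursor with
  site-determining ions force-included, longer windows, shorter cycles.

All masses are monoisotopic. Heavy standards carry a stable-isotope label
on the C-terminal K or R, so the label mass appears in the precursor and
in y ions only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import (AA_MONO, HEAVY_LABEL, NEUTRAL_LOSS_H3PO4, PHOSPHO,
                        PHOSPHO_RESIDUES, PROTON, WATER)
from .kinome import TargetPeptide

logger = logging.getLogger(__name__)


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide backbone with phospho positions, label channel and charge."""

    backbone: str
    phospho_positions: frozenset[int]
    label: str = "light"          # "light" | "heavy"
    charge: int = 2

    def __post_init__(self) -> None:
        if self.label not in ("light", "heavy"):
            raise AssayError(f"unknown label {self.label!r}")
        if self.charge < 1:
            raise AssayError("charge must be >= 1")
        for p in self.phospho_positions:
            if self.backbone[p - 1] not in PHOSPHO_RESIDUES:
                raise AssayError(f"phospho position {p} is not S/T/Y")
        if self.label == "heavy" and self.backbone[-1] not in HEAVY_LABEL:
            raise AssayError(
                "heavy label requires a C-terminal K or R "
                f"(peptide ends in {self.backbone[-1]})"
            )

    @property
    def label_mass(self) -> float:
        if self.label == "heavy":
            return HEAVY_LABEL[self.backbone[-1]]
        return 0.0


@dataclass(frozen=True)
class Transition:
    """One precursor -> product ion pair."""

    precursor_mz: float
    precursor_charge: int
    ion_type: str                 # "y" | "b"
    ion_index: int
    product_charge: int
    neutral_loss: bool
    product_mz: float
    collision_energy: float
    rank: int
    site_determining: bool
    label: str

    @property
    def annotation(self) -> str:
        """Skyline-style ion annotation, e.g. ``y7``, ``y7-98``, ``b4``."""
        loss = "-98" if self.neutral_loss else ""
        chg = f"({self.product_charge}+)" if self.product_charge > 1 else ""
        return f"{self.ion_type}{self.ion_index}{loss}{chg}"


@dataclass(frozen=True)
class AssayDefinition:
    """Light + heavy transition sets for one target, one acquisition mode."""

    target: TargetPeptide
    light: ModifiedPeptide
    heavy: ModifiedPeptide
    transitions: tuple[Transition, ...]
    mode: str                     # "survey" | "quantification"
    expected_rt: float | None = None   # minutes (or iRT before mapping)
    window: float | None = None        # minutes

    @property
    def precursor_charges(self) -> tuple[int, ...]:
        return tuple(sorted({t.precursor_charge for t in self.transitions}))

    @property
    def peptide_id(self) -> str:
        """Unique phospho-form identifier: the light modified sequence."""
        return _modified_sequence(self.light)

    def channel(self, label: str, precursor_charge: int) -> list[Transition]:
        return [t for t in self.transitions
                if t.label == label and t.precursor_charge == precursor_charge]


@dataclass(frozen=True)
class AssayParams:
    """Knobs of transition generation; defaults match the two mode presets."""

    survey_transitions: int = 3
    quant_transitions: int = 7
    min_ion_index: int = 2
    product_charge_2_min_length: int = 6   # fragments this long may be 2+
    allow_product_charge_2: bool = False
    precursor_charge_3_min_length: int = 15
    ce_offset: float = 0.0


def peptide_neutral_mass(peptide: ModifiedPeptide) -> float:
    """Monoisotopic neutral mass including phospho and label modifications."""
    try:
        residues = sum(AA_MONO[aa] for aa in peptide.backbone)
    except KeyError as err:
        raise AssayError(f"unknown residue {err.args[0]!r}") from err
    return (residues + WATER + PHOSPHO * len(peptide.phospho_positions)
            + peptide.label_mass)


def precursor_mz(peptide: ModifiedPeptide) -> float:
    """Precursor m/z: (neutral mass + z protons) / z."""
    z = peptide.charge
    return (peptide_neutral_mass(peptide) + z * PROTON) / z


def fragment_mz(peptide: ModifiedPeptide, ion_type: str, ion_index: int,
                product_charge: int = 1, neutral_loss: bool = False) -> float:
    """m/z of a y or b fragment ion, optionally minus phosphoric acid.

    y ions carry the C-terminal residues (and the heavy label); b ions the
    N-terminal residues. The neutral loss (-H3PO4) is only defined for
    fragments containing at least one phospho position.
    """
    n = len(peptide.backbone)
    if ion_type not in ("y", "b"):
        raise AssayError(f"unknown ion type {ion_type!r}")
    if not (1 <= ion_index <= n - 1):
        raise AssayError(f"ion index {ion_index} outside 1..{n - 1}")
    if ion_type == "y":
        span = range(n - ion_index + 1, n + 1)   # 1-based residue positions
        base = WATER + peptide.label_mass
    else:
        span = range(1, ion_index + 1)
        base = 0.0
    residues = sum(AA_MONO[peptide.backbone[p - 1]] for p in span)
    n_phospho = sum(1 for p in peptide.phospho_positions if p in span)
    mass = residues + base + PHOSPHO * n_phospho
    if neutral_loss:
        if n_phospho == 0:
            raise AssayError(
                f"{ion_type}{ion_index} carries no phosphate; "
                "neutral loss undefined"
            )
        mass -= NEUTRAL_LOSS_H3PO4
    return (mass + product_charge * PROTON) / product_charge


def collision_energy(precursor_mz_th: float, precursor_charge: int,
                     offset: float = 0.0) -> float:
    """Charge-dependent linear collision energy (V).

    Doubly charged precursors: CE = 0.03 m/z + 2.905; charge three and
    higher: CE = 0.038 m/z + 2.281. ``offset`` accommodates empirical
    per-transition stepping.
    """
    if precursor_charge < 2:
        raise AssayError("collision energy is defined for charge >= 2")
    if precursor_charge == 2:
        return 0.03 * precursor_mz_th + 2.905 + offset
    return 0.038 * precursor_mz_th + 2.281 + offset


def site_determining_ions(
    backbone: str, candidate_positions,
) -> list[tuple[str, int]]:
    """Fragment ions that discriminate phosphosite positional isomers.

    Returns the (ion_type, ion_index) pairs whose residue span contains a
    non-empty proper subset of the candidate S/T/Y positions — exactly the
    ions whose mass differs between isomers. Empty when there is a single
    candidate (nothing to discriminate).
    """
    candidates = frozenset(candidate_positions)
    if not candidates:
        raise AssayError("need at least one candidate position")
    for p in candidates:
        if backbone[p - 1] not in PHOSPHO_RESIDUES:
            raise AssayError(f"candidate position {p} is not S/T/Y")
    n = len(backbone)
    out: list[tuple[str, int]] = []
    for i in range(1, n):
        b_span = set(range(1, i + 1))
        inside = candidates & b_span
        if inside and inside != candidates:
            out.append(("b", i))
    for j in range(1, n):
        y_span = set(range(n - j + 1, n + 1))
        inside = candidates & y_span
        if inside and inside != candidates:
            out.append(("y", j))
    return out


def _choose_precursor_charges(backbone: str, params: AssayParams) -> list[int]:
    # 2+ always; 3+ when the peptide is long or carries an internal basic
    # residue (H/K/R anywhere but the C-terminus).
    charges = [2]
    if (len(backbone) >= params.precursor_charge_3_min_length
            or any(aa in "HKR" for aa in backbone[:-1])):
        charges.append(3)
    return charges


def _candidate_ions(peptide: ModifiedPeptide, params: AssayParams):
    """All theoretical y/b ions (plus neutral-loss variants) above the
    minimum index, as (ion_type, index, product_charge, neutral_loss)."""
    n = len(peptide.backbone)
    cands = []
    for ion_type in ("y", "b"):
        for idx in range(params.min_ion_index, n):
            charges = [1]
            if params.allow_product_charge_2 and idx >= params.product_charge_2_min_length:
                charges.append(2)
            for pc in charges:
                cands.append((ion_type, idx, pc, False))
                span = (range(n - idx + 1, n + 1) if ion_type == "y"
                        else range(1, idx + 1))
                if any(p in span for p in peptide.phospho_positions):
                    cands.append((ion_type, idx, pc, True))
    return cands


def _annotation(ion_type: str, idx: int, pc: int, loss: bool) -> str:
    loss_s = "-98" if loss else ""
    chg = f"({pc}+)" if pc > 1 else ""
    return f"{ion_type}{idx}{loss_s}{chg}"


def _default_rank_key(cand) -> tuple:
    ion_type, idx, pc, loss = cand
    # y before b, longer first, no-loss before loss, 1+ before 2+
    return (0 if ion_type == "y" else 1, -idx, int(loss), pc)


def build_assay(target: TargetPeptide, mode: str = "survey",
                library_ranks: dict[str, float] | None = None,
                params: AssayParams | None = None,
                expected_rt: float | None = None) -> AssayDefinition:
    """Build the light+heavy transition set for one target peptide.

    Candidate ions are all theoretical y/b fragments (with neutral-loss
    variants for phospho-bearing fragments), ranked by spectral-library
    intensity when ``library_ranks`` maps annotations (e.g. ``"y7"``,
    ``"y7-98"``) to relative intensities, otherwise by a default priority
    (y over b, longer ions first). Survey mode keeps the top 3 per
    precursor; quantification mode keeps up to 7 with all applicable
    site-determining ions force-included. Light and heavy channels share
    the ion annotation list.
    """
    if mode not in ("survey", "quantification"):
        raise AssayError(f"unknown mode {mode!r}")
    params = params or AssayParams()
    if not target.tryptic_cterm:
        raise AssayError(
            f"{target.backbone}: heavy C-terminal labeling requires K/R"
        )
    light = ModifiedPeptide(target.backbone, target.phospho_positions,
                            "light", 2)
    heavy = ModifiedPeptide(target.backbone, target.phospho_positions,
                            "heavy", 2)

    cands = _candidate_ions(light, params)
    if library_ranks:
        def sort_key(c):
            known = _annotation(*c) in library_ranks
            inten = library_ranks.get(_annotation(*c), 0.0)
            return (0 if known else 1, -inten) + _default_rank_key(c)
    else:
        sort_key = _default_rank_key
    cands.sort(key=sort_key)

    n_keep = (params.survey_transitions if mode == "survey"
              else params.quant_transitions)
    if len(cands) < params.survey_transitions:
        logger.warning("%s: only %d candidate ions", target.backbone, len(cands))

    selected = list(cands[:n_keep])
    site_det: set[tuple[str, int]] = set()
    stys = [i + 1 for i, aa in enumerate(target.backbone)
            if aa in PHOSPHO_RESIDUES]
    if mode == "quantification" and len(stys) > 1:
        site_det = set(site_determining_ions(target.backbone, stys))
        # force-include site-determining ions (plain 1+, no loss), best first
        forced = [c for c in cands
                  if (c[0], c[1]) in site_det and c[2] == 1 and not c[3]]
        for c in forced:
            if c in selected:
                continue
            # evict the worst non-site-determining pick to stay within budget
            evictable = [s for s in reversed(selected)
                         if (s[0], s[1]) not in site_det]
            if len(selected) < n_keep:
                selected.append(c)
            elif evictable:
                selected.remove(evictable[0])
                selected.append(c)
        selected.sort(key=sort_key)

    transitions: list[Transition] = []
    for z in _choose_precursor_charges(target.backbone, params):
        for pep in (replace(light, charge=z), replace(heavy, charge=z)):
            pre_mz = precursor_mz(pep)
            ce = collision_energy(pre_mz, z, params.ce_offset)
            for rank, (ion_type, idx, pc, loss) in enumerate(selected, start=1):
                transitions.append(Transition(
                    precursor_mz=pre_mz,
                    precursor_charge=z,
                    ion_type=ion_type,
                    ion_index=idx,
                    product_charge=pc,
                    neutral_loss=loss,
                    product_mz=fragment_mz(pep, ion_type, idx, pc, loss),
                    collision_energy=ce,
                    rank=rank,
                    site_determining=(ion_type, idx) in site_det,
                    label=pep.label,
                ))
    return AssayDefinition(
        target=target, light=light, heavy=heavy,
        transitions=tuple(transitions), mode=mode, expected_rt=expected_rt,
    )


@dataclass(frozen=True)
class RtCalibration:
    """Linear map from a reference retention-time scale (iRT) to minutes."""

    slope: float
    intercept: float
    residual_sd: float

    def predict(self, reference_value: float) -> float:
        return self.slope * reference_value + self.intercept


def calibrate_rt(observed_rts, reference_values) -> RtCalibration:
    """Least-squares line mapping reference (iRT) values to observed minutes."""
    obs = np.asarray(observed_rts, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if obs.shape != ref.shape or obs.size < 2:
        raise AssayError("need >= 2 paired retention-time standards")
    if np.ptp(ref) == 0:
        raise AssayError("degenerate standards: all reference values identical")
    slope, intercept = np.polyfit(ref, obs, 1)
    resid = obs - (slope * ref + intercept)
    dof = max(obs.size - 2, 1)
    return RtCalibration(float(slope), float(intercept),
                         float(np.sqrt(np.sum(resid ** 2) / dof)))


@dataclass(frozen=True)
class ModeParams:
    """Scheduling presets: window (min) and cycle time (s) per mode."""

    window: float
    cycle_time: float
    dwell_floor: float = 0.010    # seconds

    @classmethod
    def survey(cls) -> "ModeParams":
        return cls(window=4.0, cycle_time=4.0)

    @classmethod
    def quantification(cls, window: float = 6.0,
                       cycle_time: float = 2.75) -> "ModeParams":
        if not (6.0 <= window <= 10.0):
            raise AssayError("quantification window must be 6-10 min")
        if not (2.5 <= cycle_time <= 3.0):
            raise AssayError("quantification cycle time must be 2.5-3 s")
        return cls(window=window, cycle_time=cycle_time)


@dataclass(frozen=True)
class ScheduledMethod:
    """A scheduled acquisition method with its feasibility report."""

    assays: tuple[AssayDefinition, ...]
    cycle_time: float             # s
    dwell_floor: float            # s
    max_concurrent: int
    worst_rt: float               # min
    min_dwell: float              # s
    feasible: bool
    contributing: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.assays:
            rows.append({
                "backbone": a.target.backbone,
                "expected_rt": a.expected_rt,
                "window_start": a.expected_rt - a.window / 2,
                "window_end": a.expected_rt + a.window / 2,
                "n_transitions": len(a.transitions),
            })
        return pd.DataFrame(rows)


def schedule_method(assays: list[AssayDefinition],
                    rt_map: RtCalibration | None = None,
                    mode_params: ModeParams | None = None) -> ScheduledMethod:
    """Assign scheduling windows and check dwell-time feasibility.

    Each assay gets the window ``[rt - w/2, rt + w/2]`` around its expected
    RT (mapped from the reference scale through ``rt_map`` if given). The
    maximum number of concurrently scheduled transitions over all of
    elution is found by an exact event sweep over window boundaries; the
    worst-point dwell time is ``cycle_time / max_concurrent``.
    Infeasibility (dwell below the floor) is reported, never raised.
    """
    if not assays:
        raise AssayError("no assays to schedule")
    if mode_params is None:
        mode = assays[0].mode
        mode_params = (ModeParams.survey() if mode == "survey"
                       else ModeParams.quantification())
    w = mode_params.window
    placed: list[AssayDefinition] = []
    for a in assays:
        if a.expected_rt is None:
            raise AssayError(f"{a.target.backbone}: expected_rt missing")
        rt = rt_map.predict(a.expected_rt) if rt_map is not None else a.expected_rt
        placed.append(replace(a, expected_rt=rt, window=w))

    # Event sweep over closed intervals: at equal times, starts before ends,
    # so touching windows count as concurrent (conservative for dwell).
    events: list[tuple[float, int, int, int]] = []
    for i, a in enumerate(placed):
        n_tr = len(a.transitions)
        events.append((a.expected_rt - w / 2, 0, n_tr, i))
        events.append((a.expected_rt + w / 2, 1, -n_tr, i))
    events.sort(key=lambda e: (e[0], e[1]))

    active: set[int] = set()
    count = 0
    max_concurrent = 0
    worst_rt = placed[0].expected_rt
    contributing: tuple[int, ...] = ()
    for t, _kind, delta, idx in events:
        if delta > 0:
            active.add(idx)
        count += delta
        if count > max_concurrent:
            max_concurrent = count
            worst_rt = t
            contributing = tuple(sorted(active))
        if delta < 0:
            active.discard(idx)

    min_dwell = mode_params.cycle_time / max_concurrent
    return ScheduledMethod(
        assays=tuple(placed),
        cycle_time=mode_params.cycle_time,
        dwell_floor=mode_params.dwell_floor,
        max_concurrent=max_concurrent,
        worst_rt=float(worst_rt),
        min_dwell=float(min_dwell),
        feasible=min_dwell >= mode_params.dwell_floor,
        contributing=tuple(placed[i].target.backbone for i in contributing),
    )


def _modified_sequence(pep: ModifiedPeptide) -> str:
    """Vendor-importable modified sequence, phospho as [+80], label as [+8]/[+10]."""
    out = []
    for i, aa in enumerate(pep.backbone, start=1):
        out.append(aa)
        if i in pep.phospho_positions:
            out.append("[+80]")
    if pep.label == "heavy":
        out.append("[+8]" if pep.backbone[-1] == "K" else "[+10]")
    return "".join(out)


def transitions_to_frame(assays: list[AssayDefinition]) -> pd.DataFrame:
    """Flat transition-list export (one row per transition)."""
    rows = []
    for a in assays:
        proteins = ";".join(sorted(a.target.kinase_ids))
        for t in a.transitions:
            pep = a.light if t.label == "light" else a.heavy
            rows.append({
                "proteins": proteins,
                "modified_sequence": _modified_sequence(pep),
                "label": t.label,
                "precursor_mz": round(t.precursor_mz, 4),
                "precursor_charge": t.precursor_charge,
                "product_mz": round(t.product_mz, 4),
                "product_charge": t.product_charge,
                "annotation": t.annotation,
                "collision_energy": round(t.collision_energy, 3),
                "expected_rt": a.expected_rt,
                "window": a.window,
            })
    return pd.DataFrame(rows, columns=[
        "proteins", "modified_sequence", "label", "precursor_mz",
        "precursor_charge", "product_mz", "product_charge", "annotation",
        "collision_energy", "expected_rt", "window"])
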