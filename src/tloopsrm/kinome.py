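"""Kinase activation-segment annotation, in-silico digestion and target design.

This module turns a kinome FASTA into the list of phosphopeptides that an
SRM assay can target: it locates the activation segment (T-loop) of each
kinase between the canonical DFG and APE motifs, enumerates the
phosphorylatable S/T/Y residues inside it, digests the protein in silico
with trypsin and/or LysC, and keeps the digest peptides that cover at
least one T-loop site and fall in a measurable length range.

Coordinates are 1-based and intervals are inclusive throughout; phospho
positions on a peptide are peptide-local and 1-based.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .constants import PHOSPHO_RESIDUES

logger = logging.getLogger(__name__)

_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class KinomeError(ValueError):
    """Raised for malformed kinome input (FASTA or annotation table)."""


class SegmentNotFoundError(LookupError):
    """No DFG...APE motif pair satisfying the length bounds was found."""


@dataclass(frozen=True)
class KinaseRecord:
    """One kinase: accession, gene symbol, sequence and optional annotations.

    ``domain_span`` and ``segment_span`` are 1-based inclusive residue
    intervals; ``segment_span`` is the activation segment (T-loop).
    """

    kinase_id: str
    gene: str
    sequence: str
    domain_span: tuple[int, int] | None = None
    segment_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise KinomeError(f"{self.kinase_id}: empty sequence")
        bad = set(self.sequence) - _VALID_AA
        if bad:
            raise KinomeError(
                f"{self.kinase_id}: non-amino-acid characters {sorted(bad)!r}"
            )
        for name, span in (("domain_span", self.domain_span),
                           ("segment_span", self.segment_span)):
            if span is not None:
                s, e = span
                if not (1 <= s <= e <= len(self.sequence)):
                    raise KinomeError(
                        f"{self.kinase_id}: {name} {span} outside sequence "
                        f"of length {len(self.sequence)}"
                    )
        if (self.segment_span is not None and self.domain_span is not None
                and not (self.domain_span[0] <= self.segment_span[0]
                         and self.segment_span[1] <= self.domain_span[1])):
            raise KinomeError(
                f"{self.kinase_id}: segment_span {self.segment_span} outside "
                f"domain_span {self.domain_span}"
            )


@dataclass(frozen=True)
class TLoopSite:
    """A phosphorylatable residue inside a kinase activation segment."""

    kinase_id: str
    position: int  # 1-based in the protein
    residue: str   # S, T or Y


@dataclass(frozen=True)
class DigestPeptide:
    """A proteolytic peptide with its parent-protein start and missed cleavages."""

    sequence: str
    start: int  # 1-based position of the first residue in the parent
    missed_cleavages: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


@dataclass(frozen=True)
class TargetPeptide:
    """A candidate SRM target: one backbone with a specific phospho-position set.

    ``phospho_positions`` are peptide-local 1-based indices of S/T/Y.
    ``kinase_ids`` is the set of kinases whose digest yields this peptide
    covering a T-loop site; identical (backbone, positions) pairs from
    different kinases are merged. ``tryptic_cterm`` is False for peptides
    ending on a residue other than K/R (protein C-terminus); such peptides
    cannot take the heavy C-terminal label.
    """

    backbone: str
    phospho_positions: frozenset[int]
    kinase_ids: frozenset[str]
    site_labels: frozenset[str]
    missed_cleavages: int = 0
    tryptic_cterm: bool = True

    def __post_init__(self) -> None:
        if not self.phospho_positions:
            raise KinomeError("TargetPeptide needs at least one phospho position")
        for p in self.phospho_positions:
            if not (1 <= p <= len(self.backbone)):
                raise KinomeError(f"phospho position {p} outside peptide")
            if self.backbone[p - 1] not in PHOSPHO_RESIDUES:
                raise KinomeError(
                    f"position {p} of {self.backbone} is "
                    f"{self.backbone[p - 1]}, not S/T/Y"
                )
        if not self.kinase_ids:
            raise KinomeError("TargetPeptide needs at least one kinase")

    @property
    def multiplicity(self) -> int:
        return len(self.phospho_positions)

    @property
    def key(self) -> tuple[str, frozenset[int]]:
        """Identity of the target: backbone plus phospho-position set."""
        return (self.backbone, self.phospho_positions)


@dataclass(frozen=True)
class SegmentParams:
    """Motif patterns and length bounds for activation-segment location.

    The segment runs from the first residue of the DFG motif to the last
    residue of the APE motif, with the number of intervening residues
    between the two motifs inside ``[min_gap, max_gap]``. If the exact
    motifs yield no valid pair, the degenerate fallback patterns are tried.
    """

    dfg_pattern: str = "DFG"
    ape_pattern: str = "APE"
    fallback_dfg: str = "D[FWL]G"
    fallback_ape: str = "AP[ED]"
    min_gap: int = 15
    max_gap: int = 40


@dataclass(frozen=True)
class TargetParams:
    """Filters applied when designing the target-peptide list."""

    enzymes: frozenset[str] = frozenset({"trypsin"})
    max_missed: int = 2
    min_length: int = 6
    max_length: int = 30
    multiplicities: tuple[int, ...] = (1, 2)
    segment: SegmentParams = field(default_factory=SegmentParams)


def _parse_header(record) -> tuple[str, str]:
    """Extract (kinase_id, gene) from a FASTA record header.

    Supports UniProt-style ``sp|ACC|NAME ... GN=GENE`` headers and plain
    ``>ID GENE ...`` headers; the gene falls back to the id.
    """
    raw_id = record.id
    desc = record.description
    if "|" in raw_id:
        parts = raw_id.split("|")
        kinase_id = parts[1] if len(parts) > 1 and parts[1] else raw_id
    else:
        kinase_id = raw_id
    m = re.search(r"\bGN=(\S+)", desc)
    if m:
        gene = m.group(1)
    else:
        tokens = desc.split()
        gene = tokens[1] if len(tokens) > 1 else kinase_id
    return kinase_id, gene


def read_kinome(fasta_path, annotation_path=None) -> list[KinaseRecord]:
    """Read kinase sequences from FASTA, with optional span annotations.

    ``annotation_path`` is a tab-separated table with columns ``kinase_id``
    and any of ``domain_start``, ``domain_end``, ``segment_start``,
    ``segment_end``; annotated spans override motif-based location later.

    Raises :class:`KinomeError` naming the offending record for malformed
    entries or non-amino-acid characters. An empty file yields an empty
    list with a warning.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    annotations: dict[str, dict] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t")
        if "kinase_id" not in ann.columns:
            raise KinomeError("annotation table lacks a kinase_id column")
        for _, row in ann.iterrows():
            annotations[str(row["kinase_id"])] = row.to_dict()

    records: list[KinaseRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        kinase_id, gene = _parse_header(rec)
        seq = str(rec.seq).upper()
        ann = annotations.get(kinase_id, {})

        def _span(prefix: str) -> tuple[int, int] | None:
            s, e = ann.get(f"{prefix}_start"), ann.get(f"{prefix}_end")
            if s is None or e is None or pd.isna(s) or pd.isna(e):
                return None
            return (int(s), int(e))

        try:
            records.append(KinaseRecord(
                kinase_id=kinase_id, gene=gene, sequence=seq,
                domain_span=_span("domain"), segment_span=_span("segment"),
            ))
        except KinomeError as err:
            raise KinomeError(f"record {kinase_id!r}: {err}") from err
    if not records:
        logger.warning("no FASTA records found in %s", fasta_path)
    return records


def locate_activation_segment(
    record: KinaseRecord, params: SegmentParams | None = None
) -> tuple[int, int]:
    """Locate the activation segment as the first valid DFG...APE motif pair.

    Returns the 1-based inclusive interval from the D of the DFG motif to
    the E of the APE motif. An externally supplied ``record.segment_span``
    is returned unchanged. Scans DFG occurrences left to right and, for
    each, APE occurrences left to right; the first pair whose intervening
    length lies within the configured bounds wins. Falls back to the
    degenerate patterns if the exact motifs find nothing.

    Raises :class:`SegmentNotFoundError` when no pair qualifies.
    """
    if record.segment_span is not None:
        return record.segment_span
    params = params or SegmentParams()
    seq = record.sequence
    for dfg_pat, ape_pat in ((params.dfg_pattern, params.ape_pattern),
                             (params.fallback_dfg, params.fallback_ape)):
        for dfg in re.finditer(dfg_pat, seq):
            dfg_start = dfg.start() + 1            # 1-based first residue
            dfg_end = dfg.end()                    # 1-based last residue
            for ape in re.finditer(ape_pat, seq):
                ape_start = ape.start() + 1
                gap = ape_start - dfg_end - 1      # intervening residues
                if gap < params.min_gap:
                    continue
                if gap > params.max_gap:
                    break                          # APEs only get farther
                return (dfg_start, ape.end())
    raise SegmentNotFoundError(
        f"{record.kinase_id}: no DFG...APE pair with "
        f"{params.min_gap}-{params.max_gap} intervening residues"
    )


def enumerate_tloop_sites(
    record: KinaseRecord, segment: tuple[int, int]
) -> list[TLoopSite]:
    """Every S/T/Y residue inside the activation segment, in sequence order."""
    s, e = segment
    return [
        TLoopSite(record.kinase_id, pos, record.sequence[pos - 1])
        for pos in range(s, e + 1)
        if record.sequence[pos - 1] in PHOSPHO_RESIDUES
    ]


def cleavage_sites(sequence: str, enzymes) -> list[int]:
    """1-based positions after which the enzyme set cleaves.

    trypsin: after K or R unless the next residue is P.
    lysC:    after K regardless of the next residue.
    A combined digest uses the union of cut points.
    """
    enzymes = set(enzymes)
    unknown = enzymes - {"trypsin", "lysC"}
    if unknown:
        raise KinomeError(f"unknown enzyme(s): {sorted(unknown)}")
    if not enzymes:
        raise KinomeError("empty enzyme set")
    cuts: set[int] = set()
    n = len(sequence)
    for i, aa in enumerate(sequence[:-1], start=1):  # never cut after the end
        nxt = sequence[i]
        if "trypsin" in enzymes and aa in "KR" and nxt != "P":
            cuts.add(i)
        if "lysC" in enzymes and aa == "K":
            cuts.add(i)
    return sorted(c for c in cuts if c < n)


def digest(sequence: str, enzymes=frozenset({"trypsin"}),
           max_missed: int = 0) -> list[DigestPeptide]:
    """All proteolytic peptides with 0..max_missed internal missed cleavages.

    Output is ordered by start position, then by peptide length.
    """
    if not sequence:
        raise KinomeError("cannot digest an empty sequence")
    if max_missed < 0:
        raise KinomeError("max_missed must be >= 0")
    cuts = cleavage_sites(sequence, enzymes)
    # Boundaries delimit the 0-missed fragments: [b_i+1 .. b_{i+1}].
    bounds = [0, *cuts, len(sequence)]
    peptides: list[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i] + 1, bounds[j]
            peptides.append(DigestPeptide(
                sequence=sequence[start - 1:end],
                start=start,
                missed_cleavages=j - i - 1,
            ))
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def _site_label(gene: str, residue: str, position: int) -> str:
    return f"{gene}_{residue}{position}"


def design_targets(
    records: list[KinaseRecord], params: TargetParams | None = None
) -> tuple[list[TargetPeptide], pd.DataFrame]:
    """Design the SRM target-peptide list for a set of kinases.

    For each kinase the activation segment is taken from the record or
    located by motif; every S/T/Y inside it is a candidate T-loop site.
    Digest peptides containing at least one site and within the length
    bounds are kept ("accessible"); one target is emitted per distinct
    (backbone, phospho-position set), merging identical peptides across
    kinases. Doubly phosphorylated forms are emitted for every site pair
    on one backbone when multiplicity 2 is allowed.

    Returns ``(targets, skip_report)`` where the report lists kinases that
    contributed no target and why. Kinases are never a hard error here.
    """
    params = params or TargetParams()
    merged: dict[tuple[str, frozenset[int]], dict] = {}
    skipped: list[dict] = []

    for rec in records:
        try:
            segment = locate_activation_segment(rec, params.segment)
        except SegmentNotFoundError as err:
            logger.info("skipping %s: %s", rec.kinase_id, err)
            skipped.append({"kinase_id": rec.kinase_id, "gene": rec.gene,
                            "reason": "segment not found"})
            continue
        sites = enumerate_tloop_sites(rec, segment)
        if not sites:
            skipped.append({"kinase_id": rec.kinase_id, "gene": rec.gene,
                            "reason": "no S/T/Y in segment"})
            continue
        site_by_pos = {s.position: s for s in sites}
        contributed = False
        for pep in digest(rec.sequence, params.enzymes, params.max_missed):
            if not (params.min_length <= len(pep.sequence) <= params.max_length):
                continue
            covered = [p for p in site_by_pos if pep.start <= p <= pep.end]
            if not covered:
                continue
            contributed = True
            local = sorted(p - pep.start + 1 for p in covered)
            singles = [(p,) for p in local] if 1 in params.multiplicities else []
            doubles = ([(a, b) for i, a in enumerate(local) for b in local[i + 1:]]
                       if 2 in params.multiplicities else [])
            for combo in [*singles, *doubles]:
                key = (pep.sequence, frozenset(combo))
                labels = {
                    _site_label(rec.gene, rec.sequence[pp + pep.start - 2],
                                pp + pep.start - 1)
                    for pp in combo
                }
                entry = merged.setdefault(key, {
                    "kinase_ids": set(), "site_labels": set(),
                    "missed_cleavages": pep.missed_cleavages,
                    "tryptic_cterm": pep.sequence[-1] in "KR",
                })
                entry["kinase_ids"].add(rec.kinase_id)
                entry["site_labels"].update(labels)
                entry["missed_cleavages"] = min(entry["missed_cleavages"],
                                                pep.missed_cleavages)
        if not contributed:
            skipped.append({"kinase_id": rec.kinase_id, "gene": rec.gene,
                            "reason": "no accessible peptide"})

    targets = [
        TargetPeptide(
            backbone=backbone,
            phospho_positions=positions,
            kinase_ids=frozenset(entry["kinase_ids"]),
            site_labels=frozenset(entry["site_labels"]),
            missed_cleavages=entry["missed_cleavages"],
            tryptic_cterm=entry["tryptic_cterm"],
        )
        for (backbone, positions), entry in merged.items()
    ]
    targets.sort(key=lambda t: (t.backbone, sorted(t.phospho_positions)))
    report = pd.DataFrame(skipped, columns=["kinase_id", "gene", "reason"])
    return targets, report


def targets_to_frame(targets: list[TargetPeptide],
                     gene_by_kinase: dict[str, str] | None = None) -> pd.DataFrame:
    """Tabular form of a target list (the CSV export layout)."""
    rows = []
    for t in targets:
        genes = sorted({gene_by_kinase.get(k, k) for k in t.kinase_ids}
                       if gene_by_kinase else t.kinase_ids)
        rows.append({
            "kinase_ids": ";".join(sorted(t.kinase_ids)),
            "gene": ";".join(genes),
            "backbone": t.backbone,
            "phospho_positions": ";".join(map(str, sorted(t.phospho_positions))),
            "multiplicity": t.multiplicity,
            "site_labels": ";".join(sorted(t.site_labels)),
            "missed_cleavages": t.missed_cleavages,
            "tryptic_cterm": t.tryptic_cterm,
        })
    return pd.DataFrame(rows, columns=[
        "kinase_ids", "gene", "backbone", "phospho_positions", "multiplicity",
        "site_labels", "missed_cleavages", "tryptic_cterm"])


def targets_from_frame(df: pd.DataFrame) -> list[TargetPeptide]:
    """Inverse of :func:`targets_to_frame`."""
    targets = []
    for _, row in df.iterrows():
        targets.append(TargetPeptide(
            backbone=row["backbone"],
            phospho_positions=frozenset(
                int(p) for p in str(row["phospho_positions"]).split(";")),
            kinase_ids=frozenset(str(row["kinase_ids"]).split(";")),
            site_labels=frozenset(str(row["site_labels"]).split(";")),
            missed_cleavages=int(row.get("missed_cleavages", 0)),
            tryptic_cterm=bool(row.get("tryptic_cterm", True)),
        ))
    return targets
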