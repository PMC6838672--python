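"""Kinase-group resolution for ambiguous T-loop peptides.

Because activation segments are highly conserved, a tryptic T-loop peptide
is not always unique to one kinase. Following the protein-grouping
principle, kinases that are indistinguishable by a detected peptide are
reported together as one *kinase group*; the group identity is the exact
kinase set of the peptide (its ambiguity class), and groups with identical
kinase sets merge, pooling their evidence peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .kinome import TargetPeptide

PeptideKey = tuple[str, frozenset[int]]


class GroupingError(ValueError):
    pass


@dataclass(frozen=True)
class KinaseGroup:
    """A set of kinases indistinguishable by the detected peptide evidence."""

    group_id: str
    kinase_ids: frozenset[str]
    evidence_peptides: frozenset[PeptideKey]

    @property
    def n_members(self) -> int:
        return len(self.kinase_ids)


@dataclass(frozen=True)
class GroupingResult:
    """Groups plus the summary counts attached to a detection set."""

    groups: tuple[KinaseGroup, ...]
    n_sites: int
    n_groups: int
    n_kinases: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "group_id": g.group_id,
                "members": ";".join(sorted(g.kinase_ids)),
                "n_members": g.n_members,
                "n_evidence_peptides": len(g.evidence_peptides),
            }
            for g in self.groups
        ], columns=["group_id", "members", "n_members", "n_evidence_peptides"])


class PeptideKinaseMap:
    """Inverse index of the target list: peptide key -> kinase set.

    Also carries the kinase-id -> gene-symbol lookup used to build
    deterministic group names.
    """

    def __init__(self, mapping: dict[PeptideKey, frozenset[str]],
                 genes: dict[str, str]):
        self.mapping = mapping
        self.genes = genes

    def __contains__(self, key: PeptideKey) -> bool:
        return key in self.mapping

    def __getitem__(self, key: PeptideKey) -> frozenset[str]:
        return self.mapping[key]

    def __len__(self) -> int:
        return len(self.mapping)

    def group_name(self, kinase_ids: frozenset[str]) -> str:
        """Canonical group id: gene symbols sorted lexicographically, '-'-joined."""
        return "-".join(sorted(self.genes.get(k, k) for k in kinase_ids))


def build_peptide_kinase_map(
    targets: list[TargetPeptide],
    gene_by_kinase: dict[str, str] | None = None,
) -> PeptideKinaseMap:
    """Build the peptide -> kinase-set index from a designed target list.

    Raises :class:`GroupingError` on an empty target list or on duplicate
    entries that assign the same peptide to the same kinase under disjoint
    site labels (a design inconsistency).
    """
    if not targets:
        raise GroupingError("empty target list")
    mapping: dict[PeptideKey, frozenset[str]] = {}
    labels_seen: dict[tuple[PeptideKey, str], frozenset[str]] = {}
    for t in targets:
        key = t.key
        for k in t.kinase_ids:
            prev = labels_seen.get((key, k))
            mine = frozenset(lbl for lbl in t.site_labels)
            if prev is not None and not (prev & mine):
                raise GroupingError(
                    f"conflicting duplicate entries for peptide {key[0]} "
                    f"and kinase {k}: disjoint site labels"
                )
            labels_seen[(key, k)] = mine
        mapping[key] = mapping.get(key, frozenset()) | t.kinase_ids
    genes = dict(gene_by_kinase or {})
    return PeptideKinaseMap(mapping, genes)


def resolve_groups(
    detected: list[PeptideKey] | list[TargetPeptide],
    mapping: PeptideKinaseMap,
) -> GroupingResult:
    """Collapse detected peptides into kinase groups.

    Each detected peptide contributes its kinase set (ambiguity class);
    detections with identical kinase sets merge into one group pooling
    evidence. ``n_sites`` counts distinct detected peptide keys,
    ``n_kinases`` the union of all group members. Groups are sorted by
    group_id, making the output independent of detection order.

    Raises :class:`GroupingError` listing any detected peptide missing
    from the mapping.
    """
    keys: list[PeptideKey] = [
        d.key if isinstance(d, TargetPeptide) else d for d in detected
    ]
    missing = sorted({k[0] for k in keys if k not in mapping})
    if missing:
        raise GroupingError(f"detected peptides absent from mapping: {missing}")

    by_set: dict[frozenset[str], set[PeptideKey]] = {}
    for key in keys:
        by_set.setdefault(mapping[key], set()).add(key)

    groups = tuple(sorted(
        (KinaseGroup(
            group_id=mapping.group_name(kset),
            kinase_ids=kset,
            evidence_peptides=frozenset(ev),
        ) for kset, ev in by_set.items()),
        key=lambda g: g.group_id,
    ))
    all_members = frozenset().union(*by_set) if by_set else frozenset()
    return GroupingResult(
        groups=groups,
        n_sites=len(set(keys)),
        n_groups=len(groups),
        n_kinases=len(all_members),
    )
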