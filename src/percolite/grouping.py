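"""Protein grouping by peptide-set relations.

Two proteins are merged into one inference unit when one's peptide set is
a superset of the other's (identical sets included).  Grouping over
*theoretical* peptide sets can be computed from the database alone,
before any spectra are observed; grouping over *observed* (inferred)
peptide sets reproduces the shared-peptide-retaining mode.  After
grouping, only peptides unique to a single group carry evidence for
protein inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set

from .digest import DigestParams, ProteinRecord, digest

__all__ = [
    "ProteinGroup",
    "PeptideGroupMap",
    "group_by_theoretical_peptides",
    "group_by_observed_peptides",
    "assign_unique_peptides",
    "write_groups_tsv",
]

GROUP_ID_SEP = ";"


@dataclass(frozen=True)
class ProteinGroup:
    """A merged set of proteins treated as one inference unit.

    ``group_id`` is the member accessions sorted bytewise and joined with
    semicolons, which makes grouping output deterministic.  A group whose
    peptide set is empty can never be identified and is flagged.
    """

    group_id: str
    members: FrozenSet[str]
    peptides: FrozenSet[str]
    is_decoy: bool = False
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a protein group must have at least one member")


def _make_group(members: Iterable[str], peptides: FrozenSet[str], is_decoy: bool) -> ProteinGroup:
    members = frozenset(members)
    return ProteinGroup(
        group_id=GROUP_ID_SEP.join(sorted(members)),
        members=members,
        peptides=peptides,
        is_decoy=is_decoy,
        flagged_empty=not peptides,
    )


def _merge_peptide_sets(
    pepsets: Mapping[str, FrozenSet[str]], is_decoy: bool
) -> List[ProteinGroup]:
    """Merge proteins whose peptide sets are identical or nested.

    A protein whose set is a strict subset of exactly one *maximal*
    superset is merged into it; a subset of two or more non-nested sets
    stays its own group (conservative ambiguity rule).  Proteins with an
    empty peptide set are kept as flagged singleton groups.
    """
    empty = [pid for pid in pepsets if not pepsets[pid]]
    # identical sets collapse first
    by_set: Dict[FrozenSet[str], List[str]] = {}
    for pid in sorted(pepsets):
        if pepsets[pid]:
            by_set.setdefault(pepsets[pid], []).append(pid)
    groups: List[Dict] = [
        {"members": set(ids), "peptides": s} for s, ids in sorted(by_set.items(), key=lambda kv: sorted(kv[1]))
    ]

    changed = True
    while changed:
        changed = False
        # index: peptide -> indices of live groups containing it
        index: Dict[str, List[int]] = {}
        alive = [i for i, g in enumerate(groups) if g is not None]
        for i in alive:
            for pep in groups[i]["peptides"]:
                index.setdefault(pep, []).append(i)
        # visit small sets first for determinism
        for i in sorted(alive, key=lambda k: (len(groups[k]["peptides"]), min(groups[k]["members"]))):
            g = groups[i]
            if g is None:
                continue
            probe = next(iter(g["peptides"]))
            supersets = [
                j
                for j in index[probe]
                if j != i
                and groups[j] is not None
                and g["peptides"] < groups[j]["peptides"]
            ]
            if not supersets:
                continue
            maximal = [
                j
                for j in supersets
                if not any(
                    groups[j]["peptides"] < groups[k]["peptides"]
                    for k in supersets
                    if k != j
                )
            ]
            if len(maximal) == 1:
                target = groups[maximal[0]]
                target["members"] |= g["members"]
                groups[i] = None
                changed = True

    out = [
        _make_group(g["members"], g["peptides"], is_decoy)
        for g in groups
        if g is not None
    ]
    out.extend(_make_group([pid], frozenset(), is_decoy) for pid in sorted(empty))
    out.sort(key=lambda g: g.group_id)
    return out


def group_by_theoretical_peptides(
    proteins: Sequence[ProteinRecord], params: DigestParams = DigestParams()
) -> List[ProteinGroup]:
    """Group proteins by their theoretical digest peptide sets.

    Targets and decoys are grouped independently, so a group never mixes
    the two.  Every input protein ends up in exactly one group.
    """
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("protein ids must be unique")
    out: List[ProteinGroup] = []
    for is_decoy in (False, True):
        pepsets = {
            p.id: frozenset(digest(p.sequence, params))
            for p in proteins
            if p.is_decoy == is_decoy
        }
        if pepsets:
            out.extend(_merge_peptide_sets(pepsets, is_decoy))
    return out


def group_by_observed_peptides(
    observed: Mapping[str, Set[str]], is_decoy: bool = False
) -> List[ProteinGroup]:
    """Group proteins by their observed (inferred) peptide sets.

    ``observed`` maps protein id to the set of its peptides passing the
    chosen peptide-level q-value threshold; proteins with no inferred
    peptides are omitted.  This mode retains shared peptides and exists
    to reproduce the poorly calibrated protein-level FDR behaviour.
    """
    pepsets = {pid: frozenset(peps) for pid, peps in observed.items() if peps}
    if not pepsets:
        return []
    return _merge_peptide_sets(pepsets, is_decoy)


@dataclass(frozen=True)
class PeptideGroupMap:
    """Map from peptide sequence to the set of groups containing it."""

    mapping: Dict[str, FrozenSet[str]]

    def groups_of(self, peptide: str) -> FrozenSet[str]:
        return self.mapping.get(peptide, frozenset())

    def is_unique(self, peptide: str) -> bool:
        return len(self.mapping.get(peptide, ())) == 1

    @property
    def unique(self) -> Dict[str, str]:
        """Peptides mapped to exactly one group, as ``{peptide: group_id}``."""
        return {
            pep: next(iter(gids))
            for pep, gids in self.mapping.items()
            if len(gids) == 1
        }


def assign_unique_peptides(groups: Sequence[ProteinGroup]) -> PeptideGroupMap:
    """Build the peptide -> group-id map over the given groups.

    Downstream inference keeps only peptides unique to one group; call
    this separately for target and decoy groups so uniqueness is judged
    within each label class.
    """
    mapping: Dict[str, Set[str]] = {}
    for g in groups:
        for pep in g.peptides:
            mapping.setdefault(pep, set()).add(g.group_id)
    return PeptideGroupMap({pep: frozenset(gids) for pep, gids in mapping.items()})


def write_groups_tsv(
    groups: Sequence[ProteinGroup], path: str | Path, unique_map: PeptideGroupMap | None = None
) -> None:
    """Write a grouping report: one row per group with peptide counts."""
    if unique_map is None:
        unique_map = assign_unique_peptides(groups)
    with open(path, "w") as fh:
        fh.write("group_id\tmembers\tn_theoretical_peptides\tn_group_unique_peptides\n")
        for g in sorted(groups, key=lambda g: g.group_id):
            n_unique = sum(1 for pep in g.peptides if unique_map.is_unique(pep))
            fh.write(
                f"{g.group_id}\t{GROUP_ID_SEP.join(sorted(g.members))}\t"
                f"{len(g.peptides)}\t{n_unique}\n"
            )
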