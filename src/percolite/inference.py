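"""Protein-group scoring, picked target-decoy competition and reporting.

Four scorers turn peptide-level evidence into one number per protein
group: the best peptide score, the two-peptide rule (best peptide score,
but groups lacking two distinct confident peptides are removed), the
product of peptide-level posterior error probabilities, and Fisher's
combination of peptide p-values.  Protein-level FDR then uses the picked
strategy: each target group competes against the decoy group built from
the reversed copies of its members, and only the better-scoring member
of each pair is retained before q-value estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .grouping import GROUP_ID_SEP, ProteinGroup
from .stats import ScoredEntity, fisher_combine, qvalues_from_target_decoy

__all__ = [
    "PeptideEvidence",
    "ProteinScore",
    "METHODS",
    "is_higher_better",
    "score_protein_groups",
    "pair_groups",
    "picked_competition",
    "protein_report",
]

METHODS = ("best_peptide", "two_peptide", "product_pep", "fisher")
_HIGHER_BETTER = {"best_peptide": True, "two_peptide": True, "product_pep": False, "fisher": False}


def is_higher_better(method: str) -> bool:
    if method not in _HIGHER_BETTER:
        raise ValueError(f"unknown protein inference method {method!r}")
    return _HIGHER_BETTER[method]


@dataclass(frozen=True)
class PeptideEvidence:
    """Best-PSM evidence for one distinct peptide sequence.

    One record per peptide per label; ``score`` is the best PSM score
    for that peptide, and the confidence fields come from peptide-level
    target-decoy estimation.
    """

    peptide: str
    score: float
    group_id: str
    label: str
    q_value: float = 1.0
    pep: float = 1.0
    p_value: Optional[float] = None


@dataclass(frozen=True)
class ProteinScore:
    """One protein group's score under one inference method."""

    group_id: str
    label: str
    method: str
    value: float

    @property
    def higher_better(self) -> bool:
        return is_higher_better(self.method)


def score_protein_groups(
    evidence: Sequence[PeptideEvidence],
    method: str,
    peptide_q_threshold: float = 0.01,
) -> List[ProteinScore]:
    """Aggregate peptide evidence into one score per (group, label).

    ``peptide_q_threshold`` is applied only where the method calls for
    it: the two-peptide rule counts distinct peptides at or below the
    threshold and removes groups with fewer than two ("one-hit
    wonders").  ``product_pep`` multiplies the PEPs of all the group's
    peptides; ``fisher`` combines their empirical p-values.  Groups with
    zero evidence simply do not appear.
    """
    higher = is_higher_better(method)  # validates the method name
    by_group: Dict[tuple, List[PeptideEvidence]] = {}
    for ev in evidence:
        by_group.setdefault((ev.group_id, ev.label), []).append(ev)
    out: List[ProteinScore] = []
    for (gid, label), evs in sorted(by_group.items()):
        if method in ("best_peptide", "two_peptide"):
            value = max(e.score for e in evs)
            if method == "two_peptide":
                n_confident = len({e.peptide for e in evs if e.q_value <= peptide_q_threshold})
                if n_confident < 2:
                    continue
        elif method == "product_pep":
            value = float(np.prod([e.pep for e in evs]))
        else:  # fisher
            ps = [e.p_value for e in evs]
            if any(p is None for p in ps):
                raise ValueError(f"group {gid!r}: Fisher's method requires peptide p-values")
            value = fisher_combine(ps)
        out.append(ProteinScore(group_id=gid, label=label, method=method, value=value))
    return out


def pair_groups(
    target_groups: Sequence[ProteinGroup],
    decoy_groups: Sequence[ProteinGroup],
    decoy_prefix: str = "decoy_",
) -> Dict[str, str]:
    """Match each target group to its mirrored decoy group.

    A target group pairs with the decoy group whose member set is
    exactly the prefixed (reversed) counterparts of the target members;
    anything else stays unpaired — reversal is a bijection on
    accessions, but group topology may differ between the two databases,
    and unpaired survival is the conservative fallback.
    """
    decoy_by_members: Dict[FrozenSet[str], str] = {
        g.members: g.group_id for g in decoy_groups
    }
    pairing: Dict[str, str] = {}
    for g in target_groups:
        mirrored = frozenset(decoy_prefix + m for m in g.members)
        if mirrored in decoy_by_members:
            pairing[g.group_id] = decoy_by_members[mirrored]
    return pairing


def picked_competition(
    target_scores: Sequence[ProteinScore],
    decoy_scores: Sequence[ProteinScore],
    pairing: Mapping[str, str],
) -> List[ProteinScore]:
    """Picked target-decoy competition at the protein-group level.

    For each matched pair only the better-scoring member survives
    (respecting the method's orientation); an exact tie removes both,
    which is unbiased under the null.  Unpaired entries survive
    unchanged.
    """
    overlap = set(pairing.keys()) & set(pairing.values())
    if overlap:
        raise ValueError(f"group ids appear on both sides of the pairing: {sorted(overlap)[:3]}")
    targets = {s.group_id: s for s in target_scores}
    decoys = {s.group_id: s for s in decoy_scores}
    if len(targets) != len(target_scores) or len(decoys) != len(decoy_scores):
        raise ValueError("duplicate group ids within one side of the competition")
    contested = {
        pairing[g] for g in pairing if g in targets and pairing[g] in decoys
    }
    survivors: List[ProteinScore] = []
    for gid, t in targets.items():
        d_gid = pairing.get(gid)
        d = decoys.get(d_gid) if d_gid is not None else None
        if d is None:
            survivors.append(t)
            continue
        if t.method != d.method:
            raise ValueError("paired scores computed with different methods")
        if t.value == d.value:
            continue  # exact tie: both members removed
        t_wins = (t.value > d.value) if t.higher_better else (t.value < d.value)
        survivors.append(t if t_wins else d)
    survivors.extend(d for gid, d in decoys.items() if gid not in contested)
    return survivors


def protein_report(picked: Sequence[ProteinScore]) -> pd.DataFrame:
    """Protein-level confidence table after the picked competition.

    Scores are orientation-normalized (lower-better methods are negated)
    before target-decoy q-value estimation; the reported ``score``
    column keeps the method's native value.
    """
    if not picked:
        return pd.DataFrame(columns=["group_id", "label", "method", "score", "q_value"])
    methods = {s.method for s in picked}
    if len(methods) > 1:
        raise ValueError("cannot mix methods in one protein report")
    method = next(iter(methods))
    sign = 1.0 if is_higher_better(method) else -1.0
    entities = [
        ScoredEntity(id=s.group_id, score=sign * s.value, label=s.label) for s in picked
    ]
    table = qvalues_from_target_decoy(entities)
    value_of = {s.group_id: s.value for s in picked}
    table = table.rename(columns={"id": "group_id"})
    table["method"] = method
    table["score"] = [value_of[g] for g in table["group_id"]]
    return table[["group_id", "label", "method", "score", "q_value"]]
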