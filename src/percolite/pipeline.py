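"""End-to-end rescoring pipeline: PSM -> peptide -> protein reports.

Glues the modules together the way the command-line ``rescore``
subcommand uses them: semi-supervised rescoring of the PSM table,
best-PSM collapse to distinct peptides per label, peptide-level
q-values/PEPs/p-values, and — when a protein database is supplied —
theoretical-peptide grouping, group-unique evidence, one of the four
inference scorers, the picked competition, and protein-level q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .digest import DigestParams, ProteinRecord
from .grouping import assign_unique_peptides, group_by_theoretical_peptides
from .inference import (
    PeptideEvidence,
    pair_groups,
    picked_competition,
    protein_report,
    score_protein_groups,
)
from .pin import PsmTable
from .rescore import TrainConfig, rescore
from .simulate import DECOY_PREFIX, reverse_proteins
from .stats import empirical_pvalues, pep_estimates, target_decoy_qvalues

__all__ = ["PipelineResult", "peptide_table", "protein_level", "run_pipeline"]


@dataclass
class PipelineResult:
    psms: pd.DataFrame
    peptides: pd.DataFrame
    proteins: Optional[pd.DataFrame]


def peptide_table(table: PsmTable, scores: np.ndarray) -> pd.DataFrame:
    """Best-PSM collapse to distinct (stripped) peptides per label,
    with peptide-level q-values, PEPs and empirical p-values."""
    df = pd.DataFrame(
        {
            "peptide": table.stripped_peptides,
            "is_target": table.is_target,
            "score": np.asarray(scores, dtype=float),
        }
    )
    idx = df.groupby(["peptide", "is_target"], sort=True)["score"].idxmax()
    out = df.loc[idx].reset_index(drop=True)
    s = out["score"].to_numpy()
    t = out["is_target"].to_numpy()
    out["q_value"] = target_decoy_qvalues(s, t)
    out["pep"] = pep_estimates(s, t)
    out["p_value"] = empirical_pvalues(s, s[~t])
    out["label"] = np.where(t, "target", "decoy")
    return out.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)


def protein_level(
    peptides: pd.DataFrame,
    target_proteins: Sequence[ProteinRecord],
    decoy_proteins: Optional[Sequence[ProteinRecord]] = None,
    method: str = "best_peptide",
    digest_params: DigestParams = DigestParams(),
    peptide_q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Protein grouping, scoring and picked protein-level q-values.

    Peptides not unique to one protein group (within their label class)
    are discarded, matching the grouping-before-observation strategy.
    The decoy database defaults to the reversed targets.
    """
    if decoy_proteins is None:
        decoy_proteins = reverse_proteins(target_proteins)
    t_groups = group_by_theoretical_peptides(target_proteins, digest_params)
    d_groups = group_by_theoretical_peptides(list(decoy_proteins), digest_params)
    unique = {
        "target": assign_unique_peptides(t_groups).unique,
        "decoy": assign_unique_peptides(d_groups).unique,
    }
    evidence: List[PeptideEvidence] = []
    for row in peptides.itertuples(index=False):
        gid = unique[row.label].get(row.peptide)
        if gid is None:
            continue
        evidence.append(
            PeptideEvidence(
                peptide=row.peptide,
                score=float(row.score),
                group_id=gid,
                label=row.label,
                q_value=float(row.q_value),
                pep=float(row.pep),
                p_value=float(row.p_value),
            )
        )
    t_scores = score_protein_groups(
        [e for e in evidence if e.label == "target"], method, peptide_q_threshold
    )
    d_scores = score_protein_groups(
        [e for e in evidence if e.label == "decoy"], method, peptide_q_threshold
    )
    pairing = pair_groups(t_groups, d_groups, DECOY_PREFIX)
    picked = picked_competition(t_scores, d_scores, pairing)
    report = protein_report(picked)

    n_peps: Dict[str, int] = {}
    best_pep: Dict[str, str] = {}
    best_score: Dict[str, float] = {}
    for e in evidence:
        n_peps[e.group_id] = n_peps.get(e.group_id, 0) + 1
        if e.group_id not in best_score or e.score > best_score[e.group_id]:
            best_score[e.group_id] = e.score
            best_pep[e.group_id] = e.peptide
    report["n_peptides"] = [n_peps.get(g, 0) for g in report["group_id"]]
    report["best_peptide"] = [best_pep.get(g, "") for g in report["group_id"]]
    return report


def run_pipeline(
    table: PsmTable,
    train_config: TrainConfig = TrainConfig(),
    target_proteins: Optional[Sequence[ProteinRecord]] = None,
    method: str = "best_peptide",
    digest_params: DigestParams = DigestParams(),
    peptide_q_threshold: float = 0.01,
) -> PipelineResult:
    """Rescore a PSM table and derive peptide- and protein-level reports."""
    scores, _model = rescore(table, train_config)
    t = table.is_target
    psms = pd.DataFrame(
        {
            "spec_id": table.spec_ids,
            "scan": table.scans,
            "label": np.where(t, "target", "decoy"),
            "peptide": table.stripped_peptides,
            "score": scores,
            "q_value": target_decoy_qvalues(scores, t),
            "pep": pep_estimates(scores, t),
        }
    ).sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    peptides = peptide_table(table, scores)
    proteins = None
    if target_proteins is not None:
        proteins = protein_level(
            peptides,
            target_proteins,
            method=method,
            digest_params=digest_params,
            peptide_q_threshold=peptide_q_threshold,
        )
    return PipelineResult(psms=psms, peptides=peptides, proteins=proteins)
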