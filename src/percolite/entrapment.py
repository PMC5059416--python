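"""Sample/entrapment databases and FDR calibration assessment.

An entrapment database is built by shuffling the tryptic peptides of a
*sample* database: matches to the sample are assumed correct, matches to
the entrapment part are known false positives, so the fraction of
entrapment entities among accepted targets ("entrapment FDR") audits the
decoy-based q-values from the outside.  A configurable fraction of
sample peptides is kept unshuffled to emulate shared peptides between
related proteins.

With an entrapment part ``m`` times the sample size, an incorrect target
match lands in the sample with probability ``1/(m+1)``, so the
entrapment FDR undercounts true false positives by a relative ``1/m``
at the PSM level (about 11% for the default ``m = 9``); at the protein
level correct sample proteins conceal most of these strays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .digest import DigestParams, ProteinRecord, base_fragments, digest
from .grouping import (
    assign_unique_peptides,
    group_by_observed_peptides,
    group_by_theoretical_peptides,
)
from .inference import (
    PeptideEvidence,
    pair_groups,
    picked_competition,
    protein_report,
    score_protein_groups,
)
from .pin import tdc_winner
from .rescore import choose_initial_direction
from .simulate import (
    DECOY_PREFIX,
    SimConfig,
    reverse_proteins,
    simulate_proteome,
    simulate_psms,
)
from .stats import empirical_pvalues, pep_estimates, target_decoy_qvalues

__all__ = [
    "EntrapmentConfig",
    "BenchmarkDatabase",
    "CalibrationCurve",
    "build_entrapment_database",
    "expected_psm_undercount",
    "entrapment_fdr",
    "calibration_curve",
    "run_calibration",
    "CalibrationResult",
]


@dataclass(frozen=True)
class EntrapmentConfig:
    """Benchmark construction parameters.

    Defaults follow the calibration setup this package emulates: an
    entrapment part nine times the sample size, 4% of sample peptides
    kept unshuffled as shared peptides, and a full tryptic digest with
    proline suppression, no missed cleavages, peptide length 7-50.
    """

    multiplier: int = 9
    shared_rate: float = 0.04
    digest: DigestParams = field(default_factory=DigestParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if not 0.0 <= self.shared_rate < 1.0:
            raise ValueError("shared_rate must be in [0, 1)")


@dataclass
class BenchmarkDatabase:
    sample: List[ProteinRecord]
    entrapment: List[ProteinRecord]
    shared_peptides: Set[str]
    n_shuffle_failures: int = 0

    @property
    def targets(self) -> List[ProteinRecord]:
        return list(self.sample) + list(self.entrapment)


def expected_psm_undercount(multiplier: int) -> float:
    """Expected relative undercount of false positives at the PSM level.

    Incorrect target matches split ``multiplier : 1`` between entrapment
    and sample, so the entrapment FDR misses a fraction
    ``(1/(m+1)) / (m/(m+1)) = 1/m`` of the true false positives.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    return 1.0 / multiplier


def _shuffle_fragment(
    fragment: str, rng: np.random.Generator, forbidden: Set[str]
) -> Tuple[str, bool]:
    """Permute a fragment's residues, keeping the C-terminal one in place.

    Retries up to 10 times if the permutation reproduces the original
    sequence or collides with a sample peptide; after that the last
    attempt is accepted and flagged.  Fragments of length <= 2 (or with
    an interior of identical residues) cannot change and are returned
    as-is.
    """
    interior = fragment[:-1]
    if len(fragment) <= 2 or len(set(interior)) <= 1:
        return fragment, False
    letters = list(interior)
    candidate = fragment
    for _ in range(10):
        perm = rng.permutation(len(letters))
        candidate = "".join(letters[i] for i in perm) + fragment[-1]
        if candidate != fragment and candidate not in forbidden:
            return candidate, False
    return candidate, True


def build_entrapment_database(
    sample: Sequence[ProteinRecord], config: EntrapmentConfig = EntrapmentConfig()
) -> BenchmarkDatabase:
    """Construct the entrapment part by per-peptide shuffling.

    ``floor(shared_rate * n_distinct_sample_peptides)`` peptides are
    drawn once, globally, as the shared set and kept verbatim in every
    entrapment copy.  Each of the ``multiplier`` copies of each sample
    protein is rebuilt from its tryptic fragments: shared fragments stay,
    all others are shuffled with their C-terminal residue fixed (so the
    tryptic boundary structure, and hence the digestion statistics, are
    preserved).  Shuffles may still move a proline next to a cleavage
    site; such cases are accepted, not repaired.
    """
    if not sample:
        raise ValueError("sample database is empty")
    rng = np.random.default_rng([config.seed, 7])
    sample_peptides = sorted(
        set().union(*(digest(p.sequence, config.digest) for p in sample))
    )
    n_shared = int(math.floor(config.shared_rate * len(sample_peptides)))
    shared_idx = rng.choice(len(sample_peptides), size=n_shared, replace=False)
    shared = {sample_peptides[i] for i in shared_idx}
    forbidden = set(sample_peptides)

    entrapment: List[ProteinRecord] = []
    failures = 0
    for copy in range(1, config.multiplier + 1):
        for prot in sample:
            pieces = []
            for frag in base_fragments(prot.sequence, config.digest):
                if frag in shared:
                    pieces.append(frag)
                else:
                    shuffled, failed = _shuffle_fragment(frag, rng, forbidden)
                    failures += int(failed)
                    pieces.append(shuffled)
            entrapment.append(
                ProteinRecord(id=f"{prot.id}_entrap{copy}", sequence="".join(pieces))
            )
    return BenchmarkDatabase(
        sample=list(sample),
        entrapment=entrapment,
        shared_peptides=shared,
        n_shuffle_failures=failures,
    )


def entrapment_fdr(is_entrapment_sorted: np.ndarray) -> np.ndarray:
    """Cumulative entrapment fraction along a score-ranked target list.

    Input is the entrapment indicator of accepted targets ordered from
    best to worst score; entry ``k`` is the entrapment FDR when the top
    ``k + 1`` targets are accepted.
    """
    is_entrapment_sorted = np.asarray(is_entrapment_sorted, dtype=bool)
    if is_entrapment_sorted.size == 0:
        raise ValueError("empty accepted list: entrapment FDR is undefined")
    cum = np.cumsum(is_entrapment_sorted)
    return cum / np.arange(1, is_entrapment_sorted.size + 1)


@dataclass
class CalibrationCurve:
    """Paired (decoy FDR, entrapment FDR) points over descending scores."""

    decoy_fdr: np.ndarray
    entrapment_fdr: np.ndarray
    n_accepted: np.ndarray

    def entrapment_at(self, q_threshold: float) -> float:
        """Entrapment FDR of the largest accepted set with decoy q <= threshold."""
        ok = np.flatnonzero(self.decoy_fdr <= q_threshold)
        if ok.size == 0:
            return 0.0
        return float(self.entrapment_fdr[ok[-1]])

    def max_deviation(self, lo: float, hi: float) -> float:
        """Maximal multiplicative deviation from the identity line on [lo, hi].

        Returns ``max(decoy/entrapment, entrapment/decoy)`` over points
        whose decoy FDR lies in the interval; NaN if no point does or a
        coordinate is zero there.
        """
        mask = (self.decoy_fdr >= lo) & (self.decoy_fdr <= hi)
        if not mask.any():
            return float("nan")
        d = self.decoy_fdr[mask]
        e = self.entrapment_fdr[mask]
        if np.any(e == 0) or np.any(d == 0):
            return float("nan")
        ratio = np.maximum(d / e, e / d)
        return float(ratio.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "decoy_fdr": self.decoy_fdr,
                "entrapment_fdr": self.entrapment_fdr,
                "n_accepted": self.n_accepted,
            }
        )


def calibration_curve(
    q_values: np.ndarray, is_entrapment: np.ndarray
) -> CalibrationCurve:
    """Build the calibration curve from a ranked target list.

    ``q_values`` and ``is_entrapment`` are aligned and ordered by
    descending score (q non-decreasing).  One point is emitted per
    distinct q-value, at the last (largest) accepted set attaining it.
    """
    q_values = np.asarray(q_values, dtype=float)
    is_entrapment = np.asarray(is_entrapment, dtype=bool)
    if q_values.size == 0:
        return CalibrationCurve(np.array([]), np.array([]), np.array([], dtype=int))
    efdr = entrapment_fdr(is_entrapment)
    # last index of each distinct q value
    last = np.flatnonzero(np.diff(q_values) != 0)
    idx = np.append(last, q_values.size - 1)
    return CalibrationCurve(
        decoy_fdr=q_values[idx],
        entrapment_fdr=efdr[idx],
        n_accepted=idx + 1,
    )


@dataclass
class CalibrationResult:
    curve: CalibrationCurve
    report: pd.DataFrame  # picked protein report (targets and decoys)
    database: BenchmarkDatabase
    n_sample_accepted_1pct: int
    n_entrapment_accepted_1pct: int


def _peptide_level(table, scores):
    """Collapse PSMs to best-scoring distinct peptide per label."""
    df = pd.DataFrame(
        {
            "peptide": table.stripped_peptides,
            "is_target": table.is_target,
            "score": scores,
        }
    )
    idx = df.groupby(["peptide", "is_target"], sort=True)["score"].idxmax()
    return df.loc[idx].reset_index(drop=True)


def run_calibration(
    n_sample_proteins: int = 1000,
    n_spectra: int = 50_000,
    seed: int = 1,
    shared_peptide_mode: bool = False,
    method: str = "best_peptide",
    peptide_q_threshold: float = 0.01,
    entrap_config: Optional[EntrapmentConfig] = None,
    sim_config: Optional[SimConfig] = None,
) -> CalibrationResult:
    """End-to-end calibration experiment on a synthetic benchmark.

    Builds sample + entrapment + reversed-decoy databases, simulates
    PSMs whose correct matches come from the sample part only, collapses
    to peptide level, groups proteins (by theoretical peptide sets with
    group-unique evidence, or — in ``shared_peptide_mode`` — by observed
    peptide sets with shared peptides retained), scores groups, applies
    the picked competition, and compares decoy q-values with the
    entrapment FDR.
    """
    seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(3) >> 1]
    if entrap_config is None:
        entrap_config = EntrapmentConfig(seed=seeds[1])
    base_sim = sim_config or SimConfig()
    proteome_cfg = SimConfig(
        n_proteins=n_sample_proteins,
        protein_length=base_sim.protein_length,
        n_spectra=n_spectra,
        prop_correct=base_sim.prop_correct,
        n_features=base_sim.n_features,
        effect_size=base_sim.effect_size,
        feature_correlation=base_sim.feature_correlation,
        present_fraction=1.0,
        seed=seeds[0],
        digest=entrap_config.digest,
    )
    sample = simulate_proteome(proteome_cfg)
    db = build_entrapment_database(sample, entrap_config)
    targets = db.targets
    sample_ids = {p.id for p in db.sample}

    psm_cfg = SimConfig(
        n_proteins=proteome_cfg.n_proteins,
        protein_length=proteome_cfg.protein_length,
        n_spectra=n_spectra,
        prop_correct=proteome_cfg.prop_correct,
        n_features=proteome_cfg.n_features,
        effect_size=proteome_cfg.effect_size,
        feature_correlation=proteome_cfg.feature_correlation,
        present_fraction=1.0,
        seed=seeds[2],
        digest=entrap_config.digest,
    )
    table, _ = simulate_psms(targets, psm_cfg, present_ids=sorted(sample_ids))

    # single-feature score chosen by the semi-supervised initializer
    j, sign = choose_initial_direction(table.features, table.is_target)
    psm_scores = sign * table.features[:, j]

    # winner-take-all competition per spectrum keeps decoy counts in line
    # with incorrect-target counts
    table = tdc_winner(table, psm_scores)
    psm_scores = sign * table.features[:, j]

    peptides = _peptide_level(table, psm_scores)
    pep_seqs = peptides["peptide"].to_numpy()
    pep_scores = peptides["score"].to_numpy()
    pep_is_target = peptides["is_target"].to_numpy()
    pep_q = target_decoy_qvalues(pep_scores, pep_is_target)
    pep_pep = pep_estimates(pep_scores, pep_is_target)
    decoy_pep_scores = pep_scores[~pep_is_target]
    pep_p = empirical_pvalues(pep_scores, decoy_pep_scores)

    decoy_db = reverse_proteins(targets)
    evidence: List[PeptideEvidence] = []
    if not shared_peptide_mode:
        t_groups = group_by_theoretical_peptides(targets, entrap_config.digest)
        d_groups = group_by_theoretical_peptides(decoy_db, entrap_config.digest)
        unique_t = assign_unique_peptides(t_groups).unique
        unique_d = assign_unique_peptides(d_groups).unique
        for i in range(len(pep_seqs)):
            lookup = unique_t if pep_is_target[i] else unique_d
            gid = lookup.get(pep_seqs[i])
            if gid is None:
                continue  # shared or out-of-database peptide: discarded
            evidence.append(
                PeptideEvidence(
                    peptide=pep_seqs[i],
                    score=float(pep_scores[i]),
                    group_id=gid,
                    label="target" if pep_is_target[i] else "decoy",
                    q_value=float(pep_q[i]),
                    pep=float(pep_pep[i]),
                    p_value=float(pep_p[i]),
                )
            )
    else:
        # observed-peptide mode: shared peptides retained, grouping done on
        # the peptides passing the peptide-level q threshold
        by_label_rows = {True: [], False: []}
        for i in range(len(pep_seqs)):
            if pep_q[i] <= peptide_q_threshold:
                by_label_rows[bool(pep_is_target[i])].append(i)
        pep_info = {
            (pep_seqs[i], bool(pep_is_target[i])): i for i in range(len(pep_seqs))
        }
        groups_by_label = {}
        for is_t, rows in by_label_rows.items():
            proteins_db = targets if is_t else decoy_db
            observed_set = {pep_seqs[i] for i in rows}
            observed: Dict[str, Set[str]] = {}
            for p in proteins_db:
                obs = digest(p.sequence, entrap_config.digest) & observed_set
                if obs:
                    observed[p.id] = obs
            groups = group_by_observed_peptides(observed, is_decoy=not is_t)
            groups_by_label[is_t] = groups
            for g in groups:
                label = "target" if is_t else "decoy"
                for pep in g.peptides:
                    i = pep_info[(pep, is_t)]
                    evidence.append(
                        PeptideEvidence(
                            peptide=pep,
                            score=float(pep_scores[i]),
                            group_id=g.group_id,
                            label=label,
                            q_value=float(pep_q[i]),
                            pep=float(pep_pep[i]),
                            p_value=float(pep_p[i]),
                        )
                    )
        t_groups = groups_by_label.get(True, [])
        d_groups = groups_by_label.get(False, [])

    t_scores = score_protein_groups(
        [e for e in evidence if e.label == "target"], method, peptide_q_threshold
    )
    d_scores = score_protein_groups(
        [e for e in evidence if e.label == "decoy"], method, peptide_q_threshold
    )
    pairing = pair_groups(t_groups, d_groups, DECOY_PREFIX)
    picked = picked_competition(t_scores, d_scores, pairing)
    report = protein_report(picked)

    target_rows = report[report["label"] == "target"].reset_index(drop=True)
    is_entr = np.array(
        [
            all(m not in sample_ids for m in gid.split(";"))
            for gid in target_rows["group_id"]
        ],
        dtype=bool,
    )
    curve = calibration_curve(target_rows["q_value"].to_numpy(), is_entr)
    accepted = target_rows["q_value"].to_numpy() <= 0.01
    n_ent = int((is_entr & accepted).sum())
    n_smp = int((~is_entr & accepted).sum())
    return CalibrationResult(
        curve=curve,
        report=report,
        database=db,
        n_sample_accepted_1pct=n_smp,
        n_entrapment_accepted_1pct=n_ent,
    )
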