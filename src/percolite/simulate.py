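"""Seeded synthetic proteomes and PSM sets.

The generator stands in for large public datasets at desk scale.  It
emits random protein sequences whose lysine/arginine frequency gives a
mean tryptic fragment length near 10 residues, and PIN-format PSM sets
with one target and one decoy match per spectrum.  Correct target
matches draw their peptide from a "present" protein and their features
from a shifted multivariate normal; incorrect targets and all decoys
draw features from the same standard normal, so decoys and incorrect
targets are exchangeable by construction — the assumption every
decoy-based FDR guarantee tested downstream rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .digest import DigestParams, ProteinRecord, digest
from .pin import PsmTable

__all__ = [
    "SimConfig",
    "AMINO_ACIDS",
    "simulate_proteome",
    "reverse_proteins",
    "simulate_psms",
    "DECOY_PREFIX",
]

DECOY_PREFIX = "decoy_"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# K + R at 10% combined so the geometric cleavage spacing gives ~10-residue
# tryptic fragments; the other 18 residues share the rest uniformly.
_FREQS = np.array([0.05 if aa in "KR" else 0.9 / 18 for aa in AMINO_ACIDS])
_FREQS = _FREQS / _FREQS.sum()


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic world.

    ``effect_size`` is the per-feature mean shift (in units of the
    feature's standard deviation) of correct-target PSMs; one strongly
    informative feature plus weaker and pure-noise features mimics the
    typical search-engine feature block.  ``prop_correct`` is the
    fraction of spectra generated by a peptide of a present protein.
    """

    n_proteins: int = 1000
    protein_length: Tuple[int, int] = (150, 450)
    n_spectra: int = 50_000
    prop_correct: float = 0.5
    n_features: int = 5
    effect_size: Tuple[float, ...] = (3.0, 1.0, 0.5, 0.0, 0.0)
    feature_correlation: float = 0.0
    present_fraction: float = 0.3
    seed: int = 0
    digest: DigestParams = field(default_factory=DigestParams)

    def __post_init__(self) -> None:
        if self.n_proteins < 0 or self.n_spectra < 0 or self.n_features < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.prop_correct <= 1.0:
            raise ValueError("prop_correct must be in [0, 1]")
        if not 0.0 <= self.present_fraction <= 1.0:
            raise ValueError("present_fraction must be in [0, 1]")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must be in [0, 1)")
        if len(self.effect_size) != self.n_features:
            raise ValueError("effect_size length must equal n_features")


def simulate_proteome(config: SimConfig) -> List[ProteinRecord]:
    """Generate ``n_proteins`` random sequences, deterministic per seed."""
    rng = np.random.default_rng([config.seed, 11])
    lo, hi = config.protein_length
    records = []
    letters = np.array(list(AMINO_ACIDS))
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=_FREQS))
        records.append(ProteinRecord(id=f"SYN{i + 1:05d}", sequence=seq))
    return records


def reverse_proteins(
    proteins: Sequence[ProteinRecord], prefix: str = DECOY_PREFIX
) -> List[ProteinRecord]:
    """Sequence-reversed decoy database; ids gain the decoy prefix."""
    return [
        ProteinRecord(id=prefix + p.id, sequence=p.sequence[::-1], is_decoy=True)
        for p in proteins
    ]


def _peptide_index(
    proteins: Sequence[ProteinRecord], params: DigestParams
) -> Tuple[List[str], Dict[str, List[str]]]:
    pep_to_prot: Dict[str, List[str]] = {}
    for p in proteins:
        for pep in digest(p.sequence, params):
            pep_to_prot.setdefault(pep, []).append(p.id)
    peptides = sorted(pep_to_prot)
    for v in pep_to_prot.values():
        v.sort()
    return peptides, pep_to_prot


def _correlated_normal(rng: np.random.Generator, n: int, d: int, rho: float) -> np.ndarray:
    z = rng.standard_normal((n, d))
    if rho == 0.0:
        return z
    # exchangeable correlation: x_j = sqrt(1-rho) z_j + sqrt(rho) z0
    shared = rng.standard_normal((n, 1))
    return np.sqrt(1.0 - rho) * z + np.sqrt(rho) * shared


def simulate_psms(
    proteome: Sequence[ProteinRecord],
    config: SimConfig,
    present_ids: Optional[Sequence[str]] = None,
) -> Tuple[PsmTable, pd.DataFrame]:
    """Generate a PIN-style PSM table and its ground-truth sidecar.

    One target and one decoy PSM per spectrum.  ``present_ids`` fixes the
    set of proteins treated as present in the sample; by default a seeded
    subset of size ``present_fraction * len(proteome)`` is drawn.
    Returns the table and a DataFrame with columns
    ``spec_id, is_correct, source_protein``.
    """
    rng = np.random.default_rng([config.seed, 23])
    peptides, pep_to_prot = _peptide_index(proteome, config.digest)
    if not peptides:
        raise ValueError("proteome digests to no peptides under the given parameters")
    ids = [p.id for p in proteome]
    if present_ids is None:
        n_present = int(round(config.present_fraction * len(ids)))
        chosen = rng.choice(len(ids), size=n_present, replace=False)
        present_ids = [ids[i] for i in sorted(chosen)]
    present_set = set(present_ids)
    present_peps = sorted(
        pep for pep, prots in pep_to_prot.items() if any(pr in present_set for pr in prots)
    )
    if config.prop_correct > 0 and not present_peps:
        raise ValueError("no present peptides available while prop_correct > 0")

    decoys = reverse_proteins(proteome)
    decoy_peps, decoy_pep_to_prot = _peptide_index(decoys, config.digest)

    n = config.n_spectra
    has_correct = rng.random(n) < config.prop_correct
    target_idx = rng.integers(0, len(peptides), size=n)
    if present_peps:
        present_draw = rng.integers(0, len(present_peps), size=n)
    else:
        present_draw = np.zeros(n, dtype=int)
    decoy_idx = rng.integers(0, len(decoy_peps), size=n)

    # The target search reports the best of its candidates, so even a
    # spectrum with a correct explanation carries an incorrect-candidate
    # score that can occasionally win — mirroring the decoy search, which
    # always fields such a candidate.  Candidate selection uses the most
    # informative feature as the stand-in search-engine score.
    effect = np.asarray(config.effect_size, dtype=float)
    j_star = int(np.argmax(effect))
    c_feats = _correlated_normal(rng, n, config.n_features, config.feature_correlation)
    c_feats = c_feats + effect[None, :]
    i_feats = _correlated_normal(rng, n, config.n_features, config.feature_correlation)
    d_feats = _correlated_normal(rng, n, config.n_features, config.feature_correlation)
    correct = has_correct & (c_feats[:, j_star] >= i_feats[:, j_star])
    t_feats = np.where(correct[:, None], c_feats, i_feats)

    spec_ids: List[str] = []
    scans: List[int] = []
    is_target: List[bool] = []
    feats: List[np.ndarray] = []
    pep_field: List[str] = []
    prots: List[Tuple[str, ...]] = []
    truth_rows = []
    for i in range(n):
        sid = f"s{i + 1:07d}"
        if correct[i]:
            pep = present_peps[present_draw[i]]
            owners = [pr for pr in pep_to_prot[pep] if pr in present_set]
            source = owners[0]
        else:
            pep = peptides[target_idx[i]]
            source = ""
        dpep = decoy_peps[decoy_idx[i]]
        spec_ids += [sid, sid]
        scans += [i + 1, i + 1]
        is_target += [True, False]
        feats += [t_feats[i], d_feats[i]]
        pep_field += [f"-.{pep}.-", f"-.{dpep}.-"]
        prots += [tuple(pep_to_prot[pep]), tuple(decoy_pep_to_prot[dpep])]
        truth_rows.append((sid, bool(correct[i]), source))

    table = PsmTable(
        spec_ids=np.array(spec_ids, dtype=object),
        scans=np.array(scans, dtype=int),
        is_target=np.array(is_target, dtype=bool),
        features=np.array(feats, dtype=float) if feats else np.empty((0, config.n_features)),
        feature_names=tuple(f"feat{j + 1}" for j in range(config.n_features)),
        peptides=np.array(pep_field, dtype=object),
        proteins=prots,
    )
    truth = pd.DataFrame(truth_rows, columns=["spec_id", "is_correct", "source_protein"])
    return table, truth
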