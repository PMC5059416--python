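"""PIN (Percolator INput) tab-delimited PSM tables.

The format is ``SpecId  Label  ScanNr  feat1..featN  Peptide  Proteins``
with ``Label`` in {1, -1}; protein accessions occupy the remaining
tab-separated cells of each row.  An optional second line starting with
``DefaultDirection`` is parsed and ignored.  PSMs of the same spectrum
share a ``SpecId``, which is what the subset sampler and target-decoy
competition key on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "PSMRecord",
    "PsmTable",
    "read_pin",
    "write_pin",
    "strip_flanks",
    "tdc_compete",
    "tdc_winner",
]

_FLANK_RE = re.compile(r"^.\.(.*)\..$", re.DOTALL)
_MOD_RE = re.compile(r"\[[^\]]*\]")


def strip_flanks(peptide: str) -> str:
    """Normalize a PIN peptide string for sequence matching.

    Removes single-character flanking residues (``K.PEPTIDER.S`` ->
    ``PEPTIDER``), bracketed modification annotations, and any residual
    non-residue characters, leaving the plain upper-case sequence.
    """
    m = _FLANK_RE.match(peptide)
    inner = m.group(1) if m else peptide
    inner = _MOD_RE.sub("", inner)
    # lowercase letters mark terminal modifications (e.g. "n" for N-term)
    # and are dropped along with any other non-residue character
    return re.sub(r"[^A-Z]", "", inner)


@dataclass(frozen=True)
class PSMRecord:
    """One spectrum-peptide match."""

    spec_id: str
    scan: int
    label: str  # "target" or "decoy"
    features: np.ndarray
    peptide: str  # stripped sequence
    protein_ids: Tuple[str, ...]


@dataclass
class PsmTable:
    """Column-oriented PSM collection (the in-memory form of a PIN file)."""

    spec_ids: np.ndarray  # str
    scans: np.ndarray  # int
    is_target: np.ndarray  # bool
    features: np.ndarray  # (n, d) float
    feature_names: Tuple[str, ...]
    peptides: np.ndarray  # str, as written in the file (flanked)
    proteins: List[Tuple[str, ...]]

    def __post_init__(self) -> None:
        n = len(self.spec_ids)
        if not (
            len(self.scans) == len(self.is_target) == self.features.shape[0]
            == len(self.peptides) == len(self.proteins) == n
        ):
            raise ValueError("PsmTable columns have inconsistent lengths")
        if self.features.ndim != 2 or self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix does not match feature names")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("PSM features must be finite")

    def __len__(self) -> int:
        return len(self.spec_ids)

    @property
    def stripped_peptides(self) -> np.ndarray:
        return np.array([strip_flanks(p) for p in self.peptides], dtype=object)

    def select(self, index: np.ndarray) -> "PsmTable":
        """Row subset (boolean mask or integer index), order-preserving."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return PsmTable(
            spec_ids=self.spec_ids[index],
            scans=self.scans[index],
            is_target=self.is_target[index],
            features=self.features[index],
            feature_names=self.feature_names,
            peptides=self.peptides[index],
            proteins=[self.proteins[i] for i in index],
        )

    def to_records(self) -> List[PSMRecord]:
        return [
            PSMRecord(
                spec_id=str(self.spec_ids[i]),
                scan=int(self.scans[i]),
                label="target" if self.is_target[i] else "decoy",
                features=self.features[i].copy(),
                peptide=strip_flanks(str(self.peptides[i])),
                protein_ids=tuple(self.proteins[i]),
            )
            for i in range(len(self))
        ]


def read_pin(path: str | Path) -> PsmTable:
    """Parse a PIN file.

    Raises ``ValueError`` on a malformed header, an unknown label, or a
    ragged feature block.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 5:
            raise ValueError(f"{path}: PIN header needs at least 5 columns")
        lowered = [h.lower() for h in header[:3]]
        if lowered != ["specid", "label", "scannr"]:
            raise ValueError(
                f"{path}: PIN header must start with SpecId, Label, ScanNr (got {header[:3]})"
            )
        try:
            pep_col = next(i for i, h in enumerate(header) if h.lower() == "peptide")
        except StopIteration:
            raise ValueError(f"{path}: PIN header has no Peptide column") from None
        feature_names = tuple(header[3:pep_col])
        if not feature_names:
            raise ValueError(f"{path}: PIN file declares no features")

        spec_ids: List[str] = []
        scans: List[int] = []
        is_target: List[bool] = []
        feats: List[List[float]] = []
        peptides: List[str] = []
        proteins: List[Tuple[str, ...]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if lineno == 2 and cols[0].lower() == "defaultdirection":
                continue
            if len(cols) < pep_col + 2:
                raise ValueError(f"{path}: line {lineno}: too few columns")
            label = cols[1]
            if label not in ("1", "-1"):
                raise ValueError(f"{path}: line {lineno}: Label must be 1 or -1, got {label!r}")
            spec_ids.append(cols[0])
            scans.append(int(cols[2]))
            is_target.append(label == "1")
            feats.append([float(v) for v in cols[3:pep_col]])
            peptides.append(cols[pep_col])
            proteins.append(tuple(cols[pep_col + 1 :]))
    return PsmTable(
        spec_ids=np.array(spec_ids, dtype=object),
        scans=np.array(scans, dtype=int),
        is_target=np.array(is_target, dtype=bool),
        features=np.array(feats, dtype=float),
        feature_names=feature_names,
        peptides=np.array(peptides, dtype=object),
        proteins=proteins,
    )


def write_pin(table: PsmTable, path: str | Path) -> None:
    """Write a PsmTable as a PIN file; floats use repr so rows round-trip."""
    with open(path, "w") as fh:
        fh.write(
            "SpecId\tLabel\tScanNr\t" + "\t".join(table.feature_names) + "\tPeptide\tProteins\n"
        )
        for i in range(len(table)):
            feats = "\t".join(repr(float(v)) for v in table.features[i])
            prots = "\t".join(table.proteins[i])
            label = "1" if table.is_target[i] else "-1"
            fh.write(
                f"{table.spec_ids[i]}\t{label}\t{table.scans[i]}\t{feats}\t"
                f"{table.peptides[i]}\t{prots}\n"
            )


def tdc_compete(table: PsmTable, scores: np.ndarray) -> PsmTable:
    """Target-decoy competition at PSM level.

    Keeps the best-scoring target and the best-scoring decoy per spectrum
    (``spec_id``); ties resolve to the earliest row for determinism.
    """
    scores = np.asarray(scores, dtype=float)
    best: dict = {}
    for i in range(len(table)):
        key = (table.spec_ids[i], bool(table.is_target[i]))
        if key not in best or scores[i] > scores[best[key]]:
            best[key] = i
    keep = np.array(sorted(best.values()), dtype=int)
    return table.select(keep)


def tdc_winner(table: PsmTable, scores: np.ndarray) -> PsmTable:
    """Winner-take-all target-decoy competition per spectrum.

    Keeps the single best-scoring PSM of each spectrum, target or decoy.
    This makes the number of surviving decoys match the number of
    surviving incorrect targets in expectation, which is what keeps
    decoy-based FDR estimates calibrated when a sizeable fraction of
    spectra have correct matches.  Ties resolve to the earliest row.
    """
    scores = np.asarray(scores, dtype=float)
    best: dict = {}
    for i in range(len(table)):
        key = table.spec_ids[i]
        if key not in best or scores[i] > scores[best[key]]:
            best[key] = i
    keep = np.array(sorted(best.values()), dtype=int)
    return table.select(keep)
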