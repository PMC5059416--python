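"""FASTA handling and in-silico proteolytic digestion.

Proteins are cleaved with a simple rule-based enzyme model (trypsin by
default: cleavage C-terminal to K or R, optionally suppressed when the
next residue is proline).  Digestion yields the set of peptides obtainable
with up to ``missed_cleavages`` skipped cleavage sites, filtered to a
length window.  These theoretical peptide sets are the basis for protein
grouping and for the entrapment benchmark construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Set

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "DigestParams",
    "read_fasta",
    "write_fasta",
    "cleavage_sites",
    "base_fragments",
    "digest",
]

#: residues cleaved C-terminally, per enzyme
CLEAVAGE_RULES = {"trypsin": "KR"}


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence entry.

    Parameters
    ----------
    id:
        Accession, unique within a database.
    sequence:
        Upper-case amino-acid string (20-letter alphabet plus ambiguity
        codes such as X, which are digested literally).
    is_decoy:
        Whether the record belongs to the reversed decoy database.
    """

    id: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class DigestParams:
    """Parameters of the in-silico digest.

    Defaults model a full tryptic digest with proline suppression, no
    missed cleavages and a 7-50 residue peptide length window (the window
    conventionally used in database searching).
    """

    enzyme: str = "trypsin"
    suppress_proline: bool = True
    missed_cleavages: int = 0
    min_len: int = 7
    max_len: int = 50

    def __post_init__(self) -> None:
        if self.enzyme not in CLEAVAGE_RULES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")


def read_fasta(path: str | Path) -> List[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    The id is the header token before the first whitespace.  Sequences
    are upper-cased and line breaks removed.  A sequence line appearing
    before any header, or a duplicated id, raises ``ValueError`` (the
    former naming the offending line number).
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
    records: List[ProteinRecord] = []
    seen: Set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write protein records as FASTA with fixed line wrapping."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def cleavage_sites(sequence: str, params: DigestParams) -> List[int]:
    """Return cut positions (string indices) strictly inside ``sequence``.

    A cut at position ``i`` separates ``sequence[:i]`` from
    ``sequence[i:]``.  Sites follow the enzyme rule; when
    ``suppress_proline`` is set, a site is skipped if the residue after
    the cut is P.
    """
    residues = CLEAVAGE_RULES[params.enzyme]
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in residues:
            if params.suppress_proline and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def base_fragments(sequence: str, params: DigestParams) -> List[str]:
    """Split ``sequence`` at every cleavage site (zero missed cleavages).

    The returned fragments tile the sequence in order; no length filter
    is applied.
    """
    bounds = [0] + cleavage_sites(sequence, params) + [len(sequence)]
    return [sequence[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]


def digest(sequence: str, params: DigestParams = DigestParams()) -> Set[str]:
    """Digest a protein sequence into its theoretical peptide set.

    With ``m = params.missed_cleavages``, the result contains every
    concatenation of up to ``m + 1`` adjacent base fragments whose length
    falls within ``[min_len, max_len]``.  Duplicate peptides collapse
    (a set is returned); the empty set is a legal result.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    frags = base_fragments(sequence, params)
    out: Set[str] = set()
    m = params.missed_cleavages
    for i in range(len(frags)):
        pep = ""
        for j in range(i, min(i + m + 1, len(frags))):
            pep += frags[j]
            if len(pep) > params.max_len:
                break
            if len(pep) >= params.min_len:
                out.add(pep)
    return out
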