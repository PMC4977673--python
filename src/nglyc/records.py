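"""Core domain records and plain-text I/O.

Conventions used throughout the package:

* residue coordinates are 1-based and inclusive, matching the site names
  used in the glycoproteomics literature (N225 = asparagine at position 225);
* sequences are upper-case strings over the 20 standard amino acids;
* tabular files are TSV with ``#``-prefixed header comment lines stating the
  conventions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: CAZy class prefixes recognised in family labels (CBM is a module, not a class).
CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")

EVIDENCE_COLUMNS = [
    "protein_id",
    "peptide",
    "start",
    "end",
    "mods",
    "spectrum_count",
    "condition",
]


class RecordError(ValueError):
    """Raised when an input record violates the package's schema."""


@dataclass(frozen=True)
class ProteinRecord:
    """A (mature, secreted-or-not) protein sequence with its annotations.

    CAZy family annotation is consumed as input (e.g. from a dbCAN run done
    upstream); ``cazy_families`` is empty for non-CAZy proteins.
    """

    id: str
    sequence: str
    cazy_families: tuple[str, ...] = ()
    secreted: bool = True
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordError("protein id must be non-empty")
        if not self.sequence:
            raise RecordError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise RecordError(
                f"{self.id}: non-standard residues {sorted(bad)!r}; "
                "only the 20 standard amino acids are accepted"
            )
        object.__setattr__(self, "cazy_families", tuple(self.cazy_families))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_cazy(self) -> bool:
        return len(self.cazy_families) > 0

    @property
    def cazy_class(self) -> str:
        """Class prefix of the first family label, or ``"non-CAZy"``."""
        if not self.cazy_families:
            return "non-CAZy"
        fam = self.cazy_families[0]
        for cls in CAZY_CLASSES:
            if fam.startswith(cls):
                return cls
        return "non-CAZy"


@dataclass
class SequonSite:
    """One N-X-S/T sequon: a candidate N-glycosylation site.

    ``position`` indexes the Asn (1-based).  ``window`` is the 13-character
    flanking context covering positions -6..+6 with the site asparagine
    rendered as lower-case ``n`` and ``-`` padding beyond the termini.
    ``status`` is one of the three evidence classes (``validated``,
    ``non_validated``, ``non_covered``) or ``unset`` before classification.
    """

    protein_id: str
    position: int
    sequon: str
    sequon_type: str  # "NXS" | "NXT"
    window: str
    status: str = "unset"
    n_tagged_spectra: int = 0
    proline_x: bool = False  # sequon exists only because X=P was allowed
    secreted: bool = True

    def __post_init__(self) -> None:
        if len(self.sequon) != 3 or self.sequon[0] != "N":
            raise RecordError(f"malformed sequon {self.sequon!r}")
        if self.sequon_type not in ("NXS", "NXT"):
            raise RecordError(f"bad sequon_type {self.sequon_type!r}")
        if len(self.window) != 13 or self.window[6] != "n":
            raise RecordError(f"malformed window {self.window!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.position)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=p.description)
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(
    path: str | Path,
    annotations: pd.DataFrame | None = None,
) -> list[ProteinRecord]:
    """Read proteins from FASTA, optionally joining an annotation table.

    The annotation table has columns ``protein_id``, ``cazy_families``
    (semicolon-joined, empty for non-CAZy) and ``secreted`` (0/1).
    """
    ann: dict[str, tuple[tuple[str, ...], bool]] = {}
    if annotations is not None:
        for row in annotations.itertuples(index=False):
            fams = tuple(f for f in str(row.cazy_families).split(";") if f and f != "nan")
            ann[str(row.protein_id)] = (fams, bool(int(row.secreted)))
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fams, secreted = ann.get(rec.id, ((), True))
        proteins.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                cazy_families=fams,
                secreted=secreted,
                description=rec.description,
            )
        )
    return proteins


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, header_notes: Sequence[str] = ()) -> None:
    """Write a TSV with '#'-prefixed convention notes above the header row."""
    path = Path(path)
    with open(path, "w") as fh:
        for note in header_notes:
            fh.write(f"# {note}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def annotations_frame(proteins: Iterable[ProteinRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [p.id for p in proteins],
            "cazy_families": [";".join(p.cazy_families) for p in proteins],
            "secreted": [int(p.secreted) for p in proteins],
        }
    )


def sites_frame(sites: Iterable[SequonSite]) -> pd.DataFrame:
    rows = [dataclasses.asdict(s) for s in sites]
    cols = [
        "protein_id", "position", "sequon", "sequon_type", "window",
        "status", "n_tagged_spectra", "proline_x", "secreted",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Evidence table dialect
# ---------------------------------------------------------------------------

def format_mods(mods: Sequence[tuple[str, int]]) -> str:
    """Render modifications as ``name@position`` joined by ';' ('' if none)."""
    return ";".join(f"{name}@{pos}" for name, pos in mods)


def parse_mods(text: str) -> list[tuple[str, int]]:
    """Parse the ``name@position;...`` modification dialect (strict)."""
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return []
    mods = []
    for tok in str(text).split(";"):
        if "@" not in tok:
            raise RecordError(f"malformed modification token {tok!r}")
        name, _, pos = tok.partition("@")
        if not pos.isdigit():
            raise RecordError(f"malformed modification position in {tok!r}")
        mods.append((name, int(pos)))
    return mods


def validate_evidence(evidence: pd.DataFrame, proteins: Iterable[ProteinRecord] | None = None) -> pd.DataFrame:
    """Validate the evidence-table schema; returns the frame with typed columns.

    Raises :class:`RecordError` naming the offending row on the first
    violation (strict, fail-fast parsing).
    """
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise RecordError(f"evidence table missing columns {missing}")
    evidence = evidence.copy()
    evidence["mods"] = evidence["mods"].fillna("")
    by_id = {p.id: p for p in proteins} if proteins is not None else None
    for i, row in enumerate(evidence.itertuples(index=False)):
        if row.end < row.start or row.start < 1:
            raise RecordError(f"evidence row {i}: bad coordinates [{row.start}..{row.end}]")
        if len(row.peptide) != row.end - row.start + 1:
            raise RecordError(f"evidence row {i}: peptide length does not match coordinates")
        for name, pos in parse_mods(row.mods):
            if not 1 <= pos <= len(row.peptide):
                raise RecordError(f"evidence row {i}: modification position {pos} outside peptide")
        if by_id is not None:
            prot = by_id.get(row.protein_id)
            if prot is None:
                raise RecordError(f"evidence row {i}: unknown protein {row.protein_id!r}")
            if prot.sequence[row.start - 1: row.end] != row.peptide:
                raise RecordError(
                    f"evidence row {i}: peptide does not match protein slice "
                    f"{row.protein_id}[{row.start}..{row.end}]"
                )
    return evidence
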