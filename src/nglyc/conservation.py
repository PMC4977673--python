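"""Site conservation across homolog multiple alignments.

The homolog set and its E-value gate (BLAST against related genomes,
typically E <= 1e-70) are upstream of this module: it consumes an aligned
FASTA in which one row is the query protein.  A query site is conserved in
a homolog when the homolog carries an intact N-X-S/T sequon at (or, in
tolerant mode, within a few columns of) the query site's alignment column
— alignment gaps shift sequons in primary-sequence terms even when the
glycan occupies a similar position in the folded protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .records import RecordError, SequonSite

GAP = "-"


@dataclass
class HomologAlignment:
    """A multiple alignment of a query protein and its homologs."""

    ids: list[str]
    rows: list[str]
    query_id: str
    evalue_gate: float | None = None  # recorded input metadata, not computed

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or not self.rows:
            raise RecordError("alignment needs matching ids and rows")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise RecordError("alignment rows differ in length")
        if self.query_id not in self.ids:
            raise RecordError(f"query id {self.query_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def query_row(self) -> str:
        return self.rows[self.ids.index(self.query_id)]

    def degapped_query(self) -> str:
        return self.query_row.replace(GAP, "")

    def homolog_ids(self) -> list[str]:
        return [i for i in self.ids if i != self.query_id]


def read_alignment(path: str | Path, query_id: str | None = None) -> HomologAlignment:
    """Read an aligned FASTA; the query is the first record unless named."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise RecordError(f"no records in alignment {path}")
    return HomologAlignment(ids=ids, rows=rows, query_id=query_id or ids[0])


def map_site_to_column(msa: HomologAlignment, position: int) -> int:
    """Alignment column (0-based) holding the query's residue ``position`` (1-based)."""
    seen = 0
    for col, ch in enumerate(msa.query_row):
        if ch != GAP:
            seen += 1
            if seen == position:
                return col
    raise IndexError(f"position {position} beyond degapped query length {seen}")


def _sequon_at(degapped: str, idx0: int, allow_proline_X: bool) -> bool:
    """Does ``degapped`` carry an N-X-S/T sequon starting at 0-based ``idx0``?"""
    if idx0 < 0 or idx0 + 2 > len(degapped) - 1:
        return False
    if degapped[idx0] != "N" or degapped[idx0 + 2] not in "ST":
        return False
    if degapped[idx0 + 1] == "P" and not allow_proline_X:
        return False
    return True


def site_conserved_in(
    msa: HomologAlignment,
    homolog_id: str,
    column: int,
    window_tol: int = 0,
    allow_proline_X: bool = False,
) -> tuple[bool, int | None]:
    """Verdict and column offset for one homolog at one mapped column.

    True iff the homolog has an Asn within +-``window_tol`` columns of
    ``column`` whose degapped context is an intact N-X-S/T sequon; the
    offset records the displacement (0 = same column).  The nearest
    qualifying Asn wins; ties prefer the smaller |offset|, then upstream.
    """
    if not 0 <= column < msa.n_columns:
        raise IndexError(f"column {column} outside alignment")
    row = msa.rows[msa.ids.index(homolog_id)]
    # column -> 0-based degapped index for this homolog
    col_to_idx = {}
    seen = 0
    for c, ch in enumerate(row):
        if ch != GAP:
            col_to_idx[c] = seen
            seen += 1
    degapped = row.replace(GAP, "")
    offsets = sorted(range(-window_tol, window_tol + 1), key=lambda o: (abs(o), o))
    for off in offsets:
        c = column + off
        if c in col_to_idx and _sequon_at(degapped, col_to_idx[c], allow_proline_X):
            return True, off
    return False, None


@dataclass
class SiteConservation:
    """Conservation of one query site over the homolog rows of an alignment."""

    site: SequonSite
    n_homologs: int
    n_conserved: int
    conservation_pct: float
    verdicts: dict[str, tuple[bool, int | None]] = field(default_factory=dict)


def conservation_percent(
    msa: HomologAlignment,
    sites: Sequence[SequonSite],
    window_tol: int = 0,
    allow_proline_X: bool = False,
) -> list[SiteConservation]:
    """Per-site conservation percentages over the non-query alignment rows."""
    homologs = msa.homolog_ids()
    if not homologs:
        raise RecordError("alignment has no homolog rows")
    out = []
    for site in sites:
        column = map_site_to_column(msa, site.position)
        verdicts = {
            h: site_conserved_in(msa, h, column, window_tol, allow_proline_X)
            for h in homologs
        }
        n_cons = sum(1 for ok, _ in verdicts.values() if ok)
        out.append(
            SiteConservation(
                site=site,
                n_homologs=len(homologs),
                n_conserved=n_cons,
                conservation_pct=100.0 * n_cons / len(homologs),
                verdicts=verdicts,
            )
        )
    return out


def conservation_frame(results: Iterable[SiteConservation]) -> pd.DataFrame:
    """Tabular mirror of the per-site conservation report (1-decimal %)."""
    return pd.DataFrame(
        {
            "protein_id": [r.site.protein_id for r in results],
            "position": [r.site.position for r in results],
            "sequon": [r.site.sequon for r in results],
            "conservation_pct": [round(r.conservation_pct, 1) for r in results],
            "n_conserved": [r.n_conserved for r in results],
            "n_homologs": [r.n_homologs for r in results],
        }
    )
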