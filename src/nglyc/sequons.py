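"""Sequon scanning and flanking-window extraction.

N-linked glycosylation in eukaryotes occurs at the Asn-X-Ser/Thr sequon.
By default X may not be proline, the behaviour of the oligosaccharyl-
transferase consensus used by standard predictors; pass
``allow_proline_X=True`` for the literal N-X-S/T reading.
"""

from __future__ import annotations

from typing import Iterable

from .records import ProteinRecord, SequonSite

PAD = "-"


def flanking_window(protein: ProteinRecord, position: int, half_width: int = 6) -> str:
    """Flanking context of length ``2*half_width + 1`` centred on an Asn.

    ``position`` is 1-based.  The centre residue is rendered lower-case
    ``n``; positions beyond the protein termini are padded with ``-``.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise IndexError(f"position {position} out of range for {protein.id}")
    if seq[position - 1] != "N":
        raise ValueError(f"{protein.id} position {position} is {seq[position-1]}, not N")
    i = position - 1
    left = seq[max(0, i - half_width): i]
    right = seq[i + 1: i + 1 + half_width]
    left = PAD * (half_width - len(left)) + left
    right = right + PAD * (half_width - len(right))
    return left + "n" + right


def scan_sequons(
    protein: ProteinRecord,
    allow_proline_X: bool = False,
    half_width: int = 6,
) -> list[SequonSite]:
    """Return every N-X-[S/T] sequon of ``protein`` in ascending position.

    Overlapping sequons are all reported.  A sequon whose +2 residue would
    fall beyond the C-terminus is not a sequon.  Sites that exist only
    because X=P was allowed are flagged via ``proline_x``.
    """
    seq = protein.sequence
    sites: list[SequonSite] = []
    for i in range(len(seq) - 2):
        if seq[i] != "N" or seq[i + 2] not in "ST":
            continue
        is_proline_x = seq[i + 1] == "P"
        if is_proline_x and not allow_proline_X:
            continue
        position = i + 1
        sites.append(
            SequonSite(
                protein_id=protein.id,
                position=position,
                sequon=seq[i: i + 3],
                sequon_type="NXT" if seq[i + 2] == "T" else "NXS",
                window=flanking_window(protein, position, half_width),
                proline_x=is_proline_x,
                secreted=protein.secreted,
            )
        )
    return sites


def scan_all(
    proteins: Iterable[ProteinRecord],
    allow_proline_X: bool = False,
) -> list[SequonSite]:
    """Scan a whole protein set; sites grouped by protein, ascending position."""
    sites: list[SequonSite] = []
    for protein in proteins:
        sites.extend(scan_sequons(protein, allow_proline_X=allow_proline_X))
    return sites
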