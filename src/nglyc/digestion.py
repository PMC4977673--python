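"""In-silico tryptic digestion, peptide mass arithmetic and coverage mapping.

Trypsin cleaves C-terminal to Lys/Arg except when the next residue is
proline.  Masses are monoisotopic (the study-style 10 ppm precursor
tolerance implies monoisotopic bookkeeping).  The Endo H treatment used
upstream of LC-MS/MS leaves a single GlcNAc on each formerly glycosylated
asparagine; that remnant is modelled purely as the +203.0794 Da delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mass as _pmass

from .records import ProteinRecord, RecordError, SequonSite, parse_mods

#: Monoisotopic modification deltas (Da).
MOD_DELTAS = {
    "GlcNAc_remnant": 203.079373,   # HexNAc residue left on Asn by Endo H
    "carbamidomethyl": 57.021464,   # fixed, Cys (iodoacetamide)
    "oxidation": 15.994915,         # variable, Met
}

#: Residue each modification may sit on.
MOD_TARGETS = {"GlcNAc_remnant": "N", "carbamidomethyl": "C", "oxidation": "M"}


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with 1-based inclusive protein coordinates."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise RecordError("peptide sequence length does not match coordinates")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices *after* which trypsin cleaves (K/R not followed by P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinRecord,
    max_missed: int = 1,
    min_length: int = 1,
    max_length: int | None = None,
) -> list[Peptide]:
    """Enumerate tryptic peptides with 0..``max_missed`` missed cleavages.

    Zero-missed peptides tile the protein exactly; a peptide with *m* missed
    cleavages spans *m*+1 consecutive zero-missed fragments.
    """
    seq = protein.sequence
    cuts = cleavage_sites(seq)
    # fragment boundaries as 0-based half-open [s, e)
    bounds = [0] + [c + 1 for c in cuts] + [len(seq)]
    peptides: list[Peptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(max_missed + 1):
            j = i + m
            if j >= n_frag:
                break
            s, e = bounds[i], bounds[j + 1]
            if e - s < min_length:
                continue
            if max_length is not None and e - s > max_length:
                continue
            peptides.append(
                Peptide(
                    protein_id=protein.id,
                    start=s + 1,
                    end=e,
                    sequence=seq[s:e],
                    missed_cleavages=m,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_mass(
    peptide: Peptide | str,
    mods: Sequence[tuple[str, int]] = (),
) -> float:
    """Monoisotopic peptide mass: residue masses + water + modification deltas.

    ``mods`` are ``(name, position)`` pairs with 1-based positions within the
    peptide; each modification must sit on its compatible residue.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    total = _pmass.fast_mass(seq)  # residues + H2O, monoisotopic
    for name, pos in mods:
        if name not in MOD_DELTAS:
            raise RecordError(f"unknown modification {name!r}")
        if not 1 <= pos <= len(seq):
            raise RecordError(f"modification position {pos} outside peptide")
        if seq[pos - 1] != MOD_TARGETS[name]:
            raise RecordError(
                f"{name} must sit on {MOD_TARGETS[name]}, found {seq[pos-1]} at {pos}"
            )
        total += MOD_DELTAS[name]
    return total


def map_coverage(
    evidence: pd.DataFrame,
    sites: Iterable[SequonSite],
    proteins: Iterable[ProteinRecord] | None = None,
) -> dict[tuple[str, int], list[int]]:
    """Map each sequon site to the evidence rows whose peptide covers its Asn.

    Returns ``{(protein_id, position): [evidence row indices]}``; an empty
    list means the site is non-covered.  A site is covered iff some observed
    peptide's [start..end] contains the site position.
    """
    if proteins is not None:
        known = {p.id for p in proteins}
        unknown = set(evidence["protein_id"]) - known
        if unknown:
            raise RecordError(f"evidence references unknown proteins {sorted(unknown)}")
    by_protein: dict[str, list[tuple[int, int, int]]] = {}
    for idx, pid, s, e in zip(
        evidence.index, evidence["protein_id"], evidence["start"], evidence["end"]
    ):
        by_protein.setdefault(pid, []).append((int(s), int(e), idx))
    coverage: dict[tuple[str, int], list[int]] = {}
    for site in sites:
        hits = [
            idx
            for (s, e, idx) in by_protein.get(site.protein_id, [])
            if s <= site.position <= e
        ]
        coverage[site.key] = hits
    return coverage


def tagged_at_site(evidence_row: Mapping, site_position: int) -> bool:
    """True if the evidence row carries a GlcNAc remnant on the site's Asn."""
    start = int(evidence_row["start"])
    for name, pos in parse_mods(evidence_row["mods"]):
        if name == "GlcNAc_remnant" and start + pos - 1 == site_position:
            return True
    return False
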