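"""Three-class evidence partition of predicted sequons and summaries.

Every predicted site falls in exactly one class:

* ``validated`` — at least one covering peptide carries the +203 GlcNAc
  remnant on the site's asparagine;
* ``non_validated`` — covered by identified peptides but never tagged at
  that asparagine (non-glycosylated according to the data);
* ``non_covered`` — no identified peptide spans the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .digestion import map_coverage, tagged_at_site
from .records import ProteinRecord, SequonSite, parse_mods

logger = logging.getLogger(__name__)

STATUSES = ("validated", "non_validated", "non_covered")


def find_inconsistent_evidence(
    evidence: pd.DataFrame,
    sites: Iterable[SequonSite],
) -> list[int]:
    """Indices of evidence rows with a GlcNAc remnant on a non-sequon residue.

    Such rows are reported on the warning stream and excluded from
    classification (a remnant can only sit on a sequon asparagine).
    """
    site_keys = {s.key for s in sites}
    bad: list[int] = []
    for idx, pid, start, mods in zip(
        evidence.index, evidence["protein_id"], evidence["start"], evidence["mods"]
    ):
        for name, pos in parse_mods(mods):
            if name != "GlcNAc_remnant":
                continue
            if (pid, int(start) + pos - 1) not in site_keys:
                bad.append(idx)
                break
    return bad


def classify_sites(
    sites: Sequence[SequonSite],
    evidence: pd.DataFrame,
    min_tagged_spectra: int = 1,
) -> list[SequonSite]:
    """Assign each site its evidence class; returns the same site objects.

    ``min_tagged_spectra`` is an optional stricter filter: a site is
    validated only if its tagged covering peptides account for at least
    that many spectra (default 1, i.e. presence-based).  Sites failing the
    filter but covered are classed non_validated.
    """
    inconsistent = find_inconsistent_evidence(evidence, sites)
    if inconsistent:
        logger.warning(
            "excluding %d evidence row(s) with GlcNAc remnant outside any sequon: %s",
            len(inconsistent), inconsistent,
        )
        evidence = evidence.drop(index=inconsistent)
    coverage = map_coverage(evidence, sites)
    for site in sites:
        rows = coverage[site.key]
        if not rows:
            site.status = "non_covered"
            site.n_tagged_spectra = 0
            continue
        tagged = [
            r for r in rows if tagged_at_site(evidence.loc[r], site.position)
        ]
        n_spectra = int(evidence.loc[tagged, "spectrum_count"].sum()) if tagged else 0
        site.n_tagged_spectra = n_spectra
        site.status = "validated" if n_spectra >= min_tagged_spectra else "non_validated"
    return list(sites)


@dataclass
class SiteStatusSummary:
    """Counts per evidence class plus the CAZyme-restricted tallies."""

    counts: dict[str, int]
    n_sites: int
    validated_in_cazy: int
    n_cazy_proteins_with_validated: int
    validated_positions: dict[str, list[int]] = field(default_factory=dict)

    def formatted_positions(self, protein_id: str) -> str:
        """Validated positions rendered as the literature does ("225, 365")."""
        return ", ".join(str(p) for p in self.validated_positions.get(protein_id, []))


def summarize_sites(
    sites: Sequence[SequonSite],
    proteins: Iterable[ProteinRecord] | None = None,
) -> SiteStatusSummary:
    """Aggregate classified sites into global and per-protein summaries."""
    counts = {s: 0 for s in STATUSES}
    counts["unset"] = 0
    validated_positions: dict[str, list[int]] = {}
    for site in sites:
        counts[site.status] = counts.get(site.status, 0) + 1
        if site.status == "validated":
            validated_positions.setdefault(site.protein_id, []).append(site.position)
    for positions in validated_positions.values():
        positions.sort()
    cazy_ids = {p.id for p in proteins if p.is_cazy} if proteins is not None else set()
    validated_in_cazy = sum(
        len(v) for pid, v in validated_positions.items() if pid in cazy_ids
    )
    n_cazy_with = sum(1 for pid in validated_positions if pid in cazy_ids)
    return SiteStatusSummary(
        counts=counts,
        n_sites=len(sites),
        validated_in_cazy=validated_in_cazy,
        n_cazy_proteins_with_validated=n_cazy_with,
        validated_positions=validated_positions,
    )
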