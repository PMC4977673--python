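"""Spectral-count secretome summaries: condition overlaps, CAZy family
proportions and top proteins per functional group.

The detection table is a protein x condition matrix of total spectrum
counts (label-free spectral counting).  A protein counts as detected in a
condition when its spectrum count there is positive.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .records import ProteinRecord, RecordError


def _check_table(table: pd.DataFrame) -> None:
    if table.shape[1] < 1:
        raise RecordError("detection table needs at least one condition column")
    if (table.values < 0).any():
        raise RecordError("spectrum counts must be nonnegative")


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scaling per condition (spectral-count 'quantitative value').

    Each condition column is scaled so its total equals the grand mean of
    the per-condition totals, making columns comparable.
    """
    _check_table(table)
    totals = table.sum(axis=0)
    target = totals.mean()
    return table * (target / totals.replace(0, pd.NA))


def condition_overlap(table: pd.DataFrame) -> dict:
    """Per-condition detection counts and all Venn region counts.

    Returns ``{"per_condition": {...}, "regions": {frozenset: count},
    "n_detected": int}``; regions are keyed by the exact set of conditions
    a protein is detected in, so the 2^k - 1 region counts sum to the
    number of detected proteins.
    """
    _check_table(table)
    detected = table > 0
    conditions = list(table.columns)
    per_condition = {c: int(detected[c].sum()) for c in conditions}
    regions: dict[frozenset, int] = {}
    for r in range(1, len(conditions) + 1):
        for combo in combinations(conditions, r):
            regions[frozenset(combo)] = 0
    n_detected = 0
    for _, row in detected.iterrows():
        present = frozenset(c for c in conditions if row[c])
        if present:
            regions[present] += 1
            n_detected += 1
    return {"per_condition": per_condition, "regions": regions, "n_detected": n_detected}


def class_family_proportions(
    table: pd.DataFrame,
    proteins: Iterable[ProteinRecord],
    min_display_pct: float = 2.0,
    weight: str = "spectra",
) -> dict[str, dict[str, pd.DataFrame]]:
    """Within-class CAZy family percentages, with a display threshold.

    Each CAZy class (GH/CE/PL/AA/...) is normalised to 100 %.  ``weight``
    selects the quantity summed per family: ``"spectra"`` (summed spectrum
    counts) or ``"proteins"`` (number of detected proteins).  Families at or
    above ``min_display_pct`` are shown; those below are aggregated into an
    ``"other"`` row in the ``display`` frame while the ``full`` frame keeps
    every family.
    """
    _check_table(table)
    if weight not in ("spectra", "proteins"):
        raise RecordError("weight must be 'spectra' or 'proteins'")
    rows = []
    by_id = {p.id: p for p in proteins}
    for pid, counts in table.iterrows():
        prot = by_id.get(pid)
        if prot is None or not prot.is_cazy:
            continue
        total = counts.sum()
        if total <= 0:
            continue
        value = float(total) if weight == "spectra" else 1.0
        for fam in prot.cazy_families:
            cls = prot.cazy_class
            rows.append({"class": cls, "family": fam, "value": value})
            break  # first family defines the class/family assignment
    if not rows:
        return {}
    df = pd.DataFrame(rows).groupby(["class", "family"], as_index=False)["value"].sum()
    out: dict[str, pd.DataFrame] = {}
    for cls, sub in df.groupby("class"):
        sub = sub.copy()
        sub["pct"] = 100.0 * sub["value"] / sub["value"].sum()
        sub = sub.sort_values("pct", ascending=False, kind="stable").reset_index(drop=True)
        shown = sub[sub["pct"] >= min_display_pct].copy()
        hidden_pct = sub.loc[sub["pct"] < min_display_pct, "pct"].sum()
        if hidden_pct > 0:
            shown = pd.concat(
                [shown, pd.DataFrame([{"class": cls, "family": "other",
                                       "value": pd.NA, "pct": hidden_pct}])],
                ignore_index=True,
            )
        out[cls] = {"full": sub, "display": shown}
    return out


def top_proteins(
    table: pd.DataFrame,
    group_labels: Mapping[str, str],
    k: int = 10,
) -> dict[str, pd.DataFrame]:
    """Per functional group, proteins ranked by total spectrum count.

    ``group_labels`` maps protein id to a functional-group label (e.g.
    "cellulases", "hemicellulases", "others").  Ties are broken by protein
    id so the ranking is order-independent.
    """
    _check_table(table)
    totals = table.sum(axis=1)
    rows = [
        {"protein_id": pid, "group": group_labels[pid], "total_count": float(totals[pid])}
        for pid in table.index
        if pid in group_labels
    ]
    out: dict[str, pd.DataFrame] = {g: pd.DataFrame(columns=["protein_id", "group", "total_count"])
                                    for g in set(group_labels.values())}
    if rows:
        df = pd.DataFrame(rows)
        for group, sub in df.groupby("group"):
            sub = sub.sort_values(
                ["total_count", "protein_id"], ascending=[False, True], kind="stable"
            ).head(k).reset_index(drop=True)
            out[group] = sub
    return out
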