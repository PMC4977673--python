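"""Motif report and flanking-residue chemical-class profile.

Windows are 13-character strings covering positions -6..+6 around the site
asparagine (lower-case ``n`` at the centre, ``-`` padding at termini).
Motif patterns use the same coordinate frame: residue letters are literal
and never match a terminus pad, ``.`` is a don't-care, ``n`` marks the site.

The background for enrichment is the set of Asn-centred windows over the
supplied background proteins; with that definition the background percent
of the ``n.T`` motif approximates the Thr residue frequency of the
proteome, which is the natural null for sequon-position statistics.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .records import ProteinRecord, RecordError, SequonSite
from .sequons import flanking_window

WINDOW_LEN = 13
CENTER = 6

#: Side-chain chemical classes for flanking-profile plots.
CHEMICAL_CLASSES = {
    "Hydrophobic": set("AVLIM"),
    "Aromatic": set("FYW"),
    "Polar uncharged": set("STNCQ"),
    "Acidic": set("DE"),
    "Basic": set("KRH"),
    "Unique": set("GP"),
}

#: Standard motifs of the sequon family: N-X-S, N-X-T and the X-specific
#: variants of N-X-T discussed in the glycoproteomics literature.
STANDARD_MOTIFS = {
    "NXS": "......n.S....",
    "NXT": "......n.T....",
    "NGT": "......nGT....",
    "NST": "......nST....",
    "NTT": "......nTT....",
}


def validate_pattern(pattern: str) -> str:
    if len(pattern) != WINDOW_LEN:
        raise RecordError(f"motif pattern must be {WINDOW_LEN} characters: {pattern!r}")
    if pattern.count("n") != 1 or pattern[CENTER] != "n":
        raise RecordError(f"motif pattern needs exactly one central 'n': {pattern!r}")
    if not re.fullmatch(r"[A-Z.n]+", pattern):
        raise RecordError(f"motif pattern alphabet is residue letters, '.' and 'n': {pattern!r}")
    return pattern


def pattern_regex(pattern: str) -> re.Pattern:
    """Compile a motif pattern.

    '.' is a don't-care (any residue or a terminus pad); an explicit
    residue letter never matches a pad, so constrained positions must
    exist in the protein.
    """
    validate_pattern(pattern)
    out = []
    for ch in pattern:
        if ch == ".":
            out.append("[A-Z-]")
        elif ch == "n":
            out.append("n")
        else:
            out.append(re.escape(ch))
    return re.compile("".join(out))


def matches(pattern: str, window: str) -> bool:
    return pattern_regex(pattern).fullmatch(window) is not None


def background_windows(proteins: Iterable[ProteinRecord]) -> list[str]:
    """Every Asn-centred window over the background protein set."""
    windows = []
    for protein in proteins:
        for i, aa in enumerate(protein.sequence):
            if aa == "N":
                windows.append(flanking_window(protein, i + 1))
    return windows


@dataclass(frozen=True)
class MotifRow:
    """One row of the motif report (Table-2 style)."""

    motif: str
    dataset_matches: int
    dataset_pct: float
    background_pct: float
    fold_enrichment: float
    binomial_p: float | None = None


def motif_report(
    windows: Sequence[str],
    background: Iterable[ProteinRecord] | Sequence[str],
    motifs: Sequence[str],
    with_p: bool = False,
) -> list[MotifRow]:
    """Count each motif in the foreground windows and the Asn background.

    ``background`` may be a protein set (Asn windows are extracted) or a
    pre-extracted window list.  Percentages follow the report convention:
    dataset_pct = 100 * matches / n_windows; fold enrichment is their ratio.
    """
    if not windows:
        raise RecordError("empty window set")
    bg = (
        list(background)
        if background and isinstance(next(iter(background)), str)
        else background_windows(background)
    )
    rows = []
    for pattern in motifs:
        rx = pattern_regex(pattern)
        n_fg = sum(1 for w in windows if rx.fullmatch(w))
        n_bg = sum(1 for w in bg if rx.fullmatch(w))
        dataset_pct = 100.0 * n_fg / len(windows)
        background_pct = 100.0 * n_bg / len(bg) if bg else float("nan")
        fold = dataset_pct / background_pct if background_pct and background_pct > 0 else math.inf
        p = None
        if with_p and bg:
            p = float(stats.binomtest(n_fg, len(windows), max(n_bg / len(bg), 1e-300),
                                      alternative="greater").pvalue)
        rows.append(MotifRow(pattern, n_fg, dataset_pct, background_pct, fold, p))
    return rows


def report_frame(rows: Sequence[MotifRow]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["dataset_pct_display"] = df["dataset_pct"].round(1)
    df["background_pct_display"] = df["background_pct"].round(2)
    return df


def sequon_preference(sites: Iterable[SequonSite]) -> pd.DataFrame:
    """Per evidence class, the percent split between N-X-T and N-X-S sequons."""
    records: dict[str, dict[str, int]] = {}
    for site in sites:
        d = records.setdefault(site.status, {"NXT": 0, "NXS": 0})
        d[site.sequon_type] += 1
    rows = []
    for status, d in sorted(records.items()):
        n = d["NXT"] + d["NXS"]
        rows.append(
            {
                "status": status,
                "n_sites": n,
                "pct_NXT": 100.0 * d["NXT"] / n if n else float("nan"),
                "pct_NXS": 100.0 * d["NXS"] / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def flanking_class_profile(windows: Sequence[str]) -> pd.DataFrame:
    """Chemical-class frequencies per flanking position (-6..+6).

    Positions 0 (the Asn) and +2 (the sequon Ser/Thr) are excluded, as are
    terminus pad characters; at each remaining position the class
    frequencies over non-pad residues sum to 1.
    """
    positions = [p for p in range(-6, 7) if p not in (0, 2)]
    rows = []
    for pos in positions:
        idx = pos + CENTER
        residues = [w[idx] for w in windows if w[idx] != "-"]
        n = len(residues)
        row: dict[str, float | int] = {"position": pos, "n_residues": n}
        for cls, members in CHEMICAL_CLASSES.items():
            row[cls] = (sum(1 for r in residues if r in members) / n) if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def count_matrix(windows: Sequence[str]) -> pd.DataFrame:
    """Position x residue count matrix (sequence-logo ready)."""
    alphabet = sorted("ACDEFGHIKLMNPQRSTVWY")
    data = {aa: [0] * WINDOW_LEN for aa in alphabet}
    for w in windows:
        for i, ch in enumerate(w):
            if ch in data:
                data[ch][i] += 1
    df = pd.DataFrame(data)
    df.insert(0, "position", list(range(-6, 7)))
    return df


def greedy_motif_search(
    windows: Sequence[str],
    background: Iterable[ProteinRecord] | Sequence[str],
    max_depth: int = 3,
    p_threshold: float = 1e-6,
) -> list[str]:
    """Simple motif-x-style greedy search for enriched flanking motifs.

    Repeatedly fixes the (position, residue) pair with the smallest binomial
    enrichment p-value until no pair beats ``p_threshold`` or ``max_depth``
    letters are fixed.  Exploratory output; not used by the report path.
    """
    bg = (
        list(background)
        if background and isinstance(next(iter(background)), str)
        else background_windows(background)
    )
    pattern = list("......n......")
    fg = list(windows)
    for _ in range(max_depth):
        best: tuple[float, int, str] | None = None
        for idx in range(WINDOW_LEN):
            if pattern[idx] != ".":
                continue
            fg_col = [w[idx] for w in fg if w[idx] != "-"]
            bg_col = [w[idx] for w in bg if w[idx] != "-"]
            if not fg_col or not bg_col:
                continue
            for aa in set(fg_col):
                k = fg_col.count(aa)
                p0 = max(bg_col.count(aa) / len(bg_col), 1e-300)
                p = stats.binomtest(k, len(fg_col), p0, alternative="greater").pvalue
                if best is None or p < best[0]:
                    best = (float(p), idx, aa)
        if best is None or best[0] > p_threshold:
            break
        _, idx, aa = best
        pattern[idx] = aa
        rx = pattern_regex("".join(pattern))
        fg = [w for w in fg if rx.fullmatch(w)]
        bg = [w for w in bg if w[idx] == aa]
        if not fg:
            break
    return ["".join(pattern)]
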