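"""Synthetic secretome generator with known ground truth.

Every pipeline input — secreted proteins with planted sequons, tryptic
peptide evidence with GlcNAc-remnant tags, homolog families, and
permethylated-glycan MALDI peak lists — can be generated here with the
planted parameters recorded, so each downstream stage is testable against
truth without any external data.

Defaults emulate the study design this package targets: a filamentous
fungus grown on three carbon sources (glucose, pretreated sugarcane
bagasse, xylan), a secretome of a few hundred proteins rich in CAZymes,
high sequon occupancy, and a high-mannose glycan pool dominated by
Hex5HexNAc2 with traces up to Hex17-18.

Randomness: one master seed; each stage draws from its own substream
(numpy ``SeedSequence`` spawn keys), so stages are individually
reproducible and a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .digestion import digest
from .records import ProteinRecord, RecordError
from .sequons import scan_sequons

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: X-position alphabet for planted sequons: no Pro (OST disfavours it), and
#: no Asn/Ser/Thr so planting can never create a second, accidental sequon.
X_ALPHABET = "ACDEFGHIKLMQRVWY"
DEFAULT_CONDITIONS = ("glucose", "SCB", "xylan")
#: Planting slots are every third position: a sequon spans 3 residues, so
#: slots never overlap.
SLOT_SPACING = 3

CAZY_FAMILY_POOL = (
    "GH3", "GH5", "GH6", "GH7", "GH10", "GH11", "GH28", "GH43", "GH81",
    "CE1", "CE5", "CE16", "PL1", "PL4", "AA3", "AA7", "AA8", "AA9", "CBM1",
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    seed: int = 0
    n_proteins: int = 265
    length_range: tuple[int, int] = (200, 800)
    sequon_density: float = 0.5        # expected sequons per 100 residues
    occupancy: float = 0.9             # P(an existing sequon is glycosylated)
    coverage: float = 0.8              # P(a tryptic peptide is observed)
    missed_cleavage_rate: float = 0.1  # P(observed peptide keeps one missed cleavage)
    n_conditions: int = 3
    abundance_dispersion: float = 0.5  # Poisson-gamma overdispersion of counts
    homolog_retention: float = 0.6     # P(homolog retains a query sequon)
    indel_rate: float = 0.02           # per-column gap probability in homologs
    #: relative abundance per Hex count over Hex3..Hex18 (Hex5-dominant,
    #: traces at Hex14..Hex17, as in high-mannose fungal pools)
    glycan_weights: tuple[float, ...] = (
        1, 2, 10, 6, 4, 3, 2, 1, 0.5, 0.3, 0.2, 0.1, 0.05, 0.05, 0.05, 0.02
    )
    mass_error_sd: float = 0.05        # Da, MALDI-TOF reflector scale
    motif_preset: str | None = None
    cazy_fraction: float = 0.6         # fraction of proteins given a CAZy family
    substitution_rate: float = 0.1     # homolog divergence outside sequons

    def __post_init__(self) -> None:
        probs = {
            "occupancy": self.occupancy,
            "coverage": self.coverage,
            "missed_cleavage_rate": self.missed_cleavage_rate,
            "homolog_retention": self.homolog_retention,
            "indel_rate": self.indel_rate,
            "cazy_fraction": self.cazy_fraction,
            "substitution_rate": self.substitution_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise RecordError(f"{name}={p} outside [0, 1]")
        if self.length_range[0] < 20 or self.length_range[0] > self.length_range[1]:
            raise RecordError(f"bad length_range {self.length_range}")
        if self.sequon_density < 0 or self.mass_error_sd < 0:
            raise RecordError("sequon_density and mass_error_sd must be nonnegative")
        w = np.asarray(self.glycan_weights, dtype=float)
        if (w < 0).any() or w.sum() == 0:
            raise RecordError("glycan_weights must be nonnegative and not all zero")
        if self.n_proteins < 1 or self.n_conditions < 1:
            raise RecordError("n_proteins and n_conditions must be positive")

    def condition_names(self) -> list[str]:
        names = list(DEFAULT_CONDITIONS[: self.n_conditions])
        names += [f"condition_{i+1}" for i in range(len(names), self.n_conditions)]
        return names

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        d["glycan_weights"] = list(self.glycan_weights)
        return d


@dataclass
class GroundTruth:
    """Planted truth for downstream parameter-recovery checks."""

    #: (protein_id, 1-based Asn position) -> occupied?
    site_truth: dict[tuple[str, int], bool] = field(default_factory=dict)
    #: protein_id -> list over homologs of per-site retention draws
    homolog_retention_draws: dict[str, list[dict[int, bool]]] = field(default_factory=dict)
    #: Hex count -> planted pool proportion
    glycan_proportions: dict[int, float] = field(default_factory=dict)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [k[0] for k in self.site_truth],
                "position": [k[1] for k in self.site_truth],
                "occupied": [int(v) for v in self.site_truth.values()],
            }
        )


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _strip_sequons(seq: list[str], rng: np.random.Generator) -> None:
    """Remove every N..S/T triplet (X unrestricted) by replacing the Asn.

    Replacement residues are drawn from the X alphabet (no N/S/T/P), so a
    fix can never create a new sequon; one left-to-right pass suffices.
    """
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 2] in "ST":
            seq[i] = rng.choice(list(X_ALPHABET))


def generate_secretome(config: SimulationConfig) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate the secretome FASTA-equivalent with planted sequons.

    Background residues are uniform over the 20 standard amino acids;
    accidental sequons are stripped and the configured density is planted
    by substitution at non-overlapping slots, so the emitted sequon set is
    exactly the planted set.  Each planted site's occupied/unoccupied truth
    is drawn once here with probability ``occupancy``.
    """
    rng = _stage_rng(config.seed, 0)
    lo, hi = config.length_range
    # feasibility: a length-L protein offers ~L/3 non-overlapping slots
    max_density = 100.0 * ((lo - 2) // SLOT_SPACING) / lo
    if config.sequon_density > max_density:
        raise RecordError(
            f"sequon_density {config.sequon_density}/100aa infeasible for "
            f"length_range {config.length_range} (max ~{max_density:.1f})"
        )
    proteins: list[ProteinRecord] = []
    truth = GroundTruth()
    truth.glycan_proportions = planted_glycan_proportions(config)
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = [str(a) for a in rng.choice(list(AA20), size=length)]
        _strip_sequons(seq, rng)
        n_slots = (length - 2) // SLOT_SPACING
        p_slot = min(config.sequon_density * length / (100.0 * n_slots), 1.0)
        planted = [s for s in range(n_slots) if rng.random() < p_slot]
        pid = f"SYN_{i+1:05d}"
        for s in planted:
            pos0 = s * SLOT_SPACING  # 0-based Asn index
            seq[pos0] = "N"
            seq[pos0 + 1] = str(rng.choice(list(X_ALPHABET)))
            seq[pos0 + 2] = "T" if rng.random() < 0.5 else "S"
            truth.site_truth[(pid, pos0 + 1)] = bool(rng.random() < config.occupancy)
        is_cazy = rng.random() < config.cazy_fraction
        fams = (str(rng.choice(list(CAZY_FAMILY_POOL))),) if is_cazy else ()
        proteins.append(
            ProteinRecord(
                id=pid,
                sequence="".join(seq),
                cazy_families=fams,
                secreted=bool(rng.random() < 0.9),
                description=f"synthetic secretome protein {i+1}",
            )
        )
    return proteins, truth


def simulate_peptide_evidence(
    proteins: Sequence[ProteinRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Emit a tryptic peptide-evidence table in the classifier's dialect.

    Zero-missed tryptic peptides are each observed with probability
    ``coverage``; an observed peptide is extended into its one-missed
    variant with probability ``missed_cleavage_rate``.  Covering peptides
    of occupied sequons carry the GlcNAc remnant on the sequon Asn; Cys
    residues carry fixed carbamidomethyl; Met oxidation appears at a fixed
    low rate.  Spectrum counts are Poisson-gamma (negative-binomial-like)
    per condition around a per-protein lognormal abundance.
    """
    rng = _stage_rng(config.seed, 1)
    conditions = config.condition_names()
    occupied = {k for k, v in truth.site_truth.items() if v}
    rows = []
    for protein in proteins:
        base = digest(protein, max_missed=0, min_length=1)
        with_missed = digest(protein, max_missed=1, min_length=1)
        next_missed = {
            p.start: p for p in with_missed if p.missed_cleavages == 1
        }
        abundance = float(rng.lognormal(mean=1.5, sigma=1.0))
        for pep in base:
            if rng.random() >= config.coverage:
                continue
            if rng.random() < config.missed_cleavage_rate and pep.start in next_missed:
                pep = next_missed[pep.start]
            mods = []
            for off, aa in enumerate(pep.sequence):
                pos_in_protein = pep.start + off
                if aa == "N" and (protein.id, pos_in_protein) in occupied:
                    mods.append(("GlcNAc_remnant", off + 1))
                elif aa == "C":
                    mods.append(("carbamidomethyl", off + 1))
                elif aa == "M" and rng.random() < 0.2:
                    mods.append(("oxidation", off + 1))
            mods_text = ";".join(f"{n}@{p}" for n, p in mods)
            shape = 1.0 / config.abundance_dispersion if config.abundance_dispersion > 0 else None
            for cond in conditions:
                if shape is None:
                    count = int(rng.poisson(abundance))
                else:
                    lam = rng.gamma(shape, abundance / shape)
                    count = int(rng.poisson(lam))
                rows.append(
                    {
                        "protein_id": protein.id,
                        "peptide": pep.sequence,
                        "start": pep.start,
                        "end": pep.end,
                        "mods": mods_text,
                        "spectrum_count": count + 1,  # observed => >=1 spectrum
                        "condition": cond,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "peptide", "start", "end", "mods",
                 "spectrum_count", "condition"],
    )


def simulate_homolog_family(
    protein: ProteinRecord,
    n_homologs: int,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], list[dict[int, bool]]]:
    """Build an aligned family: query first, then diverged homologs.

    Each homolog independently retains each query sequon with probability
    ``homolog_retention`` (non-retained Asn becomes Asp); other columns
    diverge by substitution and acquire deletions at ``indel_rate``; short
    homolog-specific insertions appear as gap columns in the other rows.
    Retained sequon triplets are never mutated, deleted, or split by an
    insertion.  Returns ``(alignment rows as (id, seq), retention draws)``.
    """
    if n_homologs < 1:
        raise RecordError("n_homologs must be >= 1")
    sites = scan_sequons(protein)
    if not sites:
        raise RecordError(f"{protein.id} has no sequon; nothing to conserve")
    if rng is None:
        rng = _stage_rng(config.seed, 2)
    query = protein.sequence
    rows_chars: list[list[str | None]] = []  # None marks a deletion (gap)
    retention_draws: list[dict[int, bool]] = []
    insertions: list[dict[int, str]] = []  # per homolog: before-index -> inserted text
    for _ in range(n_homologs):
        chars: list[str | None] = list(query)
        draws: dict[int, bool] = {}
        retained_idx: set[int] = set()
        for s in sites:
            keep = bool(rng.random() < config.homolog_retention)
            draws[s.position] = keep
            if keep:
                retained_idx.update(range(s.position - 1, s.position + 2))
            else:
                chars[s.position - 1] = "D"  # Asn -> Asp destroys the sequon
        for i in range(len(chars)):
            if i in retained_idx:
                continue  # retained sequon triplets stay intact
            if rng.random() < config.substitution_rate:
                chars[i] = str(rng.choice(list(X_ALPHABET)))
            elif rng.random() < config.indel_rate:
                chars[i] = None
        ins: dict[int, str] = {}
        for i in range(len(query) + 1):
            inside_sequon = any(s.position - 1 < i < s.position + 2 for s in sites)
            if not inside_sequon and rng.random() < config.indel_rate:
                ins[i] = "".join(rng.choice(list(X_ALPHABET), size=int(rng.integers(1, 4))))
        rows_chars.append(chars)
        retention_draws.append(draws)
        insertions.append(ins)
    # merge homolog-specific insertions into common gap columns
    aligned_query = []
    aligned_rows = [[] for _ in range(n_homologs)]
    for i in range(len(query) + 1):
        for h, ins in enumerate(insertions):
            if i in ins:
                text = ins[i]
                aligned_query.extend("-" * len(text))
                for h2 in range(n_homologs):
                    aligned_rows[h2].extend(text if h2 == h else "-" * len(text))
        if i < len(query):
            aligned_query.append(query[i])
            for h in range(n_homologs):
                ch = rows_chars[h][i]
                aligned_rows[h].append(ch if ch is not None else "-")
    out = [(protein.id, "".join(aligned_query))]
    for h in range(n_homologs):
        out.append((f"{protein.id}_hom{h+1:03d}", "".join(aligned_rows[h])))
    if truth is not None:
        truth.homolog_retention_draws[protein.id] = retention_draws
    return out, retention_draws


def planted_glycan_proportions(config: SimulationConfig) -> dict[int, float]:
    w = np.asarray(config.glycan_weights, dtype=float)
    hex_counts = range(3, 3 + len(w))
    total = w.sum()
    return {h: float(x / total) for h, x in zip(hex_counts, w)}


def simulate_glycan_peaks(
    config: SimulationConfig,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """MALDI peak list for the planted permethylated Hex_nHexNAc_2 pool.

    One peak per nonzero composition and condition, at the theoretical
    sodiated m/z plus Gaussian mass error; intensities proportional to the
    planted weights with multiplicative lognormal noise.
    """
    from .glycans import GlycanComposition, permethylated_mz

    rng = _stage_rng(config.seed, 3)
    if conditions is None:
        conditions = config.condition_names()
    rows = []
    for cond in conditions:
        for h, weight in zip(range(3, 3 + len(config.glycan_weights)), config.glycan_weights):
            if weight <= 0:
                continue
            mz = permethylated_mz(GlycanComposition(h, 2))
            err = float(rng.normal(0.0, config.mass_error_sd)) if config.mass_error_sd > 0 else 0.0
            noise = float(rng.lognormal(0.0, 0.2)) if config.mass_error_sd > 0 else 1.0
            rows.append(
                {
                    "mz": mz + err,
                    "intensity": weight * noise,
                    "condition": cond,
                    "true_n_hex": h,
                }
            )
    return pd.DataFrame(rows, columns=["mz", "intensity", "condition", "true_n_hex"])


# ---------------------------------------------------------------------------
# The 151-window preset
# ---------------------------------------------------------------------------

#: (count, +1 residue constraint) blocks of the N-X-T windows: 19 NGT,
#: 12 NTT, 14 NST, remainder with X drawn outside {G, T, S, P}.
_PRESET_NXT_BLOCKS = ((19, "G"), (12, "T"), (14, "S"), (64, None))
_PRESET_N_NXS = 42
_PRESET_SEED = 151


def motif_preset(name: str) -> list[str]:
    """Named flanking-window sets with fixed motif composition.

    ``"paper-motifs"``: 151 windows reproducing the published dataset-match
    counts — 42 N-X-S and 109 N-X-T sequons, the latter including 19 with
    Gly, 12 with Thr and 14 with Ser at the X position.  Unconstrained
    positions are filled uniformly at random from a fixed internal seed, so
    the set is deterministic.
    """
    if name != "paper-motifs":
        raise RecordError(f"unknown motif preset {name!r}")
    rng = np.random.default_rng(_PRESET_SEED)
    # X draw for the unconstrained N-X-T block must avoid G/T/S so the
    # fixed NGT/NTT/NST tallies stay exact; P is excluded as always.
    other_x_nxt = [a for a in X_ALPHABET if a != "G"]

    def fill(x: str | None, plus2: str) -> str:
        flanks = rng.choice(list(AA20), size=12)
        left = "".join(flanks[:6])
        right = "".join(flanks[6:10])
        if x is None:
            pool = other_x_nxt if plus2 == "T" else list(X_ALPHABET)
            x = str(rng.choice(pool))
        return left + "n" + x + plus2 + right

    windows = []
    for count, x in _PRESET_NXT_BLOCKS:
        for _ in range(count):
            windows.append(fill(x, "T"))
    for _ in range(_PRESET_N_NXS):
        windows.append(fill(None, "S"))
    assert len(windows) == 151 and all(len(w) == 13 for w in windows)
    return windows
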