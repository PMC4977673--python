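"""Generator determinism, planted-parameter recovery and round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nglyc.classify import classify_sites
from nglyc.records import ProteinRecord, RecordError, write_fasta
from nglyc.sequons import scan_all, scan_sequons
from nglyc.simulate import (
    SLOT_SPACING,
    SimulationConfig,
    generate_secretome,
    motif_preset,
    planted_glycan_proportions,
    simulate_glycan_peaks,
    simulate_homolog_family,
    simulate_peptide_evidence,
)


def _fasta_bytes(proteins):
    return "".join(f">{p.id} {p.description}\n{p.sequence}\n" for p in proteins)


def test_fixed_seed_is_byte_identical():
    cfg = SimulationConfig(seed=1, n_proteins=10)
    a_prot, a_truth = generate_secretome(cfg)
    b_prot, b_truth = generate_secretome(cfg)
    assert _fasta_bytes(a_prot) == _fasta_bytes(b_prot)
    assert a_truth.site_truth == b_truth.site_truth
    ev_a = simulate_peptide_evidence(a_prot, a_truth, cfg)
    ev_b = simulate_peptide_evidence(b_prot, b_truth, cfg)
    pd.testing.assert_frame_equal(ev_a, ev_b)
    pd.testing.assert_frame_equal(simulate_glycan_peaks(cfg), simulate_glycan_peaks(cfg))


def test_different_seeds_differ():
    a, _ = generate_secretome(SimulationConfig(seed=1, n_proteins=5))
    b, _ = generate_secretome(SimulationConfig(seed=2, n_proteins=5))
    assert _fasta_bytes(a) != _fasta_bytes(b)


def test_zero_density_means_no_sequons():
    cfg = SimulationConfig(seed=3, n_proteins=30, sequon_density=0.0)
    proteins, truth = generate_secretome(cfg)
    assert truth.site_truth == {}
    for p in proteins:
        assert scan_sequons(p) == []


def test_emitted_sequons_are_exactly_the_planted_set(small_secretome):
    proteins, truth = small_secretome
    scanned = {s.key for s in scan_all(proteins)}
    assert scanned == set(truth.site_truth)


def test_density_recovery_within_three_standard_errors():
    cfg = SimulationConfig(seed=1, n_proteins=200, sequon_density=1.5)
    proteins, truth = generate_secretome(cfg)
    total_res = sum(len(p) for p in proteins)
    observed = 100.0 * len(truth.site_truth) / total_res
    # planting model: per protein, Binomial(n_slots, p_slot) sequons
    var = 0.0
    for p in proteins:
        n_slots = (len(p) - 2) // SLOT_SPACING
        p_slot = min(cfg.sequon_density * len(p) / (100.0 * n_slots), 1.0)
        var += n_slots * p_slot * (1 - p_slot)
    se = 100.0 * np.sqrt(var) / total_res
    assert abs(observed - 1.5) <= 3 * se


def test_infeasible_density_rejected():
    with pytest.raises(RecordError):
        generate_secretome(SimulationConfig(seed=1, sequon_density=40.0))


def test_invalid_configs_rejected():
    with pytest.raises(RecordError):
        SimulationConfig(occupancy=1.5)
    with pytest.raises(RecordError):
        SimulationConfig(length_range=(10, 100))
    with pytest.raises(RecordError):
        SimulationConfig(glycan_weights=(0.0, 0.0))
    with pytest.raises(RecordError):
        SimulationConfig(glycan_weights=(-1.0, 2.0))


def test_full_coverage_full_occupancy_tags_every_covering_peptide():
    cfg = SimulationConfig(seed=2, n_proteins=10, coverage=1.0, occupancy=1.0,
                           length_range=(100, 200))
    proteins, truth = generate_secretome(cfg)
    evidence = simulate_peptide_evidence(proteins, truth, cfg)
    sites = scan_all(proteins)
    assert sites
    for site in sites:
        covering = evidence[
            (evidence["protein_id"] == site.protein_id)
            & (evidence["start"] <= site.position)
            & (evidence["end"] >= site.position)
        ]
        assert len(covering) > 0, "coverage=1 must cover every sequon"
        for mods, start in zip(covering["mods"], covering["start"]):
            assert f"GlcNAc_remnant@{site.position - start + 1}" in mods


def test_zero_coverage_gives_empty_evidence():
    cfg = SimulationConfig(seed=2, n_proteins=5, coverage=0.0)
    proteins, truth = generate_secretome(cfg)
    assert simulate_peptide_evidence(proteins, truth, cfg).empty


def test_evidence_peptides_are_legal_tryptic_slices(small_secretome, small_config):
    from nglyc.digestion import cleavage_sites
    proteins, truth = small_secretome
    evidence = simulate_peptide_evidence(proteins, truth, small_config)
    by_id = {p.id: p for p in proteins}
    for row in evidence.itertuples(index=False):
        seq = by_id[row.protein_id].sequence
        assert seq[row.start - 1: row.end] == row.peptide
        cuts = set(cleavage_sites(seq))
        # peptide boundaries are cleavage sites or protein termini
        assert row.start == 1 or (row.start - 2) in cuts
        assert row.end == len(seq) or (row.end - 1) in cuts
        internal = sum(1 for c in cuts if row.start - 1 <= c < row.end - 1)
        assert internal <= 1


def test_occupancy_recovered_within_exact_binomial_ci():
    """Planted occupancy 0.7: the validated fraction of covered sites lies
    in the exact (Clopper-Pearson) 99 % interval around 0.7."""
    cfg = SimulationConfig(seed=6, n_proteins=300, coverage=1.0, occupancy=0.7,
                           length_range=(150, 400), sequon_density=0.8)
    proteins, truth = generate_secretome(cfg)
    assert len(truth.site_truth) >= 500
    evidence = simulate_peptide_evidence(proteins, truth, cfg)
    sites = classify_sites(scan_all(proteins), evidence)
    covered = [s for s in sites if s.status != "non_covered"]
    k = sum(1 for s in covered if s.status == "validated")
    n = len(covered)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.7) / n
    assert lo <= k / n <= hi


def test_homolog_retention_mean_near_planted():
    cfg = SimulationConfig(seed=8, homolog_retention=0.9)
    protein = ProteinRecord(id="Q", sequence="AAKNCTAAAKLNGSAAAKRMMNATLLKAAA")
    counts = []
    rng = np.random.default_rng(8)
    for _ in range(60):
        _, draws = simulate_homolog_family(protein, 20, cfg, rng=rng)
        for site in scan_sequons(protein):
            counts.append(sum(d[site.position] for d in draws))
    mean = np.mean(counts)
    se = np.sqrt(20 * 0.9 * 0.1) / np.sqrt(len(counts))
    assert abs(mean - 18.0) <= 3 * se


def test_homologs_keep_retained_sequons_and_respect_truth():
    cfg = SimulationConfig(seed=9, homolog_retention=0.5, indel_rate=0.05)
    protein = ProteinRecord(id="Q", sequence="AAKNCTAAAKLNGSAAAKRMMNATLLKAAA")
    rows, draws = simulate_homolog_family(protein, 30, cfg)
    from nglyc.conservation import HomologAlignment, map_site_to_column, site_conserved_in
    msa = HomologAlignment(ids=[r[0] for r in rows], rows=[r[1] for r in rows],
                           query_id="Q")
    assert msa.degapped_query() == protein.sequence
    for h, draw in enumerate(draws):
        hid = rows[h + 1][0]
        for site in scan_sequons(protein):
            col = map_site_to_column(msa, site.position)
            ok, off = site_conserved_in(msa, hid, col)
            assert ok == draw[site.position]
            if ok:
                assert off == 0


def test_homolog_family_requires_sequon_and_homologs():
    cfg = SimulationConfig(seed=1)
    with pytest.raises(RecordError):
        simulate_homolog_family(ProteinRecord(id="q", sequence="AAAAA"), 5, cfg)
    protein = ProteinRecord(id="q", sequence="AANATAA")
    with pytest.raises(RecordError):
        simulate_homolog_family(protein, 0, cfg)


def test_glycan_peaks_zero_noise_single_composition():
    from nglyc.glycans import GlycanComposition, permethylated_mz
    weights = tuple(1.0 if h == 5 else 0.0 for h in range(3, 19))
    cfg = SimulationConfig(seed=1, glycan_weights=weights, mass_error_sd=0.0,
                           n_conditions=1)
    peaks = simulate_glycan_peaks(cfg)
    assert len(peaks) == 1
    assert peaks.loc[0, "mz"] == pytest.approx(
        permethylated_mz(GlycanComposition(5, 2)), abs=1e-9)


def test_glycan_round_trip_recovers_planted_pool():
    from nglyc.glycans import assign_compositions
    cfg = SimulationConfig(seed=12)
    peaks = simulate_glycan_peaks(cfg)
    out = assign_compositions(peaks, tolerance_da=0.2)
    planted = planted_glycan_proportions(cfg)
    for a, true_h in zip(out, peaks["true_n_hex"]):
        assert a.composition is not None
        assert a.composition.n_hex == true_h
    assert set(planted) >= {a.composition.n_hex for a in out}


def test_preset_unconstrained_positions_vary():
    w = motif_preset("paper-motifs")
    first_cols = {x[0] for x in w}
    assert len(first_cols) > 5  # filled at random, not constant
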