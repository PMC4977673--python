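"""Column mapping, per-homolog sequon verdicts and conservation percentages."""

import numpy as np
import pytest

from nglyc.conservation import (
    HomologAlignment,
    conservation_percent,
    map_site_to_column,
    site_conserved_in,
)
from nglyc.records import ProteinRecord, RecordError, SequonSite
from nglyc.sequons import scan_sequons
from nglyc.simulate import SimulationConfig, simulate_homolog_family

AA = "ACDEFGHIKLMNPQRSTVWY"


def _msa(rows, query_id=None):
    ids = [r[0] for r in rows]
    return HomologAlignment(ids=ids, rows=[r[1] for r in rows],
                            query_id=query_id or ids[0])


def _sites(seq, pid="Q"):
    return scan_sequons(ProteinRecord(id=pid, sequence=seq))


def test_gapless_column_is_position_minus_one():
    msa = _msa([("Q", "AANATAA"), ("H", "AANATAA")])
    assert map_site_to_column(msa, 3) == 2


def test_leading_gaps_shift_columns():
    msa = _msa([("Q", "---AANATAA"), ("H", "CCCAANATAA")])
    assert map_site_to_column(msa, 3) == 5  # position + 2 for 3 leading gaps


def test_column_mapping_agrees_with_degapped_prefix_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(5, 60))
        chars = list(rng.choice(list(AA), size=n))
        gap_positions = rng.random(n) < 0.3
        row = "".join("-" if g else c for c, g in zip(chars, gap_positions))
        degapped = row.replace("-", "")
        if not degapped:
            continue
        msa = _msa([("Q", row), ("H", "A" * len(row))])
        for pos in range(1, len(degapped) + 1):
            col = map_site_to_column(msa, pos)
            # oracle: degapped prefix length up to and including col
            assert len(row[: col + 1].replace("-", "")) == pos
            assert row[col] != "-"
        with pytest.raises(IndexError):
            map_site_to_column(msa, len(degapped) + 1)


def test_identical_homolog_conserves_with_zero_offset():
    msa = _msa([("Q", "AANATAA"), ("H", "AANATAA")])
    ok, off = site_conserved_in(msa, "H", 2)
    assert ok and off == 0


def test_destroyed_sequon_is_not_conserved():
    msa = _msa([("Q", "AANATAA"), ("H", "AADATAA")])  # Asn -> Asp
    ok, off = site_conserved_in(msa, "H", 2)
    assert not ok and off is None


def test_proline_x_sequon_requires_flag():
    msa = _msa([("Q", "AANATAA"), ("H", "AANPTAA")])
    assert not site_conserved_in(msa, "H", 2)[0]
    assert site_conserved_in(msa, "H", 2, allow_proline_X=True)[0]


def test_shifted_sequon_needs_tolerance():
    # homolog sequon sits 2 columns downstream of the query site column
    msa = _msa([
        ("Q", "AANATAAAA"),
        ("H", "AAGG-NATA"),
    ])
    col = map_site_to_column(msa, 3)
    assert col == 2
    assert not site_conserved_in(msa, "H", col, window_tol=0)[0]
    assert not site_conserved_in(msa, "H", col, window_tol=2)[0]
    ok, off = site_conserved_in(msa, "H", col, window_tol=3)
    assert ok and off == 3


def test_tolerance_is_monotone(rng):
    cfg = SimulationConfig(seed=3, indel_rate=0.05, homolog_retention=0.7)
    protein = ProteinRecord(id="Q", sequence="AAKNCTAAAKLNGSAAAKRMMNATLLK")
    rows, _ = simulate_homolog_family(protein, 15, cfg)
    msa = _msa(rows)
    for site in scan_sequons(protein):
        col = map_site_to_column(msa, site.position)
        prev = set()
        for tol in range(4):
            cur = {h for h in msa.homolog_ids()
                   if site_conserved_in(msa, h, col, window_tol=tol)[0]}
            assert prev <= cur
            prev = cur


def test_table3_style_fixture_percentages():
    """20 homologs with 18 and 19 retaining the two sequons -> 90.0 / 95.0."""
    query = "AANSSAAAAAANATAAAA"  # sites at 3 (NSS) and 12 (NAT)
    rows = [("Q", query)]
    for h in range(20):
        s = list(query)
        if h < 2:
            s[2] = "D"   # destroy first sequon in 2 homologs
        if h < 1:
            s[11] = "D"  # destroy second sequon in 1 homolog
        rows.append((f"H{h}", "".join(s)))
    results = conservation_percent(_msa(rows), _sites(query))
    by_pos = {r.site.position: r for r in results}
    assert by_pos[3].n_homologs == 20 and by_pos[3].n_conserved == 18
    assert by_pos[3].conservation_pct == pytest.approx(90.0)
    assert by_pos[12].conservation_pct == pytest.approx(95.0)


def test_full_retention_gives_100_percent():
    cfg = SimulationConfig(seed=4, homolog_retention=1.0, indel_rate=0.0)
    protein = ProteinRecord(id="Q", sequence="AAKNCTAAAKLNGSAAAKR")
    rows, _ = simulate_homolog_family(protein, 10, cfg)
    results = conservation_percent(_msa(rows), scan_sequons(protein))
    assert all(r.conservation_pct == 100.0 for r in results)
    # sequon columns identical to query in every homolog
    msa = _msa(rows)
    for site in scan_sequons(protein):
        col = map_site_to_column(msa, site.position)
        assert all(row[col] == "N" for row in msa.rows)


def test_zero_retention_gives_0_percent():
    cfg = SimulationConfig(seed=5, homolog_retention=0.0)
    protein = ProteinRecord(id="Q", sequence="AAKNCTAAAKLNGSAAAKR")
    rows, _ = simulate_homolog_family(protein, 10, cfg)
    results = conservation_percent(_msa(rows), scan_sequons(protein))
    assert all(r.conservation_pct == 0.0 for r in results)


def test_invariant_under_all_gap_column_insertion():
    query = "AANSSAAAAAANATAAAA"
    rows = [("Q", query), ("H1", query), ("H2", query.replace("NSS", "DSS"))]
    base = conservation_percent(_msa(rows), _sites(query))
    padded = [(rid, seq[:5] + "---" + seq[5:] + "--") for rid, seq in rows]
    shifted = conservation_percent(_msa(padded), _sites(query))
    assert [r.conservation_pct for r in base] == [r.conservation_pct for r in shifted]


def test_alignment_validation():
    with pytest.raises(RecordError):
        HomologAlignment(ids=["a", "b"], rows=["AAA", "AA"], query_id="a")
    with pytest.raises(RecordError):
        HomologAlignment(ids=["a"], rows=["AAA"], query_id="missing")
    with pytest.raises(RecordError):
        conservation_percent(_msa([("Q", "AANAT")]), _sites("AANAT"))
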