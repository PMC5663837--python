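"""Seed-match scanning, junction wrap-around, and ceRNA network assembly."""

import numpy as np
import pytest

from circkit.sponge import (
    MATCH_CLASSES,
    MiRNA,
    SeedMatch,
    build_network,
    circ_junction_site_scan,
    reverse_complement,
    scan_seed_sites,
    top_regulator_mirnas,
    verify_match,
)

MIR16 = MiRNA("hsa-miR-16", "UAGCAGCACGUAAAUAUUGGCG")
LET7 = MiRNA("let-7", "UGAGGUAGUAGGUUGUAUAGUU")


def naive_scan(circ_seq, mirnas, min_class, circular=False):
    """Brute-force oracle: direct substring comparison at every offset."""
    seq = circ_seq.upper().replace("U", "T")
    L = len(seq)
    rank = {c: i for i, c in enumerate(MATCH_CLASSES)}
    results = set()
    for mir in mirnas:
        pat = {
            "6mer": reverse_complement(mir.sequence[1:7]),
            "7mer-A1": reverse_complement(mir.sequence[1:7]) + "A",
            "7mer-m8": reverse_complement(mir.sequence[1:8]),
            "8mer": reverse_complement(mir.sequence[1:8]) + "A",
        }
        core = pat["6mer"]
        positions = range(L) if circular else range(L - 5)
        for j in positions:
            def at(k):
                return seq[(j + k) % L] if circular else (
                    seq[j + k] if 0 <= j + k < L else None
                )
            if any(at(k) != core[k] for k in range(6)):
                continue
            m8 = at(-1) == pat["7mer-m8"][0]
            a1 = at(6) == "A"
            cls = "8mer" if (m8 and a1) else "7mer-m8" if m8 else "7mer-A1" if a1 else "6mer"
            if rank[cls] < rank[min_class]:
                continue
            start = (j - 1) % L if m8 and circular else (j - 1 if m8 else j)
            results.add((mir.mirna_id, start, cls))
    return results


class TestScanSeedSites:
    def test_mir16_seed_site_found_as_7mer_m8(self):
        # reverse complement of miR-16 seed (positions 2-8, AGCAGCA) is TGCTGCT
        circ = "CCCCCTGCTGCTCCCCC"
        (m,) = scan_seed_sites(circ, [MIR16], min_class="7mer-m8")
        assert (m.mirna_id, m.site_start, m.match_class) == ("hsa-miR-16", 5, "7mer-m8")

    def test_a1_anchor_upgrades_to_8mer(self):
        (m,) = scan_seed_sites("CCCCCTGCTGCTACCCC", [MIR16], min_class="7mer-m8")
        assert m.match_class == "8mer" and m.site_len == 8

    def test_sequence_without_complement_is_empty(self):
        assert scan_seed_sites("A" * 100, [MIR16], min_class="6mer") == []

    def test_n_positions_never_match(self):
        assert scan_seed_sites("CCCCCTGCNGCTCCCC", [MIR16], min_class="6mer") == []

    def test_empty_sequence_is_empty_not_error(self):
        assert scan_seed_sites("", [MIR16]) == []

    def test_overlapping_sites_are_all_reported(self):
        circ = "TGCTGCTGCTGCT"  # overlapping TGCTGCT / GCTGCT occurrences
        got = {(m.site_start, m.match_class)
               for m in scan_seed_sites(circ, [MIR16], min_class="6mer")}
        assert len(got) >= 2

    @pytest.mark.parametrize("min_class", list(MATCH_CLASSES))
    def test_matches_brute_force_oracle(self, min_class):
        rng = np.random.default_rng(23)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            mirnas = [
                MiRNA(f"m{i}", "".join(rng.choice(list("ACGU"), size=22)))
                for i in range(8)
            ]
            got = {
                (m.mirna_id, m.site_start, m.match_class)
                for m in scan_seed_sites(seq, mirnas, min_class)
            }
            assert got == naive_scan(seq, mirnas, min_class)

    def test_match_sets_shrink_with_stricter_class(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        mirnas = [MiRNA(f"m{i}", "".join(rng.choice(list("ACGU"), size=21)))
                  for i in range(20)]
        counts = [len(scan_seed_sites(seq, mirnas, c)) for c in MATCH_CLASSES]
        assert counts[0] >= counts[1] >= counts[2] >= counts[3]

    def test_every_report_reverifies_by_reverse_complement(self):
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        mirnas = [MiRNA(f"m{i}", "".join(rng.choice(list("ACGU"), size=22)))
                  for i in range(10)]
        by_id = {m.mirna_id: m for m in mirnas}
        matches = scan_seed_sites(seq, mirnas, "6mer", circular=True)
        assert matches and all(verify_match(seq, by_id[m.mirna_id], m) for m in matches)


class TestJunctionScan:
    def test_site_split_across_junction_is_found(self):
        # TGCTGCT split 4+3: sequence ends with TGCT and starts with GCT
        pattern = reverse_complement(MIR16.sequence[1:8])  # TGCTGCT
        seq = pattern[4:] + "CCCCCCCCCCCCCCCC" + pattern[:4]
        L = len(seq)
        (m,) = circ_junction_site_scan(seq, [MIR16], min_class="7mer-m8")
        assert m.site_start == L - 4
        assert m.site_start + m.site_len > L

    def test_linear_scan_misses_the_junction_site(self):
        pattern = reverse_complement(MIR16.sequence[1:8])
        seq = pattern[4:] + "CCCCCCCCCCCCCCCC" + pattern[:4]
        assert scan_seed_sites(seq, [MIR16], "7mer-m8", circular=False) == []

    def test_rotation_shifts_sites_and_preserves_counts(self):
        rng = np.random.default_rng(77)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        mirnas = [MiRNA(f"m{i}", "".join(rng.choice(list("ACGU"), size=22)))
                  for i in range(6)]
        base = {
            (m.mirna_id, m.site_start, m.match_class)
            for m in scan_seed_sites(seq, mirnas, "6mer", circular=True)
        }
        for k in (1, 13, 150, 299):
            rotated = seq[k:] + seq[:k]
            got = {
                (m.mirna_id, (m.site_start + k) % len(seq), m.match_class)
                for m in scan_seed_sites(rotated, mirnas, "6mer", circular=True)
            }
            assert got == base

    def test_circular_scan_agrees_with_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=250))
            mirnas = [MiRNA(f"m{i}", "".join(rng.choice(list("ACGU"), size=22)))
                      for i in range(6)]
            got = {
                (m.mirna_id, m.site_start, m.match_class)
                for m in scan_seed_sites(seq, mirnas, "6mer", circular=True)
            }
            assert got == naive_scan(seq, mirnas, "6mer", circular=True)


class TestNetwork:
    def test_counting_example(self):
        matches = [
            SeedMatch("circ1", "mir1", 0, 7, "7mer-m8"),
            SeedMatch("circ1", "mir2", 10, 7, "7mer-m8"),
        ]
        table = [("mir1", "geneA"), ("mir2", "geneB")]
        g = build_network(matches, table)
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 4

    def test_empty_restriction_empties_gene_layer_only(self):
        matches = [SeedMatch("circ1", "mir1", 0, 7, "7mer-m8")]
        g = build_network(matches, [("mir1", "geneA")], restrict_genes=set())
        types = {d["node_type"] for _, d in g.nodes(data=True)}
        assert types == {"circRNA", "miRNA"}
        assert g.number_of_edges() == 1

    def test_duplicate_edges_collapse_with_multiplicity(self):
        matches = [
            SeedMatch("circ1", "mir1", 0, 7, "7mer-m8"),
            SeedMatch("circ1", "mir1", 50, 8, "8mer"),
        ]
        g = build_network(matches, [])
        assert g.number_of_edges() == 1
        assert g["circ1"]["mir1"]["multiplicity"] == 2

    def test_unmatched_mirnas_stay_out_of_the_network(self):
        matches = [SeedMatch("circ1", "mir1", 0, 7, "7mer-m8")]
        g = build_network(matches, [("mir_other", "geneZ")])
        assert "mir_other" not in g and "geneZ" not in g

    def test_counts_equal_relational_join_oracle(self):
        rng = np.random.default_rng(19)
        circs = [f"c{i}" for i in range(15)]
        mirs = [f"m{i}" for i in range(10)]
        genes = [f"g{i}" for i in range(12)]
        matches = [
            SeedMatch(circs[rng.integers(15)], mirs[rng.integers(10)],
                      int(rng.integers(100)), 7, "7mer-m8")
            for _ in range(60)
        ]
        table = [(mirs[rng.integers(10)], genes[rng.integers(12)]) for _ in range(40)]
        g = build_network(matches, table)
        cm = {(m.circ_id, m.mirna_id) for m in matches}
        matched = {m.mirna_id for m in matches}
        mg = {(a, b) for a, b in table if a in matched}
        exp_nodes = ({c for c, _ in cm} | {m for _, m in cm} | {b for _, b in mg})
        assert g.number_of_edges() == len(cm) + len(mg)
        assert g.number_of_nodes() == len(exp_nodes)


class TestTopRegulators:
    def test_planted_high_degree_mirna_ranks_first(self):
        matches = [SeedMatch(f"c{i}", "hub", 0, 7, "7mer-m8") for i in range(10)]
        for i in range(3):
            matches.append(SeedMatch(f"c{i}", "minor", 5, 7, "7mer-m8"))
        ranked = top_regulator_mirnas(matches)
        assert ranked[0] == ("hub", 10)

    def test_k_larger_than_mirna_count_returns_all(self):
        matches = [SeedMatch("c1", "m1", 0, 7, "7mer-m8")]
        assert top_regulator_mirnas(matches, k=100) == [("m1", 1)]

    def test_empty_matches(self):
        assert top_regulator_mirnas([]) == []

    def test_distinct_circ_degree_not_site_count(self):
        matches = [
            SeedMatch("c1", "m1", i, 7, "7mer-m8") for i in range(5)  # 5 sites, 1 circ
        ] + [SeedMatch(f"c{i}", "m2", 0, 7, "7mer-m8") for i in range(2)]
        assert top_regulator_mirnas(matches)[0] == ("m2", 2)
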