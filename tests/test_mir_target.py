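"""Seed-site scanning, duplex MFE dynamic programming (vs exhaustive
enumeration), and seed mutagenesis."""

import numpy as np
import pytest

from ilc2kit.mir_target import (
    _CAN_PAIR,
    DuplexResult,
    RnaFormatError,
    RnaSeq,
    duplex_mfe,
    load_energy_params,
    mutate_seed,
    read_fasta,
    revcomp,
    scan_seed_sites,
    write_fasta,
)
from ilc2kit.synthetic_data import simulate_utr


# ---------------------------------------------------------------------------
# independent exhaustive oracle for duplex hybridization


def oracle_mfe(mseq: str, tseq: str, max_loop: int = 15) -> float:
    """Enumerate every legal antiparallel pairing chain and score it
    directly from the parameter table (independent of the DP)."""
    tab = load_energy_params()

    def pairable(a, b):
        return (a, b) in _CAN_PAIR

    def terminal(a, b):
        return tab["terminal_au"] if (a, b) in {("A", "U"), ("U", "A"),
                                               ("G", "U"), ("U", "G")} else 0.0

    def loop(size, kind):
        table = tab[kind]
        if size in table:
            return table[size]
        base = max(table)
        return table[base] + tab["loop_extrapolation_coef"] * np.log(size / base)

    def gap(i1, j1, i2, j2):
        li, lj = i2 - i1 - 1, j1 - j2 - 1
        if li > max_loop or lj > max_loop:
            return None
        if li == 0 and lj == 0:
            key = f"{mseq[i1]}{mseq[i2]}/{tseq[j1]}{tseq[j2]}"
            x, y, _, z, w = key
            return tab["stack"].get(key, tab["stack"].get(f"{w}{z}/{y}{x}"))
        if li == 0 or lj == 0:
            return loop(li + lj, "bulge")
        return (loop(li + lj, "internal")
                + min(tab["internal_asymmetry"] * abs(li - lj),
                      tab["internal_asymmetry_max"]))

    pairs = [(i, j) for i in range(len(mseq)) for j in range(len(tseq))
             if pairable(mseq[i], tseq[j])]
    best = [0.0]

    def extend(chain, energy):
        i0, j0 = chain[-1]
        total = energy + terminal(mseq[i0], tseq[j0])
        if total < best[0]:
            best[0] = total
        for (i, j) in pairs:
            if i > i0 and j < j0:
                g = gap(i0, j0, i, j)
                if g is not None:
                    extend(chain + [(i, j)], energy + g)

    for (i, j) in pairs:
        extend([(i, j)], tab["duplex_init"] + terminal(mseq[i], tseq[j]))
    return best[0]


class TestRnaSeq:
    def test_t_converted_and_validated(self):
        assert RnaSeq("x", "acgt").seq == "ACGU"
        with pytest.raises(RnaFormatError):
            RnaSeq("x", "ACGN")
        with pytest.raises(RnaFormatError):
            RnaSeq("x", "")

    def test_fasta_round_trip(self, tmp_path, mir3p, mir5p):
        write_fasta([mir3p, mir5p], tmp_path / "m.fa")
        back = read_fasta(tmp_path / "m.fa")
        assert [(r.id, r.seq) for r in back] == [
            (mir3p.id, mir3p.seq), (mir5p.id, mir5p.seq)]


class TestScanner:
    def test_forced_8mer(self, mir3p):
        # UTR = complement of miR positions 8..2 plus A opposite pos 1
        site = revcomp(mir3p.seq[1:8]) + "A"
        utr = RnaSeq("u", "CGCG" + site + "CGCG")
        hits = scan_seed_sites(utr, mir3p)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].site_class) == (4, 12, "8mer")
        assert hits[0].matched == site

    def test_no_core_no_hits(self, mir3p):
        assert scan_seed_sites(RnaSeq("u", "CCCCCCCCCCCC"), mir3p) == []

    def test_class_filter(self, mir3p):
        site = revcomp(mir3p.seq[1:8]) + "A"
        utr = RnaSeq("u", "CGCG" + site + "CGCG")
        assert scan_seed_sites(utr, mir3p, {"6mer"}) == []
        assert len(scan_seed_sites(utr, mir3p, {"8mer"})) == 1

    def test_round_trip_with_simulator(self, mir5p):
        utr, implants = simulate_utr(mir5p.seq, 3, "7mer-m8", 300, seed=8)
        hits = scan_seed_sites(RnaSeq("u", utr), mir5p)
        assert [(h.start, h.end) for h in hits] == implants
        assert all(h.site_class == "7mer-m8" for h in hits)

    def test_flank_shift_invariance(self, mir3p):
        utr, _ = simulate_utr(mir3p.seq, 2, "8mer", 150, seed=13)
        base = scan_seed_sites(RnaSeq("u", utr), mir3p)
        flank = "CGGC" * 3
        shifted = scan_seed_sites(RnaSeq("u", flank + utr + flank), mir3p)
        assert [(h.start - len(flank), h.end - len(flank),
                 h.site_class) for h in shifted] == [
            (h.start, h.end, h.site_class) for h in base]

    def test_overlapping_sites_sorted(self, mir3p):
        core = revcomp(mir3p.seq[1:7])
        utr = RnaSeq("u", core + core + "CC")
        hits = scan_seed_sites(utr, mir3p)
        assert [h.start for h in hits] == sorted(h.start for h in hits)
        assert len(hits) == 2


class TestDuplex:
    def test_no_complementarity_zero(self):
        res = duplex_mfe(RnaSeq("m", "AAAA"), RnaSeq("t", "CCCC"))
        assert res == DuplexResult(mfe=0.0, pairing=[], alignment="")

    def test_single_stack_hand_sum(self):
        tab = load_energy_params()
        res = duplex_mfe(RnaSeq("m", "GC"), RnaSeq("t", "GC"))
        expected = (tab["stack"]["GC/CG"] + tab["duplex_init"])
        assert res.mfe == pytest.approx(expected, abs=1e-12)
        assert res.pairing == [(0, 1), (1, 0)]

    def test_au_stack_hand_sum_with_terminals(self):
        tab = load_energy_params()
        # 5'UA3' / 3'AU5' : one UA/AU stack, both ends are A-U pairs
        res = duplex_mfe(RnaSeq("m", "UA"), RnaSeq("t", "UA"))
        expected = (tab["stack"]["UA/AU"] + tab["duplex_init"]
                    + 2 * tab["terminal_au"])
        assert res.mfe == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            m = "".join(rng.choice(list("ACGU"), rng.integers(2, 9)))
            t = "".join(rng.choice(list("ACGU"), rng.integers(2, 9)))
            dp = duplex_mfe(RnaSeq("m", m), RnaSeq("t", t)).mfe
            assert dp == pytest.approx(oracle_mfe(m, t), abs=1e-9), (m, t)

    def test_pairing_is_antiparallel_chain(self, mir3p):
        target = RnaSeq("t", revcomp(mir3p.seq))
        res = duplex_mfe(mir3p, target)
        mi = [p[0] for p in res.pairing]
        tj = [p[1] for p in res.pairing]
        assert mi == sorted(mi)
        assert tj == sorted(tj, reverse=True)
        assert res.mfe < -15  # perfect complement is very stable

    def test_extension_never_raises_mfe(self):
        """Appending a complementary base pair at the duplex end can
        only stabilize (stack energies are negative for WC pairs)."""
        rng = np.random.default_rng(5)
        comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
        for _ in range(15):
            m = "".join(rng.choice(list("ACGU"), 6))
            t = revcomp(m)
            e_base = duplex_mfe(RnaSeq("m", m), RnaSeq("t", t)).mfe
            ext = "G"
            m2 = m + ext
            t2 = comp[ext] + t
            e_ext = duplex_mfe(RnaSeq("m", m2), RnaSeq("t", t2)).mfe
            assert e_ext <= e_base + 1e-9

    def test_perfect_beats_single_mismatch(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            m = "".join(rng.choice(list("ACGU"), 8))
            t = revcomp(m)
            e_perfect = duplex_mfe(RnaSeq("m", m), RnaSeq("t", t)).mfe
            k = int(rng.integers(2, 6))
            bad = {"A": "C", "C": "A", "G": "A", "U": "C"}[t[k]]
            t_mut = t[:k] + bad + t[k + 1:]
            e_mut = duplex_mfe(RnaSeq("m", m), RnaSeq("t", t_mut)).mfe
            assert e_perfect < e_mut - 1e-9

    def test_alignment_rendering(self, mir3p):
        res = duplex_mfe(mir3p, RnaSeq("t", revcomp(mir3p.seq)))
        lines = res.alignment.splitlines()
        assert len(lines) == 4
        assert lines[0].startswith("target 5'")
        assert lines[3].startswith("miRNA  3'")


class TestMutateSeed:
    def test_abolishes_and_is_local(self, mir3p):
        utr_str, _ = simulate_utr(mir3p.seq, 2, "8mer", 220, seed=3)
        utr = RnaSeq("u", utr_str)
        hits = scan_seed_sites(utr, mir3p)
        assert len(hits) == 2
        mutated = mutate_seed(utr, hits[0], mir3p, seed=1)
        new_hits = scan_seed_sites(mutated, mir3p)
        # the mutated interval is clean, the other site survives
        assert not any(h.start < hits[0].end and h.end > hits[0].start
                       for h in new_hits)
        assert any((h.start, h.end) == (hits[1].start, hits[1].end)
                   for h in new_hits)

    def test_minimal_substitutions(self, mir3p):
        utr_str, _ = simulate_utr(mir3p.seq, 1, "8mer", 120, seed=6)
        utr = RnaSeq("u", utr_str)
        site = scan_seed_sites(utr, mir3p)[0]
        mutated = mutate_seed(utr, site, mir3p, seed=2)
        n_changed = sum(a != b for a, b in zip(utr.seq, mutated.seq))
        assert 1 <= n_changed <= 3

    def test_does_not_lower_duplex_mfe(self, mir3p):
        utr_str, _ = simulate_utr(mir3p.seq, 1, "8mer", 120, seed=7)
        utr = RnaSeq("u", utr_str)
        site = scan_seed_sites(utr, mir3p)[0]
        mutated = mutate_seed(utr, site, mir3p, seed=3)
        lo, hi = max(0, site.start - 10), min(len(utr.seq), site.end + 10)
        e_wt = duplex_mfe(mir3p, RnaSeq("w", utr.seq[lo:hi])).mfe
        e_mut = duplex_mfe(mir3p, RnaSeq("w", mutated.seq[lo:hi])).mfe
        assert e_mut >= e_wt - 1e-9

    def test_determinism(self, mir3p):
        utr_str, _ = simulate_utr(mir3p.seq, 1, "8mer", 120, seed=9)
        utr = RnaSeq("u", utr_str)
        site = scan_seed_sites(utr, mir3p)[0]
        assert (mutate_seed(utr, site, mir3p, seed=4).seq
                == mutate_seed(utr, site, mir3p, seed=4).seq)
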