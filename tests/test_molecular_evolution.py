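"""Codon-level Ka/Ks checked against brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from genefamkit.genetics import SENSE_CODONS, STOP_CODONS, codons_of
from genefamkit.io_formats import CdsRecord, ValidationError
from genefamkit.molecular_evolution import (
    CodonAlignment, SaturationError, codon_align, date_pair, jukes_cantor,
    kaks, ng86_counts,
)


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> float:
    """Synonymous site count by direct enumeration (stops nonsynonymous)."""
    syn = 0
    for pos, nt in itertools.product(range(3), "ACGT"):
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1:]
        if alt not in STOP_CODONS and _aa(alt) == _aa(codon):
            syn += 1
    return syn / 3.0


def oracle_differences(a: str, b: str) -> tuple[float, float]:
    """(Sd, Nd) by enumerating every substitution order explicitly."""
    diff = [p for p in range(3) if a[p] != b[p]]
    all_paths, clean = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, stopped = a, 0, 0, False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                stopped = True
                nd += 1
            elif _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not stopped:
            clean.append((sd, nd))
    use = clean or all_paths
    return (sum(x for x, _ in use) / len(use),
            sum(y for _, y in use) / len(use))


def aln_of(codons_a, codons_b) -> CodonAlignment:
    return CodonAlignment(tuple(codons_a), tuple(codons_b))


class TestNg86Counts:
    @pytest.mark.parametrize("a,b,sd,nd", [
        ("TTT", "TTC", 1.0, 0.0),   # Phe -> Phe
        ("TTT", "GTT", 0.0, 1.0),   # Phe -> Val
    ])
    def test_single_difference_codons(self, a, b, sd, nd):
        _, _, Sd, Nd = ng86_counts(aln_of([a], [b]))
        assert (Sd, Nd) == (sd, nd)

    def test_against_enumeration_oracle(self):
        """500 random codon pairs match the pathway-enumeration oracle."""
        rng = np.random.default_rng(20260922)
        for _ in range(500):
            a, b = rng.choice(SENSE_CODONS, size=2)
            S, N, Sd, Nd = ng86_counts(aln_of([a], [b]))
            exp_S = (oracle_sites(a) + oracle_sites(b)) / 2.0
            exp_Sd, exp_Nd = oracle_differences(a, b)
            assert S == pytest.approx(exp_S, abs=1e-12)
            assert Sd == pytest.approx(exp_Sd, abs=1e-12)
            assert Nd == pytest.approx(exp_Nd, abs=1e-12)

    def test_site_conservation(self):
        rng = np.random.default_rng(7)
        for n in (1, 7, 40):
            a = rng.choice(SENSE_CODONS, size=n)
            b = rng.choice(SENSE_CODONS, size=n)
            S, N, _, _ = ng86_counts(aln_of(a, b))
            assert S + N == pytest.approx(3.0 * n, abs=1e-9)

    def test_symmetry(self):
        from genefamkit.synthetic_data import simulate_divergent_pair

        rng = np.random.default_rng(11)
        a, b, _, _ = simulate_divergent_pair(120, 0.4, 0.3, rng)
        ca, cb = codons_of(a.sequence[:-3]), codons_of(b.sequence[:-3])
        r1, r2 = kaks(aln_of(ca, cb)), kaks(aln_of(cb, ca))
        assert r1.ka == pytest.approx(r2.ka) and r1.ks == pytest.approx(r2.ks)
        # raw counts are symmetric too, on arbitrary (even unrelated) codons
        x = rng.choice(SENSE_CODONS, size=30)
        y = rng.choice(SENSE_CODONS, size=30)
        assert ng86_counts(aln_of(x, y)) == ng86_counts(aln_of(y, x))

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError):
            aln_of(["TAA"], ["TTT"])


class TestKaks:
    def test_identical_sequences(self):
        a = ["ATG", "GCT", "AAA"]
        r = kaks(aln_of(a, a))
        assert r.ka == 0 and r.ks == 0 and r.divergence_time_mya == 0
        assert r.omega is None and not r.positive_selection

    def test_purifying_flag(self):
        # one synonymous difference, zero nonsynonymous -> omega = 0 < 1
        r = kaks(aln_of(["TTT", "GCA", "AAA"], ["TTC", "GCA", "AAA"]))
        assert r.omega == 0.0 and r.purifying

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.76)


class TestDating:
    @pytest.mark.parametrize("ks,mya", [
        (0.019, 1.17), (0.098, 6.03), (0.040, 2.46), (0.0, 0.0)])
    def test_clock_values(self, ks, mya):
        assert date_pair(ks, 8.12e-9) == pytest.approx(mya, rel=0.01, abs=1e-9)

    def test_high_ks(self):
        # printed time comes from the unrounded Ks, so agreement is ~0.1%
        assert date_pair(1.338, 8.12e-9) == pytest.approx(82.41, rel=0.001)

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            date_pair(0.1, 0.0)


class TestCodonAlign:
    def test_identical_cds(self):
        cds = CdsRecord("a", "ATGGCTAAATAA")
        aln = codon_align(cds, CdsRecord("b", cds.sequence), "MAK", "MAK")
        assert aln.n_codons == 3
        _, _, Sd, Nd = ng86_counts(aln)
        assert Sd == 0 and Nd == 0

    def test_gap_column_dropped(self):
        a = CdsRecord("a", "ATGGCTAAATAA")        # M A K
        b = CdsRecord("b", "ATGAAATAA")           # M K
        aln = codon_align(a, b, "MAK", "M-K")
        assert aln.codons_a == ("ATG", "AAA") and aln.codons_b == ("ATG", "AAA")

    def test_translation_mismatch_rejected(self):
        a = CdsRecord("a", "ATGGCTAAATAA")
        with pytest.raises(ValidationError, match="translation"):
            codon_align(a, a, "MAA", "MAA")

    def test_threading_matches_independent_rethreading(self):
        rng = np.random.default_rng(3)
        ca = list(rng.choice(SENSE_CODONS, size=12))
        cb = ca[:5] + ca[7:]                      # two-codon deletion
        rec_a = CdsRecord("a", "".join(ca) + "TAA")
        rec_b = CdsRecord("b", "".join(cb) + "TAA")
        pa = "".join(_aa(c) for c in ca)
        pb_row = pa[:5] + "--" + pa[7:]
        aln = codon_align(rec_a, rec_b, pa, pb_row)
        # independent expectation: all codons except the deleted two
        assert aln.codons_a == tuple(ca[:5] + ca[7:])
        assert aln.codons_b == tuple(cb)
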