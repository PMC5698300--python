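"""Similarity search, retention filter, RBH orthology and NG86 Ka/Ks."""

import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from lbdkit.ortho import (
    AlignmentHit,
    all_vs_all_hits,
    kaks_ng86,
    make_aligner,
    ortholog_presence_matrix,
    reciprocal_best_hits,
    retain_hits,
)
from lbdkit.simulate import SimConfig, generate_ortholog_families

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_local_score(a, b, matrix, gap_open=-11, gap_extend=-1):
    """Smith-Waterman with affine gaps, straightforward 3-matrix DP."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i - 1][j - 1] + s, Y[i - 1][j - 1] + s)
            best = max(best, M[i][j])
    return best


class TestAllVsAll:
    def test_identical_sequences_identity_one(self, rng):
        seq = "".join(rng.choice(list(AA), size=200))
        hits = all_vs_all_hits({"a": seq}, {"b": seq})
        assert hits[0].identity == 1.0
        assert hits[0].e_value < 1e-100

    def test_unrelated_random_pairs_fail_evalue(self, rng):
        """Random 200-mers never approach the 1e-20 retention cutoff."""
        for _ in range(50):
            a = "".join(rng.choice(list(AA), size=200))
            b = "".join(rng.choice(list(AA), size=200))
            hit = all_vs_all_hits({"a": a}, {"b": b})[0]
            assert hit.e_value > 1e-20

    def test_score_equals_dp_oracle_on_toy_peptides(self, rng):
        blosum = substitution_matrices.load("BLOSUM62")
        aligner = make_aligner()
        # gap model parity: Biopython charges open at the first gap position
        for _ in range(10):
            a = "".join(rng.choice(list(AA), size=12))
            b = "".join(rng.choice(list(AA), size=15))
            got = aligner.score(a, b)
            want = brute_force_local_score(
                a, b, blosum, gap_open=-11.0, gap_extend=-1.0
            )
            assert got == pytest.approx(want)

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            all_vs_all_hits({"a": "AC1DEF"}, {"b": "ACDEF"})

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            all_vs_all_hits({}, {"b": "ACDEF"})


def _hit(q, s, score=500.0, e=1e-30, ident=0.9):
    return AlignmentHit(q, s, score, 100.0, e, ident, 100)


class TestRetention:
    def test_passing_hit_retained(self):
        assert retain_hits([_hit("a", "b", e=1e-25, ident=0.41)])

    def test_identity_boundary_strict(self):
        assert not retain_hits([_hit("a", "b", e=1e-25, ident=0.40)])

    def test_evalue_boundary_strict(self):
        assert not retain_hits([_hit("a", "b", e=1e-20, ident=0.90)])
        assert not retain_hits([_hit("a", "b", e=1e-19, ident=0.90)])

    def test_tightening_thresholds_never_adds(self):
        hits = [
            _hit("a", "b", e=1e-25, ident=0.5),
            _hit("a", "c", e=1e-21, ident=0.45),
            _hit("a", "d", e=1e-40, ident=0.41),
        ]
        loose = set(
            (h.query, h.subject) for h in retain_hits(hits, 1e-20, 0.40)
        )
        for e_max, id_min in [(1e-22, 0.40), (1e-20, 0.44), (1e-30, 0.6)]:
            tight = set(
                (h.query, h.subject) for h in retain_hits(hits, e_max, id_min)
            )
            assert tight <= loose


class TestReciprocalBestHits:
    def _exhaustive_rbh(self, score_ab, score_ba):
        """Independent brute-force check over all candidate pairs."""
        pairs = []
        for a in score_ab:
            for b in score_ab[a]:
                # best by (score, lexicographically smaller id)
                best_for_a = sorted(
                    score_ab[a].items(), key=lambda kv: (-kv[1], kv[0])
                )[0][0]
                best_for_b = sorted(
                    score_ba[b].items(), key=lambda kv: (-kv[1], kv[0])
                )[0][0]
                if best_for_a == b and best_for_b == a:
                    pairs.append((a, b))
        return sorted(set(pairs))

    def test_toy_tables_match_exhaustive_oracle(self):
        score_ab = {
            "a1": {"b1": 900, "b2": 300, "b3": 100},
            "a2": {"b1": 400, "b2": 800, "b3": 200},
            "a3": {"b1": 100, "b2": 250, "b3": 700},
        }
        score_ba = {
            "b1": {"a1": 900, "a2": 400, "a3": 100},
            "b2": {"a1": 300, "a2": 800, "a3": 250},
            "b3": {"a1": 100, "a2": 750, "a3": 700},
        }
        hits_ab = [
            _hit(a, b, score=s) for a, row in score_ab.items() for b, s in row.items()
        ]
        hits_ba = [
            _hit(b, a, score=s) for b, row in score_ba.items() for a, s in row.items()
        ]
        got = reciprocal_best_hits(hits_ab, hits_ba)
        assert got == self._exhaustive_rbh(score_ab, score_ba)
        # b3's best match is a2 (750 > 700), so a3/b3 is not reciprocal
        assert got == [("a1", "b1"), ("a2", "b2")]

    def test_non_reciprocal_best_is_no_pair(self):
        hits_ab = [_hit("a", "b", score=500)]
        hits_ba = [_hit("b", "a2", score=600), _hit("b", "a", score=500)]
        assert reciprocal_best_hits(hits_ab, hits_ba) == []

    def test_symmetry_under_role_swap(self):
        hits_ab = [_hit("a1", "b1", 900), _hit("a2", "b1", 800)]
        hits_ba = [_hit("b1", "a1", 900)]
        fwd = reciprocal_best_hits(hits_ab, hits_ba)
        rev = reciprocal_best_hits(hits_ba, hits_ab)
        assert sorted((b, a) for a, b in fwd) == rev

    def test_tie_broken_by_identity_then_id(self):
        hits_ab = [
            _hit("a", "b2", score=500, ident=0.8),
            _hit("a", "b1", score=500, ident=0.9),
        ]
        hits_ba = [_hit("b1", "a", score=500)]
        assert reciprocal_best_hits(hits_ab, hits_ba) == [("a", "b1")]


class TestClosedLoopOrthology:
    def test_perfect_recovery_without_loss_or_duplication(self):
        config = SimConfig(
            seed=31, n_family_genes=10, n_species=2,
            loss_prob=0.0, dup_prob=0.0, mutation_rate=0.03,
        )
        fam = generate_ortholog_families(config)
        matrix, results = ortholog_presence_matrix(fam.vitis, fam.species)
        for r in results:
            assert r.category == "one_to_one"
            assert fam.truth[(r.vitis_gene, r.species)] == "one_to_one"

    def test_planted_loss_is_no_match(self):
        config = SimConfig(
            seed=32, n_family_genes=6, n_species=2, loss_prob=1.0, dup_prob=0.0
        )
        fam = generate_ortholog_families(config)
        assert all(c == "no_match" for c in fam.truth.values())
        matrix, results = ortholog_presence_matrix(fam.vitis, fam.species)
        assert all(r.category == "no_match" for r in results)

    def test_planted_duplication_is_homolog_only(self):
        config = SimConfig(
            seed=33, n_family_genes=6, n_species=1,
            loss_prob=0.0, dup_prob=1.0, mutation_rate=0.03,
        )
        fam = generate_ortholog_families(config)
        matrix, results = ortholog_presence_matrix(fam.vitis, fam.species)
        assert all(r.category == "homolog_only" for r in results)


# ---------------------------------------------------------------------------
# NG86 oracle
# ---------------------------------------------------------------------------

def _translate(codon):
    return str(Seq(codon).translate())


def oracle_sites(codon):
    """Synonymous site count of a codon by direct enumeration."""
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if _translate(alt) == "*":
                continue
            valid += 1
            if _translate(alt) == _translate(codon):
                syn += 1
        if valid:
            s += syn / valid
    return s


def oracle_differences(c1, c2):
    """Pathway-averaged (syn, nonsyn) substitutions via Biopython translate."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, syn, non, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _translate(nxt) == "*":
                ok = False
                break
            if _translate(nxt) == _translate(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            results.append((syn, non))
    assert results, "oracle only covers stop-free pathways"
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def _random_sense_codons(rng, n):
    codons = []
    while len(codons) < n:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if _translate(c) != "*":
            codons.append(c)
    return codons


class TestKaKsNG86:
    def test_identical_sequences(self):
        r = kaks_ng86("ATGGCTAAA", "ATGGCTAAA")
        assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None

    def test_synonymous_only_change(self):
        # TTT -> TTC is Phe -> Phe
        r = kaks_ng86("TTTAAAGGGCCC", "TTCAAAGGGCCC")
        assert r.nd == 0.0 and r.sd == 1.0
        assert r.pn == 0.0 and r.ps > 0.0

    def test_site_conservation(self, rng):
        """Ns + Ss equals three sites per codon."""
        for _ in range(5):
            codons = _random_sense_codons(rng, 20)
            seq = "".join(codons)
            r = kaks_ng86(seq, seq)
            assert r.n_sites + r.s_sites == pytest.approx(3 * len(codons))

    def test_counts_match_enumeration_oracle(self, rng):
        """Site counts and substitution proportions against an independent
        per-codon enumeration on random 30-codon pairs."""
        for _ in range(10):
            ca = _random_sense_codons(rng, 30)
            cb = []
            for c in ca:
                if rng.random() < 0.25:
                    # mutate 1-2 positions, keeping the codon sense
                    c2 = c
                    for _ in range(int(rng.integers(1, 3))):
                        pos = int(rng.integers(3))
                        nt = str(rng.choice([x for x in "ACGT" if x != c2[pos]]))
                        cand = c2[:pos] + nt + c2[pos + 1:]
                        if _translate(cand) != "*":
                            c2 = cand
                    cb.append(c2)
                else:
                    cb.append(c)
            a, b = "".join(ca), "".join(cb)
            r = kaks_ng86(a, b)
            s_or = (sum(map(oracle_sites, ca)) + sum(map(oracle_sites, cb))) / 2
            sd_or = nd_or = 0.0
            for x, y in zip(ca, cb):
                s, n = oracle_differences(x, y)
                sd_or += s
                nd_or += n
            assert r.s_sites == pytest.approx(s_or)
            assert r.sd == pytest.approx(sd_or)
            assert r.nd == pytest.approx(nd_or)
            assert r.ps == pytest.approx(sd_or / s_or)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            kaks_ng86("ATGGCT", "ATGGCTAAA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            kaks_ng86("ATGTAAGCT", "ATGTAAGCT")

    def test_jukes_cantor_value(self):
        """d = -3/4 ln(1 - 4p/3) applied to the raw proportions."""
        seq_a = "AAATTTGGGCCCGATGAT" * 3
        seq_b = "AAATTCGGGCCCGATGAC" * 3
        r = kaks_ng86(seq_a, seq_b)
        assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 * r.ps / 3))
        assert r.ka == pytest.approx(0.0)
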