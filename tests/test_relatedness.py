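"""Genome relatedness indices: ANI, AAI, POCP and threshold flags."""

from __future__ import annotations

import numpy as np
import pytest

from pankit.io import GenomeRecord, ProteinRecord
from pankit.relatedness import (
    RelatednessResult,
    aai,
    ani,
    pocp,
    relatedness_matrix,
    reverse_complement,
)
from pankit.simulate import (
    SequenceEvolutionSpec,
    evolve_sequence,
    random_sequence,
    simulate_genome_pair,
    simulate_proteomes,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestAni:
    def test_identical_genomes(self):
        genome = GenomeRecord("g1", random_sequence(8000, seed=1))
        other = GenomeRecord("g2", genome.sequence)
        result = ani(genome, other)
        assert result.value == pytest.approx(100.0)
        assert result.n_support > 0
        assert result.same_species

    def test_reverse_complement_strand_handling(self):
        genome = GenomeRecord("g1", random_sequence(8000, seed=2))
        flipped = GenomeRecord("g2", reverse_complement(genome.sequence))
        result = ani(genome, flipped)
        assert result.value == pytest.approx(100.0)

    def test_monotone_in_divergence(self):
        values = []
        for rate in (0.01, 0.05, 0.10, 0.20):
            a, b = simulate_genome_pair(
                length=10_000, substitution_rate=rate, seed=5
            )
            values.append(ani(a, b).value)
        assert values == sorted(values, reverse=True)

    def test_unrelated_genomes_leave_no_support(self):
        a = GenomeRecord("g1", random_sequence(3000, seed=7))
        b = GenomeRecord("g2", random_sequence(3000, seed=8))
        result = ani(a, b)
        # random 3-kb sequences: fragments either fail the filters or
        # find only spurious low-identity windows
        assert result.n_support == 0 or result.value < 90.0

    def test_short_genome_rejected(self):
        a = GenomeRecord("g1", "ACGT" * 10)
        b = GenomeRecord("g2", random_sequence(2000, seed=9))
        with pytest.raises(ValueError):
            ani(a, b)


class TestAaiPocp:
    def test_identical_proteomes_aai(self):
        proteomes, _ = simulate_proteomes(
            n_genomes=1, n_families=15, divergence=0.0, seed=21
        )
        a = proteomes["SG01"]
        b = [ProteinRecord(p.protein_id + "_b", "G2", p.sequence) for p in a]
        result = aai(a, b)
        assert result.value == pytest.approx(100.0)
        assert result.n_support == len(a)
        assert result.same_genus_aai

    def test_aai_tracks_planted_divergence(self):
        # ancestor proteome vs a copy evolved at 10% divergence: the
        # expected identity of every RBH pair is exactly 0.90
        rng = np.random.default_rng(22)
        ancestors = [
            ProteinRecord(f"anc{i}", "G1", "".join(
                rng.choice(list(AA), int(rng.integers(150, 400)))
            ))
            for i in range(40)
        ]
        evolved = [
            ProteinRecord(
                p.protein_id + "_e", "G2",
                evolve_sequence(
                    p.sequence,
                    SequenceEvolutionSpec(
                        substitution_rate=0.10, alphabet="protein",
                        seed=int(rng.integers(2**31 - 1)),
                    ),
                ),
            )
            for p in ancestors
        ]
        result = aai(ancestors, evolved)
        assert result.value == pytest.approx(90.0, abs=1.0)
        assert result.n_support >= 38

    def test_disjoint_random_proteomes_undefined(self):
        rng = np.random.default_rng(3)
        a = [
            ProteinRecord(f"a{i}", "G1", "".join(rng.choice(list(AA), 120)))
            for i in range(8)
        ]
        b = [
            ProteinRecord(f"b{i}", "G2", "".join(rng.choice(list(AA), 120)))
            for i in range(8)
        ]
        result = aai(a, b)
        assert result.value is None
        assert result.n_support == 0

    def test_identical_proteomes_pocp(self):
        proteomes, _ = simulate_proteomes(
            n_genomes=1, n_families=15, divergence=0.0, seed=25
        )
        a = proteomes["SG01"]
        b = [ProteinRecord(p.protein_id + "_b", "G2", p.sequence) for p in a]
        result = pocp(a, b)
        assert result.value == pytest.approx(100.0)
        assert result.same_genus_pocp

    def test_pocp_half_conserved(self):
        # 10 shared + 10 private proteins per proteome: C1 = C2 = 10,
        # T1 = T2 = 20, POCP = 100 * 20/40 = 50
        shared, _ = simulate_proteomes(
            n_genomes=1, n_families=10, divergence=0.0, seed=26,
            length_range=(150, 250),
        )
        rng = np.random.default_rng(27)
        private = lambda tag: [
            ProteinRecord(f"{tag}{i}", tag, "".join(rng.choice(list(AA), 150)))
            for i in range(10)
        ]
        a = [ProteinRecord(p.protein_id + "_a", "G1", p.sequence) for p in shared["SG01"]]
        b = [ProteinRecord(p.protein_id + "_b", "G2", p.sequence) for p in shared["SG01"]]
        result = pocp(a + private("G1"), b + private("G2"))
        assert result.value == pytest.approx(50.0)
        assert result.n_support == 20

    def test_no_conserved_proteins_gives_zero(self):
        rng = np.random.default_rng(30)
        a = [ProteinRecord("a1", "G1", "".join(rng.choice(list(AA), 100)))]
        b = [ProteinRecord("b1", "G2", "".join(rng.choice(list(AA), 100)))]
        result = pocp(a, b)
        assert result.value == 0.0

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            aai([], [ProteinRecord("b1", "G2", "MKVLAW")])


class TestInterpretationFlags:
    @pytest.mark.parametrize(
        "metric,value,flag,expected",
        [
            ("ANI", 95.1, "same_species", True),
            ("ANI", 94.9, "same_species", False),
            ("AAI", 65.1, "same_genus_aai", True),
            ("AAI", 64.9, "same_genus_aai", False),
            ("POCP", 50.1, "same_genus_pocp", True),
            ("POCP", 49.9, "same_genus_pocp", False),
        ],
    )
    def test_threshold_straddling(self, metric, value, flag, expected):
        result = RelatednessResult("a", "b", metric, value, 10)
        assert getattr(result, flag) is expected

    def test_undefined_value_never_flags(self):
        result = RelatednessResult("a", "b", "ANI", None, 0)
        assert not result.same_species


def test_relatedness_matrix_is_symmetric():
    results = [
        RelatednessResult("g1", "g2", "ANI", 80.0, 5),
        RelatednessResult("g1", "g3", "ANI", 70.0, 5),
        RelatednessResult("g2", "g3", "ANI", None, 0),
    ]
    mat = relatedness_matrix(results)
    assert list(mat.index) == ["g1", "g2", "g3"]
    assert mat.loc["g1", "g2"] == mat.loc["g2", "g1"] == 80.0
    assert np.isnan(mat.loc["g2", "g3"])
    assert (np.diag(mat) == 100.0).all()
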