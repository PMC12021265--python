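import numpy as np
import pytest

from nifcast.codon_features import (
    DEGENERATE_CODONS,
    FAMILIES,
    ReferenceSet,
    cai,
    count_codons,
    e_metric,
    ecd,
    fop,
    rscu,
    rscu_from_counts,
    strain_codon_features,
)
from nifcast.records import CodingSequence, StrainRecord


def _cds(nt, gene="nifd", cid="g1"):
    return CodingSequence(id=cid, gene=gene, nucleotides=nt)


def _uniform_gene():
    """One occurrence of every sense codon -> uniform within-family usage."""
    return _cds("".join(DEGENERATE_CODONS) + "ATGTGG")


def random_cds(rng, n_codons=120):
    sense = list(DEGENERATE_CODONS)
    codons = rng.choice(sense, size=n_codons)
    return _cds("".join(codons))


class TestRSCU:
    def test_uniform_usage_all_ones(self):
        prof = rscu(_uniform_gene())
        assert np.allclose(prof.vector(), 1.0)

    def test_phe_only_ttt(self):
        prof = rscu(_cds("TTTTTTTTT"))
        assert prof.values["TTT"] == pytest.approx(2.0)
        assert prof.values["TTC"] == 0.0

    def test_atg_only_neutral(self):
        prof = rscu(_cds("ATGATG"))
        assert np.allclose(prof.vector(), 1.0)

    def test_family_sum_conservation(self, rng):
        prof = rscu(random_cds(rng))
        counts = None
        for aa, fam in FAMILIES.items():
            if len(fam) < 2:
                continue
            total = sum(prof.values[c] for c in fam)
            assert total == pytest.approx(len(fam), abs=1e-9)

    def test_length_not_multiple_of_three_errors(self):
        with pytest.raises(ValueError, match="divisible"):
            _cds("ATGT")


class TestECD:
    def test_all_ones_zero(self):
        assert ecd(rscu(_uniform_gene())) == pytest.approx(0.0, abs=1e-12)

    def test_single_biased_family(self):
        # Phe family at (2, 0), everything else neutral
        values = {c: 1.0 for c in DEGENERATE_CODONS}
        values["TTT"], values["TTC"] = 2.0, 0.0
        from nifcast.codon_features import RSCUProfile

        assert ecd(RSCUProfile(values)) == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_oracle_on_random_cds(self, rng):
        """rscu+ecd agree with dictionary counting + direct formula, 100 genes."""
        for _ in range(100):
            g = random_cds(rng, n_codons=int(rng.integers(30, 200)))
            # independent oracle: plain dict count, then the formula
            counts = {}
            for i in range(0, len(g.nucleotides), 3):
                c = g.nucleotides[i : i + 3]
                counts[c] = counts.get(c, 0) + 1
            acc = 0.0
            for aa, fam in FAMILIES.items():
                if len(fam) < 2:
                    continue
                tot = sum(counts.get(c, 0) for c in fam)
                for c in fam:
                    x = counts.get(c, 0) / (tot / len(fam)) if tot else 1.0
                    acc += (x - 1.0) ** 2
            assert ecd(rscu(g)) == pytest.approx(np.sqrt(acc), abs=1e-12)


@pytest.fixture()
def phe_ref():
    """Reference preferring TTC over TTT (w: TTC=1, TTT=0.25)."""
    w = {c: 1.0 for c in DEGENERATE_CODONS}
    w["TTT"] = 0.25
    return ReferenceSet(w=w)


class TestCAIFop:
    def test_all_optimal_gene(self, phe_ref):
        assert cai(_cds("TTCTTC"), phe_ref) == pytest.approx(1.0)
        assert fop(_cds("TTCTTC"), phe_ref) == pytest.approx(1.0)

    def test_geometric_mean(self, phe_ref):
        # two codons with w = 1 and 0.25 -> sqrt(0.25) = 0.5
        assert cai(_cds("TTCTTT"), phe_ref) == pytest.approx(0.5)

    def test_order_invariance(self, phe_ref, rng):
        g1 = _cds("TTCTTTGGTGGC")
        codons = [g1.nucleotides[i : i + 3] for i in range(0, 12, 3)]
        g2 = _cds("".join(rng.permutation(codons)))
        assert cai(g1, phe_ref) == pytest.approx(cai(g2, phe_ref))

    def test_fop_counts(self, phe_ref):
        # 2 optimal (TTC) of 4 scoreable
        assert fop(_cds("TTCTTCTTTTTT"), phe_ref) == pytest.approx(0.5)

    def test_fop_zero(self, phe_ref):
        assert fop(_cds("TTTTTT"), phe_ref) == 0.0

    def test_monotone_under_optimalization(self, rng):
        """Swapping any codon to its family-optimal one never lowers CAI/Fop."""
        ref = ReferenceSet.from_cds([random_cds(rng, 300)])
        g = random_cds(rng, 60)
        base_cai, base_fop = cai(g, ref), fop(g, ref)
        codons = g.codons()
        fam_best = {}
        for aa, fam in FAMILIES.items():
            if len(fam) >= 2:
                fam_best.update({c: max(fam, key=lambda x: ref.w[x]) for c in fam})
        for i in range(len(codons)):
            swapped = list(codons)
            swapped[i] = fam_best.get(codons[i], codons[i])
            g2 = _cds("".join(swapped))
            assert cai(g2, ref) >= base_cai - 1e-12
            assert fop(g2, ref) >= base_fop - 1e-12

    def test_no_scoreable_codons_errors(self, phe_ref):
        with pytest.raises(ValueError, match="score"):
            cai(_cds("ATGTGG"), phe_ref)


class TestEMetric:
    def test_uniform_zero(self):
        assert e_metric(_uniform_gene()) == pytest.approx(0.0, abs=1e-12)

    def test_phe_only_all_ttt(self):
        assert e_metric(_cds("TTTTTTTTT")) == pytest.approx(0.5)

    def test_duplication_invariant(self, rng):
        g = random_cds(rng, 50)
        g2 = _cds(g.nucleotides * 2)
        assert e_metric(g2) == pytest.approx(e_metric(g), abs=1e-12)


class TestStrainFeatures:
    def _strain(self, cds_list):
        return StrainRecord(strain_id="s", activity=1.0, cds=cds_list)

    def test_single_copy_equals_value(self, phe_ref):
        g = _cds("TTTTTTTTT", gene="nifd")
        fv = strain_codon_features(self._strain([g]), phe_ref, ["nifD"], include_rscu=False)
        got = dict(zip(fv.names, fv.values))
        assert got["Average_nifD_E"] == pytest.approx(e_metric(g))

    def test_two_copies_averaged(self, phe_ref):
        g1 = _cds("TTTTTTTTT", gene="nifd", cid="a")  # E = 0.5
        g2 = _cds("TTTTTCTTTTTC", gene="nifd", cid="b")  # uniform Phe -> E = 0
        fv = strain_codon_features(self._strain([g1, g2]), phe_ref, ["nifD"], include_rscu=False)
        got = dict(zip(fv.names, fv.values))
        assert got["Average_nifD_E"] == pytest.approx(0.25)

    def test_absent_gene_nan(self, phe_ref):
        g = _cds("TTTTTT", gene="nifd")
        fv = strain_codon_features(self._strain([g]), phe_ref, ["nifK"], include_rscu=False)
        got = dict(zip(fv.names, fv.values))
        assert np.isnan(got["Average_nifK_E"])

    def test_rscu_block_width(self, phe_ref):
        g = _cds("TTTTTT", gene="nifd")
        fv = strain_codon_features(self._strain([g]), phe_ref, [], include_rscu=True)
        assert sum(n.startswith("rscu_") for n in fv.names) == 59
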