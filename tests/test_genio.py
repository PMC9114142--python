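"""Genotype I/O, MAF filtering and imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from corrbreak import genio


def _toy(dosages, scaffold="s1", positions=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = [f"m{j}" for j in range(m)]
    if positions is None:
        positions = list(range(0, 100 * m, 100))
    mm = pd.DataFrame(
        {"scaffold": [scaffold] * m, "pos_bp": positions},
        index=pd.Index(markers, name="marker"),
    )
    return genio.GenotypeMatrix(
        individual_ids=np.array([f"i{k}" for k in range(n)], dtype=object),
        marker_ids=np.array(markers, dtype=object),
        dosages=dosages,
        marker_map=mm,
    )


class TestGenotypeMatrix:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            genio.GenotypeMatrix(
                individual_ids=np.array(["a", "b"], dtype=object),
                marker_ids=np.array(["m0"], dtype=object),
                dosages=np.zeros((3, 1)),
                marker_map=_toy(np.zeros((1, 1))).marker_map,
            )

    def test_duplicate_ids_rejected(self):
        mm = _toy(np.zeros((2, 1))).marker_map
        with pytest.raises(ValueError, match="duplicate"):
            genio.GenotypeMatrix(
                individual_ids=np.array(["a", "a"], dtype=object),
                marker_ids=np.array(["m0"], dtype=object),
                dosages=np.zeros((2, 1)),
                marker_map=mm,
            )

    def test_allele_freqs_ignore_missing(self):
        g = _toy([[0, 2], [2, np.nan], [1, 0]])
        np.testing.assert_allclose(g.allele_freqs(), [0.5, 0.5])

    def test_subset_round_trips(self):
        g = _toy(np.arange(12).reshape(4, 3) % 3)
        sub = g.subset_individuals(["i2", "i0"]).subset_markers(["m1"])
        assert list(sub.individual_ids) == ["i2", "i0"]
        np.testing.assert_allclose(sub.dosages[:, 0], [g.dosages[2, 1], g.dosages[0, 1]])


class TestDosageIO:
    def test_round_trip_with_missing(self, tmp_path):
        g = _toy([[0, 1], [2, np.nan], [1, 0]])
        genio.write_dosages(g, tmp_path / "d.tsv")
        genio.write_marker_map(g.marker_map, tmp_path / "m.tsv")
        back = genio.read_dosages(tmp_path / "d.tsv", tmp_path / "m.tsv")
        np.testing.assert_array_equal(
            np.isnan(back.dosages), np.isnan(g.dosages)
        )
        np.testing.assert_allclose(
            back.dosages[~np.isnan(g.dosages)], g.dosages[~np.isnan(g.dosages)]
        )
        assert list(back.marker_map["pos_bp"]) == list(g.marker_map["pos_bp"])

    def test_invalid_token_reported_with_location(self, tmp_path):
        (tmp_path / "d.tsv").write_text("id\tm0\nind1\t7\n")
        (tmp_path / "m.tsv").write_text("marker\tscaffold\tpos_bp\nm0\ts1\t10\n")
        with pytest.raises(ValueError, match="ind1"):
            genio.read_dosages(tmp_path / "d.tsv", tmp_path / "m.tsv")


class TestVCF:
    def test_reads_biallelic_snps_and_skips_others(self, tmp_path):
        vcf = "\n".join(
            [
                "##fileformat=VCFv4.2",
                "##contig=<ID=s1>",
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb",
                "s1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1",
                "s1\t200\tsnp2\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1",  # multi-allelic
                "s1\t300\tsnp3\tA\tGT\t.\t.\t.\tGT\t0/0\t0/1",  # indel
                "s1\t400\tsnp4\tC\tT\t.\t.\t.\tGT\t1/1\t./.",
                "",
            ]
        )
        path = tmp_path / "x.vcf"
        path.write_text(vcf)
        g = genio.read_vcf(path)
        assert list(g.marker_ids) == ["snp1", "snp4"]
        assert g.marker_map.attrs["n_skipped"] == 2
        np.testing.assert_allclose(g.dosages[:, 0], [0.0, 1.0])
        assert g.dosages[0, 1] == 2.0 and np.isnan(g.dosages[1, 1])


class TestMafFilter:
    def test_threshold_is_strict(self):
        # 50 individuals, marker freq exactly 0.01 must be removed
        d = np.zeros((50, 2))
        d[0, 0] = 1  # freq 0.01 -> dropped under strict >
        d[:25, 1] = 1  # freq 0.25 -> kept
        g = _toy(d)
        out, rep = genio.maf_filter(g, 0.01)
        assert list(out.marker_ids) == ["m1"]
        assert rep.n_removed_maf == 1 and rep.n_retained == 1

    def test_minor_allele_folding(self):
        # alt-allele frequency 0.75 -> MAF 0.25 (exactly representable)
        d = np.array([[2.0]] * 5 + [[1.0]] * 5)
        out, _ = genio.maf_filter(_toy(d), 0.2)
        assert out.n_markers == 1
        out, _ = genio.maf_filter(_toy(d), 0.25)
        assert out.n_markers == 0

    def test_all_missing_marker_counted_separately(self):
        d = np.array([[np.nan, 1.0], [np.nan, 0.0]])
        out, rep = genio.maf_filter(_toy(d), 0.0)
        assert rep.n_removed_all_missing == 1
        assert list(out.marker_ids) == ["m1"]


class TestMeanImpute:
    def test_fills_with_observed_mean_and_flags_cells(self):
        g = _toy([[0, 2], [2, np.nan], [1, 0]])
        out = genio.mean_impute(g)
        assert out.dosages[1, 1] == pytest.approx(1.0)
        assert out.imputed[1, 1] and not out.imputed[0, 0]
        # hard-call statistics ignore the imputed cell
        assert not out.hard_call_mask()[1, 1]

    def test_all_missing_marker_is_an_error(self):
        g = _toy([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="all-missing"):
            genio.mean_impute(g)

    @given(st.integers(0, 2**32 - 1))
    def test_imputation_preserves_observed_calls(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(8, 5)).astype(float)
        d[rng.random(d.shape) < 0.2] = np.nan
        if np.isnan(d).all(axis=0).any():
            return
        g = _toy(d)
        out = genio.mean_impute(g)
        obs = ~np.isnan(d)
        np.testing.assert_allclose(out.dosages[obs], d[obs])
        assert np.isfinite(out.dosages).all()
        assert (out.dosages >= 0).all() and (out.dosages <= 2).all()


def test_pedigree_round_trip(tmp_path):
    ped = pd.DataFrame(
        {"id": ["f1", "f2", "x"], "sire": [None, None, "f1"], "dam": [None, None, "f2"]}
    )
    genio.write_pedigree(ped, tmp_path / "p.tsv")
    back = genio.read_pedigree(tmp_path / "p.tsv")
    assert back["sire"].tolist() == [None, None, "f1"]
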