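import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinscreen as ks
from kinscreen.genotype_io import MISSING


def write(path, text):
    path.write_text(text)


@pytest.fixture
def ped_fixture(tmp_path):
    """Two samples, three markers; marker 3 alleles tie and break to 'A'."""
    write(
        tmp_path / "toy.map",
        "1\trs1\t0\t1\n1\trs2\t0\t2\nX\trs3\t0\t3\n",
    )
    write(
        tmp_path / "toy.ped",
        "POP s1 0 0 1 0 A G C C A A\n"
        "POP s2 0 0 2 0 G G C T C C\n",
    )
    return tmp_path / "toy"


class TestReadPedMap:
    def test_minor_allele_counting_by_hand(self, ped_fixture):
        ds = ks.read_dataset(str(ped_fixture), "ped-map")
        assert ds.sample_ids == ["s1", "s2"]
        assert ds.marker_ids == ["rs1", "rs2", "rs3"]
        # rs1: A appears once vs G three times -> minor A; rs2: T minor;
        # rs3: A/C tie -> lexicographically smaller A is minor
        assert ds.genotypes.tolist() == [[1, 0, 2], [0, 1, 0]]
        assert list(ds.sex_declared) == ["male", "female"]
        assert list(ds.chrom) == ["1", "1", "X"]

    def test_empty_map_is_an_error(self, tmp_path):
        write(tmp_path / "e.map", "")
        write(tmp_path / "e.ped", "")
        with pytest.raises(ValueError, match="empty marker file"):
            ks.read_dataset(str(tmp_path / "e"), "ped-map")

    def test_wrong_marker_count_names_line(self, tmp_path):
        write(tmp_path / "b.map", "1\trs1\t0\t1\n1\trs2\t0\t2\n")
        write(tmp_path / "b.ped", "P s1 0 0 1 0 A A\n")
        with pytest.raises(ValueError, match=r"b\.ped:1"):
            ks.read_dataset(str(tmp_path / "b"), "ped-map")

    def test_invalid_allele_code_rejected(self, tmp_path):
        write(tmp_path / "c.map", "1\trs1\t0\t1\n")
        write(tmp_path / "c.ped", "P s1 0 0 1 0 A Z\n")
        with pytest.raises(ValueError, match="invalid allele"):
            ks.read_dataset(str(tmp_path / "c"), "ped-map")


class TestWrite:
    def test_missing_written_as_zero_zero(self, tmp_path):
        ds = ks.GenotypeDataset(
            sample_ids=["s1"],
            marker_ids=["rs1"],
            chrom=["1"],
            genotypes=np.array([[MISSING]]),
        )
        ks.write_dataset(ds, str(tmp_path / "m"), "ped-map")
        assert (tmp_path / "m.ped").read_text().split()[-2:] == ["0", "0"]

    def test_x_male_hemizygote_written_as_homozygote_pair(self, tmp_path):
        ds = ks.GenotypeDataset(
            sample_ids=["s1"],
            marker_ids=["rsX1"],
            chrom=["X"],
            genotypes=np.array([[2]]),
            sex_declared=["male"],
        )
        ks.write_dataset(ds, str(tmp_path / "x"), "ped-map")
        assert (tmp_path / "x.ped").read_text().split()[-2:] == ["A", "A"]

    def test_unwritable_path_is_an_error(self, tmp_path):
        ds = ks.GenotypeDataset(
            sample_ids=["s1"], marker_ids=["rs1"], chrom=["1"],
            genotypes=np.array([[1]]),
        )
        with pytest.raises(ValueError, match="unwritable"):
            ks.write_dataset(ds, str(tmp_path / "no_such_dir" / "x"), "ped-map")


@pytest.mark.parametrize("dialect", ["ped-map", "tabular"])
def test_round_trip_on_simulated_cohort(tmp_path, dialect, small_cohort):
    _, _, ds, _ = small_cohort
    ks.write_dataset(ds, str(tmp_path / "rt"), dialect)
    back = ks.read_dataset(str(tmp_path / "rt"), dialect)
    assert back == ds


@given(
    data=st.data(),
    n=st.integers(2, 6),
    m=st.integers(1, 8),
)
def test_round_trip_property_random_datasets(data, n, m, tmp_path_factory):
    g = np.array(
        data.draw(
            st.lists(
                st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=m, max_size=m),
                min_size=n,
                max_size=n,
            )
        ),
        dtype=np.int8,
    )
    # orient to the sample minor allele so the ped-map read rule applies
    nonmiss = g != MISSING
    copies = np.where(nonmiss, g, 0).sum(axis=0)
    slots = 2 * nonmiss.sum(axis=0)
    for j in np.flatnonzero(copies * 2 > slots):
        col = g[:, j]
        col[col != MISSING] = 2 - col[col != MISSING]
    ds = ks.GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        marker_ids=[f"rs{j}" for j in range(m)],
        chrom=["1"] * m,
        genotypes=g,
    )
    tmp = tmp_path_factory.mktemp("rt")
    for dialect in ("ped-map", "tabular"):
        ks.write_dataset(ds, str(tmp / "p"), dialect)
        assert ks.read_dataset(str(tmp / "p"), dialect) == ds


class TestFilterMarkers:
    def make(self, geno, ids=None, chrom=None):
        geno = np.asarray(geno)
        m = geno.shape[1]
        return ks.GenotypeDataset(
            sample_ids=[f"s{i}" for i in range(geno.shape[0])],
            marker_ids=ids or [f"rs{j}" for j in range(m)],
            chrom=chrom or ["1"] * m,
            genotypes=geno,
        )

    def test_all_reference_marker_removed_as_monomorphic(self):
        ds = self.make([[0, 1], [0, 2]])
        out, rep = ks.filter_markers(ds)
        assert rep.n_monomorphic_removed == 1
        assert out.marker_ids == ["rs1"]

    def test_duplicate_marker_id_keeps_first(self):
        ds = self.make([[0, 1], [1, 2]], ids=["rs1", "rs1"])
        out, rep = ks.filter_markers(ds)
        assert rep.n_duplicate_removed == 1
        assert rep.removed_ids == ["rs1"]
        assert out.genotypes.tolist() == [[0], [1]]

    def test_clean_dataset_unchanged(self):
        ds = self.make([[0, 1], [1, 2]])
        out, rep = ks.filter_markers(ds)
        assert out == ds
        assert (rep.n_duplicate_removed, rep.n_monomorphic_removed) == (0, 0)

    def test_idempotent(self, small_cohort):
        _, _, ds, _ = small_cohort
        once, _ = ks.filter_markers(ds)
        twice, rep = ks.filter_markers(once)
        assert twice == once
        assert rep.removed_ids == []


class TestAlleleFrequencies:
    def test_symmetric_case(self):
        ds = ks.GenotypeDataset(
            sample_ids=["a", "b", "c"], marker_ids=["rs1"], chrom=["1"],
            genotypes=np.array([[0], [1], [2]]),
        )
        assert ks.allele_frequencies(ds)[0] == pytest.approx(0.5)

    def test_hand_count(self):
        ds = ks.GenotypeDataset(
            sample_ids=["a", "b", "c"], marker_ids=["rs1"], chrom=["1"],
            genotypes=np.array([[0], [0], [1]]),
        )
        assert ks.allele_frequencies(ds)[0] == pytest.approx(1 / 6)

    def test_all_missing_marker_is_an_error(self):
        ds = ks.GenotypeDataset(
            sample_ids=["a", "b"], marker_ids=["rs1"], chrom=["1"],
            genotypes=np.array([[MISSING], [MISSING]]),
        )
        with pytest.raises(ValueError, match="rs1"):
            ks.allele_frequencies(ds)

    def test_x_male_counts_one_allele(self):
        # male 2 on X contributes 1/1 copies; female 1 contributes 1/2
        ds = ks.GenotypeDataset(
            sample_ids=["m", "f"], marker_ids=["rsX1"], chrom=["X"],
            genotypes=np.array([[2], [1]]),
            sex_declared=["male", "female"],
        )
        assert ks.allele_frequencies(ds)[0] == pytest.approx(2 / 3)

    def test_filtered_dataset_frequencies_strictly_inside_unit_interval(
        self, small_cohort
    ):
        _, _, ds, _ = small_cohort
        filtered, _ = ks.filter_markers(ds)
        f = ks.allele_frequencies(filtered)
        assert np.all(f > 0) and np.all(f < 1)
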