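"""QC filters, file round trips, config parsing and the pipeline driver."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwaselect.containers import MISSING, GenotypeMatrix
from gwaselect.io import (
    read_causal,
    read_covariates,
    read_genotypes,
    read_phenotype,
    write_causal,
    write_covariates,
    write_genotypes,
    write_phenotype,
    write_selection,
)
from gwaselect.pipeline import RunConfig, child_seed, load_config, run_pipeline
from gwaselect.qc import hwe_pvalues, qc_filter
from gwaselect.simulate import make_setting


def build(values):
    return GenotypeMatrix.from_values(np.asarray(values, dtype=np.int8))


def column(counts0, counts1, counts2, missing=0):
    col = [0] * counts0 + [1] * counts1 + [2] * counts2 + [MISSING] * missing
    return np.array(col, dtype=np.int8)


class TestQC:
    def test_maf_counting(self):
        # counts (900, 90, 10) -> allele freq of the counted allele
        # (2*10 + 90) / 2000 = 0.055
        G = build(np.column_stack([column(900, 90, 10), column(250, 500, 250)]))
        out, rep = qc_filter(G, maf_min=0.01)
        assert rep.n_removed_maf == 0 and rep.n_snps_out == 2
        out2, rep2 = qc_filter(G, maf_min=0.06)
        assert rep2.n_removed_maf == 1 and rep2.n_snps_out == 1

    def test_hwe_chi_square_oracle(self):
        # (AA, Aa, aa) = (360, 480, 160) at q=0.4: expected (360, 480, 160),
        # chi-square ~ 0 -> retained
        col = column(360, 480, 160)
        p = hwe_pvalues(col[:, None])
        assert p[0] > 0.99
        # gross heterozygote deficit: all homozygotes
        bad = column(500, 0, 500)
        obs = np.array([500, 0, 500])
        exp = 1000 * np.array([0.25, 0.5, 0.25])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert hwe_pvalues(bad[:, None])[0] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-10)
        G = build(np.column_stack([col, bad]))
        out, rep = qc_filter(G)
        assert rep.n_removed_hwe == 1 and rep.n_snps_out == 1

    def test_callrate_filter_and_imputation(self):
        keep = column(225, 450, 225, missing=100)  # 10% missing: boundary kept
        drop = column(225, 425, 200, missing=150)  # 15% missing: dropped
        G = build(np.column_stack([keep, drop]))
        out, rep = qc_filter(G, callrate_min=0.90)
        assert rep.n_removed_callrate == 1
        assert rep.n_imputed_entries == 100
        assert rep.n_snps_out == rep.n_snps_in - (
            rep.n_removed_callrate + rep.n_removed_maf + rep.n_removed_hwe
        )
        imputed = out.values[-100:, 0]
        freq = (2 * 225 + 450) / (2 * 900)
        assert np.allclose(imputed, 2 * freq)

    def test_all_removed_is_an_error(self):
        G = build(column(1000, 0, 0)[:, None])  # monomorphic -> MAF 0
        with pytest.raises(ValueError):
            qc_filter(G, maf_min=0.01)


class TestIO:
    def test_raw_round_trip(self, tmp_path):
        G, y, causal = make_setting("high", p=500, seed=4, n=60)
        path = tmp_path / "g.raw"
        write_genotypes(G, path, phenotype=y)
        G2, y2 = read_genotypes(path, format="raw")
        assert np.array_equal(G.values, G2.values)
        assert np.array_equal(G.snp_ids, G2.snp_ids)
        assert np.allclose(y, y2, atol=1e-4)  # %.6g round trip

    def test_csv_round_trip_with_missing(self, tmp_path):
        vals = np.array([[0, 1, MISSING], [2, MISSING, 1]], dtype=np.int8)
        G = GenotypeMatrix.from_values(vals)
        path = tmp_path / "g.csv"
        write_genotypes(G, path, format="csv")
        G2, _ = read_genotypes(path, format="csv")
        assert np.array_equal(G.values, G2.values)

    def test_invalid_genotype_token_names_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,snp1,snp2\nid1,0,3\nid2,1,2\n")
        with pytest.raises(ValueError, match="snp2"):
            read_genotypes(path, format="csv")

    def test_raw_dialect_header_check(self, tmp_path):
        path = tmp_path / "bad.raw"
        path.write_text("FID IID snp1_A\n1 1 2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_genotypes(path, format="raw")

    def test_phenotype_covariate_causal_round_trips(self, tmp_path):
        y = np.array([1.5, -2.25, 0.0])
        write_phenotype(y, tmp_path / "y.tsv")
        assert np.allclose(read_phenotype(tmp_path / "y.tsv"), y)
        C = np.array([[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]])
        write_covariates(C, tmp_path / "c.tsv")
        assert np.allclose(read_covariates(tmp_path / "c.tsv"), C)
        G, yv, causal = make_setting("low", p=150, seed=1, n=40)
        write_causal(G, causal, tmp_path / "causal.tsv")
        df = read_causal(tmp_path / "causal.tsv")
        assert len(df) == 25
        assert set(df["ld_class"]) == {"partially_permuted"}

    def test_write_selection_deterministic(self, tmp_path):
        df = pd.DataFrame({"snp": ["a", "b"], "value": [0.123456789, 1e-8]})
        write_selection(df, tmp_path / "one.tsv")
        write_selection(df, tmp_path / "two.tsv")
        assert (tmp_path / "one.tsv").read_bytes() == (tmp_path / "two.tsv").read_bytes()
        empty = pd.DataFrame({"snp": [], "value": []})
        write_selection(empty, tmp_path / "empty.tsv")
        assert (tmp_path / "empty.tsv").read_text().strip() == "snp\tvalue"


class TestPipeline:
    def test_config_round_trip_and_validation(self, tmp_path):
        cfg_text = (
            "seed: 3\nsettings: high\nalphas: 1, 0.1\ncriteria: 1se\n"
            "k: 5\nreps: 2\np: 300\nn_causal: 25\nout: {out}\n"
        )
        path = tmp_path / "run.cfg"
        path.write_text(cfg_text.format(out=tmp_path / "res.tsv"))
        cfg = load_config(path)
        assert cfg.alphas == (1.0, 0.1) and cfg.k == 5
        with pytest.raises(ValueError):
            RunConfig(alphas=(1.5,))
        with pytest.raises(ValueError):
            RunConfig(criteria=("best",))
        bad = tmp_path / "bad.cfg"
        bad.write_text("alphas = 1\n")
        with pytest.raises(ValueError):
            load_config(bad)

    def test_child_seeds_are_stable_and_distinct(self):
        a = child_seed(5, "table1")
        assert a == child_seed(5, "table1")
        assert a != child_seed(5, "cv")
        assert 0 <= a < 2**31

    def test_run_pipeline_smoke_and_determinism(self, tmp_path):
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        base = dict(seed=1, settings=("high",), alphas=(1.0,), criteria=("1se",),
                    k=5, reps=2, p=300, n_causal=25)
        assert run_pipeline(RunConfig(out=str(out1), **base)) == 0
        assert run_pipeline(RunConfig(out=str(out2), **base)) == 0
        assert out1.read_bytes() == out2.read_bytes()
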