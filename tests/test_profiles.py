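"""Expression ranking, metagene profiles and association statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bsmeth import (
    add_site_levels,
    compute_rpkm,
    expression_association,
    length_association,
    metagene_profile,
    rank_genes,
)
from conftest import make_sites


def levels_frame(rows):
    return add_site_levels(make_sites(rows))


class TestRpkm:
    def test_arithmetic(self):
        assert compute_rpkm([10], [1000], 1e6)[0] == pytest.approx(10.0)

    def test_zero_count(self):
        assert compute_rpkm([0], [500], 1e6)[0] == 0.0

    def test_scale_factor_is_divisor_and_round_trips(self):
        base = compute_rpkm([10], [1000], 1e6)
        scaled = compute_rpkm([10], [1000], 1e6, scale_factors=[2.0])
        assert scaled[0] == pytest.approx(base[0] / 2.0)
        np.testing.assert_allclose(scaled * np.array([2.0]), base)

    def test_zero_library_size_error(self):
        with pytest.raises(ValueError):
            compute_rpkm([1], [100], 0)


class TestRankGenes:
    def _table(self, rpkms):
        return pd.DataFrame(
            {"gene_id": [f"g{i:03d}" for i in range(len(rpkms))], "rpkm": rpkms}
        )

    def test_ten_expressed_one_per_rank(self):
        rpkms = [float(i + 1) for i in range(10)]
        out = rank_genes(self._table(rpkms), k=10)
        assert list(out.sort_values("rpkm")["rank"]) == list(range(1, 11))

    def test_all_silent_rank_zero(self):
        out = rank_genes(self._table([0.0] * 10), k=10)
        assert (out["rank"] == 0).all()

    def test_pigeonhole_bin_sizes(self):
        out = rank_genes(self._table(list(np.arange(1.0, 102.0))), k=10)
        sizes = out[out["rank"] > 0].groupby("rank").size()
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 101

    def test_partition(self, rng):
        rpkms = np.where(rng.random(57) < 0.3, 0.0, rng.lognormal(1, 1, 57))
        out = rank_genes(self._table(list(rpkms)), k=7)
        assert len(out) == 57 and out["gene_id"].is_unique
        assert set(out.loc[out["rpkm"] == 0, "rank"]) <= {0}
        assert (out.loc[out["rpkm"] > 0, "rank"] > 0).all()

    def test_rank_order_follows_rpkm(self):
        out = rank_genes(self._table([5.0, 1.0, 3.0, 0.0]), k=3)
        by_gene = out.set_index("gene_id")["rank"]
        assert by_gene["g003"] == 0
        assert by_gene["g001"] < by_gene["g002"] < by_gene["g000"]


def _gene(gene_id, chrom, start, end, strand, rank=0):
    return {
        "gene_id": gene_id,
        "chrom": chrom,
        "start": start,
        "end": end,
        "strand": strand,
        "rank": rank,
    }


class TestMetageneProfile:
    def test_uniform_gene_gives_flat_profile(self):
        sl = levels_frame(
            [("c", p, "+", "CpG", 3, 6) for p in range(0, 9000, 20)]
        )
        genes = pd.DataFrame([_gene("g1", "c", 3000, 6000, "+")])
        prof = metagene_profile(genes, sl)
        np.testing.assert_allclose(prof["mean_level"], 0.5)
        # TSS window: 20 flank bins + 20 body bins
        assert len(prof[prof["anchor"] == "TSS"]) == 40

    def test_minus_strand_tss_signal_flips(self):
        # minus-strand gene [1000, 2000): its TSS is at 1999, so body bin 0
        # covers genomic positions 1900..1999 (distances 0..99 running left)
        rows = [("c", p, "-", "CpG", 5, 5) for p in range(1900, 2000, 10)]
        rows += [("c", p, "-", "CpG", 0, 5) for p in range(1000, 1900, 10)]
        sl = levels_frame(rows)
        genes = pd.DataFrame([_gene("g1", "c", 1000, 2000, "-")])
        prof = metagene_profile(genes, sl)
        tss = prof[prof["anchor"] == "TSS"].set_index("bin")
        assert tss.loc[0, "mean_level"] == pytest.approx(1.0)
        assert tss.loc[1, "mean_level"] == pytest.approx(0.0)

    def test_strand_flip_is_involution(self):
        """A minus-strand gene with a mirrored site layout yields the same
        profile as its plus-strand counterpart."""
        L = 10_000
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(np.arange(2000, 8000), 300, replace=False))
        lv = rng.integers(0, 6, 300)
        plus = levels_frame(
            [("c", int(p), "+", "CpG", int(c), 5) for p, c in zip(pos, lv)]
        )
        minus = levels_frame(
            [("c", int(L - 1 - p), "-", "CpG", int(c), 5) for p, c in zip(pos, lv)]
        )
        gp = pd.DataFrame([_gene("g", "c", 4000, 6000, "+")])
        gm = pd.DataFrame([_gene("g", "c", L - 6000, L - 4000, "-")])
        pp = metagene_profile(gp, plus).set_index(["anchor", "bin"])
        pm = metagene_profile(gm, minus).set_index(["anchor", "bin"])
        pd.testing.assert_frame_equal(pp, pm)

    def test_bins_match_brute_force(self, rng):
        sl = levels_frame(
            [
                ("c", int(p), "+", "CpG", int(c), 5)
                for p, c in zip(
                    rng.choice(8000, 500, replace=False), rng.integers(0, 6, 500)
                )
            ]
        )
        genes = pd.DataFrame([_gene("g1", "c", 3000, 4500, "+")])
        prof = metagene_profile(genes, sl).query("anchor == 'TSS'")
        for row in prof.itertuples(index=False):
            lo = 3000 + row.bin * 100
            sub = sl[(sl["pos"] >= lo) & (sl["pos"] < lo + 100) & sl["eligible"]]
            assert row.mean_level == pytest.approx(sub["level"].mean())

    def test_short_gene_contributes_only_covered_bins(self):
        sl = levels_frame([("c", p, "+", "CpG", 5, 5) for p in range(0, 9000, 20)])
        genes = pd.DataFrame([_gene("g1", "c", 4000, 4300, "+")])
        prof = metagene_profile(genes, sl)
        tss_body = prof[(prof["anchor"] == "TSS") & (prof["bin"] >= 0)]
        assert tss_body["bin"].max() == 2  # 300 bp gene: bins 0..2 only

    def test_empty_rank_absent(self):
        sl = levels_frame([("c", 100, "+", "CpG", 5, 5)])
        genes = pd.DataFrame([_gene("g1", "c", 50, 500, "+", rank=4)])
        prof = metagene_profile(genes, sl)
        assert set(prof["rank"]) == {4}


class TestAssociations:
    def _genes(self, levels, lengths, status=None, rpkm=None):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i:03d}" for i in range(len(levels))],
                "level": levels,
                "length": lengths,
            }
        )
        df["status"] = status if status is not None else "methylated"
        if rpkm is not None:
            df["rpkm"] = rpkm
        return df

    def test_monotone_length_gives_r_one(self):
        res = length_association(
            self._genes([0.1, 0.4, 0.9], [100, 500, 2000])
        )
        assert res.spearman_r == pytest.approx(1.0)

    def test_permuted_labels_give_null_r(self, rng):
        levels = rng.random(50)
        lengths = rng.permutation(rng.integers(100, 5000, 50))
        res = length_association(self._genes(list(levels), list(lengths)))
        # independent permutation null: |r| small relative to its spread
        assert abs(res.spearman_r) < 3 / np.sqrt(49)

    def test_methylated_genes_longer_wilcoxon(self, rng):
        n = 40
        res = length_association(
            self._genes(
                list(rng.random(2 * n)),
                list(rng.integers(3000, 6000, n)) + list(rng.integers(100, 2000, n)),
                ["methylated"] * n + ["unmethylated"] * n,
            )
        )
        assert res.wilcoxon_p < 0.01

    def test_exclusion_count_exact(self):
        genes = self._genes(
            list(np.linspace(0, 1, 10)), [1000] * 10, rpkm=list(np.arange(10.0))
        )
        res = expression_association(genes, exclude_top_fraction=0.2)
        assert res.n_excluded == 8 and res.n_all == 10

    def test_top_dip_raises_r_after_exclusion(self, rng):
        # unimodal: level rises with expression but dips in the top decile
        n = 200
        rpkm = np.sort(rng.lognormal(1, 1, n))
        level = np.linspace(0.05, 0.8, n) + rng.normal(0, 0.03, n)
        level[-n // 10 :] = 0.3 + rng.normal(0, 0.03, n // 10)
        genes = self._genes(list(level), [1000] * n, rpkm=list(rpkm))
        res = expression_association(genes, exclude_top_fraction=0.2)
        assert res.spearman_r_excluded > res.spearman_r_all

    def test_fraction_validation(self):
        genes = self._genes([0.1, 0.2, 0.3], [1, 2, 3], rpkm=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            expression_association(genes, exclude_top_fraction=1.0)


def test_spearman_equals_rank_then_pearson(rng):
    """The library Spearman matches an independent rank-transform + Pearson
    computation to 1e-12 (ties included)."""
    for _ in range(20):
        x = rng.integers(0, 20, 60).astype(float)
        y = x * 0.5 + rng.normal(0, 2, 60)
        r_lib = stats.spearmanr(x, y).statistic
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        r_ind = np.corrcoef(rx, ry)[0, 1]
        assert r_lib == pytest.approx(r_ind, abs=1e-12)
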