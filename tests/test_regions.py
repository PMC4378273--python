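"""Region levels, element summaries, density track and repeat analyses."""

import numpy as np
import pandas as pd
import pytest

from bsmeth import (
    add_site_levels,
    element_summary,
    feature_methylation,
    mcg_density_track,
    region_level,
    repeat_divergence_analysis,
    site_level,
)
from conftest import make_sites


def levels_frame(rows):
    """site-levels frame from (chrom,pos,strand,context,c_count,depth)."""
    return add_site_levels(make_sites(rows))


class TestSiteLevel:
    def test_examples(self):
        assert site_level(5, 5) == (1.0, True)
        assert site_level(1, 4) == (0.25, False)
        assert site_level(0, 10) == (0.0, True)

    def test_zero_depth_error(self):
        with pytest.raises(ValueError):
            site_level(0, 0)


class TestRegionLevel:
    def test_mean_of_two(self):
        sl = levels_frame([("c", 10, "+", "CpG", 5, 5), ("c", 20, "+", "CpG", 0, 5)])
        assert region_level("c", 0, 100, sl).level == pytest.approx(0.5)

    def test_unweighted_mean_not_depth_weighted(self):
        # levels 0.2 (depth 10), 0.4 (depth 5), 0.9 (depth 20): plain mean 0.5
        sl = levels_frame(
            [
                ("c", 1, "+", "CpG", 2, 10),
                ("c", 2, "+", "CpG", 2, 5),
                ("c", 3, "+", "CpG", 18, 20),
            ]
        )
        assert region_level("c", 0, 10, sl).level == pytest.approx(0.5)

    def test_ineligible_sites_excluded(self):
        sl = levels_frame([("c", 1, "+", "CpG", 4, 4), ("c", 2, "+", "CpG", 0, 5)])
        assert region_level("c", 0, 10, sl).level == pytest.approx(0.0)

    def test_empty_region_level_is_nan_but_classifiable(self):
        sl = levels_frame([("c", 1, "+", "CpG", 1, 4)])  # not eligible
        calls = make_sites([("c", 1, "+", "CpG", 4, 4), ("c", 3, "-", "CpG", 4, 4)])
        calls["is_methylated"] = True
        res = region_level("c", 0, 10, sl, calls)
        assert np.isnan(res.level)
        assert res.n_mcgs == 2 and res.status == "methylated"

    def test_two_mcgs_make_region_methylated(self):
        sl = levels_frame([("c", 1, "+", "CpG", 5, 5)])
        calls = make_sites(
            [("c", 1, "+", "CpG", 5, 5), ("c", 2, "-", "CpG", 5, 5)]
        )
        calls["is_methylated"] = True
        assert region_level("c", 0, 10, sl, calls).status == "methylated"
        assert region_level("c", 0, 2, sl, calls).status == "unmethylated"

    def test_matches_brute_force_on_random_regions(self, rng):
        n = 400
        sl = levels_frame(
            [
                (
                    "c",
                    int(p),
                    "+" if rng.random() < 0.5 else "-",
                    rng.choice(["CpG", "CHH"]),
                    int(c),
                    int(d),
                )
                for p, c, d in zip(
                    rng.choice(5000, n, replace=False),
                    rng.integers(0, 5, n),
                    rng.integers(1, 15, n),
                )
            ]
        )
        for _ in range(100):
            s = int(rng.integers(0, 4900))
            e = s + int(rng.integers(10, 400))
            sub = sl[
                (sl["pos"] >= s) & (sl["pos"] < e)
                & (sl["context"] == "CpG") & sl["eligible"]
            ]
            got = region_level("c", s, e, sl)
            if sub.empty:
                assert np.isnan(got.level)
            else:
                assert got.level == pytest.approx(sub["level"].mean())
                assert got.n_covered_cpgs == len(sub)


class TestElementSummary:
    def _fixture(self):
        # one gene [100, 400): CDS [100,200), intron [200,300), CDS [300,400)
        gene_features = pd.DataFrame(
            [
                ("g1", "CDS", "c", 100, 200),
                ("g1", "intron", "c", 200, 300),
                ("g1", "CDS", "c", 300, 400),
            ],
            columns=["gene_id", "kind", "chrom", "start", "end"],
        )
        genes = pd.DataFrame(
            [("g1", "c", 100, 400, "+")],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )
        repeats = pd.DataFrame(
            [("r1", "c", 5000, 5200, "+", "SINE", 0.1)],
            columns=["repeat_id", "chrom", "start", "end", "strand", "rclass", "divergence"],
        )
        ncrnas = pd.DataFrame(
            [("n1", "c", 6000, 6100, "+", "tRNA")],
            columns=["ncrna_id", "chrom", "start", "end", "strand", "kind"],
        )
        return gene_features, genes, repeats, ncrnas

    def test_methylation_confined_to_cds(self):
        gf, genes, repeats, ncrnas = self._fixture()
        rows = [("c", p, "+", "CpG", 5, 5) for p in range(100, 200, 10)]  # CDS hot
        rows += [("c", p, "+", "CpG", 0, 5) for p in range(8000, 9000, 50)]  # other
        sl = levels_frame(rows)
        out = element_summary(sl, gf, genes, repeats, ncrnas, {"c": 10_000})
        by_kind = out.set_index("kind")["level"]
        assert by_kind["CDS"] == pytest.approx(1.0)
        assert by_kind["other"] == pytest.approx(0.0)

    def test_precedence_cds_over_repeat_and_flank(self):
        gf, genes, repeats, ncrnas = self._fixture()
        # site inside CDS and inside an overlapping repeat interval
        repeats.loc[0, ["start", "end"]] = [150, 250]
        sl = levels_frame([("c", 160, "+", "CpG", 5, 5), ("c", 220, "+", "CpG", 5, 5)])
        out = element_summary(sl, gf, genes, repeats, ncrnas, {"c": 10_000})
        counts = out.set_index("kind")["n_sites"]
        assert counts["CDS"] == 1  # 160 claimed by CDS despite repeat overlap
        assert counts["intron"] == 1  # 220: intron beats repeat
        assert "repeat:SINE" not in counts.index

    def test_absent_kinds_are_absent_not_zero(self):
        gf, genes, repeats, ncrnas = self._fixture()
        sl = levels_frame([("c", 8000, "+", "CpG", 0, 5)])
        out = element_summary(
            sl, gf, genes, repeats.iloc[0:0], ncrnas, {"c": 10_000}
        )
        assert not out["kind"].str.startswith("repeat:").any()

    def test_each_site_counted_once(self, tiny_run):
        from bsmeth.annotation import gene_subfeatures

        g = tiny_run["genome"]
        sl = tiny_run["site_levels"]
        out = element_summary(
            sl,
            gene_subfeatures(g.genes, g.exons),
            g.genes,
            g.repeats,
            g.ncrnas,
            g.chrom_lengths,
        )
        n_elig = (
            (sl["context"] == "CpG") & sl["eligible"] & (sl["chrom"] != "spike")
        ).sum()
        assert out["n_sites"].sum() == n_elig


class TestDensityTrack:
    def _calls(self, positions, chrom="c"):
        df = make_sites([(chrom, p, "+", "CpG", 5, 5) for p in positions])
        df["is_methylated"] = True
        return df

    def test_window_arithmetic(self):
        track = mcg_density_track(self._calls(range(10)), {"c": 1000})
        assert len(track) == 1
        assert track.iloc[0]["density"] == pytest.approx(0.01)

    def test_no_calls_all_zero(self):
        calls = self._calls([])
        track = mcg_density_track(calls, {"c": 3000})
        assert (track["density"] == 0).all() and len(track) == 3

    def test_partial_last_window_uses_actual_length(self):
        track = mcg_density_track(self._calls([2400]), {"c": 2500})
        last = track.iloc[-1]
        assert last["end"] - last["start"] == 500
        assert last["density"] == pytest.approx(1 / 500)

    def test_total_count_conserved(self, tiny_run):
        calls = tiny_run["calls"]
        g = tiny_run["genome"]
        track = mcg_density_track(calls, g.chrom_lengths)
        expected = (
            (calls["context"] == "CpG")
            & calls["is_methylated"]
            & (calls["chrom"] != g.spike_chrom)
        ).sum()
        assert track["n_mcgs"].sum() == expected
        np.testing.assert_allclose(
            track["density"] * (track["end"] - track["start"]), track["n_mcgs"]
        )


class TestRepeatDivergence:
    def _repeats(self, levels, divs, status=None):
        df = pd.DataFrame({"level": levels, "divergence": divs})
        df["status"] = status if status is not None else "methylated"
        return df

    def test_perfect_anticorrelation(self):
        res = repeat_divergence_analysis(
            self._repeats([0.9, 0.5, 0.1], [0.0, 0.2, 0.4])
        )
        assert res.spearman_r == pytest.approx(-1.0)

    def test_constant_levels_reported_undefined(self):
        res = repeat_divergence_analysis(
            self._repeats([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        )
        assert np.isnan(res.spearman_r)

    def test_methylated_group_younger_detected(self, rng):
        n = 60
        meth_div = rng.uniform(0.0, 0.15, n)
        unmeth_div = rng.uniform(0.2, 0.5, n)
        df = self._repeats(
            list(rng.uniform(0.5, 1, n)) + list(rng.uniform(0, 0.1, n)),
            list(meth_div) + list(unmeth_div),
            ["methylated"] * n + ["unmethylated"] * n,
        )
        res = repeat_divergence_analysis(df)
        assert res.wilcoxon_p < 0.05

    def test_too_few_repeats_error(self):
        with pytest.raises(ValueError):
            repeat_divergence_analysis(self._repeats([0.5], [0.1]))

    def test_status_count_monotone_in_alpha(self, tiny_run):
        """Lower calling alpha never creates new methylated features."""
        from bsmeth import call_methylation

        sites, e = tiny_run["sites"], tiny_run["error"].error_rate
        g = tiny_run["genome"]
        sl = tiny_run["site_levels"]
        counts = []
        for alpha in (0.05, 0.01, 0.001):
            calls = call_methylation(sites, e, alpha=alpha)
            ft = feature_methylation(g.repeats, sl, calls)
            counts.append((ft["status"] == "methylated").sum())
        assert counts[0] >= counts[1] >= counts[2]
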