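import numpy as np
import pandas as pd
import pytest

from exoarch import occupancy as occ
from exoarch import synthetic_data as sd
from exoarch import tagio
from exoarch.tagio import TagDataset


def tags_at(positions, strand="+", chrom="c", **kw):
    return TagDataset.from_records(
        [(chrom, p, strand) for p in positions], **kw
    )


class TestWindowSum:
    def test_upstream_window_counts(self):
        t = tags_at([950] * 10)  # TSS-50 for tss=1000
        assert occ.window_sum(t, "c", 1000, "+", (-400, 0)) == 10

    def test_downstream_window_excludes(self):
        t = tags_at([950] * 10)
        assert occ.window_sum(t, "c", 1000, "+", (0, 400)) == 0

    def test_minus_strand_mirrors(self):
        # tags 50 bp 3' of a minus-strand TSS sit at lower genomic coords
        t = tags_at([950] * 4)
        assert occ.window_sum(t, "c", 1000, "-", (0, 400)) == 4
        assert occ.window_sum(t, "c", 1000, "-", (-400, 0)) == 0

    def test_half_open_bounds(self):
        t = tags_at([1000, 1399, 1400])
        assert occ.window_sum(t, "c", 1000, "+", (0, 400)) == 2

    def test_weight_applied(self):
        t = tags_at([990])
        t.weight = 2.5
        assert occ.window_sum(t, "c", 1000, "+", (-400, 0)) == 2.5

    def test_strand_flip_conserves_total(self, rng):
        pos = rng.integers(600, 1400, 200)
        t = tags_at(pos.tolist())
        mirrored = tags_at((2000 - pos).tolist())
        a = occ.window_sum(t, "c", 1000, "+", (-400, 400))
        b = occ.window_sum(mirrored, "c", 1000, "-", (-400, 400))
        assert a == b

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            occ.window_sum(tags_at([1]), "c", 10, "+", (5, 5))


class TestRap1SiteOccupancy:
    def test_all_tags_at_site_no_downstream(self):
        t = tags_at([500] * 8)
        at, down = occ.rap1_site_occupancy(t, "c", 500, "+", normalize=None)
        assert at == 8 and down == 0

    def test_uniform_ratio_matches_window_widths(self):
        t = tags_at(list(range(100, 900)))  # one tag per bp
        at, down = occ.rap1_site_occupancy(t, "c", 500, "+", normalize=None)
        assert at == 81 and down == 121  # closed-form for a uniform rate

    def test_flank_normalization_flattens_uniform(self):
        t = tags_at(list(range(100, 900)))
        at, down = occ.rap1_site_occupancy(t, "c", 500, "+", normalize="flank")
        assert at == pytest.approx(1.0) and down == pytest.approx(1.0)

    def test_simulated_coactivator_peaks_downstream(self):
        _, arches = sd.build_genome(20, seed=31)
        exo = sd.ExoModel(depth=80, background_rate=0.002)
        fhl1 = tagio.shift_tags(
            sd.simulate_chipexo(arches, exo, sd.condition("normal"), "Fhl1", seed=32)
        )
        at_tot = down_tot = 0.0
        for a in arches:
            up = a.upstream_rap1()
            if up is None:
                continue
            at, down = occ.rap1_site_occupancy(fhl1, a.chrom, up, a.strand, normalize=None)
            at_tot += at
            down_tot += down
        assert down_tot > 2 * at_tot  # major cross-linking ~100 bp downstream


class TestNormalizeTable:
    def _table(self, col):
        return occ.OccupancyTable(raw=pd.DataFrame({"F": col}, index=list("abc")[: len(col)]))

    def test_median_normalized_log2(self):
        out = occ.normalize_table(self._table([1, 2, 4]))
        np.testing.assert_allclose(out.log2["F"], [-1, 0, 1])

    def test_constant_column_ties(self):
        out = occ.normalize_table(self._table([5, 5, 5]))
        np.testing.assert_allclose(out.log2["F"], 0)
        assert out.percent_rank["F"].nunique() == 1

    def test_scale_invariance(self):
        a = occ.normalize_table(self._table([1, 2, 4]))
        b = occ.normalize_table(self._table([2, 4, 8]))
        np.testing.assert_allclose(a.log2["F"], b.log2["F"])

    def test_percent_rank_range_and_monotone_invariance(self):
        raw = [3, 1, 10, 7]
        a = occ.normalize_table(
            occ.OccupancyTable(raw=pd.DataFrame({"F": raw}, index=list("abcd")))
        )
        b = occ.normalize_table(
            occ.OccupancyTable(
                raw=pd.DataFrame({"F": [x**2 for x in raw]}, index=list("abcd"))
            )
        )
        assert a.percent_rank["F"].between(0, 100).all()
        np.testing.assert_allclose(a.percent_rank["F"], b.percent_rank["F"])

    def test_all_zero_column_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            occ.normalize_table(self._table([0, 0, 0]), pseudocount=0.0)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            occ.normalize_table(self._table([1]))


@pytest.fixture(scope="module")
def cohort():
    _, arches = sd.build_genome(30, seed=41)
    exo = sd.ExoModel(depth=50, stop_jitter_sd=1.0, background_rate=0.005)
    hmo1 = tagio.shift_tags(
        sd.simulate_chipexo(arches, exo, sd.condition("normal"), "Hmo1", seed=42)
    )
    return arches, hmo1


class TestHmo1Breadth:

    def test_broad_gene_recovers_planted_breadth(self, cohort):
        arches, hmo1 = cohort
        for a in arches:
            if a.hmo1_class != "broad":
                continue
            r = occ.hmo1_breadth(
                hmo1, a.gene_id, a.chrom, a.tss, a.strand, a.upstream_rap1(),
                threshold_rule="combined",
            )
            assert abs(r.breadth - a.hmo1_breadth) <= 15

    def test_none_gene_near_zero(self, cohort):
        arches, hmo1 = cohort
        for a in arches:
            if a.hmo1_class != "none" or a.upstream_rap1() is None:
                continue
            r = occ.hmo1_breadth(
                hmo1, a.gene_id, a.chrom, a.tss, a.strand, a.upstream_rap1(),
                threshold_rule="combined",
            )
            assert r.breadth <= 10

    def test_infinite_threshold_zeroes_breadth(self, cohort):
        arches, hmo1 = cohort
        a = arches[0]
        if a.upstream_rap1() is None:
            a = next(x for x in arches if x.upstream_rap1() is not None)
        r = occ.hmo1_breadth(
            hmo1, a.gene_id, a.chrom, a.tss, a.strand, a.upstream_rap1(),
            threshold_rule="infinite",
        )
        assert r.breadth == 0

    def test_classify_rank_mode_group_sizes(self):
        recs = [occ.BreadthRecord(f"g{i}", b) for i, b in enumerate(range(130, 0, -1))]
        out = occ.classify_breadth(recs, mode="rank", group_sizes=(30, 30, 58))
        counts = {}
        for r in out:
            counts[r.group] = counts.get(r.group, 0) + 1
        assert counts == {"broad": 30, "narrow": 30, "none": 58, "unassigned": 12}

    def test_classify_bp_mode(self):
        recs = [occ.BreadthRecord("a", 160), occ.BreadthRecord("b", 110), occ.BreadthRecord("c", 3)]
        out = occ.classify_breadth(recs, mode="bp")
        assert [r.group for r in out] == ["broad", "narrow", "none"]


class TestHeatshockFoldChange:
    def test_identical_conditions_zero(self):
        m = pd.Series([10.0, 20, 30], index=list("abc"))
        fc, _ = occ.heatshock_fold_change(m, m, pd.Series([1, 2, 3], index=list("abc")))
        np.testing.assert_allclose(fc, 0)

    def test_seventy_percent_loss(self, rng):
        n = 400
        idx = [f"g{i}" for i in range(n)]
        mock = pd.Series(rng.poisson(300, n).astype(float), index=idx)
        hs = pd.Series(rng.poisson(300 * 0.3, n).astype(float), index=idx)
        fc, _ = occ.heatshock_fold_change(mock, hs, pd.Series(rng.random(n), index=idx))
        assert fc.mean() == pytest.approx(np.log2(0.3), abs=0.05)

    def test_quartile_means_monotone_in_programmed_loss(self, rng):
        n = 200
        idx = [f"g{i}" for i in range(n)]
        breadth = pd.Series(np.linspace(170, 0, n), index=idx)
        retention = 0.2 + 0.6 * (1 - breadth / 170)  # broader -> more loss
        mock = pd.Series(rng.poisson(500, n).astype(float), index=idx)
        hs = pd.Series(rng.poisson(500 * retention), index=idx).astype(float)
        _, groups = occ.heatshock_fold_change(mock, hs, breadth)
        means = groups["mean"].to_numpy()  # quartile 1 = broadest
        assert np.all(np.diff(means) > 0)


class TestEctopicFraction:
    def test_all_upstream_gives_one(self):
        t = tags_at([900] * 5)  # TSS-100
        assert occ.ectopic_fraction(t, "c", 1000, "+") == pytest.approx(1.0)

    def test_all_at_tss_gives_zero(self):
        t = tags_at([1000] * 5)
        assert occ.ectopic_fraction(t, "c", 1000, "+") == pytest.approx(0.0)

    def test_zero_denominator_missing(self):
        t = tags_at([5000])
        assert occ.ectopic_fraction(t, "c", 1000, "+") is None


class TestCorrelationMatrix:
    def _normalize(self, df):
        return occ.normalize_table(occ.OccupancyTable(raw=df))

    def test_unit_diagonal_and_identical_columns(self, rng):
        raw = pd.DataFrame(
            {"A": rng.poisson(50, 10), "B": rng.poisson(50, 10)},
            index=[f"g{i}" for i in range(10)],
        )
        raw["C"] = raw["A"]
        m = occ.correlation_matrix(self._normalize(raw), "log2")
        assert m.loc["A", "A"] == pytest.approx(1.0)
        assert m.loc["A", "C"] == pytest.approx(1.0)
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)

    def test_corecruited_factors_correlate(self, rng):
        # shared latent recruitment level -> Poisson-scaled observations
        latent = rng.gamma(4.0, 50.0, size=120)
        raw = pd.DataFrame(
            {
                "Sua7": rng.poisson(latent),
                "Toa2": rng.poisson(latent),
                "Noise": rng.poisson(np.full(120, latent.mean())),
            },
            index=[f"g{i}" for i in range(120)],
        )
        m = occ.correlation_matrix(self._normalize(raw), "log2")
        assert m.loc["Sua7", "Toa2"] > 0.7
        assert abs(m.loc["Sua7", "Noise"]) < 0.4

    def test_too_few_genes_rejected(self):
        df = pd.DataFrame({"A": [1, 2], "B": [2, 3]})
        with pytest.raises(ValueError):
            occ.correlation_matrix(occ.OccupancyTable(raw=df, log2=df), "log2")
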