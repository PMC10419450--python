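"""Candidate genes, hotspots, genotype-combination summaries and correlations."""

import numpy as np
import pandas as pd
import pytest

import peachgs as pg


def _panel(trait, ids):
    members = pd.DataFrame({"id": list(ids), "models": [("mlm",)] * len(ids),
                            "n_models": [1] * len(ids)})
    return pg.MarkerPanel(trait=trait, members=members)


def _marker_map(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])


class TestTraitCorrelation:
    def test_trivial_cases(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        p = pg.PhenotypeTable(
            values=pd.DataFrame({"x": x, "neg": -x, "same": x},
                                index=[f"s{i}" for i in range(5)]),
            kinds={t: "quantitative" for t in ("x", "neg", "same")})
        r, _ = pg.trait_correlation_matrix(p)
        assert r.loc["x", "x"] == pytest.approx(1.0)
        assert r.loc["x", "neg"] == pytest.approx(-1.0)
        assert r.loc["x", "same"] == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        b = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        p = pg.PhenotypeTable(
            values=pd.DataFrame({"a": a, "b": b},
                                index=[f"s{i}" for i in range(5)]),
            kinds={"a": "quantitative", "b": "quantitative"})
        r, pv = pg.trait_correlation_matrix(p)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        assert r.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
        assert 0 <= pv.loc["a", "b"] <= 1

    def test_sparse_trait_excluded(self, caplog):
        p = pg.PhenotypeTable(
            values=pd.DataFrame({
                "full": [1.0, 2.0, 3.0, 4.0],
                "sparse": [1.0, np.nan, np.nan, np.nan]},
                index=list("abcd")),
            kinds={"full": "quantitative", "sparse": "quantitative"})
        with caplog.at_level("WARNING", logger="peachgs"):
            r, _ = pg.trait_correlation_matrix(p)
        assert "sparse" not in r.columns and "sparse" in caplog.text


class TestCandidateGenes:
    def test_worked_terpene_synthase_locus(self):
        """A SNP at chr4:1,328,075 picks up genes spanning 1,390,452-1,422,386
        within its downstream 100-kb flank."""
        markers = _marker_map([("rs172271", "chr4", 1_328_075, "A", "T")])
        genes = [
            pg.GeneModel(id="tps1", chrom="chr4", start=1_390_452, end=1_394_000),
            pg.GeneModel(id="tps2", chrom="chr4", start=1_405_000, end=1_409_800),
            pg.GeneModel(id="tps3", chrom="chr4", start=1_418_000, end=1_422_386),
            pg.GeneModel(id="far", chrom="chr4", start=1_500_000, end=1_510_000),
        ]
        out = pg.candidate_genes(["rs172271"], genes, markers)
        assert [g.id for g in out["rs172271"]] == ["tps1", "tps2", "tps3"]

    def test_inclusive_boundary(self):
        markers = _marker_map([("s1", "chr1", 200_000, "A", "T")])
        at_edge = pg.GeneModel(id="edge", chrom="chr1",
                               start=300_000, end=301_000)
        past_edge = pg.GeneModel(id="out", chrom="chr1",
                                 start=300_001, end=301_000)
        out = pg.candidate_genes(["s1"], [at_edge, past_edge], markers,
                                 flank_bp=100_000)
        assert [g.id for g in out["s1"]] == ["edge"]

    def test_empty_annotation(self):
        markers = _marker_map([("s1", "chr1", 100, "A", "T")])
        assert pg.candidate_genes(["s1"], [], markers) == {"s1": []}

    def test_missing_chromosome_flagged(self, caplog):
        markers = _marker_map([("s1", "chr9", 100, "A", "T")])
        genes = [pg.GeneModel(id="g", chrom="chr1", start=50, end=80)]
        with caplog.at_level("WARNING", logger="peachgs"):
            out = pg.candidate_genes(["s1"], genes, markers)
        assert out["s1"] == [] and "chr9" in caplog.text

    def test_matches_brute_force_interval_scan(self, tiny_dataset):
        g = tiny_dataset["g"]
        genes = pg.read_gff3(tiny_dataset["gff"])
        rng = np.random.default_rng(17)
        snp_ids = list(rng.choice(g.markers["id"], size=30, replace=False))
        flank = 60_000
        out = pg.candidate_genes(snp_ids, genes, g, flank_bp=flank)
        lookup = g.markers.set_index("id")
        for sid in snp_ids:
            chrom, pos = lookup.loc[sid, "chrom"], int(lookup.loc[sid, "pos"])
            brute = {gm.id for gm in genes
                     if gm.chrom == chrom
                     and gm.start <= pos + flank and gm.end >= max(1, pos - flank)}
            assert {gm.id for gm in out[sid]} == brute


class TestDetectHotspots:
    MAP = _marker_map([
        ("snp_dec", "chr2", 2_663_753, "A", "T"),
        ("snp_oct", "chr2", 2_721_214, "G", "C"),
        ("far_a", "chr5", 1_000_000, "A", "T"),
        ("far_b", "chr5", 1_300_001, "A", "T"),
    ])

    def test_worked_two_lactone_hotspot(self):
        """Two lactone-associated SNPs 57 kb apart form one hotspot spanning
        chr2:2,663,753-2,721,214."""
        panels = [_panel("gamma_decalactone", ["snp_dec"]),
                  _panel("gamma_octalactone", ["snp_oct"])]
        regions = pg.detect_hotspots(panels, self.MAP)
        assert len(regions) == 1
        hs = regions[0]
        assert (hs.chrom, hs.start, hs.end) == ("chr2", 2_663_753, 2_721_214)
        assert set(hs.traits) == {"gamma_decalactone", "gamma_octalactone"}

    def test_strict_window(self):
        """SNPs 300,001 bp apart do not cluster at a 300-kb window."""
        panels = [_panel("t1", ["far_a"]), _panel("t2", ["far_b"])]
        assert pg.detect_hotspots(panels, self.MAP, window_bp=300_000) == []

    def test_single_trait_cluster_not_reported(self):
        panels = [_panel("t1", ["snp_dec", "snp_oct"]), _panel("t2", ["far_a"])]
        assert pg.detect_hotspots(panels, self.MAP) == []

    def test_matches_brute_force_clustering(self):
        """Randomized panels vs an O(n^2) all-pairs connected-components oracle."""
        rng = np.random.default_rng(23)
        rows = []
        for i in range(60):
            rows.append((f"s{i}", f"chr{rng.integers(1, 4)}",
                         int(rng.integers(1, 5_000_000)), "A", "T"))
        marker_map = _marker_map(rows)
        ids = [r[0] for r in rows]
        panels = [_panel("t1", ids[:30]), _panel("t2", ids[30:])]
        window = 300_000
        regions = pg.detect_hotspots(panels, marker_map, window_bp=window)

        # oracle: union-find over all pairs within the window on a chromosome
        info = {r[0]: (r[1], r[2]) for r in rows}
        trait_of = {s: ("t1" if s in ids[:30] else "t2") for s in ids}
        parent = {s: s for s in ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in ids:
            for b in ids:
                if a < b and info[a][0] == info[b][0] \
                        and abs(info[a][1] - info[b][1]) <= window:
                    parent[find(a)] = find(b)
        clusters = {}
        for s in ids:
            clusters.setdefault(find(s), []).append(s)
        expected = set()
        for members in clusters.values():
            if len({trait_of[s] for s in members}) >= 2:
                pos = [info[s][1] for s in members]
                expected.add((info[members[0]][0], min(pos), max(pos),
                              tuple(sorted(members))))
        got = {(r.chrom, r.start, r.end, tuple(r.snp_ids)) for r in regions}
        assert got == expected

    def test_regions_disjoint_and_multi_trait(self, tiny_dataset):
        g = tiny_dataset["g"]
        rng = np.random.default_rng(29)
        ids = list(g.markers["id"])
        panels = [_panel("a", rng.choice(ids, 20, replace=False)),
                  _panel("b", rng.choice(ids, 20, replace=False))]
        regions = pg.detect_hotspots(panels, g, window_bp=100_000)
        for r in regions:
            assert len(set(r.traits)) >= 2
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                assert e1 < s2


class TestGenotypeComboPercentage:
    def _toy(self):
        g = pg.GenotypeMatrix(
            dosage=np.array([[0.0, 2.0], [0.0, 2.0], [2.0, 0.0],
                             [2.0, 0.0], [0.0, 2.0], [2.0, 0.0]]),
            sample_ids=[f"s{i}" for i in range(6)],
            markers=_marker_map([("mA", "chr1", 100, "T", "G"),
                                 ("mB", "chr1", 200, "G", "A")]))
        return g

    def test_single_combination_is_100(self):
        g = pg.GenotypeMatrix(
            dosage=np.array([[0.0], [0.0], [0.0]]),
            sample_ids=["a", "b", "c"],
            markers=_marker_map([("m", "chr1", 10, "A", "T")]))
        p = pg.PhenotypeTable(
            values=pd.DataFrame({"q": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]),
            kinds={"q": "quantitative"})
        out = pg.genotype_combo_percentage(g, p, "q", ["m"])
        assert len(out) == 1 and out["percent"].iloc[0] == pytest.approx(100.0)

    def test_worked_arithmetic(self):
        """Combo means 4 and 2 against an overall mean of 3: 133.3% / 66.7%."""
        g = self._toy()
        p = pg.PhenotypeTable(
            values=pd.DataFrame({"q": [4.0, 4.0, 2.0, 2.0, 4.0, 2.0]},
                                index=g.sample_ids),
            kinds={"q": "quantitative"})
        out = pg.genotype_combo_percentage(g, p, "q", ["mA", "mB"])
        got = dict(zip(out["combo"], out["percent"]))
        assert got["TT/AA"] == pytest.approx(400 / 3)
        assert got["GG/GG"] == pytest.approx(200 / 3)

    def test_matches_groupby_oracle_and_weighted_identity(self, tiny_dataset):
        g, pheno = tiny_dataset["g"], tiny_dataset["pheno"]
        markers = list(np.random.default_rng(31).choice(
            g.markers["id"], 2, replace=False))
        raw = pheno.values["aroma_a"].astype(float) + 10.0  # positive scale
        p = pg.PhenotypeTable(values=pd.DataFrame({"aroma_a": raw}),
                              kinds={"aroma_a": "quantitative"})
        out = pg.genotype_combo_percentage(g, p, "aroma_a", markers)
        weighted = (out["percent"] * out["n"]).sum() / out["n"].sum()
        assert weighted == pytest.approx(100.0, abs=1e-9)
        # brute-force group-by
        from peachgs.postgwas import _combo_strings

        combos = _combo_strings(g, markers)
        overall = raw.mean()
        for _, row in out.iterrows():
            members = raw[(combos == row["combo"]).to_numpy()]
            assert row["percent"] == pytest.approx(100 * members.mean() / overall)
            assert row["n"] == len(members)

    def test_normalized_trait_requires_raw_values(self, tiny_dataset):
        g = tiny_dataset["g"]
        pheno = pg.normalize_traits(tiny_dataset["pheno"])
        markers = [g.markers["id"].iloc[0]]
        with pytest.raises(ValueError, match="raw"):
            pg.genotype_combo_percentage(g, pheno, "aroma_a", markers)
        raw = tiny_dataset["pheno"].values["aroma_a"].astype(float) + 10.0
        out = pg.genotype_combo_percentage(g, pheno, "aroma_a", markers,
                                           raw_values=raw)
        assert (out["n"] > 0).all()

    def test_qualitative_modal_percentage(self):
        g = self._toy()
        p = pg.PhenotypeTable(
            values=pd.DataFrame({"b": [1.0, 1.0, 0.0, 0.0, 0.0, 0.0]},
                                index=g.sample_ids),
            kinds={"b": "binomial"})
        out = pg.genotype_combo_percentage(g, p, "b", ["mA", "mB"])
        got = dict(zip(out["combo"], out["percent"]))
        assert got["TT/AA"] == pytest.approx(200 / 3)  # modal class 1 in 2/3
        assert got["GG/GG"] == pytest.approx(100.0)


class TestDiagnosticMarkerAccuracy:
    def test_perfect_rule(self):
        combos = pd.Series(["TT/TT", "CC/CC", "TT/TT"], index=list("abc"))
        pheno = pd.Series(["peach", "nectarine", "peach"], index=list("abc"))
        acc, confusion, excluded = pg.diagnostic_marker_accuracy(
            combos, pheno, {"TT/TT": "peach", "CC/CC": "nectarine"})
        assert acc == pytest.approx(1.0)
        assert excluded == 0
        assert confusion.loc["peach", "peach"] == 2

    def test_minority_rule(self):
        combos = pd.Series(["x"] * 10, index=[f"s{i}" for i in range(10)])
        pheno = pd.Series(["a"] * 7 + ["b"] * 3, index=[f"s{i}" for i in range(10)])
        acc, _, _ = pg.diagnostic_marker_accuracy(combos, pheno, {"x": "b"})
        assert acc == pytest.approx(0.3)

    def test_twenty_samples_two_discordant(self):
        idx = [f"s{i}" for i in range(20)]
        combos = pd.Series(["TT"] * 10 + ["CC"] * 10, index=idx)
        pheno = pd.Series(["p"] * 9 + ["n"] + ["n"] * 9 + ["p"], index=idx)
        acc, _, _ = pg.diagnostic_marker_accuracy(
            combos, pheno, {"TT": "p", "CC": "n"})
        assert acc == pytest.approx(0.90)

    def test_unknown_combos_excluded_and_counted(self):
        idx = list("abcd")
        combos = pd.Series(["TT", "TT", "??", "!!"], index=idx)
        pheno = pd.Series(["p", "p", "p", "n"], index=idx)
        acc, _, excluded = pg.diagnostic_marker_accuracy(combos, pheno,
                                                         {"TT": "p"})
        assert acc == pytest.approx(1.0) and excluded == 2

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pg.diagnostic_marker_accuracy(pd.Series(dtype=object),
                                          pd.Series(dtype=object), {})


class TestExpressionTraitCorrelation:
    STAGES = [f"S{i}" for i in range(6)]

    def _frame(self, **rows):
        return pd.DataFrame(rows, index=self.STAGES).T

    def test_perfect_correlations(self):
        content = pd.Series([1.0, 2, 3, 4, 5, 6], index=self.STAGES)
        expr = self._frame(up=[1.0, 2, 3, 4, 5, 6], down=[6.0, 5, 4, 3, 2, 1])
        out = pg.expression_trait_correlation(expr, content)
        assert out.loc["up", "r"] == pytest.approx(1.0)
        assert out.loc["down", "r"] == pytest.approx(-1.0)
        assert bool(out.loc["up", "significant"])

    def test_matches_hand_formula(self):
        content = pd.Series([2.0, 1, 4, 3, 6, 5], index=self.STAGES)
        x = np.array([1.0, 3, 2, 5, 4, 6])
        expr = self._frame(g=x)
        out = pg.expression_trait_correlation(expr, content)
        y = content.to_numpy()
        expected = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert out.loc["g", "r"] == pytest.approx(expected, abs=1e-12)

    def test_constant_expression_flagged_not_erred(self):
        content = pd.Series([1.0, 2, 3, 4, 5, 6], index=self.STAGES)
        expr = self._frame(flat=[2.0] * 6)
        out = pg.expression_trait_correlation(expr, content)
        assert np.isnan(out.loc["flat", "r"])
        assert bool(out.loc["flat", "constant"])
        assert not bool(out.loc["flat", "significant"])

    def test_too_few_shared_stages_errors(self):
        content = pd.Series([1.0, 2.0], index=["S0", "S1"])
        expr = self._frame(g=[1.0, 2, 3, 4, 5, 6])
        with pytest.raises(ValueError, match="stages"):
            pg.expression_trait_correlation(expr, content)
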