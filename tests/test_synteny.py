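import numpy as np
import pandas as pd
import pytest

from cavemap import synteny as sy
from oracles import Hit, enumerate_resolver_cases, resolve_oracle

TABLE3_CURRENT = [42, 23, 28, 24, 22, 37, 31, 42, 31, 14, 36, 26, 34, 24, 27,
                  23, 52, 32, 42, 21, 16, 42, 33, 38, 31]
TABLE3_FIRST_STUDY = [13, 6, 6, 3, 15, 9, 11, 4, 5, 3, 0, 7, 11, 6, 5, 3, 6,
                      8, 3, 7, 3, 4, 6, 8, 3]


def _hits_frame(rows):
    out = []
    for k, row in enumerate(rows):
        base = {"qseqid": "mk1", "sseqid": "T1", "pident": 98.0, "length": 60,
                "mismatch": 1, "gapopen": 0, "qstart": 1, "qend": 60,
                "sstart": 100, "send": 160, "evalue": 1e-20,
                "bitscore": 110.0, "route": "direct"}
        base.update(row)
        out.append(base)
    return pd.DataFrame(out)


class TestParseHitTable:
    def test_round_trip_and_evalue_filter(self, tmp_path):
        frame = _hits_frame([{"evalue": 1e-20}, {"evalue": 15.0,
                                                 "sseqid": "T2"}])
        path = tmp_path / "hits.tsv"
        frame.drop(columns="route")[sy.HIT_COLUMNS].to_csv(
            path, sep="\t", header=False, index=False)
        parsed = sy.parse_hit_table(path)
        assert len(parsed) == 1              # e-value 15 > cutoff 10 dropped
        assert parsed.evalue.iloc[0] == 1e-20

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert sy.parse_hit_table(path).empty

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q\tT1\t98\t60\t1\t0\t1\t60\t100\t160\t1e-20\t110\n"
                        "q\tT1\tnot_a_number\n")
        with pytest.raises(ValueError, match="line 2"):
            sy.parse_hit_table(path)


class TestCollapse:
    def test_single_hit_unchanged(self):
        frame = _hits_frame([{}])
        out = sy.collapse_per_target(frame)
        pd.testing.assert_frame_equal(out, frame)

    def test_lowest_evalue_retained_per_pair(self):
        frame = _hits_frame([{"evalue": 1e-5}, {"evalue": 1e-20}])
        out = sy.collapse_per_target(frame)
        assert len(out) == 1
        assert out.evalue.iloc[0] == 1e-20

    def test_allele_pair_collapse_shares_marker_id(self):
        # the two allele variants hit the same target; the better one wins
        frame = _hits_frame([{"evalue": 1e-12, "pident": 96.0},
                             {"evalue": 1e-15, "pident": 95.0}])
        out = sy.collapse_per_target(frame)
        assert len(out) == 1
        assert out.evalue.iloc[0] == 1e-15

    def test_row_order_invariance(self):
        rows = [{"evalue": 1e-5, "sseqid": "T2"}, {"evalue": 1e-20},
                {"evalue": 1e-8, "sseqid": "T2", "pident": 99.0}]
        a = sy.collapse_per_target(_hits_frame(rows))
        b = sy.collapse_per_target(_hits_frame(rows[::-1]))
        pd.testing.assert_frame_equal(
            a.sort_values("sseqid").reset_index(drop=True),
            b.sort_values("sseqid").reset_index(drop=True))


class TestResolveMarker:
    def _resolve(self, rows, support):
        frame = _hits_frame(rows)
        return sy.resolve_marker(frame, {t: [f"sup_{t}"] for t in support})

    def test_single_robust(self):
        a = self._resolve([{"sseqid": "chr6"}], set())
        assert (a.target, a.category) == ("chr6", "single_robust")

    def test_top_supported(self):
        a = self._resolve([{"sseqid": "chr6", "evalue": 1e-20},
                           {"sseqid": "chr3", "evalue": 1e-5}], {"chr6"})
        assert (a.target, a.category) == ("chr6", "top_supported")

    def test_not_top_supported(self):
        a = self._resolve([{"sseqid": "chr3", "evalue": 1e-20},
                           {"sseqid": "chr6", "evalue": 1e-5}], {"chr6"})
        assert (a.target, a.category) == ("chr6", "not_top_supported")

    def test_top_unsupported(self):
        a = self._resolve([{"sseqid": "chr3", "evalue": 1e-20},
                           {"sseqid": "chr6", "evalue": 1e-5}], set())
        assert (a.target, a.category) == ("chr3", "top_unsupported")

    def test_unresolved_discarded(self):
        a = self._resolve([{"sseqid": "chr3"}, {"sseqid": "chr6"}], set())
        assert a.category == "unresolved"
        assert a.target is None

    def test_matches_exhaustive_decision_table(self):
        for hits, support in enumerate_resolver_cases():
            frame = _hits_frame([h._asdict() | {"sseqid": h.target,
                                                "evalue": h.evalue,
                                                "pident": h.pident,
                                                "sstart": h.sstart,
                                                "send": h.send}
                                 for h in hits])
            frame = frame.drop(columns=["target"])
            got = sy.resolve_marker(frame,
                                    {t: ["sup"] for t in support})
            want_target, want_cat = resolve_oracle(hits, support)
            assert (got.target, got.category) == (want_target, want_cat), \
                (hits, support)

    def test_category_partition(self, small_cross):
        _, truemap, _, _ = small_cross
        from cavemap.simcross import simulate_hit_tables

        tables, _ = simulate_hit_tables(truemap, decoy_rate=0.5,
                                        conserved_fraction=0.9, seed=5)
        marker_group = {m: f"chr{truemap.chromosome_of(m)}"
                        for m in truemap.markers.index}
        collapsed = sy.collapse_per_target(tables["genomic"])
        resolved = sy.resolve_route(collapsed, marker_group)
        assert set(resolved) == set(collapsed.qseqid)
        counts = sy.category_counts(resolved, n_queries=len(truemap.markers))
        assert counts.n.sum() == len(truemap.markers)
        with_target = sum(1 for a in resolved.values() if a.target is not None)
        unresolved = sum(1 for a in resolved.values() if a.category == "unresolved")
        assert with_target + unresolved == len(resolved)

    def test_support_strictly_helps(self, small_cross):
        _, truemap, _, _ = small_cross
        from cavemap.simcross import simulate_hit_tables

        tables, truth = simulate_hit_tables(truemap, decoy_rate=0.5,
                                            conserved_fraction=0.9, seed=6,
                                            strong_decoy_rate=0.4)
        marker_group = {m: f"chr{truemap.chromosome_of(m)}"
                        for m in truemap.markers.index}
        collapsed = sy.collapse_per_target(tables["genomic"])
        resolved = sy.resolve_route(collapsed, marker_group)

        def accuracy(assignments):
            ok = tot = 0
            for mid, a in assignments.items():
                if a.target is None:
                    continue
                tot += 1
                ok += a.target == truth[mid]
            return ok / tot

        baseline = {}
        for mid, sub in collapsed.groupby("qseqid"):
            baseline[mid] = sy.resolve_marker(sub, None)
        assert accuracy(resolved) > accuracy(baseline)


class TestExtractFlank:
    def test_centered(self):
        assert sy.extract_flank(100_000, 5000) == (4032, 6031)

    def test_left_clip(self):
        assert sy.extract_flank(100_000, 10) == (1, 2000)

    def test_short_scaffold(self):
        assert sy.extract_flank(500, 300) == (1, 500)

    def test_outside_errors(self):
        with pytest.raises(ValueError):
            sy.extract_flank(1000, 990)   # tag overhangs the scaffold end
        with pytest.raises(ValueError):
            sy.extract_flank(1000, 0)


class TestCombineRoutes:
    def _setup(self, rows_by_route, group="LG1"):
        tables, results = {}, {}
        marker_group = {"mk1": group, "sup1": group}
        for route, rows in rows_by_route.items():
            frame = _hits_frame(rows)
            frame["route"] = route
            collapsed = sy.collapse_per_target(frame)
            tables[route] = collapsed
            results[route] = sy.resolve_route(collapsed, marker_group)
        return sy.combine_routes(results, tables, marker_group)

    def test_single_route_passthrough(self):
        out = self._setup({"genomic": [{"sseqid": "chr2"}]})
        assert out["mk1"].target == "chr2"
        assert out["mk1"].route == "genomic"

    def test_agreeing_routes_keep_lowest_evalue_route(self):
        out = self._setup({
            "genomic": [{"sseqid": "chr2", "evalue": 1e-30}],
            "direct": [{"sseqid": "chr2", "evalue": 1e-10}],
        })
        assert out["mk1"].target == "chr2"
        assert out["mk1"].route == "genomic"

    def test_disagreeing_routes_supported_target_wins(self):
        marker_group = {"mk1": "LG1", "other": "LG1"}
        tables, results = {}, {}
        for route, rows in {
            "genomic": [{"sseqid": "chr9", "evalue": 1e-30},
                        {"qseqid": "other", "sseqid": "chr2",
                         "evalue": 1e-25}],
            "transcriptomic": [{"sseqid": "chr2", "evalue": 1e-12}],
        }.items():
            frame = _hits_frame(rows)
            frame["route"] = route
            collapsed = sy.collapse_per_target(frame)
            tables[route] = collapsed
            results[route] = sy.resolve_route(collapsed, marker_group)
        out = sy.combine_routes(results, tables, marker_group)
        # 'other' single-candidate marker supports chr2 on LG1; for mk1 the
        # top candidate (chr9) is unsupported while chr2 is supported
        assert out["mk1"].target == "chr2"
        assert out["mk1"].category == "not_top_supported"


class TestStats:
    def test_mean_links_match_published_style_tables(self):
        assert sy.mean_links_per_chromosome(TABLE3_CURRENT) == 30.84
        assert sy.mean_links_per_chromosome(TABLE3_FIRST_STUDY) == 6.20

    def test_resolution_rate(self):
        assert sy.resolution_rate(784, 2235) == 35.1
        assert sy.resolution_rate(593, 2235) == 26.5
        assert sy.resolution_rate(298, 2235) == 13.3

    def test_zero_links_empty_report(self):
        report = sy.synteny_stats(pd.DataFrame(columns=["marker", "group",
                                                        "pos_cM", "target",
                                                        "target_bp"]), {})
        assert report["total_links"] == 0
        assert report["per_chromosome"] == []
        assert sy.oxford_matrix(pd.DataFrame()).empty

    def test_stats_report(self):
        rng = np.random.default_rng(3)
        rows = []
        for k in range(60):
            rows.append({"marker": f"m{k}", "group": f"LG{k % 3 + 1}",
                         "pos_cM": float(k), "target": f"chr{k % 2 + 1}",
                         "target_bp": 1000 * k, "category": "single_robust",
                         "route": "genomic"})
        links = pd.DataFrame(rows)
        report = sy.synteny_stats(links, {"chr1": 30.0, "chr2": 60.0})
        assert report["total_links"] == 60
        per = {e["chromosome"]: e for e in report["per_chromosome"]}
        assert per["chr1"]["n_links"] == 30
        assert per["chr1"]["links_per_mb"] == pytest.approx(1.0)
        matrix = sy.oxford_matrix(links)
        assert matrix.to_numpy().sum() == 60
        lines = sy.circos_lines(links)
        assert len(lines) == 60 and lines[0].startswith("LG1 ")
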