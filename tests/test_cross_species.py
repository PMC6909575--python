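"""Species table loading, filtering, and correlation statistics."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tegc.cross_species import (
    InsufficientDataError,
    SpeciesRecord,
    analysis_suite,
    apply_filters,
    correlate,
    exact_spearman_p,
    load_species_table,
    mean_c_value,
    write_species_table,
)


def rec(i, **kwargs):
    defaults = dict(
        species_id=f"Species sp{i}",
        lineage_flags=frozenset({"teleost"}),
        c_values_pg=(1.0,),
    )
    defaults.update(kwargs)
    return SpeciesRecord(**defaults)


class TestLoadTable:
    HEADER = (
        "species_id\tshort_code\tlineage_flags\tc_values_pg\tassembly_size_mb\t"
        "gc_genome\tte_percent\tgc_te\tgc_rep\tgc_nonrep\n"
    )

    def test_multi_cvalue_cell(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            self.HEADER
            + "Danio rerio\tDre\tteleost\t1.75;1.80\t1371\t36.8\t39.0\t39.5\t38.0\t36.5\n"
        )
        (r,) = load_species_table(p)
        assert r.c_values_pg == (1.75, 1.80)
        assert mean_c_value(r) == pytest.approx(1.775)
        assert r.lineage_flags == frozenset({"teleost"})

    def test_missing_cells_become_missing_not_zero(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER + "X y\tXy\tteleost\t1.0\t.\t\t.\t\t.\t.\n")
        (r,) = load_species_table(p)
        assert r.assembly_size_mb is None
        assert r.gc_te is None

    def test_negative_cvalue_reports_line(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER + "A b\tAb\tteleost\t-1.0\t.\t.\t.\t.\t.\t.\n")
        with pytest.raises(ValueError, match="line 2"):
            load_species_table(p)

    def test_unparseable_numeric_reports_line(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER + "A b\tAb\tteleost\t1.0\tbig\t.\t.\t.\t.\t.\n")
        with pytest.raises(ValueError, match="line 2"):
            load_species_table(p)

    def test_unknown_column_warns_but_loads(self, tmp_path, caplog):
        import logging

        p = tmp_path / "t.tsv"
        p.write_text(
            "species_id\tbogus\nA b\tz\n"
        )
        with caplog.at_level(logging.WARNING, logger="tegc.cross_species"):
            (r,) = load_species_table(p)
        assert r.species_id == "A b"
        assert any("bogus" in m for m in caplog.messages)

    def test_roundtrip(self, tmp_path):
        records = [
            rec(1, c_values_pg=(1.2, 1.4), gc_genome=40.0, te_percent=20.0),
            rec(2, lineage_flags=frozenset({"teleost", "salmonid"}), gc_te=44.5),
        ]
        p = tmp_path / "t.tsv"
        write_species_table(records, p)
        loaded = load_species_table(p)
        assert [r.species_id for r in loaded] == [r.species_id for r in records]
        assert loaded[0].c_values_pg == (1.2, 1.4)
        assert loaded[1].lineage_flags == frozenset({"teleost", "salmonid"})
        assert loaded[0].gc_te is None

    def test_percent_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="gc_genome"):
            rec(1, gc_genome=140.0)


class TestMeanCValue:
    @pytest.mark.parametrize(
        "cvals,expected", [((1.0, 1.4), 1.2), ((2.0,), 2.0), ((), None)]
    )
    def test_mean(self, cvals, expected):
        r = rec(1, c_values_pg=cvals)
        assert mean_c_value(r) == expected


class TestFilters:
    def panel(self):
        out = [rec(i) for i in range(10)]
        out += [
            rec(10 + i, lineage_flags=frozenset({"teleost", "salmonid"}))
            for i in range(8)
        ]
        return out

    def test_exclude_salmonids(self):
        kept, excluded = apply_filters(self.panel(), ["exclude_salmonids"])
        assert len(excluded) == 8
        assert all(name == "exclude_salmonids" for _, name in excluded)
        assert len(kept) + len(excluded) == 18

    def test_no_filter_identity(self):
        panel = self.panel()
        kept, excluded = apply_filters(panel, [])
        assert kept == panel and excluded == []

    def test_require_variables(self):
        panel = [rec(i, gc_te=40.0) for i in range(5)] + [rec(9)] * 3
        kept, excluded = apply_filters(panel, ["require_variables(gc_te)"])
        assert len(kept) == 5 and len(excluded) == 3

    def test_unknown_filter_is_config_error(self):
        with pytest.raises(ValueError, match="unknown filter"):
            apply_filters(self.panel(), ["exclude_sharks"])


class TestCorrelate:
    def linear_panel(self):
        return [
            rec(i, c_values_pg=(float(i),), te_percent=2.0 * i)
            for i in range(1, 4)
        ]

    def test_exact_linear_pearson(self):
        r = correlate(self.linear_panel(), "size_pg", "te_percent", "pearson")
        assert r.coefficient == pytest.approx(1.0)
        assert r.n == 3

    def test_sign_antisymmetry(self):
        panel = [
            rec(i, c_values_pg=(float(i),), te_percent=50.0 - 2.0 * i, gc_genome=2.0 * i)
            for i in range(1, 9)
        ]
        up = correlate(panel, "size_pg", "gc_genome", "pearson")
        down = correlate(panel, "size_pg", "te_percent", "pearson")
        assert up.coefficient == pytest.approx(-down.coefficient)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            correlate(self.linear_panel()[:2], "size_pg", "te_percent")

    def test_zero_variance_flagged_undefined(self):
        panel = [rec(i, c_values_pg=(1.0,), gc_genome=30.0 + i) for i in range(5)]
        r = correlate(panel, "size_pg", "gc_genome", "pearson")
        assert r.coefficient is None and r.p_value is None

    def test_missing_values_pairwise_deleted(self):
        panel = self.linear_panel() + [rec(99)]  # no te_percent
        r = correlate(panel, "size_pg", "te_percent", "pearson")
        assert r.n == 3

    def test_filters_recorded(self):
        panel = self.linear_panel() + [
            rec(50 + i, lineage_flags=frozenset({"teleost", "salmonid"}),
                c_values_pg=(9.0,), te_percent=1.0)
            for i in range(3)
        ]
        r = correlate(panel, "size_pg", "te_percent", "pearson", ["exclude_salmonids"])
        assert len(r.excluded) == 3 and r.n == 3
        assert r.filter_description == "exclude_salmonids"

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-100, max_value=100),
                st.floats(min_value=-100, max_value=100),
            ),
            min_size=5,
            max_size=12,
        ),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-5, max_value=5),
    )
    def test_pearson_affine_invariance(self, pts, scale, shift):
        panel = [
            rec(i, c_values_pg=(float(i + 1),), gc_genome=50 + x / 4, te_percent=50 + y / 4)
            for i, (x, y) in enumerate(pts)
        ]
        panel2 = [
            rec(i, c_values_pg=(float(i + 1),),
                gc_genome=min(100, max(0, (r.gc_genome - 50) * scale / 20 + 50 + shift)),
                te_percent=r.te_percent)
            for i, r in enumerate(panel)
        ]
        try:
            r1 = correlate(panel, "gc_genome", "te_percent", "pearson")
            r2 = correlate(panel2, "gc_genome", "te_percent", "pearson")
        except InsufficientDataError:
            return
        if r1.coefficient is None or r2.coefficient is None:
            return
        # positive affine rescaling of x leaves Pearson r unchanged (up to
        # clipping at the percent bounds, avoided by the small scale factor)
        assert r1.coefficient == pytest.approx(r2.coefficient, abs=1e-9)

    def test_spearman_equals_rank_then_pearson(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 13))
            x, y = rng.normal(size=n), rng.normal(size=n)
            panel = [
                rec(i, gc_genome=50 + xi, te_percent=50 + yi)
                for i, (xi, yi) in enumerate(zip(x, y))
            ]
            r = correlate(panel, "gc_genome", "te_percent", "spearman")
            oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
            assert r.coefficient == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=6), rng.normal(size=6)
        rho, p = exact_spearman_p(x, y)
        # independent enumeration: recompute rank-pearson over all 6! orders
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rx_c = rx - rx.mean()
        obs = None
        vals = []
        for perm in permutations(ry):
            ry_c = np.asarray(perm) - np.mean(perm)
            vals.append(float(rx_c @ ry_c / np.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))))
        obs = stats.spearmanr(x, y).statistic
        expect = sum(1 for v in vals if abs(v) >= abs(obs) - 1e-12) / len(vals)
        assert rho == pytest.approx(obs, abs=1e-12)
        assert p == pytest.approx(expect, abs=1e-12)

    def test_reorder_invariance(self):
        rng = np.random.default_rng(3)
        panel = [
            rec(i, c_values_pg=(float(rng.uniform(0.5, 4)),),
                gc_genome=float(rng.uniform(35, 48)))
            for i in range(12)
        ]
        r1 = correlate(panel, "size_pg", "gc_genome", "spearman")
        r2 = correlate(list(reversed(panel)), "size_pg", "gc_genome", "spearman")
        assert r1.coefficient == pytest.approx(r2.coefficient)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestAnalysisSuite:
    def test_skips_logged_not_silent(self):
        panel = [rec(i, c_values_pg=(float(i + 1),), te_percent=5.0 * i) for i in range(5)]
        report = analysis_suite(panel)  # no gc data at all
        skipped_names = [name for name, _ in report.skipped]
        assert any("gc_te~gc_genome" in n or "gc_te" in n for n in skipped_names)
        # size~TE still computed
        assert any(r.x_var == "size_pg" and r.y_var == "te_percent" for r in report.results)

    def test_deterministic_output(self):
        rng = np.random.default_rng(8)
        panel = [
            rec(i, c_values_pg=(float(rng.uniform(1, 3)),),
                gc_genome=float(rng.uniform(36, 46)),
                te_percent=float(rng.uniform(5, 50)),
                gc_te=float(rng.uniform(38, 50)),
                gc_rep=float(rng.uniform(36, 48)),
                gc_nonrep=float(rng.uniform(36, 48)),
                assembly_size_mb=float(rng.uniform(500, 3000)))
            for i in range(12)
        ]
        f1 = analysis_suite(panel).to_frame()
        f2 = analysis_suite(panel).to_frame()
        assert f1.equals(f2)

    def test_sign_table_lists_te_richer_species(self):
        panel = [
            rec(1, gc_genome=42.9, gc_te=42.0),  # TE pool GC-poorer than host
            rec(2, gc_genome=40.0, gc_te=44.0),
        ]
        report = analysis_suite(panel)
        table = report.sign_table.set_index("species_id")
        assert not table.loc["Species sp1", "te_gc_richer"]
        assert bool(table.loc["Species sp2", "te_gc_richer"])
        assert table.loc["Species sp1", "gc_te_minus_gc_genome"] == pytest.approx(-0.9)
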