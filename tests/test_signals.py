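"""Oracle and property tests for the four disproportionality algorithms and
the consensus screen."""

import math

import numpy as np
import pytest

from pvsignal.ingest import Report
from pvsignal.signals import (
    ContingencyTable,
    PriorParams,
    SignalConfig,
    bcpnn_ic,
    bcpnn_ic_approx,
    build_tables,
    detect_signals,
    fit_mgps_prior,
    mgps_ebgm,
    prr_stats,
    ror_stats,
)
from pvsignal.synthetic import PlantedAssociation, PlantedSignalSpec
from pvsignal.config import PipelineConfig
from pvsignal.pipeline import clean_cases, load_input_tables


def _report(pid, events):
    return Report(
        primaryid=str(pid), caseid=str(pid), fda_dt=None, sex="unknown",
        age_years=None, age_group="unknown", country="", reporter="unknown",
        report_year=None, outcomes=frozenset(), events=tuple(events),
    )


class TestBuildTables:
    def test_direct_counts(self):
        target = [_report(1, ["x"])]
        background = [_report(10 + i, ["y"]) for i in range(10)]
        t = build_tables(target, background)["x"]
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 10)

    def test_repeated_pt_counts_once(self):
        target = [_report(1, ["x", "x"])]
        background = [_report(2, ["y"])]
        assert build_tables(target, background)["x"].a == 1

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(4)
        pts = [f"pt{i}" for i in range(6)]
        target = [
            _report(i, rng.choice(pts, size=rng.integers(1, 4), replace=False))
            for i in range(8)
        ]
        background = [
            _report(100 + i, rng.choice(pts, size=rng.integers(1, 4), replace=False))
            for i in range(12)
        ]
        tables = build_tables(target, background)
        for pt in pts:
            a = sum(1 for r in target if pt in r.events)
            c = sum(1 for r in background if pt in r.events)
            t = tables[pt]
            assert (t.a, t.b, t.c, t.d) == (a, len(target) - a, c, len(background) - c)

    def test_margins_identical_across_pts(self, demo_populations):
        target, background, _ = demo_populations
        tables = build_tables(target, background)
        margins = {(t.a + t.b, t.c + t.d) for t in tables.values()}
        assert margins == {(len(target), len(background))}

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="no target"):
            build_tables([], [_report(1, ["x"])])


class TestRorPrr:
    def test_hand_arithmetic_table(self):
        t = ContingencyTable(10, 90, 100, 9900)
        ror, lo, hi, flag = ror_stats(t)
        assert ror == pytest.approx(11.0, abs=1e-12)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert lo == pytest.approx(11.0 * math.exp(-1.959963984540054 * se), rel=1e-9)
        assert hi == pytest.approx(11.0 * math.exp(+1.959963984540054 * se), rel=1e-9)
        assert flag
        prr, chi2, pflag = prr_stats(t)
        assert prr == pytest.approx(10.0, abs=1e-12)
        assert pflag

    def test_independence_table(self):
        t = ContingencyTable(1, 1, 1, 1)
        ror, _, _, flag = ror_stats(t)
        assert ror == pytest.approx(1.0) and not flag
        prr, _, pflag = prr_stats(ContingencyTable(10, 90, 100, 900))
        assert prr == pytest.approx(1.0) and not pflag

    def test_minimum_count_gate(self):
        t = ContingencyTable(2, 8, 1, 9999)  # huge effect, a < 3
        assert not ror_stats(t)[3]
        assert not prr_stats(t)[2]

    def test_zero_cell_continuity_correction(self):
        t = ContingencyTable(5, 95, 0, 1000)
        ror, lo, hi, _ = ror_stats(t)
        assert math.isfinite(ror) and math.isfinite(hi) and ror > 1
        expected = (5.5 * 1000.5) / (95.5 * 0.5)
        assert ror == pytest.approx(expected, rel=1e-12)

    def test_matches_independent_formulas_on_random_tables(self):
        """ROR/PRR/chi2 agree with independently coded textbook formulas to
        1e-9 on random small tables."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, size=4))
            if a + b == 0 or c + d == 0 or a + b + c + d == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            aa, bb, cc, dd = (
                (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
                if min(a, b, c, d) == 0
                else (a, b, c, d)
            )
            assert ror_stats(t)[0] == pytest.approx(aa * dd / (bb * cc), rel=1e-9)
            assert prr_stats(t)[0] == pytest.approx(
                (aa / (aa + bb)) / (cc / (cc + dd)), rel=1e-9
            )
            n = a + b + c + d
            # Yates chi-square, coded independently
            expect = [
                (a + b) * (a + c) / n, (a + b) * (b + d) / n,
                (c + d) * (a + c) / n, (c + d) * (b + d) / n,
            ]
            if all(e > 0 for e in expect):
                chi2 = sum(
                    (max(abs(o - e) - 0.5, 0)) ** 2 / e
                    for o, e in zip((a, b, c, d), expect)
                )
                assert prr_stats(t)[1] == pytest.approx(chi2, abs=1e-9)

    def test_ror_prr_agree_for_rare_events(self):
        # with c+d >> a+b and rare events, log ROR ~ log PRR
        t = ContingencyTable(12, 988, 40, 99_960)
        ror = ror_stats(t)[0]
        prr = prr_stats(t)[0]
        assert abs(math.log(ror) - math.log(prr)) / abs(math.log(prr)) < 0.05


class TestBcpnn:
    def test_independence_limit(self):
        t = ContingencyTable(100, 900, 1000, 9000)
        ic, ic025, flag = bcpnn_ic(t, n_draws=100_000, seed=5)
        assert abs(ic) < 0.05
        assert not flag

    def test_zero_count_shrinks_negative(self):
        ic, ic025, flag = bcpnn_ic(ContingencyTable(0, 100, 50, 5000),
                                   n_draws=20_000, seed=1)
        assert ic025 < 0 and not flag

    def test_determinism_under_fixed_seed(self):
        t = ContingencyTable(7, 93, 40, 9860)
        assert bcpnn_ic(t, 20_000, seed=3) == bcpnn_ic(t, 20_000, seed=3)

    def test_min_draws_enforced(self):
        with pytest.raises(ValueError):
            bcpnn_ic(ContingencyTable(1, 1, 1, 1), n_draws=100, seed=0)

    def test_monte_carlo_agrees_with_closed_form_grid(self):
        """On a 50-table grid the MC estimate matches the digamma/trigamma
        closed form within 0.05 for both IC and IC025."""
        counts = [0, 1, 2, 3, 5, 8, 13, 21, 34, 55]
        scales = [(20, 200, 2000), (50, 500, 10_000), (100, 400, 5000),
                  (30, 3000, 30_000), (80, 800, 4000), (200, 1000, 50_000)]
        n_checked = 0
        for nx, ny, n in scales:
            for a in counts:
                b, c = nx - a, ny - a
                d = n - a - b - c
                if min(b, c, d) < 0:
                    continue
                t = ContingencyTable(a, b, c, d)
                ic_mc, ic025_mc, _ = bcpnn_ic(t, n_draws=200_000, seed=17)
                ic_cf, ic025_cf = bcpnn_ic_approx(t)
                assert ic_mc == pytest.approx(ic_cf, abs=0.05)
                assert ic025_mc == pytest.approx(ic025_cf, abs=0.05)
                n_checked += 1
        assert n_checked >= 50


class TestMgps:
    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorParams(alpha1=-1.0)
        with pytest.raises(ValueError):
            PriorParams(w=1.0)

    def test_large_count_limit_tracks_relative_rate(self):
        t = ContingencyTable(400, 600, 1000, 99_000)
        ebgm, eb05, flag = mgps_ebgm(t)
        assert ebgm == pytest.approx(t.a / t.expected, rel=0.05)
        assert eb05 < ebgm
        assert flag

    def test_zero_count_shrinks_below_one(self):
        ebgm, eb05, flag = mgps_ebgm(ContingencyTable(0, 100, 200, 10_000))
        assert ebgm < 1.0 and not flag

    @pytest.mark.parametrize(
        "cells", [(10, 90, 100, 9900), (0, 50, 20, 930), (3, 7, 5, 85),
                  (50, 450, 100, 9400), (1, 9, 2, 988)]
    )
    def test_eb05_matches_posterior_sampling_oracle(self, cells):
        """Root-found EB05 equals the 5th percentile of direct posterior
        mixture samples within 0.01."""
        from pvsignal.signals import _mgps_posterior

        t = ContingencyTable(*cells)
        prior = PriorParams()
        _, eb05, _ = mgps_ebgm(t, prior)
        q1, (s1, s2), (r1, r2) = _mgps_posterior(t, prior)
        rng = np.random.default_rng(23)
        n = 2_000_000
        comp1 = rng.random(n) < q1
        draws = np.where(
            comp1, rng.gamma(s1, 1 / r1, size=n), rng.gamma(s2, 1 / r2, size=n)
        )
        assert eb05 == pytest.approx(np.quantile(draws, 0.05), abs=0.01)

    def test_prior_reestimation_recovers_reasonable_mixture(self):
        rng = np.random.default_rng(6)
        truth = PriorParams(0.3, 0.2, 2.0, 2.0, 0.4)
        tables = {}
        for i in range(400):
            e = float(rng.uniform(0.5, 30))
            comp = rng.random() < truth.w
            lam = rng.gamma(truth.alpha1, 1 / truth.beta1) if comp else rng.gamma(
                truth.alpha2, 1 / truth.beta2
            )
            a = int(rng.poisson(lam * e))
            n = 100_000
            nx = max(int(e * 10), a + 1)
            tables[f"pt{i}"] = ContingencyTable(
                a, nx - a, int(e * n / nx) - a if int(e * n / nx) > a else 1,
                n - nx,
            )
        fitted = fit_mgps_prior(tables)
        # the refit must at least improve the marginal likelihood vs default
        assert 0.0 < fitted.w < 1.0
        assert all(p > 0 for p in (fitted.alpha1, fitted.beta1, fitted.alpha2, fitted.beta2))


class TestDetectSignals:
    def test_consensus_is_logical_and(self, demo_populations):
        target, background, _ = demo_populations
        tables = build_tables(target, background)
        config = SignalConfig(bcpnn_draws=10_000)
        results = detect_signals(tables, config)
        assert results, "expected at least one tested PT"
        for r in results:
            assert r.consensus == (
                r.ror_flag and r.prr_flag and r.bcpnn_flag and r.mgps_flag
            )
            assert r.ror_lo <= r.ror <= r.ror_hi
            assert r.ic025 <= r.ic
            assert r.eb05 <= r.ebgm
            assert r.table.a >= config.min_count

    def test_sorted_by_descending_ror(self, demo_populations):
        target, background, _ = demo_populations
        results = detect_signals(
            build_tables(target, background), SignalConfig(bcpnn_draws=10_000)
        )
        rors = [r.ror for r in results]
        assert rors == sorted(rors, reverse=True)

    def test_empty_table_map(self):
        assert detect_signals({}, SignalConfig()) == []

    def test_planted_signal_recovered_in_consensus_list(self):
        """A single PT planted at relative risk 10 among 50 null PTs must be
        flagged by all four algorithms at n_target = 2000."""
        nulls = [(f"null{i:02d}", 0.01) for i in range(50)]
        spec = PlantedSignalSpec(
            n_target_reports=2000,
            n_background_reports=20_000,
            associations=[PlantedAssociation("stomatitis", 10.0, 0.01)],
            background_pts=nulls,
            duplicate_fraction=0.0,
            deleted_fraction=0.0,
            seed=2025,
        )
        config = PipelineConfig(synthetic=spec)
        config.signal.bcpnn_draws = 20_000
        tables, deleted = load_input_tables(config)
        target, background, _ = clean_cases(tables, deleted, config)
        results = detect_signals(build_tables(target, background), config.signal)
        consensus = {r.pt for r in results if r.consensus}
        assert "stomatitis" in consensus

    def test_null_corpus_consensus_no_looser_than_any_single_algorithm(self):
        """On all-null corpora the consensus false-positive count cannot
        exceed the most conservative single algorithm's (AND semantics),
        and stays low in absolute terms."""
        flags = {"ror": 0, "prr": 0, "bcpnn": 0, "mgps": 0, "consensus": 0}
        n_tested = 0
        for seed in range(5):
            spec = PlantedSignalSpec(
                n_target_reports=300,
                n_background_reports=3000,
                associations=[],
                background_pts=[(f"null{i:02d}", 0.02) for i in range(40)],
                duplicate_fraction=0.0, deleted_fraction=0.0, seed=seed,
            )
            config = PipelineConfig(synthetic=spec)
            config.signal.bcpnn_draws = 10_000
            tables, deleted = load_input_tables(config)
            target, background, _ = clean_cases(tables, deleted, config)
            for r in detect_signals(build_tables(target, background), config.signal):
                n_tested += 1
                flags["ror"] += r.ror_flag
                flags["prr"] += r.prr_flag
                flags["bcpnn"] += r.bcpnn_flag
                flags["mgps"] += r.mgps_flag
                flags["consensus"] += r.consensus
        assert n_tested > 50
        most_conservative = min(flags["ror"], flags["prr"], flags["bcpnn"], flags["mgps"])
        assert flags["consensus"] <= most_conservative
        assert flags["consensus"] / n_tested <= 0.05
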