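"""Scoring-progress analytics against independent brute-force recomputation."""

from datetime import date

import numpy as np
import pytest

from fieldgrid import analytics
from fieldgrid.errors import NotFoundError, UnsupportedTraitError
from fieldgrid.fixtures import SynthSpec, synth_trial
from fieldgrid.model import TraitType, add_measurement, create_trial

from .conftest import ts

# ---------------------------------------------------------------------------
# brute-force oracles: full rescans with direct formulas, no shared code paths


def brute_flags(state):
    flags = [[set() for _ in range(state.config.cols)] for _ in range(state.config.rows)]
    for r in range(state.config.rows):
        for c in range(state.config.cols):
            for name in [t.name for t in state.config.traits]:
                if len(state.records[(r, c)].measurements.get(name, ())) > 0:
                    flags[r][c].add(name)
    return flags


def brute_progress(state, name):
    return sum(
        1
        for cell in state.config.cells()
        if len(state.records[cell].measurements.get(name, ())) > 0
    )


def brute_axis(state, name):
    rows = [
        sum(
            1
            for c in range(state.config.cols)
            if state.records[(r, c)].measurements.get(name)
        )
        for r in range(state.config.rows)
    ]
    cols = [
        sum(
            1
            for r in range(state.config.rows)
            if state.records[(r, c)].measurements.get(name)
        )
        for c in range(state.config.cols)
    ]
    return rows, cols


def brute_timeline(state, name):
    """Recompute the cumulative fraction independently, per candidate date."""
    total = state.config.rows * state.config.cols
    all_dates = sorted(
        {
            m.timestamp.date()
            for rec in state.records.values()
            for ms in rec.measurements.values()
            for m in ms
        }
    )
    points = []
    for d in all_dates:
        scored = 0
        for cell in state.config.cells():
            ms = state.records[cell].measurements.get(name, ())
            if ms and min(m.timestamp.date() for m in ms) <= d:
                scored += 1
        points.append((d, scored / total))
    return points


def brute_summary_values(state, trait):
    epoch = date(1970, 1, 1)
    out = []
    for cell in state.config.cells():
        for m in state.records[cell].measurements.get(trait.name, ()):
            for v in m.values:
                out.append(float((v - epoch).days) if trait.dtype is TraitType.DATE else float(v))
    return out


def brute_five_numbers(values):
    """Direct type-7 quantiles: x[floor(h)] + frac(h)*(x[ceil(h)] - x[floor(h)])."""
    xs = sorted(values)
    n = len(xs)

    def q(p):
        h = (n - 1) * p
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return xs[0], q(0.25), q(0.5), q(0.75), xs[-1], sum(xs) / n


def brute_heatmap(state, trait):
    matrix = [[None] * state.config.cols for _ in range(state.config.rows)]
    for r in range(state.config.rows):
        for c in range(state.config.cols):
            ms = state.records[(r, c)].measurements.get(trait.name, ())
            if not ms:
                continue
            best = None
            for m in ms:
                if best is None or m.timestamp > best.timestamp:
                    best = m
            v = best.values[-1]
            if trait.dtype is TraitType.DATE:
                matrix[r][c] = float((v - date(1970, 1, 1)).days)
            elif trait.dtype is TraitType.CATEGORICAL:
                matrix[r][c] = float(trait.categories.index(v))
            else:
                matrix[r][c] = float(v)
    return matrix


# ---------------------------------------------------------------------------


@pytest.fixture(params=[0, 1, 2], ids=lambda s: f"seed{s}")
def synth(request):
    return synth_trial(
        SynthSpec(rows=4, cols=5, coverage=0.6, scoring_days=4, seed=request.param)
    )


class TestOracleEquivalence:
    def test_cell_trait_flags(self, synth):
        assert analytics.cell_trait_flags(synth) == brute_flags(synth)

    def test_progress_by_trait(self, synth):
        for p in analytics.progress_by_trait(synth):
            assert p.scored_plots == brute_progress(synth, p.trait)
            assert p.total_plots == 20
            assert p.fraction == p.scored_plots / 20

    def test_axis_marginals_conserve_totals(self, synth):
        for t in synth.config.traits:
            rows, cols = analytics.progress_by_axis(synth, t.name)
            b_rows, b_cols = brute_axis(synth, t.name)
            assert rows == b_rows and cols == b_cols
            assert sum(rows) == sum(cols) == brute_progress(synth, t.name)

    def test_timeline_matches_per_date_rescan(self, synth):
        for series in analytics.timeline(synth):
            assert list(series.points) == brute_timeline(synth, series.trait)

    def test_timeline_monotone_and_ends_at_progress(self, synth):
        progress = {p.trait: p.fraction for p in analytics.progress_by_trait(synth)}
        for series in analytics.timeline(synth):
            dates = [d for d, _ in series.points]
            fracs = [f for _, f in series.points]
            assert dates == sorted(set(dates))
            assert all(a <= b for a, b in zip(fracs, fracs[1:]))
            assert fracs[-1] == progress[series.trait]

    def test_summary_matches_direct_formulas(self, synth):
        for t in synth.config.traits:
            if t.dtype in (TraitType.TEXT, TraitType.CATEGORICAL):
                continue
            values = brute_summary_values(synth, t)
            summary = analytics.trait_summary(synth, t.name)
            mn, q1, med, q3, mx, mean = brute_five_numbers(values)
            assert summary.n == len(values)
            for got, want in zip(
                (summary.min, summary.q1, summary.median, summary.q3, summary.max, summary.mean),
                (mn, q1, med, q3, mx, mean),
            ):
                assert got == pytest.approx(want, abs=1e-12)

    def test_heatmap_matches_max_timestamp_scan(self, synth):
        for t in synth.config.traits:
            if t.dtype is TraitType.TEXT:
                continue
            assert analytics.heatmap_matrix(synth, t.name) == brute_heatmap(synth, t)

    def test_heatmap_nonabsent_count_equals_scored_plots(self, synth):
        for p in analytics.progress_by_trait(synth):
            if synth.config.trait(p.trait).dtype is TraitType.TEXT:
                continue
            matrix = analytics.heatmap_matrix(synth, p.trait)
            assert sum(v is not None for row in matrix for v in row) == p.scored_plots


class TestSmallCases:
    def test_fresh_trial_all_zero(self, state_2x3):
        assert all(not s for row in analytics.cell_trait_flags(state_2x3) for s in row)
        assert all(p.fraction == 0.0 for p in analytics.progress_by_trait(state_2x3))
        assert analytics.timeline(state_2x3)[0].points == ()
        assert analytics.trait_summary(state_2x3, "Plant height").empty

    def test_single_measurement_flags_and_marginals(self, state_2x3):
        s = add_measurement(state_2x3, (1, 2), "Plant height", ["10"], ts(2022, 6, 6))
        flags = analytics.cell_trait_flags(s)
        assert flags[1][2] == {"Plant height"} and flags[0][0] == set()
        rows, cols = analytics.progress_by_axis(s, "Plant height")
        assert rows == [0, 1] and cols == [0, 0, 1]

    def test_half_scored_fraction(self, state_2x3):
        s = state_2x3
        for cell in [(0, 0), (0, 1), (0, 2)]:
            s = add_measurement(s, cell, "Plant height", ["10"], ts(2022, 6, 6))
        (p,) = [p for p in analytics.progress_by_trait(s) if p.trait == "Plant height"]
        assert p.fraction == 0.5

    def test_timeline_two_plots_on_consecutive_days(self, config_2x3):
        # 2-plot coverage over two days on a 6-plot grid
        s = create_trial(config_2x3)
        s = add_measurement(s, (0, 0), "Plant height", ["1"], ts(2022, 6, 6, 9))
        s = add_measurement(s, (0, 1), "Plant height", ["2"], ts(2022, 6, 7, 9))
        (series,) = [x for x in analytics.timeline(s) if x.trait == "Plant height"]
        assert series.points == (
            (date(2022, 6, 6), 1 / 6),
            (date(2022, 6, 7), 2 / 6),
        )

    def test_rescoring_does_not_move_the_timeline(self, config_2x3):
        s = create_trial(config_2x3)
        s = add_measurement(s, (0, 0), "Yield", ["1"], ts(2022, 6, 6, 9))
        s = add_measurement(s, (0, 0), "Yield", ["2"], ts(2022, 6, 8, 9))
        (series,) = [x for x in analytics.timeline(s) if x.trait == "Yield"]
        assert [f for _, f in series.points] == [1 / 6, 1 / 6]

    def test_five_point_summary_on_one_to_five(self, config_2x3):
        s = create_trial(config_2x3)
        for i, cell in enumerate([(0, 0), (0, 1), (0, 2), (1, 0), (1, 1)], start=1):
            s = add_measurement(s, cell, "Plant height", [str(i)], ts(2022, 6, 6))
        summary = analytics.trait_summary(s, "Plant height")
        assert (summary.min, summary.q1, summary.median, summary.q3, summary.max, summary.mean) == (
            1, 2, 3, 4, 5, 3,
        )

    def test_single_value_summary_collapses(self, state_2x3):
        s = add_measurement(state_2x3, (0, 0), "Plant height", ["7"], ts(2022, 6, 6))
        summary = analytics.trait_summary(s, "Plant height")
        assert {summary.min, summary.q1, summary.median, summary.q3, summary.max} == {7.0}

    def test_categorical_summary_includes_zero_count_categories(self, state_2x3):
        s = add_measurement(state_2x3, (0, 0), "Growth habit", ["erect"], ts(2022, 6, 6))
        s = add_measurement(s, (0, 1), "Growth habit", ["erect"], ts(2022, 6, 6))
        summary = analytics.trait_summary(s, "Growth habit")
        assert summary.counts == {"erect": 2, "intermediate": 0, "prostrate": 0}

    def test_heatmap_latest_value_wins_for_multi_trait(self, state_2x3):
        s = add_measurement(state_2x3, (0, 0), "Yield", ["10"], ts(2022, 6, 6))
        s = add_measurement(s, (0, 0), "Yield", ["20"], ts(2022, 6, 7))
        assert analytics.heatmap_matrix(s, "Yield")[0][0] == 20.0
        assert analytics.heatmap_matrix(s, "Yield", agg="mean")[0][0] == 15.0

    def test_text_trait_unsupported_for_heatmap_and_summary(self, state_2x3):
        with pytest.raises(UnsupportedTraitError):
            analytics.heatmap_matrix(state_2x3, "Notes")
        with pytest.raises(UnsupportedTraitError):
            analytics.trait_summary(state_2x3, "Notes")

    def test_unknown_trait_rejected(self, state_2x3):
        with pytest.raises(NotFoundError):
            analytics.progress_by_axis(state_2x3, "ghost")

    def test_scatter_pairs_only_doubly_scored_plots(self, state_2x3):
        s = add_measurement(state_2x3, (0, 0), "Plant height", ["10"], ts(2022, 6, 6))
        s = add_measurement(s, (0, 0), "Tiller count", ["3"], ts(2022, 6, 6))
        s = add_measurement(s, (0, 1), "Plant height", ["12"], ts(2022, 6, 6))
        assert analytics.scatter_pairs(s, "Plant height", "Tiller count") == [(10.0, 3.0)]
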