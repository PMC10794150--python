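"""Frequencies, AND/OR replicate merging, placeholder arithmetic, scores, hits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trnadisplay import (
    CountTable,
    annotate_hits,
    assemble_variant_matrix,
    call_hits,
    compute_scores,
    frequencies,
    ln_enrichment,
    score_counts,
)
from trnadisplay.errors import EmptyResultError, EmptySampleError
from trnadisplay.variant_model import SampleSpec

SPECS_332 = [
    SampleSpec("pos1", "positive", 1, "m"),
    SampleSpec("pos2", "positive", 2, "m"),
    SampleSpec("pos3", "positive", 3, "m"),
    SampleSpec("neg1", "negative", 1, "m"),
    SampleSpec("neg2", "negative", 2, "m"),
    SampleSpec("neg3", "negative", 3, "m"),
    SampleSpec("in1", "input", 1),
    SampleSpec("in2", "input", 2),
]


def table(**samples) -> CountTable:
    t = CountTable()
    for sid, cnts in samples.items():
        t.add_sample(sid, cnts)
    return t


class TestFrequencies:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"A": 9, "B": 1}, {"A": 0.9, "B": 0.1}),
            ({"A": 7}, {"A": 1.0}),
            ({"A": 1, "B": 1, "C": 2}, {"A": 0.25, "B": 0.25, "C": 0.5}),
        ],
    )
    def test_count_over_total(self, counts, expected):
        ft = frequencies(table(s=counts))
        assert ft.freqs["s"] == expected
        assert ft.totals["s"] == sum(counts.values())

    def test_frequencies_sum_to_one_per_sample(self):
        ft = frequencies(table(a={"A": 3, "B": 11, "C": 5}, b={"A": 2, "D": 8}))
        for sid in ("a", "b"):
            assert abs(sum(ft.freqs[sid].values()) - 1.0) < 1e-9

    def test_zero_total_sample_is_an_error(self):
        t = CountTable()
        t.counts["empty"] = {}
        with pytest.raises(EmptySampleError, match="empty"):
            frequencies(t)

    def test_scale_invariance(self):
        f1 = frequencies(table(s={"A": 3, "B": 7}))
        f2 = frequencies(table(s={"A": 300, "B": 700}))
        assert f1.freqs["s"] == f2.freqs["s"]


class TestReplicateMerge:
    def test_variant_missing_from_one_positive_replicate_is_dropped(self):
        t = table(
            pos1={"AAA": 5, "BBB": 5}, pos2={"AAA": 5, "BBB": 5}, pos3={"AAA": 10},
            neg1={"AAA": 10}, in1={"AAA": 10},
        )
        specs = [
            SampleSpec("pos1", "positive", 1, "m"), SampleSpec("pos2", "positive", 2, "m"),
            SampleSpec("pos3", "positive", 3, "m"), SampleSpec("neg1", "negative", 1, "m"),
            SampleSpec("in1", "input", 1),
        ]
        m = assemble_variant_matrix(frequencies(t), specs)
        assert m.variants == ["AAA"]

    def test_placeholder_is_095_counts_over_replicate_total(self):
        t = table(
            pos1={"AAA": 100}, neg1={"CCC": 10_000}, in1={"AAA": 50, "CCC": 50},
        )
        specs = [
            SampleSpec("pos1", "positive", 1, "m"),
            SampleSpec("neg1", "negative", 1, "m"),
            SampleSpec("in1", "input", 1),
        ]
        m = assemble_variant_matrix(frequencies(t), specs)
        assert m.variants == ["AAA"]
        assert m.neg[0, 0] == pytest.approx(0.95 / 10_000, rel=0, abs=0)
        assert bool(m.neg_placeholder[0, 0])

    def test_fully_observed_variant_gets_no_placeholders(self):
        t = table(
            pos1={"AAA": 4, "BBB": 6}, neg1={"AAA": 5, "BBB": 5}, in1={"AAA": 2, "BBB": 8},
        )
        specs = [
            SampleSpec("pos1", "positive", 1, "m"),
            SampleSpec("neg1", "negative", 1, "m"),
            SampleSpec("in1", "input", 1),
        ]
        m = assemble_variant_matrix(frequencies(t), specs)
        assert not m.neg_placeholder.any() and not m.input_placeholder.any()
        assert m.pos[m.variants.index("AAA"), 0] == 0.4

    def test_no_surviving_variant_is_an_error(self):
        t = table(pos1={"AAA": 1}, pos2={"BBB": 1}, neg1={"AAA": 1}, in1={"AAA": 1})
        specs = [
            SampleSpec("pos1", "positive", 1, "m"), SampleSpec("pos2", "positive", 2, "m"),
            SampleSpec("neg1", "negative", 1, "m"), SampleSpec("in1", "input", 1),
        ]
        with pytest.raises(EmptyResultError):
            assemble_variant_matrix(frequencies(t), specs)


class TestScores:
    def test_enrichment_is_quotient_of_mean_frequencies(self):
        t = table(
            pos1={"AAA": 2, "ZZZ": 98}, pos2={"AAA": 3, "ZZZ": 97}, pos3={"AAA": 4, "ZZZ": 96},
            neg1={"AAA": 1, "ZZZ": 99}, in1={"AAA": 1, "ZZZ": 99},
        )
        specs = [
            SampleSpec("pos1", "positive", 1, "m"), SampleSpec("pos2", "positive", 2, "m"),
            SampleSpec("pos3", "positive", 3, "m"), SampleSpec("neg1", "negative", 1, "m"),
            SampleSpec("in1", "input", 1),
        ]
        scores = score_counts(t, specs).set_index("variant")
        assert scores.loc["AAA", "enrichment"] == pytest.approx(0.03 / 0.01, rel=1e-12)

    def test_selectivity_is_mean_pos_over_mean_neg(self):
        t = table(
            pos1={"AAA": 30, "ZZZ": 970},
            neg1={"AAA": 3, "ZZZ": 997},
            in1={"AAA": 10, "ZZZ": 990},
        )
        specs = [
            SampleSpec("pos1", "positive", 1, "m"),
            SampleSpec("neg1", "negative", 1, "m"),
            SampleSpec("in1", "input", 1),
        ]
        with pytest.warns(UserWarning, match="single positive replicate"):
            scores = score_counts(t, specs).set_index("variant")
        assert scores.loc["AAA", "selectivity"] == pytest.approx(10.0, rel=1e-12)
        assert scores.loc["AAA", "dispersion"] == 0.0
        assert not scores.loc["AAA", "dispersion_defined"]

    def test_identical_positive_frequencies_give_zero_dispersion(self):
        t = table(
            pos1={"AAA": 5, "ZZZ": 5}, pos2={"AAA": 50, "ZZZ": 50},
            neg1={"AAA": 1, "ZZZ": 1}, in1={"AAA": 1, "ZZZ": 1},
        )
        specs = [
            SampleSpec("pos1", "positive", 1, "m"), SampleSpec("pos2", "positive", 2, "m"),
            SampleSpec("neg1", "negative", 1, "m"), SampleSpec("in1", "input", 1),
        ]
        scores = score_counts(t, specs)
        assert (scores["dispersion"] == 0).all()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_selectivity_identity_and_positivity_on_random_tables(self, seed):
        # S = E / E- to machine precision; all scores strictly positive
        rng = np.random.default_rng(seed)
        variants = ["AAA", "CCC", "GGG", "KKK", "WWW"][: rng.integers(2, 6)]
        t = CountTable()
        specs = []
        for cond, short, n in (("positive", "pos", 3), ("negative", "neg", 3), ("input", "in", 2)):
            for r in range(1, n + 1):
                sid = f"{short}{r}"
                # positives observe everything; others drop variants at random
                cnts = {}
                for v in variants:
                    c = int(rng.integers(1, 500))
                    if cond != "positive" and rng.random() < 0.3:
                        c = 0
                    if c:
                        cnts[v] = c
                if not cnts:
                    cnts[variants[0]] = 1
                t.add_sample(sid, cnts)
                specs.append(SampleSpec(sid, cond, r, None if cond == "input" else "m"))
        scores = score_counts(t, specs)
        assert (scores["enrichment"] > 0).all()
        assert (scores["neg_enrichment"] > 0).all()
        assert (scores["selectivity"] > 0).all()
        np.testing.assert_allclose(
            scores["selectivity"],
            scores["enrichment"] / scores["neg_enrichment"],
            rtol=1e-12,
        )

    def test_placeholder_monotonicity_in_negative_counts(self):
        # replacing the 0.95 placeholder with an observed count of 1 lowers S
        def selectivity(neg_aaa: int) -> float:
            neg = {"ZZZ": 999}
            if neg_aaa:
                neg["AAA"] = neg_aaa
                neg["ZZZ"] = 1000 - neg_aaa
            t = table(pos1={"AAA": 100, "ZZZ": 900}, neg1=neg, in1={"AAA": 10, "ZZZ": 990})
            specs = [
                SampleSpec("pos1", "positive", 1, "m"),
                SampleSpec("neg1", "negative", 1, "m"),
                SampleSpec("in1", "input", 1),
            ]
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores = score_counts(t, specs).set_index("variant")
            return float(scores.loc["AAA", "selectivity"])

        s_placeholder = selectivity(0)
        values = [selectivity(c) for c in (1, 2, 5, 20)]
        assert s_placeholder > values[0]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestHits:
    def _scores(self, rows):
        df = pd.DataFrame(rows)
        df["contains_stop"] = df["variant"].str.contains(r"\*")
        df["dispersion_defined"] = True
        return df

    def test_inclusive_thresholds_at_the_boundary(self):
        scores = self._scores(
            [
                {"variant": "AAA", "enrichment": 5.0, "selectivity": 10.0, "dispersion": 0.1},
                {"variant": "CCC", "enrichment": 4.999, "selectivity": 10.0, "dispersion": 0.1},
                {"variant": "GGG", "enrichment": 5.0, "selectivity": 9.999, "dispersion": 0.1},
            ]
        )
        hits = call_hits(scores)
        assert list(hits["variant"]) == ["AAA"]

    def test_dispersion_ceiling_excludes_noisy_variants(self):
        scores = self._scores(
            [
                {"variant": "AAA", "enrichment": 50.0, "selectivity": 50.0, "dispersion": 1.5},
                {"variant": "CCC", "enrichment": 50.0, "selectivity": 50.0, "dispersion": 0.5},
            ]
        )
        assert list(call_hits(scores)["variant"]) == ["CCC"]

    def test_stop_variants_excluded_by_default_but_flaggable(self):
        scores = self._scores(
            [
                {"variant": "A*A", "enrichment": 50.0, "selectivity": 50.0, "dispersion": 0.1},
                {"variant": "CCC", "enrichment": 50.0, "selectivity": 40.0, "dispersion": 0.1},
            ]
        )
        assert list(call_hits(scores)["variant"]) == ["CCC"]
        assert list(call_hits(scores, exclude_stops=False)["variant"]) == ["A*A", "CCC"]

    def test_ranking_by_selectivity_then_enrichment_then_key(self):
        scores = self._scores(
            [
                {"variant": "TTT", "enrichment": 6.0, "selectivity": 20.0, "dispersion": 0.1},
                {"variant": "AAA", "enrichment": 9.0, "selectivity": 30.0, "dispersion": 0.1},
                {"variant": "GGG", "enrichment": 9.0, "selectivity": 30.0, "dispersion": 0.1},
                {"variant": "CCC", "enrichment": 7.0, "selectivity": 30.0, "dispersion": 0.1},
            ]
        )
        assert list(call_hits(scores)["variant"]) == ["AAA", "GGG", "CCC", "TTT"]

    def test_annotate_hits_adds_boolean_column(self):
        scores = self._scores(
            [
                {"variant": "AAA", "enrichment": 6.0, "selectivity": 20.0, "dispersion": 0.1},
                {"variant": "CCC", "enrichment": 1.0, "selectivity": 1.0, "dispersion": 0.1},
            ]
        )
        out = annotate_hits(scores)
        assert out.set_index("variant")["hit"].to_dict() == {"AAA": True, "CCC": False}

    def test_empty_hit_list_is_valid(self):
        scores = self._scores(
            [{"variant": "AAA", "enrichment": 1.0, "selectivity": 1.0, "dispersion": 0.1}]
        )
        assert len(call_hits(scores)) == 0


class TestLnEnrichment:
    def test_known_values(self):
        assert ln_enrichment(0.0) == pytest.approx(np.log(2.0))
        assert ln_enrichment(5.0) == pytest.approx(np.log(7.0))

    def test_strictly_monotone(self):
        e = np.linspace(0.01, 100, 50)
        assert (np.diff(ln_enrichment(e)) > 0).all()
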