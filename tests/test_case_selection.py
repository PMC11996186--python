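import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aicm import brazil2015
from aicm.case_selection import (
    DEFAULT_RULE,
    SelectionRule,
    icd_procedure_ratio,
    link_ans,
    select_ans,
    select_sus,
)

from .conftest import make_cons_frame, make_det_frame, make_sus_frame


class TestSelectSus:
    def test_abortion_code_in_any_field_counts(self):
        df = make_sus_frame([("SP", 24, ["", "", "O062"], 2015)])
        t = select_sus(df, year=2015)
        assert t.cells[("SP", "20-29")] == 1

    def test_ectopic_molar_categories_never_count(self):
        df = make_sus_frame([("SP", 24, ["O001"], 2015)])
        assert select_sus(df, year=2015).total == 0

    def test_cooccurring_excluded_code_counts_unless_symmetric_rule(self):
        df = make_sus_frame([("SP", 24, ["O03", "O001"], 2015)])
        assert select_sus(df, year=2015).total == 1
        strict = SelectionRule(exclude_in_sus=True)
        assert select_sus(df, strict, year=2015).total == 0

    def test_year_and_age_filters(self):
        df = make_sus_frame(
            [("SP", 24, ["O03"], 2014), ("SP", 9, ["O03"], 2015),
             ("SP", 50, ["O03"], 2015), ("SP", 49, ["O03"], 2015)]
        )
        assert select_sus(df, year=2015).total == 1

    def test_empty_input_gives_zero_table(self):
        df = make_sus_frame([])
        assert select_sus(df, year=2015).total == 0


class TestLinkAns:
    def test_icd_and_procedure_on_same_event_dedup_to_one(self):
        cons = make_cons_frame([("E1", "SP", "20-24", ["O03"], 2015)])
        det = make_det_frame([("E1", "31309062")])
        lk = link_ans(cons, det)
        assert len(lk.events) == 1
        ev = lk.events.iloc[0]
        assert ev.has_abortion_icd and ev.has_abortion_procedure

    def test_excluded_icd_flag_set_even_with_procedure(self):
        cons = make_cons_frame([("E1", "SP", "20-24", ["O01"], 2015)])
        det = make_det_frame([("E1", "31303013")])
        lk = link_ans(cons, det)
        assert lk.events.iloc[0].has_excluded_icd
        assert select_ans(lk, mode="icd_or_procedure").total == 0

    def test_detail_only_event_retained_with_unknown_stratum(self):
        cons = make_cons_frame([])
        det = make_det_frame([("E9", "31309020"), ("E9", "31309062")])
        lk = link_ans(cons, det)
        assert len(lk.events) == 1
        assert lk.n_unlinkable == 1
        assert lk.events.iloc[0].has_abortion_procedure

    def test_duplicating_detail_rows_never_changes_selection(self):
        cons = make_cons_frame(
            [("E1", "SP", "20-24", [None, None, None, None], 2015),
             ("E2", "SP", "25-29", ["O05"], 2015)]
        )
        det = make_det_frame([("E1", "31309020"), ("E2", "31309062")])
        base = select_ans(link_ans(cons, det), mode="icd_or_procedure")
        doubled = select_ans(
            link_ans(cons, pd.concat([det, det], ignore_index=True)),
            mode="icd_or_procedure",
        )
        assert base == doubled


class TestSelectAns:
    def test_procedure_only_event_counts_in_combined_mode_only(self):
        cons = make_cons_frame(
            [("E1", "SP", "20-24", [None, None, None, None], 2015)]
        )
        det = make_det_frame([("E1", "31303013")])
        lk = link_ans(cons, det)
        assert select_ans(lk, mode="icd_only").total == 0
        assert select_ans(lk, mode="icd_or_procedure").total == 1

    def test_empty_events_give_zero_table(self):
        lk = link_ans(make_cons_frame([]), make_det_frame([]))
        assert select_ans(lk, mode="icd_or_procedure").total == 0

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["O03", "O06", "O00", "O01", ""]),
                st.booleans(),
                st.sampled_from(["15-19", "20-24", "30-34"]),
            ),
            max_size=25,
        )
    )
    def test_combined_mode_dominates_icd_only_cellwise(self, events):
        cons = make_cons_frame(
            [(f"E{i}", "SP", band, [icd] if icd else [None] * 4, 2015)
             for i, (icd, _, band) in enumerate(events)]
        )
        det = make_det_frame(
            [(f"E{i}", "31309020") for i, (_, proc, _) in enumerate(events) if proc]
        )
        lk = link_ans(cons, det)
        icd_t = select_ans(lk, mode="icd_only")
        both_t = select_ans(lk, mode="icd_or_procedure")
        a, b = icd_t.reindex_union(both_t)
        assert (b >= a).all()

    def test_adding_excluded_code_only_decreases_counts(self):
        rows = [("E1", "SP", "20-24", ["O03"], 2015),
                ("E2", "SP", "20-24", ["O05"], 2015)]
        base = select_ans(
            link_ans(make_cons_frame(rows), make_det_frame([])),
            mode="icd_or_procedure",
        )
        rows_excl = [("E1", "SP", "20-24", ["O03", "O00"], 2015),
                     ("E2", "SP", "20-24", ["O05"], 2015)]
        excl = select_ans(
            link_ans(make_cons_frame(rows_excl), make_det_frame([])),
            mode="icd_or_procedure",
        )
        a, b = excl.reindex_union(base)
        assert (a <= b).all() and excl.total < base.total


class TestNationalFixtures:
    """Aggregates of the generated national microdata match the margins."""

    def test_sus_selection_reproduces_national_grid(self, sus_counts):
        assert sus_counts.total == 134_054
        assert sus_counts == brazil2015.sus_margins()

    def test_ans_selection_reproduces_both_case_definitions(
        self, ans_counts_icd, ans_counts_both
    ):
        assert ans_counts_icd.total == 9_800
        assert ans_counts_both.total == 20_756

    def test_icd_procedure_ratio_national(self, ans_counts_icd, ans_counts_both):
        ratio = icd_procedure_ratio(ans_counts_both, ans_counts_icd)
        assert ratio.loc["Total", "Total"] == 2.1
        assert list(ratio.loc["Total", ["10-19", "20-29", "30-39", "40-49"]]) == [
            2.1, 2.0, 2.2, 2.2,
        ]


class TestRatioTable:
    def test_zero_denominator_is_undefined_not_error(self):
        from aicm.data_io import CountsTable

        num = CountsTable.from_dict({("A", "10-19"): 0, ("A", "20-29"): 4})
        den = CountsTable.from_dict({("A", "10-19"): 0, ("A", "20-29"): 2})
        r = num.ratio_to(den)
        assert np.isnan(r.loc["A", "10-19"])
        assert r.loc["A", "20-29"] == 2.0

    def test_two_decimal_ratio_of_printed_cells(self):
        from aicm.data_io import CountsTable

        est = CountsTable.from_dict({("BR", "10-19"): 4290})
        rep = CountsTable.from_dict({("BR", "10-19"): 669})
        assert est.ratio_to(rep, ndigits=2).loc["BR", "10-19"] == 6.41
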