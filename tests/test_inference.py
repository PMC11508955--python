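"""Marker interpretation and Boolean carrier-rule semantics."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hlatag import (
    DataError,
    GenotypeCall,
    MarkerSpec,
    MarkerStatus,
    SimConfig,
    infer_carrier,
    marker_status,
    predict_copies,
    simulate_cohort,
    zygosity_concordance,
)
from hlatag.panel import PanelRule, SNVAssay, parse_hla_allele

RS2395029 = SNVAssay("C__16222070_10", rsid="rs2395029", tag_allele="G", other_allele="T")
AS5801 = SNVAssay("5801A", mode="allele_specific", reference_channel="ß-Globin")

A31 = parse_hla_allele("A*31:01")


def status(assay_id, s, zyg=None):
    if zyg is None:
        zyg = {"positive": "het", "negative": "none", "indeterminate": "unknown"}[s]
    return MarkerStatus(assay_id, s, zyg)


def rule(combinator, *groups, target=A31):
    return PanelRule(target=target, members=tuple(tuple(g) for g in groups),
                     combinator=combinator)


class TestMarkerStatus:
    def test_het_tag_positive(self):
        m = marker_status(GenotypeCall("S1", "C__16222070_10", ("T", "G")), RS2395029)
        assert (m.status, m.zygosity) == ("positive", "het")

    def test_hom_tag_positive(self):
        m = marker_status(GenotypeCall("S1", "C__16222070_10", ("G", "G")), RS2395029)
        assert (m.status, m.zygosity) == ("positive", "hom")

    def test_no_tag_negative(self):
        m = marker_status(GenotypeCall("S1", "C__16222070_10", ("T", "T")), RS2395029)
        assert (m.status, m.zygosity) == ("negative", "none")

    def test_indeterminate_propagates(self):
        m = marker_status(
            GenotypeCall("S1", "C__16222070_10", (), "indeterminate"), RS2395029
        )
        assert m.status == "indeterminate"

    def test_foreign_alleles_rejected(self):
        with pytest.raises(DataError, match="foreign"):
            marker_status(GenotypeCall("S1", "C__16222070_10", ("A", "C")), RS2395029)

    def test_allele_specific_tokens(self):
        pos = marker_status(GenotypeCall("S1", "5801A", ("positive",)), AS5801)
        neg = marker_status(GenotypeCall("S1", "5801A", ("negative",)), AS5801)
        assert (pos.status, pos.zygosity) == ("positive", "unknown")
        assert (neg.status, neg.zygosity) == ("negative", "none")

    def test_allele_specific_bad_token(self):
        with pytest.raises(DataError):
            marker_status(GenotypeCall("S1", "5801A", ("G", "G")), AS5801)

    def test_assay_mismatch(self):
        with pytest.raises(DataError):
            marker_status(GenotypeCall("S1", "other", ("G", "T")), RS2395029)


class TestRuleSemantics:
    def test_single_passthrough(self):
        r = rule("SINGLE", ["a"])
        for s in ("positive", "negative", "indeterminate"):
            assert infer_carrier("S", [status("a", s)], r).status == s

    @pytest.mark.parametrize(
        "sa, sb, expected",
        [
            ("positive", "positive", "positive"),
            ("positive", "indeterminate", "positive"),  # ANY short-circuits
            ("positive", "negative", "positive"),
            ("negative", "negative", "negative"),
            ("negative", "indeterminate", "indeterminate"),
            ("indeterminate", "indeterminate", "indeterminate"),
        ],
    )
    def test_any(self, sa, sb, expected):
        r = rule("ANY", ["a"], ["b"])
        got = infer_carrier("S", [status("a", sa), status("b", sb)], r)
        assert got.status == expected

    @pytest.mark.parametrize(
        "sa, sb, expected",
        [
            ("positive", "positive", "positive"),
            ("positive", "negative", "negative"),
            # one determinate negative falsifies the conjunction even with
            # an indeterminate partner
            ("negative", "indeterminate", "negative"),
            ("positive", "indeterminate", "indeterminate"),
        ],
    )
    def test_all(self, sa, sb, expected):
        r = rule("ALL", ["a"], ["b"])
        got = infer_carrier("S", [status("a", sa), status("b", sb)], r)
        assert got.status == expected

    def test_all_demotes_single_marker_false_positive(self):
        # a sample positive on one tag SNV but negative on the partner must
        # come out negative under the conjunction rule
        r = rule("ALL", ["a"], ["b"])
        got = infer_carrier(
            "S", [status("a", "positive"), status("b", "negative")], r
        )
        assert got.status == "negative"

    def test_group_any_within_rule(self):
        # two assay designs for one SNV: either firing makes the group positive
        r = rule("ANY", ["a"], ["b1", "b2"])
        got = infer_carrier(
            "S",
            [status("a", "negative"), status("b1", "positive"),
             status("b2", "indeterminate")],
            r,
        )
        assert got.status == "positive"

    def test_missing_member_errors(self):
        r = rule("ALL", ["a"], ["b"])
        with pytest.raises(DataError, match="b"):
            infer_carrier("S", [status("a", "positive")], r)

    _STATUSES = ("positive", "negative", "indeterminate")

    @given(
        st.sampled_from(("ANY", "ALL")),
        st.lists(st.sampled_from(_STATUSES), min_size=2, max_size=5),
        st.integers(0, 4),
    )
    def test_monotone_upgrade_never_demotes_positive(self, comb, statuses, idx):
        idx = idx % len(statuses)
        groups = [[f"m{i}"] for i in range(len(statuses))]
        r = rule(comb, *groups)
        before = infer_carrier("S", [status(f"m{i}", s) for i, s in enumerate(statuses)], r)
        upgraded = list(statuses)
        upgraded[idx] = "positive"
        after = infer_carrier("S", [status(f"m{i}", s) for i, s in enumerate(upgraded)], r)
        if before.status == "positive":
            assert after.status == "positive"

    @given(st.lists(st.sampled_from(_STATUSES), min_size=1, max_size=4))
    def test_degenerate_member_oracles(self, statuses):
        groups = [[f"m{i}"] for i in range(len(statuses))] + [["fixed"]]
        markers = [status(f"m{i}", s) for i, s in enumerate(statuses)]
        all_rule = rule("ALL", *groups)
        any_rule = rule("ANY", *groups)
        assert (
            infer_carrier("S", markers + [status("fixed", "negative")], all_rule).status
            == "negative"
        )
        assert (
            infer_carrier("S", markers + [status("fixed", "positive")], any_rule).status
            == "positive"
        )


class TestRuleContainmentOnCohort:
    def test_all_subset_member_subset_any(self):
        cfg = SimConfig(
            n_samples=600, target="A*31:01",
            markers=(MarkerSpec("ANKCPPX", 0.9, 0.9),
                     MarkerSpec("C__33415939_10", 0.8, 0.95)),
            carrier_prevalence=0.2, seed=3,
        )
        cohort = simulate_cohort(cfg)
        from hlatag import marker_status as ms
        from hlatag.panel import default_panel

        panel = default_panel()
        by_sample = {}
        for c in cohort.calls:
            by_sample.setdefault(c.sample_id, {})[c.assay_id] = ms(
                c, panel.assays[c.assay_id]
            )
        all_rule = rule("ALL", ["ANKCPPX"], ["C__33415939_10"])
        any_rule = rule("ANY", ["ANKCPPX"], ["C__33415939_10"])
        pos = lambda r: {
            s for s, m in by_sample.items()
            if infer_carrier(s, m, r).status == "positive"
        }
        member = {
            s for s, m in by_sample.items() if m["ANKCPPX"].status == "positive"
        }
        assert pos(all_rule) <= member <= pos(any_rule)


class TestCopiesAndZygosity:
    def test_predict_copies(self):
        hom = [status("a", "positive", "hom"), status("b", "positive", "hom")]
        het = [status("a", "positive", "hom"), status("b", "positive", "het")]
        ind = [status("a", "indeterminate", "unknown")]
        assert predict_copies(hom) == 2
        assert predict_copies(het) == 1
        assert predict_copies(ind) is None
        assert predict_copies([status("a", "positive", "unknown")]) is None

    def test_copies_flagged_non_clinical(self):
        r = rule("SINGLE", ["a"])
        inf = infer_carrier("S", [status("a", "positive", "hom")], r)
        assert inf.predicted_copies == 2
        assert "copy_number_non_clinical" in inf.non_clinical_flags

    def _cohort(self, discord, n, seed):
        cfg = SimConfig(
            n_samples=n, target="A*31:01",
            markers=(MarkerSpec("ANKCPPX", 1.0, 1.0),),
            allele_frequency=0.25, zygosity_discordance_rate=discord, seed=seed,
        )
        cohort = simulate_cohort(cfg)
        from hlatag.panel import default_panel

        panel = default_panel()
        r = rule("SINGLE", ["ANKCPPX"])
        infs = []
        for c in cohort.calls:
            m = marker_status(c, panel.assays["ANKCPPX"])
            infs.append(infer_carrier(c.sample_id, {"ANKCPPX": m}, r))
        return cohort, infs

    def test_perfect_linkage_no_offdiagonal(self):
        cohort, infs = self._cohort(0.0, 400, seed=1)
        rep = zygosity_concordance(infs, cohort.references, A31)
        assert rep.n_discordant == 0
        assert rep.total == int(cohort.samples.carrier.sum())

    def test_discordance_rate_recovered(self):
        from hlatag import clopper_pearson_ci

        cohort, infs = self._cohort(0.10, 1000, seed=2)
        rep = zygosity_concordance(infs, cohort.references, A31)
        lo, hi = clopper_pearson_ci(rep.n_discordant, rep.total)
        assert lo <= 0.10 <= hi  # generating rate inside the 95% CI

    def test_single_hom_marker_two_copy_sample(self):
        from hlatag import ReferenceTyping

        r = rule("SINGLE", ["a"])
        inf = infer_carrier("S1", [status("a", "positive", "hom")], r)
        ref = ReferenceTyping("S1", "A", (A31, A31))
        rep = zygosity_concordance([inf], [ref], A31)
        assert rep.as_dict()["hom_marker_2_copies"] == 1 and rep.total == 1
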