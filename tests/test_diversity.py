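import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rdnadiv import (CohortConfig, DataError, VariantSpec, correlate_counts,
                     entropy_profile, entropy_value, generate_cohort,
                     ivf_class_counts, nonfixed_variant_count,
                     sharing_distribution, summarize_elements,
                     synthetic_variant_het_counts)


class TestEntropy:
    def test_monomorphic_site_has_zero_entropy(self, prototype, call_row):
        prof = entropy_profile(pd.DataFrame([call_row(100, 0.5)]), {"iso": 100.0},
                               prototype)
        assert prof.loc[200, "H"] == 0.0  # untouched position

    def test_even_split_gives_ln2(self, prototype, call_row):
        prof = entropy_profile(pd.DataFrame([call_row(100, 0.5)]), {"iso": 100.0},
                               prototype)
        assert prof.loc[99, "H"] == pytest.approx(math.log(2))

    def test_two_isolate_worked_example(self, prototype, call_row):
        """One of two M=100 isolates carries an alt at iVF 0.5: the pooled
        alt count is 50 of N=200 copies, H = -(0.25 ln 0.25 + 0.75 ln 0.75)."""
        prof = entropy_profile(
            pd.DataFrame([call_row(100, 0.5, isolate_id="i1")]),
            {"i1": 100.0, "i2": 100.0}, prototype,
        )
        row = prof.loc[99]
        assert row["N"] == 200
        assert row[f"n_{prototype.sequence[99]}"] == 150
        assert row["H"] == pytest.approx(0.5623, abs=2e-4)

    def test_indel_alleles_pool_into_one_category(self, prototype, call_row):
        ref = prototype.sequence[99]
        rows = [call_row(100, 0.2, isolate_id="i1", ref=ref, alt=ref + "AT"),
                call_row(100, 0.1, isolate_id="i2", ref=ref + "TG", alt=ref)]
        prof = entropy_profile(pd.DataFrame(rows), {"i1": 100.0, "i2": 100.0},
                               prototype)
        assert prof.loc[99, "n_indel"] == 30  # 20 + 10 copies

    def test_bounds_zero_to_ln5(self, prototype, call_row):
        rows = [call_row(100, 0.2, isolate_id=f"i{k}", alt=alt)
                for k, alt in enumerate(b for b in "ACGT"
                                        if b != prototype.sequence[99])]
        ref = prototype.sequence[99]
        rows.append(call_row(100, 0.2, isolate_id="i9", ref=ref, alt=ref + "A"))
        copies = {r["isolate_id"]: 100.0 for r in rows}
        prof = entropy_profile(pd.DataFrame(rows), copies, prototype)
        assert 0.0 <= prof["H"].max() <= math.log(5) + 1e-12

    def test_copies_exceeding_m_rejected(self, prototype, call_row):
        rows = [call_row(100, 0.9, isolate_id="i1"),
                call_row(100, 0.9, isolate_id="i1",
                         alt="G" if prototype.sequence[99] != "G" else "C")]
        with pytest.raises(DataError):
            entropy_profile(pd.DataFrame(rows), {"i1": 100.0}, prototype)

    def test_missing_copy_estimate_rejected(self, prototype, call_row):
        with pytest.raises(DataError):
            entropy_profile(pd.DataFrame([call_row(100, 0.5)]), {}, prototype)

    @given(st.lists(st.floats(0.0, 1000.0), min_size=2, max_size=5))
    def test_entropy_value_permutation_invariant(self, counts):
        rng = np.random.default_rng(0)
        shuffled = list(counts)
        rng.shuffle(shuffled)
        assert entropy_value(counts) == pytest.approx(entropy_value(shuffled))
        assert 0.0 <= entropy_value(counts) <= math.log(5) + 1e-9


class TestElementSummary:
    def test_shared_snv_counts(self, prototype, call_row):
        pos = prototype.element_interval("25S").start + 10
        rows = [call_row(pos, 0.1, isolate_id=f"i{k}") for k in range(3)]
        summary = summarize_elements(pd.DataFrame(rows), prototype)
        r25 = summary.set_index("element").loc["25S"]
        assert (r25["variants"], r25["polymorphic_sites"], r25["ivfps"]) == (1, 1, 3)

    def test_two_alts_one_site(self, prototype, call_row):
        pos = prototype.element_interval("18S").start + 5
        ref = prototype.sequence[pos - 1]
        alts = [b for b in "ACGT" if b != ref][:2]
        rows = [call_row(pos, 0.1, alt=alts[0]), call_row(pos, 0.2, alt=alts[1])]
        summary = summarize_elements(pd.DataFrame(rows), prototype)
        r18 = summary.set_index("element").loc["18S"]
        assert r18["variants"] == 2 and r18["polymorphic_sites"] == 1

    def test_empty_call_set_all_zero(self, prototype, call_row):
        empty = pd.DataFrame([call_row(100, 0.5)]).iloc[0:0]
        summary = summarize_elements(empty, prototype)
        assert (summary[["variants", "ivfps", "polymorphic_sites"]] == 0).all().all()

    def test_totals_conserved(self, prototype, call_row):
        rng = np.random.default_rng(3)
        rows = [call_row(int(p), 0.1, isolate_id=f"i{k % 4}")
                for k, p in enumerate(rng.integers(1, 9138, size=60))]
        df = pd.DataFrame(rows).drop_duplicates(["isolate_id", "position", "alt"])
        summary = summarize_elements(df, prototype)
        assert summary["ivfps"].sum() == len(df)
        assert summary["variants_snv"].sum() + summary["variants_indel"].sum() \
            == summary["variants"].sum()


class TestSharing:
    def test_single_carrier_shares_one(self, prototype, call_row):
        sharing, _ = sharing_distribution(pd.DataFrame([call_row(100, 0.1)]),
                                          prototype)
        assert sharing["n_isolates"].tolist() == [1]

    def test_constructed_group_difference_recovered(self, prototype, call_row):
        rows = []
        gene_pos = prototype.element_interval("25S").start + 5
        for v in range(6):  # six rRNA variants, one isolate each
            rows.append(call_row(gene_pos + v, 0.1, isolate_id=f"r{v}"))
        nts_pos = 100
        for v in range(6):  # six NTS variants, five isolates each
            for k in range(5):
                rows.append(call_row(nts_pos + v, 0.1, isolate_id=f"n{k}"))
        sharing, tests = sharing_distribution(pd.DataFrame(rows), prototype)
        med = sharing.groupby("group")["n_isolates"].median()
        assert med["rRNA"] < med["NTS"]
        row = tests.set_index(["group_a", "group_b"]).loc[("NTS", "rRNA")]
        assert row["p_adj"] < 0.05

    def test_identical_groups_nonsignificant(self, prototype, call_row):
        rows = []
        for base in (100, prototype.element_interval("18S").start + 5):
            for v in range(5):
                rows.append(call_row(base + v, 0.1, isolate_id="i1"))
        _, tests = sharing_distribution(pd.DataFrame(rows), prototype)
        assert (tests["p_adj"] > 0.9).all()


class TestNonFixed:
    @pytest.mark.parametrize("ivf,counted", [(1.0, 0), (0.99, 1), (0.5, 1)])
    def test_m100_boundary(self, prototype, call_row, ivf, counted):
        calls = pd.DataFrame([call_row(100, ivf)])
        assert nonfixed_variant_count(calls, 100.0) == counted

    def test_empty(self, prototype, call_row):
        empty = pd.DataFrame([call_row(100, 0.5)]).iloc[0:0]
        assert nonfixed_variant_count(empty, 100.0) == 0


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p, _ = correlate_counts(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _, _ = correlate_counts(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            correlate_counts([1, 1, 1], [1, 2, 3])

    def test_injected_correlation_recovered(self):
        """r_true = 0.5 at n = 400 is recovered within sampling error."""
        df = synthetic_variant_het_counts(400, 0.5, seed=123)
        r, p, (lo, hi) = correlate_counts(df["n_variants"], df["het_snps_per_kb"])
        assert abs(r - 0.5) < 0.1
        assert p < 1e-6
        assert lo < r < hi


def test_bimodal_cohort_yields_u_shape(prototype):
    """A cohort spiked with mostly very low and very high iVFs reproduces the
    U-shaped class distribution: low + high counts exceed mid counts."""
    variants = []
    rng = np.random.default_rng(5)
    positions = rng.choice(np.arange(100, 9000), size=30, replace=False)
    for i, pos in enumerate(positions):
        ref = prototype.sequence[pos - 1]
        if i < 13:
            ivf = (0.006, 0.04)
        elif i < 26:
            ivf = (0.96, 1.0)
        else:
            ivf = (0.3, 0.7)
        variants.append(VariantSpec(position=int(pos), alt="T" if ref != "T" else "A",
                                    ivf=ivf, sharing=0.8))
    cfg = CohortConfig(n_isolates=12, seed=17, variants=tuple(variants))
    _, truth = generate_cohort(cfg, prototype)
    counts = ivf_class_counts(truth.rename(columns={"true_ivf": "ivf"}))
    assert counts["low"] + counts["high"] > counts["mid"]
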