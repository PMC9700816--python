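import itertools

import numpy as np
import pandas as pd
import pytest

from rdnadiv import (ConfigError, DataError, ShellTally, all_shell_tallies,
                     bridge_proximity_report, read_structure_annotation,
                     region_enrichment, shell_log_ratio, shell_skew_test,
                     shell_tally, write_structure_annotation)
from rdnadiv._stats import fisher_exact_two_sided
from rdnadiv.selection import LOG_RATIO_SENTINEL

from .oracles import fisher_two_sided_enum


def lsu_calls(prototype, annotation, shell_counts, ivf=0.01):
    """Place one iVFP per requested (shell -> count) at distinct LSU slots."""
    slots_by_shell = {}
    for (gene, lp), shell in sorted(annotation.shell_of.items()):
        if annotation.subunit_of(gene) == "LSU":
            slots_by_shell.setdefault(shell, []).append((gene, lp))
    columns = ["isolate_id", "position", "ref", "alt", "ivf", "depth"]
    rows = []
    i = 0
    for shell, count in shell_counts.items():
        slots = slots_by_shell[shell]
        for k in range(count):
            gene, lp = slots[k % len(slots)]
            rows.append({
                "isolate_id": f"i{i}", "position": prototype.from_gene_coordinate(gene, lp),
                "ref": "A", "alt": "T", "ivf": ivf, "depth": 3000,
            })
            i += 1
    return pd.DataFrame(rows, columns=columns)


class TestShellTally:
    def test_published_worked_example(self, prototype, annotation):
        """82 of 3428 resolved shell-1 nucleotides and 7 of 875 low-iVF iVFPs
        in shell 1 give F1 = 0.024, F*1 = 0.008, log ratio -0.48."""
        counts = {"1": 7, "2": 200, "3": 200, "4": 200, "5": 168, "6+7": 100}
        assert sum(counts.values()) == 875
        tally = shell_tally(lsu_calls(prototype, annotation, counts), annotation,
                            prototype, "LSU", "low")
        assert tally.total_nucleotides == 3428
        assert tally.total_ivfps == 875
        assert round(tally.expected_fraction("1"), 3) == 0.024
        assert round(tally.observed_fraction("1"), 3) == 0.008
        assert round(tally.log_ratio("1"), 2) == -0.48

    def test_conservation_invariants(self, prototype, annotation):
        counts = {"1": 3, "2": 5, "3": 0, "4": 2, "5": 1, "6+7": 4}
        tally = shell_tally(lsu_calls(prototype, annotation, counts), annotation,
                            prototype, "LSU", "low")
        assert sum(tally.nucleotides.values()) == tally.total_nucleotides
        assert sum(tally.ivfps.values()) == tally.total_ivfps == 15
        assert sum(tally.expected_fraction(s) for s in tally.nucleotides) == pytest.approx(1.0)
        assert sum(tally.observed_fraction(s) for s in tally.nucleotides) == pytest.approx(1.0)

    def test_adding_ivfp_monotone(self, prototype, annotation):
        base = {"1": 2, "2": 2, "3": 2, "4": 2, "5": 2, "6+7": 2}
        t0 = shell_tally(lsu_calls(prototype, annotation, base), annotation,
                         prototype, "LSU", "low")
        bumped = dict(base, **{"3": 3})
        t1 = shell_tally(lsu_calls(prototype, annotation, bumped), annotation,
                         prototype, "LSU", "low")
        assert t1.observed_fraction("3") > t0.observed_fraction("3")
        for s in base:
            if s != "3":
                assert t1.observed_fraction(s) <= t0.observed_fraction(s)

    def test_unresolved_positions_go_to_side_channel(self, prototype, annotation):
        # the synthetic layout leaves 25S gene-local 1..247 unresolved
        pos = prototype.from_gene_coordinate("25S", 1)
        calls = pd.DataFrame([{"isolate_id": "i", "position": pos, "ref": "A",
                               "alt": "T", "ivf": 0.01, "depth": 100}])
        tally = shell_tally(calls, annotation, prototype, "LSU", "low")
        assert tally.excluded == 1
        assert tally.total_ivfps == 0

    def test_ivf_class_selects_rows(self, prototype, annotation):
        counts = {"1": 1, "2": 0, "3": 0, "4": 0, "5": 0, "6+7": 0}
        calls = lsu_calls(prototype, annotation, counts, ivf=0.5)  # mid class
        low = shell_tally(calls, annotation, prototype, "LSU", "low")
        mid = shell_tally(calls, annotation, prototype, "LSU", "mid")
        assert low.total_ivfps == 0 and mid.total_ivfps == 1

    def test_empty_class_fractions_zero(self, prototype, annotation):
        empty = lsu_calls(prototype, annotation, {}, ivf=0.01)
        tally = shell_tally(empty, annotation, prototype, "LSU", "high")
        assert tally.total_ivfps == 0
        assert all(tally.observed_fraction(s) == 0.0 for s in tally.nucleotides)
        assert all(tally.log_ratio(s) is None for s in tally.nucleotides)


class TestLogRatio:
    def test_equal_fractions_zero(self):
        assert shell_log_ratio(0.25, 0.25) == pytest.approx(0.0)

    def test_zero_observed_is_undefined(self):
        assert shell_log_ratio(0.0, 0.25) is None

    def test_zero_expected_rejected(self):
        with pytest.raises(DataError):
            shell_log_ratio(0.1, 0.0)

    def test_sentinel_only_in_export(self, prototype, annotation):
        tally = shell_tally(lsu_calls(prototype, annotation, {}), annotation,
                            prototype, "LSU", "low")
        analytic = tally.to_table(sentinel=False)
        export = tally.to_table(sentinel=True)
        assert analytic["log10_ratio"].isna().all()
        assert (export["log10_ratio"] == LOG_RATIO_SENTINEL).all()


class TestSkewTest:
    def test_outermost_concentration_detected(self, prototype, annotation):
        counts = {"1": 0, "2": 0, "3": 0, "4": 0, "5": 0, "6+7": 60}
        tally = shell_tally(lsu_calls(prototype, annotation, counts), annotation,
                            prototype, "LSU", "low")
        out = shell_skew_test([tally])
        assert out.loc[0, "p_raw"] < 0.01

    def test_single_tied_observation_nonsignificant(self):
        tally = ShellTally("LSU", "low", nucleotides={"1": 1}, ivfps={"1": 1})
        out = shell_skew_test([tally])
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_null_draws_rarely_significant(self, prototype, annotation):
        """iVFPs drawn from the nucleotide distribution itself: adjusted p
        stays above 0.05 in at least 90% of 100 seeded replicates."""
        nucs = annotation.shell_nucleotide_counts("LSU")
        shells = list(nucs)
        probs = np.array([nucs[s] for s in shells], dtype=float)
        probs /= probs.sum()
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(100):
            draw = rng.multinomial(80, probs)
            tally = ShellTally("LSU", "low", nucleotides=dict(nucs),
                               ivfps=dict(zip(shells, draw)))
            out = shell_skew_test([tally])
            if out.loc[0, "p_adj"] > 0.05:
                hits += 1
        assert hits >= 90

    def test_zero_class_skipped(self, prototype, annotation):
        tallies = all_shell_tallies(
            lsu_calls(prototype, annotation, {"1": 2, "2": 2, "3": 2, "4": 2,
                                              "5": 2, "6+7": 2}),
            annotation, prototype)
        out = shell_skew_test(tallies).set_index(["subunit", "ivf_class"])
        assert not out.loc[("LSU", "low"), "skipped"]
        assert out.loc[("LSU", "mid"), "skipped"]  # no mid-class iVFPs present
        assert out[~out["skipped"]]["p_adj"].notna().all()


class TestRegionEnrichment:
    def test_expected_fraction_from_marginals(self, prototype, annotation, call_row):
        """CNE spans 962 of the 3396 25S nucleotides: expected inside fraction
        962/3396 = 0.2833."""
        tally = region_enrichment(pd.DataFrame([call_row(100, 0.5)]).iloc[0:0],
                                  annotation, prototype, "CNE", genes=("25S",))
        assert tally.n_inside == 962
        assert tally.n_inside + tally.n_outside == 3396
        assert tally.expected_inside_fraction == pytest.approx(0.2833, abs=5e-4)
        assert tally.expected_inside_fraction + tally.expected_outside_fraction == 1.0

    def test_proportional_observation_nonsignificant(self, prototype, annotation):
        rows = []
        cne = sorted(p for g, p in annotation.region_sets["CNE"])
        outside = [p for p in range(1, 3397) if ("25S", p) not in annotation.region_sets["CNE"]]
        for i, lp in enumerate(cne[:96]):  # ~inside fraction of 339 total
            rows.append({"isolate_id": f"a{i}", "ivf": 0.01, "ref": "A", "alt": "T",
                         "position": prototype.from_gene_coordinate("25S", lp), "depth": 100})
        for i, lp in enumerate(outside[:243]):
            rows.append({"isolate_id": f"b{i}", "ivf": 0.01, "ref": "A", "alt": "T",
                         "position": prototype.from_gene_coordinate("25S", lp), "depth": 100})
        tally = region_enrichment(pd.DataFrame(rows), annotation, prototype, "CNE",
                                  genes=("25S",))
        row = tally.per_cutoff.set_index("cutoff").loc["1to5pct"]
        assert row["p_adj"] > 0.5

    def test_fisher_matches_enumeration(self):
        assert fisher_exact_two_sided([[8, 2], [10, 40]]) == pytest.approx(
            fisher_two_sided_enum(8, 2, 10, 40), rel=1e-9)
        for table in itertools.product((0, 2, 7, 19, 30), repeat=4):
            a, b, c, d = table
            assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
                fisher_two_sided_enum(a, b, c, d), rel=1e-9, abs=1e-12), table

    def test_empty_region_rejected(self, prototype, annotation, call_row):
        with pytest.raises(ConfigError):
            region_enrichment(pd.DataFrame([call_row(100, 0.5)]), annotation,
                              prototype, "no_such_region")


class TestBridgeReport:
    def test_no_mid_high_calls_empty_report(self, prototype, annotation, call_row):
        near, _ = bridge_proximity_report(
            pd.DataFrame([call_row(100, 0.01)]), annotation, prototype)
        assert near.empty

    def test_injected_bridge_variants_reported(self, prototype, annotation):
        bridge = sorted(annotation.region_sets["bridge_proximal"])[:3]
        rows = [{"isolate_id": f"i{k}", "ref": "A", "alt": "T", "ivf": 0.4,
                 "position": prototype.from_gene_coordinate(g, lp), "depth": 100}
                for k, (g, lp) in enumerate(bridge)]
        near, _ = bridge_proximity_report(pd.DataFrame(rows), annotation, prototype)
        assert len(near) == 3

    def test_identical_ivf_distributions_nonsignificant(self, prototype, annotation):
        """iVFs drawn identically inside and outside RP interfaces: p stays
        above 0.05 in at least 90% of 100 seeded replicates."""
        interface = sorted(annotation.region_sets["rp_interface"])
        outside = [("25S", p) for p in range(300, 500)]
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            rows = []
            for k in range(30):
                g, lp = interface[int(rng.integers(len(interface)))]
                rows.append({"isolate_id": f"a{k}", "ref": "A", "alt": "T",
                             "ivf": float(rng.uniform(0.05, 1.0)),
                             "position": prototype.from_gene_coordinate(g, lp),
                             "depth": 100})
            for k in range(30):
                g, lp = outside[int(rng.integers(len(outside)))]
                rows.append({"isolate_id": f"b{k}", "ref": "A", "alt": "T",
                             "ivf": float(rng.uniform(0.05, 1.0)),
                             "position": prototype.from_gene_coordinate(g, lp),
                             "depth": 100})
            _, cmp = bridge_proximity_report(pd.DataFrame(rows), annotation, prototype)
            if cmp["p_value"] > 0.05:
                hits += 1
        assert hits >= 90


def test_annotation_tsv_round_trip(annotation, tmp_path):
    write_structure_annotation(annotation, tmp_path / "shells.tsv",
                               tmp_path / "regions.tsv")
    back = read_structure_annotation(tmp_path / "shells.tsv", tmp_path / "regions.tsv")
    assert back.shell_of == annotation.shell_of
    assert back.gene_lengths == annotation.gene_lengths
    assert back.region_sets == annotation.region_sets
    assert back.resolved_count("LSU") == 3428
    assert back.resolved_count("SSU") == 1781
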