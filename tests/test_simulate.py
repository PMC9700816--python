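import numpy as np
import pandas as pd
import pytest

from rdnadiv import (CohortConfig, ConfigError, CoupledPairSpec, VariantSpec,
                     generate_cohort, make_titration, simulate_pileup)
from rdnadiv.pileup import BASE_INDEX
from rdnadiv.simulate import TRUTH_COLUMNS


def spec_at(prototype, position, ivf, sharing=1.0):
    ref = prototype.sequence[position - 1]
    return VariantSpec(position=position, alt="T" if ref != "T" else "A",
                       ivf=ivf, sharing=sharing)


@pytest.fixture(scope="module")
def small_cohort(prototype):
    cfg = CohortConfig(
        n_isolates=10, seed=7,
        variants=(spec_at(prototype, 300, (0.1, 0.9)),
                  spec_at(prototype, 4000, 0.02, sharing=0.5)),
        coupled_pairs=(CoupledPairSpec(
            first=spec_at(prototype, 6000, 0.5),
            second=spec_at(prototype, 6500, 0.5),
            ivf=(0.1, 0.9)),),
    )
    return cfg, generate_cohort(cfg, prototype)


class TestGenerateCohort:
    def test_same_seed_identical_truth(self, prototype, small_cohort):
        cfg, (isolates, truth) = small_cohort
        isolates2, truth2 = generate_cohort(cfg, prototype)
        assert truth.equals(truth2)
        assert [i.total_copies for i in isolates] == [i.total_copies for i in isolates2]

    def test_full_sharing_hits_every_isolate(self, small_cohort):
        _, (isolates, truth) = small_cohort
        assert truth[truth.position == 300]["isolate_id"].nunique() == len(isolates)

    def test_true_ivfs_on_copy_lattice(self, small_cohort):
        # the lattice denominator is the integer-rounded copy number
        _, (isolates, truth) = small_cohort
        m = {i.isolate_id: round(i.total_copies) for i in isolates}
        for row in truth.itertuples(index=False):
            copies = row.true_ivf * m[row.isolate_id]
            assert abs(copies - round(copies)) < 1e-9
            assert 1 - 1e-9 <= copies <= m[row.isolate_id] + 1e-9

    def test_below_one_copy_request_promoted_and_flagged(self, prototype):
        cfg = CohortConfig(
            n_isolates=3, seed=1, ploidy_weights={1: 1.0},
            copy_number_range=(150.0, 150.0),
            variants=(spec_at(prototype, 300, 0.005),),
        )
        # per-haploid estimates jitter around 150; request 0.005 < 1/M
        isolates, truth = generate_cohort(cfg, prototype)
        m = {i.isolate_id: round(i.total_copies) for i in isolates}
        assert truth["promoted"].all()
        for row in truth.itertuples(index=False):
            assert row.true_ivf == pytest.approx(1 / m[row.isolate_id])  # one copy

    def test_coupled_pairs_share_identical_ivf(self, small_cohort):
        _, (_, truth) = small_cohort
        pairs = truth[truth.coupled_group.notna()]
        assert len(pairs) > 0
        per_isolate = pairs.groupby(["isolate_id", "coupled_group"])["true_ivf"].nunique()
        assert (per_isolate == 1).all()

    def test_colliding_variants_rejected(self, prototype):
        cfg = CohortConfig(
            n_isolates=2, seed=1,
            variants=(spec_at(prototype, 300, 0.9), spec_at(prototype, 300, 0.9)),
        )
        with pytest.raises(Exception):
            generate_cohort(cfg, prototype)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(error_rate=0.2)
        with pytest.raises(ConfigError):
            CohortConfig(rdna_coverage=0)


def truth_frame(prototype, rows):
    out = []
    for pos, ivf in rows:
        ref = prototype.sequence[pos - 1]
        out.append(("iso", pos, ref, "T" if ref != "T" else "A", ivf,
                    prototype.element_of(pos), None, False))
    return pd.DataFrame(out, columns=TRUTH_COLUMNS)


class TestSimulatePileup:
    def test_same_seed_bit_identical(self, prototype):
        truth = truth_frame(prototype, [(100, 0.5)])
        p1 = simulate_pileup(prototype, truth, 500, 0.001, seed=3)
        p2 = simulate_pileup(prototype, truth, 500, 0.001, seed=3)
        assert np.array_equal(p1.base_counts, p2.base_counts)
        assert p1.indel_counts == p2.indel_counts

    def test_error_free_pileup_is_pure_reference(self, prototype):
        pile = simulate_pileup(prototype, truth_frame(prototype, []), 100, 0.0, seed=1)
        ref_idx = np.array([BASE_INDEX[b] for b in prototype.sequence])
        totals = pile.base_counts.sum(axis=2)
        nonref = totals.sum() - totals[np.arange(pile.length), ref_idx].sum()
        assert nonref == 0

    def test_alt_count_near_binomial_expectation(self, prototype):
        truth = truth_frame(prototype, [(100, 0.5)])
        pile = simulate_pileup(prototype, truth, 3000, 0.0, seed=5)
        alt = truth.loc[0, "alt"]
        k = sum(pile.base_count(100, alt))
        sd = np.sqrt(3000 * 0.25)
        assert abs(k - 1500) < 5 * sd

    def test_observed_error_rate_matches_model(self, prototype):
        """Mean non-reference fraction at truth-free sites ~ error_rate (3 SD)."""
        err = 0.002
        pile = simulate_pileup(prototype, truth_frame(prototype, []), 1000, err, seed=9)
        ref_idx = np.array([BASE_INDEX[b] for b in prototype.sequence])
        totals = pile.base_counts.sum(axis=2)
        depth = totals.sum()
        nonref = depth - totals[np.arange(pile.length), ref_idx].sum()
        sd = np.sqrt(depth * err * (1 - err))
        assert abs(nonref - depth * err) < 3 * sd

    def test_empirical_ivf_unbiased(self, prototype):
        """alt/depth is an unbiased iVF estimator over 200 simulated sites."""
        positions = list(range(200, 8200, 40))[:200]
        truth = truth_frame(prototype, [(p, 0.1) for p in positions])
        pile = simulate_pileup(prototype, truth, 3000, 0.0, seed=11)
        depths = pile.depths()
        errs = []
        for row in truth.itertuples(index=False):
            k = sum(pile.base_count(row.position, row.alt))
            errs.append(k / depths[row.position - 1] - 0.1)
        se = np.std(errs, ddof=1) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < 2 * se

    def test_indel_truth_lands_in_indel_counts(self, prototype):
        ref = prototype.sequence[99]
        truth = pd.DataFrame(
            [("iso", 100, ref, ref + "AT", 0.3, "NTS1", None, False)],
            columns=TRUTH_COLUMNS)
        pile = simulate_pileup(prototype, truth, 1000, 0.0, seed=2)
        (key,) = pile.indel_counts
        assert key == (100, ref, ref + "AT")
        f, r = pile.indel_counts[key]
        assert abs((f + r) - 300) < 5 * np.sqrt(1000 * 0.3 * 0.7)

    def test_coverage_must_be_positive(self, prototype):
        with pytest.raises(ConfigError):
            simulate_pileup(prototype, truth_frame(prototype, []), 0, 0.001, seed=1)


class TestTitration:
    def test_full_frequency_matches_pure_spike(self, prototype):
        spike = truth_frame(prototype, [(100, 0.96), (500, 1.0)])
        bg = pd.DataFrame(columns=TRUTH_COLUMNS)
        ((f, pile, mixed),) = make_titration(prototype, bg, spike, [1.0], 2000, 0.0, seed=4)
        assert f == 1.0
        assert mixed["tracked"].all()
        for row in mixed.itertuples(index=False):
            k = sum(pile.base_count(row.position, row.alt))
            n = pile.depths()[row.position - 1]
            assert abs(k / n - row.true_ivf) < 5 * np.sqrt(0.05 / 2000) + 0.01

    def test_zero_frequency_has_no_tracked_truth(self, prototype):
        spike = truth_frame(prototype, [(100, 0.96)])
        bg = pd.DataFrame(columns=TRUTH_COLUMNS)
        ((_, _, mixed),) = make_titration(prototype, bg, spike, [0.0], 2000, 0.0, seed=4)
        assert not mixed["tracked"].any() if len(mixed) else True

    def test_expected_ivf_scales_with_frequency(self, prototype):
        spike = truth_frame(prototype, [(p, 1.0) for p in range(200, 700, 50)])
        bg = pd.DataFrame(columns=TRUTH_COLUMNS)
        ((_, pile, mixed),) = make_titration(prototype, bg, spike, [0.005], 3000, 0.0, seed=6)
        assert np.allclose(mixed["true_ivf"], 0.005)
        ks = [sum(pile.base_count(r.position, r.alt)) for r in mixed.itertuples(index=False)]
        assert abs(np.mean(ks) - 15) < 10  # 10 variants x expected 15 alt reads

    def test_out_of_range_frequency_rejected(self, prototype):
        spike = truth_frame(prototype, [(100, 0.96)])
        with pytest.raises(ConfigError):
            make_titration(prototype, spike.iloc[0:0], spike, [1.5], 100, 0.0, seed=1)
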