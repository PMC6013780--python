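"""Niche ring dynamics: fate outcomes, drift, ensemble engine."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from cryptdrift.mtdna import (
    DeficiencyThreshold,
    MtDnaState,
    MutationRateSchedule,
)
from cryptdrift.niche import (
    CryptState,
    FateParams,
    NicheConfig,
    classify_crypt,
    clonality_of_deficiency,
    init_crypt,
    run_crypt,
    simulate_ensemble,
    simulate_labelled_clone,
    step_generation,
)

TINY_MU = MutationRateSchedule(mu_start=1e-30, mu_end=2e-30)


class TestNicheConfig:
    def test_default_division_count(self):
        assert NicheConfig().n_divisions == 4171

    def test_divisions_per_year(self):
        assert NicheConfig().divisions_per_year == pytest.approx(365.0 / 7.0)

    def test_generation_at_age(self):
        cfg = NicheConfig()
        assert cfg.generation_at_age(0.0) == 0
        assert cfg.generation_at_age(80.0) == 4171
        assert cfg.generation_at_age(1.0) == round(365.0 / 7.0)
        # clamped to the lifespan
        assert cfg.generation_at_age(200.0) == 4171

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_sc": 1},
            {"division_interval_days": 0.0},
            {"lifespan_years": -1.0},
            {"copy_number": 0},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            NicheConfig(**kwargs)


class TestFateParams:
    def test_replacement_rate_conversion(self):
        fate = FateParams(p_asym=0.99)
        assert fate.p_sym == pytest.approx(0.01)
        assert fate.replacement_rate_per_year(365.0 / 7.0) == pytest.approx(
            0.01 * 365.0 / 7.0
        )

    @pytest.mark.parametrize("p", [-0.1, 1.2])
    def test_validation(self, p):
        with pytest.raises(ValueError):
            FateParams(p_asym=p)


class TestSingleCrypt:
    def test_init_crypt_is_all_wild_type(self):
        crypt = init_crypt(NicheConfig())
        assert crypt.n_sc == 5
        assert all(c.mutant_total == 0 for c in crypt.cells)
        assert classify_crypt(crypt).label == "normal"

    def test_classification_labels(self):
        m = 200
        deficient = MtDnaState(wild_type_count=0, mutant_counts={1: m})
        healthy = MtDnaState.wild_type(m)
        partial = CryptState(cells=[deficient, healthy, healthy])
        full = CryptState(cells=[deficient] * 3)
        assert classify_crypt(partial).label == "partial"
        assert classify_crypt(partial).k_deficient == 1
        assert classify_crypt(full).label == "full"
        assert classify_crypt(full).k_deficient == 3

    def test_clonality_counts_distinct_dominant_lineages(self):
        a = MtDnaState(wild_type_count=0, mutant_counts={1: 200})
        b = MtDnaState(wild_type_count=0, mutant_counts={2: 150, 1: 50})
        healthy = MtDnaState.wild_type(200)
        assert clonality_of_deficiency(CryptState(cells=[a, a, healthy])) == 1
        assert clonality_of_deficiency(CryptState(cells=[a, b, healthy])) == 2

    def test_clonality_requires_a_deficient_cell(self):
        crypt = init_crypt(NicheConfig())
        with pytest.raises(ValueError):
            clonality_of_deficiency(crypt)


def _lineage_crypt(n=5, m=200):
    """A crypt whose cells each carry a unique, fully clonal lineage."""
    return CryptState(
        cells=[
            MtDnaState(wild_type_count=0, mutant_counts={i + 1: m}, copy_number=m)
            for i in range(n)
        ]
    )


class TestStepGeneration:
    def test_ring_size_is_conserved(self, rng):
        crypt = _lineage_crypt()
        for fate in (FateParams(1.0), FateParams(0.5), FateParams(0.0)):
            out = step_generation(crypt, 0.0, fate, TINY_MU, rng)
            assert out.n_sc == 5
            assert all(c.copy_number == 200 for c in out.cells)

    def test_pure_asymmetric_preserves_every_position(self, rng):
        """With invariant asymmetric outcome the clonal configuration of the
        ring never changes."""
        crypt = _lineage_crypt()
        out = crypt
        for _ in range(10):
            out = step_generation(out, 0.0, FateParams(1.0), TINY_MU, rng)
        for i, cell in enumerate(out.cells):
            assert cell.mutant_counts == {i + 1: 200}

    def test_symmetric_rounds_keep_lineages_a_subset(self, rng):
        """Symmetric outcomes duplicate one clone and expunge a neighbour, so
        the surviving lineage set only shrinks and counts still sum to N."""
        crypt = _lineage_crypt()
        out = crypt
        for _ in range(20):
            out = step_generation(out, 0.0, FateParams(0.0), TINY_MU, rng)
        lineages = [max(c.mutant_counts, key=c.mutant_counts.get) for c in out.cells]
        assert set(lineages) <= {1, 2, 3, 4, 5}
        assert len(lineages) == 5

    def test_run_crypt_without_mutation_stays_normal(self, rng):
        cfg = NicheConfig()
        traj = run_crypt(
            cfg,
            FateParams(0.99),
            TINY_MU,
            DeficiencyThreshold(),
            rng,
            record_ages=(40.0, 80.0),
        )
        assert traj.n_generations == 4171
        assert np.all(traj.k_deficient == 0)
        assert all(c.label == "normal" for c in traj.classes)


class TestEnsembleEngine:
    def test_determinism_same_seed_same_output(self):
        args = (
            NicheConfig(),
            FateParams(0.95),
            MutationRateSchedule(),
            DeficiencyThreshold(),
        )
        a = simulate_ensemble(*args, n_runs=50, record_ages=[2.0], rng=7)
        b = simulate_ensemble(*args, n_runs=50, record_ages=[2.0], rng=7)
        np.testing.assert_array_equal(a.k_deficient, b.k_deficient)
        np.testing.assert_array_equal(a.clonality, b.clonality)
        assert a.n_replacements == b.n_replacements

    def test_one_division_deficiency_matches_hypergeometric(self):
        """Single-division oracle for the compiled engine: starting one cell
        at 50% heteroplasmy with a 55% threshold, the deficiency probability
        after one division is the hypergeometric tail of drawing 200 from the
        doubled 50/50 pool."""
        theta = DeficiencyThreshold(0.55)
        assert theta.count_for(200) == 110
        p = float(hypergeom.sf(109, 400, 200, 200))
        n_runs = 20_000
        summ = simulate_ensemble(
            NicheConfig(),
            FateParams(1.0),
            TINY_MU,
            theta,
            n_runs=n_runs,
            record_ages=[7.0 / 365.0],
            rng=23,
            init_mut_count=100,
        )
        assert summ.n_generations == 1
        frac = np.mean(summ.k_deficient[:, -1] == 1)
        se = np.sqrt(p * (1 - p) / n_runs)
        assert abs(frac - p) < 3 * se

    @pytest.mark.parametrize("n_sc", [3, 5, 7])
    def test_neutral_fixation_probability_is_one_over_n(self, n_sc):
        """A single labelled stem cell fixes with probability 1/N under
        neutral drift (label layer, all-symmetric outcomes for speed)."""
        n_runs = 5000
        cfg = NicheConfig(n_sc=n_sc)
        summ = simulate_labelled_clone(
            cfg, FateParams(0.0), n_runs=n_runs, record_ages=[2.0], rng=31
        )
        k = summ.k_deficient[:, -1]
        absorbed = (k == 0) | (k == n_sc)
        assert absorbed.mean() > 0.99
        p_fix = np.mean(k[absorbed] == n_sc)
        p = 1.0 / n_sc
        se = np.sqrt(p * (1 - p) / absorbed.sum())
        assert abs(p_fix - p) < 3 * se

    def test_labelled_count_is_a_martingale(self):
        """The mean labelled-cell count stays at its initial value 1."""
        n_runs = 8000
        summ = simulate_labelled_clone(
            NicheConfig(), FateParams(0.0), n_runs=n_runs, record_ages=[0.25], rng=37
        )
        k = summ.k_deficient[:, -1].astype(float)
        se = k.std(ddof=1) / np.sqrt(n_runs)
        assert abs(k.mean() - 1.0) < 3 * se

    def test_measured_replacement_rate(self, default_ensemble):
        """Realised loss/replacement rate matches p_sym * divisions/year
        (slightly below it, because an expunged cell's own division that
        round is pre-empted)."""
        rate = default_ensemble.replacement_rate_per_sc_year()
        nominal = 0.01 * 365.0 / 7.0
        assert rate == pytest.approx(nominal, rel=0.02)
        assert rate <= nominal

    def test_class_percentages_sum_to_100(self, default_ensemble):
        table = default_ensemble.class_percentages()
        sums = table.groupby("age")["percent"].sum()
        assert np.allclose(sums, 100.0)
        for label in ("normal", "partial", "full"):
            assert np.all(default_ensemble.percent_of_class(label) >= 0)

    def test_deficiency_accumulates_with_age(self, default_ensemble):
        """Crypts with deficient stem cells become more common with age."""
        pct_affected = 100.0 - default_ensemble.percent_of_class("normal")
        first, last = pct_affected[0], pct_affected[-1]
        assert last > first
        assert default_ensemble.percent_of_class("full")[-1] > 0

    def test_full_crypt_clonality(self, default_ensemble):
        """Fully deficient crypts are overwhelmingly single-lineage: the
        point estimate must not fall more than 3 binomial SE below 99%."""
        k = default_ensemble.k_deficient[:, -1]
        clon = default_ensemble.clonality[:, -1]
        full = k == default_ensemble.n_sc
        assert full.sum() > 20
        frac_clonal = np.mean(clon[full] == 1)
        se = np.sqrt(0.99 * 0.01 / full.sum())
        assert frac_clonal >= 0.99 - 3 * se

    def test_invalid_run_count(self, rng):
        with pytest.raises(ValueError):
            simulate_ensemble(
                NicheConfig(),
                FateParams(),
                MutationRateSchedule(),
                DeficiencyThreshold(),
                n_runs=0,
                record_ages=[80.0],
                rng=rng,
            )
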