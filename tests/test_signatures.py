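"""Signature extraction, refitting, matching, and the dMMR flag."""

import numpy as np
import pandas as pd
import pytest

from ucsomatic.catalogs import SBS96_CHANNELS, MutationCatalog
from ucsomatic.signatures import (
    SignatureMatrix,
    cosine_similarity,
    extract_signatures,
    fit_exposures,
    flag_mmr_deficiency,
    goodness_of_fit,
    match_reference,
    reconstruct_spectrum,
)


def _two_sigs():
    from ucsomatic import synthetic as syn

    return SignatureMatrix(
        data=pd.DataFrame(
            {"PT": syn.pt_like_signature(), "CLOCK": syn.clock_like_signature()}
        ),
        scheme="SBS96",
    )


class TestCosine:
    def test_identical_vectors(self):
        v = np.arange(1, 97, dtype=float)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        assert cosine_similarity([1, 1, 0], [0, 0, 2]) == pytest.approx(0.0)

    def test_analytic_value(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_scale_invariance_and_symmetry(self):
        a, b = np.array([3.0, 1.0, 2.0]), np.array([1.0, 2.0, 0.5])
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, 10 * a))

    def test_zero_vector_error(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])


class TestReconstruct:
    def test_total_equals_exposure_sum(self):
        sigs = _two_sigs()
        spectrum = reconstruct_spectrum(sigs, [100.0, 0.0])
        assert spectrum.sum() == pytest.approx(100.0)

    def test_zero_exposures_zero_spectrum(self):
        assert reconstruct_spectrum(_two_sigs(), [0.0, 0.0]).sum() == 0.0

    def test_hand_computed_toy(self):
        # 4-channel toy: reconstruct and check each channel by hand
        data = pd.DataFrame(
            {"A": [0.5, 0.5, 0.0, 0.0], "B": [0.0, 0.0, 0.25, 0.75]},
            index=["c1", "c2", "c3", "c4"],
        )
        sigs = SignatureMatrix(data=data)
        out = reconstruct_spectrum(sigs, [10.0, 4.0])
        assert np.allclose(out, [5.0, 5.0, 1.0, 3.0])

    def test_negative_exposure_error(self):
        with pytest.raises(ValueError):
            reconstruct_spectrum(_two_sigs(), [-1.0, 2.0])


class TestExtract:
    def _catalog_from(self, sigs, exposures):
        counts = sigs.data.to_numpy() @ exposures.T.to_numpy()
        return MutationCatalog(
            counts=pd.DataFrame(
                counts, index=list(SBS96_CHANNELS), columns=list(exposures.index)
            ),
            scheme="SBS96",
        )

    def test_rank_one_exact_recovery(self):
        sigs = _two_sigs()
        exposures = pd.DataFrame({"PT": [5000.0], "CLOCK": [0.0]}, index=["S"])
        cat = self._catalog_from(sigs, exposures)
        rec, exp, diag = extract_signatures(cat, 1, n_restarts=3, seed=0)
        assert cosine_similarity(rec.column("S1"), sigs.column("PT")) >= 0.999
        assert diag["mean_cosine"] >= 0.999

    def test_k_zero_is_error(self):
        cat = self._catalog_from(_two_sigs(), pd.DataFrame({"PT": [10.0], "CLOCK": [5.0]}, index=["S"]))
        with pytest.raises(ValueError):
            extract_signatures(cat, 0)

    def test_all_zero_catalog_is_error(self):
        cat = MutationCatalog(
            counts=pd.DataFrame(0.0, index=list(SBS96_CHANNELS), columns=["S"]),
            scheme="SBS96",
        )
        with pytest.raises(ValueError):
            extract_signatures(cat, 1)

    def test_deterministic_under_seed(self, two_signature_cohort):
        cat = two_signature_cohort["catalog"]
        s1, e1, d1 = extract_signatures(cat, 2, n_restarts=3, seed=42)
        s2, e2, d2 = extract_signatures(cat, 2, n_restarts=3, seed=42)
        pd.testing.assert_frame_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(e1, e2)

    def test_restart_monotonicity(self, two_signature_cohort):
        """Best KL over n+1 restarts is no worse than over the first n."""
        cat = two_signature_cohort["catalog"]
        _, _, d3 = extract_signatures(cat, 2, n_restarts=3, seed=9)
        _, _, d4 = extract_signatures(cat, 2, n_restarts=4, seed=9)
        assert d4["kl"] <= d3["kl"] + 1e-6
        assert d4["restart_losses"][:3] == d3["restart_losses"]

    def test_matches_sklearn_kl_nmf_optimum(self, two_signature_cohort):
        """Independent cross-check: same KL optimum as scikit-learn's MU solver."""
        from sklearn.decomposition import NMF

        cat = two_signature_cohort["catalog"]
        V = cat.counts.to_numpy(float)
        _, _, diag = extract_signatures(cat, 2, n_restarts=5, seed=7)
        m = NMF(
            n_components=2, beta_loss="kullback-leibler", solver="mu",
            max_iter=10_000, init="random", random_state=0, tol=1e-10,
        )
        W = m.fit_transform(V)
        R = np.maximum(W @ m.components_, 1e-12)
        mask = V > 0
        sk_kl = float((V[mask] * np.log(V[mask] / R[mask])).sum() - V.sum() + R.sum())
        assert diag["kl"] == pytest.approx(sk_kl, rel=0.01)


class TestGoodnessOfFit:
    def test_single_signature_cohort_selects_one(self):
        from ucsomatic import synthetic as syn

        sigs = SignatureMatrix(
            data=pd.DataFrame({"PT": syn.pt_like_signature()}), scheme="SBS96"
        )
        config = syn.SimulationConfig(
            seed=21, n_samples=12, mutations_per_sample=2_000, signatures=sigs,
            exposures=pd.DataFrame({"PT": 1.0}, index=[f"S{i+1:02d}" for i in range(12)]),
        )
        genome, exome, _ = syn.generate_reference(config)
        variants, _ = syn.simulate_variants(config, genome, exome)
        from ucsomatic.catalogs import build_catalog

        cat = build_catalog(variants, genome, "SBS96")
        table, selected = goodness_of_fit(cat, range(1, 4), n_restarts=4, seed=21)
        assert selected == 1

    def test_scores_non_decreasing(self, two_signature_cohort):
        table, _ = goodness_of_fit(
            two_signature_cohort["catalog"], range(1, 4), n_restarts=4, seed=5
        )
        scores = table["mean_cosine"].to_numpy()
        assert (np.diff(scores) >= -1e-3).all()


class TestFitExposures:
    def test_exact_mixture_recovered(self):
        sigs = _two_sigs()
        spectrum = reconstruct_spectrum(sigs, [7000.0, 3000.0])
        exp, cos = fit_exposures(spectrum, sigs)
        assert exp["PT"] / exp.sum() == pytest.approx(0.7, abs=0.01)
        assert exp["CLOCK"] / exp.sum() == pytest.approx(0.3, abs=0.01)
        assert cos >= 0.999

    def test_pure_signature_prunes_other(self):
        sigs = _two_sigs()
        spectrum = 10_000.0 * sigs.column("PT")
        exp, cos = fit_exposures(spectrum, sigs)
        assert exp["CLOCK"] == 0.0
        assert exp["PT"] > 0
        assert cos >= 0.9999

    def test_returned_set_maximizes_cosine(self):
        """The pruned fit is never worse than any single-signature fit."""
        sigs = _two_sigs()
        rng = np.random.default_rng(0)
        spectrum = reconstruct_spectrum(sigs, [800.0, 200.0]) + rng.poisson(
            1.0, size=96
        )
        _, best_cos = fit_exposures(spectrum, sigs)
        for name in sigs.names:
            single = SignatureMatrix(data=sigs.data[[name]], scheme="SBS96")
            _, cos = fit_exposures(spectrum, single)
            assert best_cos >= cos - 1e-9

    def test_zero_spectrum(self):
        exp, cos = fit_exposures(np.zeros(96), _two_sigs())
        assert (exp == 0).all() and np.isnan(cos)

    def test_scheme_mismatch_error(self):
        with pytest.raises(ValueError, match="channels"):
            fit_exposures(np.ones(10), _two_sigs())


class TestMatchReference:
    def test_member_matches_itself(self):
        from ucsomatic.synthetic import synthetic_reference_db

        refdb = synthetic_reference_db()
        ranked = match_reference(refdb.column("SBS6"), refdb)
        assert ranked.loc[0, "reference"] == "SBS6"
        assert ranked.loc[0, "cosine"] == pytest.approx(1.0)
        assert bool(ranked.loc[0, "confident"])

    def test_orthogonal_query_not_confident(self):
        data = pd.DataFrame({"R1": [1.0, 0, 0], "R2": [0, 1.0, 0]})
        refdb = SignatureMatrix(data=data)
        ranked = match_reference([0.0, 0.0, 1.0], refdb)
        assert ranked.loc[0, "cosine"] == pytest.approx(0.0)
        assert not ranked.loc[0, "confident"]

    def test_threshold_boundary_inclusive(self):
        data = pd.DataFrame({"R1": [0.5, 0.5]})
        refdb = SignatureMatrix(data=data)
        ranked = match_reference([1.0, 1.0], refdb, confident_threshold=1.0)
        assert bool(ranked.loc[0, "confident"])

    def test_empty_refdb_error(self):
        refdb = SignatureMatrix(data=pd.DataFrame(index=["c1", "c2"]))
        with pytest.raises(ValueError):
            match_reference([1.0, 0.0], refdb)


class TestMmrFlag:
    def test_hypermutator_with_mmr_signatures_flagged(self):
        flagged, rationale = flag_mmr_deficiency(
            {"SBS6": 0.3, "SBS44": 0.2, "SBS1": 0.5},
            sample_rate=13.0,
            cohort_rates=[1.0, 0.9, 1.1, 1.2, 13.0],
        )
        assert flagged
        assert rationale["mmr_exposure_fraction"] == pytest.approx(0.5)

    def test_median_rate_not_flagged(self):
        flagged, _ = flag_mmr_deficiency(
            {"SBS6": 0.5}, sample_rate=1.0, cohort_rates=[1.0, 1.0, 1.0]
        )
        assert not flagged

    def test_high_rate_without_mmr_exposure_not_flagged(self):
        flagged, rationale = flag_mmr_deficiency(
            {"SBS1": 1.0}, sample_rate=20.0, cohort_rates=[1.0, 1.0, 1.0, 20.0]
        )
        assert not flagged
        assert rationale["rate_elevated"] and not rationale["mmr_signatures_active"]

    def test_small_cohort_error(self):
        with pytest.raises(ValueError):
            flag_mmr_deficiency({"SBS6": 1.0}, 5.0, [1.0, 2.0])
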