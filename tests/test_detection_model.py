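import numpy as np
import pandas as pd
import pytest
from _oracles import statsmodels_probs
from hypothesis import given, settings
from hypothesis import strategies as st

from symbiodrop.detection_model import (
    DetectionMatrix,
    ModelError,
    build_training_mask,
    call_absence,
    combined_detection_probability,
    fit_detection_model,
    predict_detection,
    validate_fdr,
)
from symbiodrop.io_formats import GENOME, PresenceMatrix
from symbiodrop.synthetic_data import ScenarioConfig, simulate_study


def _det(data: pd.DataFrame, mask=None) -> DetectionMatrix:
    if mask is None:
        mask = pd.DataFrame(True, index=data.index, columns=data.columns)
    return DetectionMatrix(data, mask)


def _model_probs(model, genes, species):
    return pd.DataFrame(
        [[predict_detection(model, g, s).probability for s in species] for g in genes],
        index=genes,
        columns=species,
    )


class TestTrainingMask:
    TRAITS = {"sHost": "host", "sNon": "non-host"}
    CLASSES = {"gCons": "conserved", "gSymb": "symbiosis-specific"}

    def test_symbiosis_nonhost_cell_excluded(self):
        data = pd.DataFrame(
            [[1.0, 1.0], [1.0, 0.0]], index=["gCons", "gSymb"],
            columns=["sHost", "sNon"],
        )
        det = _det(data, mask=pd.DataFrame(False, index=data.index, columns=data.columns))
        masked = build_training_mask(det, self.TRAITS, self.CLASSES)
        assert masked.mask.to_numpy().sum() == 3
        assert not masked.mask.at["gSymb", "sNon"]

    def test_unknown_detection_stays_unmasked(self):
        data = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 0.0]], index=["gCons", "gSymb"],
            columns=["sHost", "sNon"],
        )
        det = _det(data, mask=pd.DataFrame(False, index=data.index, columns=data.columns))
        masked = build_training_mask(det, self.TRAITS, self.CLASSES)
        assert masked.mask.to_numpy().sum() == 1
        assert masked.mask.at["gCons", "sHost"]

    def test_unlabeled_gene_rejected(self):
        data = pd.DataFrame([[1.0]], index=["mystery"], columns=["sHost"])
        det = _det(data)
        with pytest.raises(ModelError, match="class"):
            build_training_mask(det, self.TRAITS, {})


class TestFit:
    def test_matches_external_glm_on_small_instances(self, masked_instances):
        """Fitted probabilities agree with statsmodels' binomial GLM
        (an independent maximum-likelihood route) to 1e-3."""
        for det in masked_instances:
            model = fit_detection_model(det)
            ours = _model_probs(model, det.genes, det.species)
            oracle = statsmodels_probs(det)
            assert np.nanmax(np.abs(ours.to_numpy() - oracle.to_numpy())) < 1e-3

    def test_loglik_never_decreases(self, masked_instances):
        for det in masked_instances:
            model = fit_detection_model(det)
            diffs = np.diff(model.loglik_path)
            assert (diffs >= -1e-10).all()

    def test_separated_instance_reaches_boundary_probabilities(self):
        # gene1 always detected, gene2 undetected only in species2: the
        # likelihood supremum sits at p = (1, 1, 1, 0)
        data = pd.DataFrame(
            [[1.0, 1.0], [1.0, 0.0]], index=["g1", "g2"], columns=["s1", "s2"]
        )
        model = fit_detection_model(_det(data))
        probs = _model_probs(
            model, ["g1", "g2"], ["s1", "s2"]
        ).to_numpy()
        assert np.abs(probs - np.array([[1, 1], [1, 0]])).max() < 1e-3

    def test_never_detected_gene_is_degenerate(self):
        data = pd.DataFrame(
            [[1.0, 1.0], [0.0, 0.0]], index=["g1", "g2"], columns=["s1", "s2"]
        )
        model = fit_detection_model(_det(data))
        assert "g2" in model.degenerate_genes
        assert np.isnan(model.alpha["g2"])
        pred = predict_detection(model, "g2", "s1")
        assert pred.probability == 0.0
        assert pred.cannot_reject_presence

    def test_shift_invariance_of_probabilities(self, masked_instances):
        det = masked_instances[0]
        model = fit_detection_model(det)
        base = _model_probs(model, det.genes, det.species)
        model.alpha += 3.0
        model.beta -= 3.0
        shifted = _model_probs(model, det.genes, det.species)
        assert np.allclose(base.to_numpy(), shifted.to_numpy())

    def test_reference_species_beta_zero(self, masked_instances):
        model = fit_detection_model(masked_instances[0])
        assert model.beta[model.reference_species] == 0.0

    def test_all_degenerate_unidentifiable(self):
        data = pd.DataFrame([[0.0, 0.0]], index=["g1"], columns=["s1", "s2"])
        with pytest.raises(ModelError, match="unidentifiable"):
            fit_detection_model(_det(data))


class TestPrediction:
    def test_closed_form_values(self, masked_instances):
        model = fit_detection_model(masked_instances[0])
        g = next(g for g in model.alpha.index if np.isfinite(model.alpha[g]))
        s = model.reference_species
        model.alpha[g] = 0.0
        assert predict_detection(model, g, s).probability == 0.5
        model.alpha[g] = np.log(3)
        assert predict_detection(model, g, s).probability == pytest.approx(0.75)

    def test_unfitted_species_rejected(self, masked_instances):
        model = fit_detection_model(masked_instances[0])
        with pytest.raises(ModelError):
            predict_detection(model, model.alpha.index[0], "nonesuch")


class TestCombinedProbability:
    @pytest.mark.parametrize(
        "probs,expected",
        [([], 0.0), ([0.5, 0.5], 0.75), ([1.0, 0.2], 1.0), ([0.9, 0.9], 0.99)],
    )
    def test_known_values(self, probs, expected):
        assert combined_detection_probability(probs) == pytest.approx(expected)

    @given(
        st.lists(st.floats(0.0, 1.0), max_size=8),
        st.floats(0.0, 1.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_monotone_in_added_species_and_probability(self, probs, extra):
        base = combined_detection_probability(probs)
        assert combined_detection_probability(probs + [extra]) >= base - 1e-12
        if probs:
            bumped = sorted(probs)
            bumped[-1] = max(bumped[-1], extra)
            assert combined_detection_probability(bumped) >= base - 1e-12

    def test_combined_at_least_max(self):
        probs = [0.2, 0.6, 0.4]
        assert combined_detection_probability(probs) >= max(probs)


class TestAbsenceCalls:
    def _fixture(self):
        data = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 0.0, 0.0]],
            index=["g1", "g2", "q"],
            columns=["s1", "s2", "s3"],
        )
        mask = pd.DataFrame(True, index=data.index, columns=data.columns)
        mask.loc["q", ["s2", "s3"]] = False
        return _det(data, mask)

    def test_call_requires_undetected_queries(self):
        det = self._fixture()
        model = fit_detection_model(det)
        with pytest.raises(ModelError, match="ill-posed"):
            call_absence(model, det, ["g1"], ["s2"], theta=0.9)

    def test_threshold_splits_calls(self):
        det = self._fixture()
        model = fit_detection_model(det)
        calls = call_absence(model, det, ["q"], ["s2", "s3"], theta=0.95)
        assert calls.combined["q"] == pytest.approx(
            combined_detection_probability(
                [model.predict("q", "s2"), model.predict("q", "s3")]
            )
        )
        assert set(calls.call.unique()) <= {"absence-supported", "inconclusive"}

    def test_degenerate_gene_always_inconclusive(self):
        data = pd.DataFrame(
            [[1.0, 1.0], [0.0, 0.0]], index=["g1", "dead"], columns=["s1", "s2"]
        )
        det = _det(data)
        model = fit_detection_model(det)
        calls = call_absence(model, det, ["dead"], ["s1", "s2"], theta=0.05)
        assert calls.call["dead"] == "inconclusive"
        assert calls.combined["dead"] == 0.0


class TestHoldOutValidation:
    def test_worked_four_gene_case_gives_quarter(self):
        """Four genes present in the validation genome but undetected in
        its transcriptome, one of them confidently callable: 1/4."""
        genes = ["gA", "gB", "gC", "gD", "r1", "r2", "r3", "r4", "r5", "r6"]
        species = ["v"] + [f"s{j}" for j in range(1, 9)]
        data = pd.DataFrame(1.0, index=genes, columns=species)
        # conserved anchors: each r_i misses exactly one transcriptome
        for k, sp in enumerate(["s1", "s2", "s3", "s4", "v"], start=1):
            data.loc[f"r{k}", sp] = 0.0
        # evaluated genes are undetected in v; gA is seen everywhere
        # else (high expression effect), gB-gD only in two species
        data.loc[["gA", "gB", "gC", "gD"], "v"] = 0.0
        for g in ["gB", "gC", "gD"]:
            data.loc[g, ["s1", "s2", "s3", "s4", "s7", "s8"]] = 0.0
        mask = pd.DataFrame(True, index=genes, columns=species)
        # the validation cells of the evaluated genes are queries, not
        # presence-assumed training data
        mask.loc[["gA", "gB", "gC", "gD"], "v"] = False
        det = _det(data, mask)
        model = fit_detection_model(det)
        presence = PresenceMatrix(
            pd.DataFrame(1.0, index=genes, columns=species),
            {s: GENOME for s in species},
        )
        result = validate_fdr(model, presence, det, "v", theta=0.95,
                              genes=["gA", "gB", "gC", "gD"])
        assert result.n_evaluated == 4
        assert result.supported == ["gA"]
        assert result.false_call_rate == 0.25

    def test_no_supported_calls_gives_zero(self, clean_study):
        s = clean_study
        masked = build_training_mask(s.detection, s.traits, s.labels)
        model = fit_detection_model(masked)
        validation = next(sp for sp in s.species if s.traits[sp] == "host")
        result = validate_fdr(model, s.truth, s.detection, validation, theta=1 - 1e-12)
        assert result.n_supported == 0
        assert result.false_call_rate in (0.0, None)

    def test_empty_evaluated_set_reported_as_undefined(self):
        data = pd.DataFrame([[1.0, 1.0]], index=["g1"], columns=["v", "s1"])
        det = _det(data)
        model = fit_detection_model(det)
        presence = PresenceMatrix(
            pd.DataFrame(1.0, index=["g1"], columns=["v", "s1"]),
            {"v": GENOME, "s1": GENOME},
        )
        result = validate_fdr(model, presence, det, "v")
        assert result.false_call_rate is None
        assert result.n_evaluated == 0


class TestParameterRecovery:
    def test_alpha_beta_recovered_on_synthetic_study(self):
        """Fitted gene and species effects track the simulating values."""
        cfg = ScenarioConfig(
            n_species=30, loss_clade_size=5, n_conserved=200, n_symbiosis=0,
            n_background=0, background_loss_rate=0.0, genome_mask_rate=0.0,
            alpha_mean=1.0, alpha_sd=1.5, beta_sd=1.0, seed=314,
        )
        study = simulate_study(cfg)
        masked = build_training_mask(study.detection, study.traits, study.labels)
        model = fit_detection_model(masked)
        ok = [g for g in study.genes if np.isfinite(model.alpha.get(g, np.nan))
              and g not in model.saturated_genes]
        oks = [s for s in study.species if np.isfinite(model.beta.get(s, np.nan))
               and s not in model.degenerate_species]
        r_alpha = np.corrcoef(model.alpha[ok], study.alpha[ok])[0, 1]
        r_beta = np.corrcoef(model.beta[oks], study.beta[oks])[0, 1]
        assert r_alpha >= 0.9
        assert r_beta >= 0.9
        # linear-predictor bias per masked cell
        bias = []
        for g in ok:
            for s in oks:
                if masked.mask.at[g, s]:
                    bias.append(
                        (model.alpha[g] + model.beta[s])
                        - (study.alpha[g] + study.beta[s])
                    )
        assert abs(np.mean(bias)) <= 0.1
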