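import dataclasses

import numpy as np
import pytest

from ceqpbpk import (
    DosingRegimen,
    NoiseModel,
    StudyDesign,
    correct_isf,
    generate_dialysate_study,
    generate_study,
    nca,
    simulate,
)
from ceqpbpk.model import auc
from ceqpbpk.population import DEFAULT_DISTRIBUTIONS
from ceqpbpk.synthetic import (
    DIALYSATE_TIMES,
    residue_depletion_design,
    single_dose_plasma_design,
)


class TestNoiseModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            NoiseModel(cv=-0.1)
        with pytest.raises(ValueError):
            NoiseModel(below_lloq="impute")

    def test_unit_mean_multiplicative_noise(self):
        noise = NoiseModel(cv=0.2)
        rng = np.random.default_rng(0)
        f = noise.apply(np.ones(200_000), rng)
        assert f.mean() == pytest.approx(1.0, rel=0.005)
        assert f.std() == pytest.approx(0.2, rel=0.02)


class TestGenerateStudy:
    def test_noise_free_single_animal_equals_model(self, phys, chem):
        design = single_dose_plasma_design(n_animals=1)
        ds = generate_study(design, NoiseModel(cv=0.0), phys, chem, seed=0)
        s = simulate(phys, chem, design.regimen, max(design.times) + 0.05)
        expected = np.interp(design.times, s.time, s.trace("plasma"))
        got = ds.data.sort_values("time_h")["concentration"].to_numpy()
        quant = expected >= 0.05
        assert got[quant] == pytest.approx(expected[quant], rel=1e-9)

    def test_same_seed_identical_dataset(self, phys, chem):
        design = single_dose_plasma_design(n_animals=3,
                                           distributions=DEFAULT_DISTRIBUTIONS)
        a = generate_study(design, NoiseModel(), phys, chem, seed=7)
        b = generate_study(design, NoiseModel(), phys, chem, seed=7)
        assert a.data.equals(b.data)

    def test_empirical_cv_matches_noise_model(self, phys, chem):
        """100 animals, one time point, CV 0.2: the sample CV lands in
        [0.15, 0.25]."""
        design = StudyDesign(DosingRegimen(2.0), ("plasma",), (1.0,),
                             n_animals=100)
        ds = generate_study(design, NoiseModel(cv=0.2), phys, chem, seed=3)
        c = ds.data["concentration"].to_numpy()
        assert 0.15 < c.std(ddof=1) / c.mean() < 0.25

    def test_censor_mode_emits_no_values_below_lloq(self, phys, chem):
        design = residue_depletion_design(n_animals=4)
        ds = generate_study(design, NoiseModel(cv=0.3, below_lloq="censor"),
                            phys, chem, seed=1)
        vals = ds.data["concentration"].dropna()
        assert (vals >= ds.lloq).all()
        assert ds.data.loc[ds.data["below_lloq"], "concentration"].isna().all()

    def test_drop_mode_removes_rows(self, phys, chem):
        design = residue_depletion_design(n_animals=4)
        censor = generate_study(design, NoiseModel(cv=0.3), phys, chem, seed=1)
        drop = generate_study(design, NoiseModel(cv=0.3, below_lloq="drop"),
                              phys, chem, seed=1)
        assert len(drop.data) == int((~censor.data["below_lloq"]).sum())

    def test_truth_metadata_records_generator(self, phys, chem):
        design = single_dose_plasma_design(n_animals=1)
        ds = generate_study(design, NoiseModel(), phys, chem, seed=0)
        assert ds.meta["truth"]["chem"] == chem
        assert ds.meta["seed"] == 0


class TestDialysateStudy:
    def _design(self, n=1, dists=()):
        return StudyDesign(DosingRegimen(2.0), ("lung_if",), DIALYSATE_TIMES,
                           n_animals=n, distributions=tuple(dists),
                           study_id="dialysate")

    def test_full_recovery_no_noise_equals_lung_if(self, phys, chem):
        ds = generate_dialysate_study(self._design(), 1.0, NoiseModel(cv=0.0, lloq=0.0),
                                      phys, chem, seed=0)
        s = simulate(phys, chem, DosingRegimen(2.0), 11.3)
        expected = np.interp(DIALYSATE_TIMES, s.time, s.trace("lung_if"))
        assert ds.data["concentration"].to_numpy() == pytest.approx(expected, rel=1e-9)

    def test_round_trip_with_isf_correction(self, phys, chem):
        rr = 0.288
        ds = generate_dialysate_study(self._design(), rr, NoiseModel(cv=0.0, lloq=0.0),
                                      phys, chem, seed=0)
        s = simulate(phys, chem, DosingRegimen(2.0), 11.3)
        truth = np.interp(DIALYSATE_TIMES, s.time, s.trace("lung_if"))
        corrected = correct_isf(ds.data["concentration"].to_numpy(), rr)
        assert corrected == pytest.approx(truth, rel=1e-9)

    def test_nca_auc_consistent_with_model_auc(self, phys, chem):
        """Trapezoid NCA of the corrected dialysate profile approximates
        the model's lung-IF AUC over the sampled span."""
        ds = generate_dialysate_study(self._design(), 0.288,
                                      NoiseModel(cv=0.0, lloq=0.0),
                                      phys, chem, seed=0)
        corrected = correct_isf(ds.data["concentration"].to_numpy(), 0.288)
        res = nca(np.array(DIALYSATE_TIMES), corrected)
        s = simulate(phys, chem, DosingRegimen(2.0), 11.3)
        model_auc = auc(s, "lung_if", DIALYSATE_TIMES[0], DIALYSATE_TIMES[-1])
        assert res.auc_last == pytest.approx(model_auc, rel=0.05)

    def test_invalid_rr_rejected(self, phys, chem):
        with pytest.raises(ValueError):
            generate_dialysate_study(self._design(), 0.0, NoiseModel(), phys, chem)


class TestStudyDesign:
    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(DosingRegimen(2.0), ("plasma",), (2.0, 1.0), 1)

    def test_zero_animals_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(single_dose_plasma_design(), n_animals=0)
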