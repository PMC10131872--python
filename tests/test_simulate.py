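"""Synthetic cohort generator: reproducibility, calibration moments and
configuration validation."""

import json

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit

import mtpcost as m
from mtpcost.simulate import GeneratorError, KRW_PER_USD


def _constant_covariates():
    """Degenerate covariate model: every subject aged 60, male, CCI 1."""
    return m.CovariateModel(
        age_band_probs=(0, 0, 0, 0, 1, 0, 0),
        age_band_lo=(18, 30, 40, 50, 60, 70, 80),
        age_band_hi=(30, 40, 50, 60, 60, 80, 90),
        female_prob=0.0, cci_probs=(0.0, 1.0, 0.0),
    )


class TestReproducibility:
    def test_same_seed_same_panel(self, small_config):
        a = m.generate_cohort(small_config)
        b = m.generate_cohort(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, small_config):
        a = m.generate_cohort(small_config)
        b = m.generate_cohort(small_config, seed=999)
        assert not a["cost"].equals(b["cost"])


class TestConfigValidation:
    def test_default_config_valid(self):
        cfg = m.default_params()
        cfg.validate()
        params = cfg.params()
        assert params.kappa > 0
        assert np.linalg.eigvalsh(params.covariance()).min() >= 0

    def test_default_structural_coefficients_match_reference(self):
        cfg = m.default_params()
        assert cfg.beta["region:after_time"] == -0.0152
        assert cfg.alpha["time"] == 0.0260
        assert cfg.beta["time"] == 0.0652

    @pytest.mark.parametrize("field,value", [
        ("n_subjects", 0),
        ("vulnerable_fraction", 1.2),
        ("kappa", -1.0),
        ("rho", 1.0),
        ("sigma_a", -0.1),
        ("death_hazard", 1.5),
        ("currency_rate", 0.0),
    ])
    def test_invalid_fields_rejected(self, field, value):
        cfg = m.default_params()
        setattr(cfg, field, value)
        with pytest.raises(GeneratorError):
            cfg.validate()

    def test_dict_round_trip(self):
        cfg = m.default_params()
        back = m.GeneratorConfig.from_dict(json.loads(json.dumps(
            m.simulate._jsonable(cfg.to_dict()))))
        assert back.params().to_dict(cfg.columns) == cfg.params().to_dict(cfg.columns)


class TestPanelStructure:
    def test_panel_shape_and_columns(self, small_panel, small_config):
        assert len(small_panel) == small_config.n_subjects * 49
        assert set(small_panel["time"]) == set(range(49))
        for col in ("subject_id", "time", "cost", "region", "age", "sex",
                    "income", "coverage", "cci"):
            assert col in small_panel.columns
        assert (small_panel["cost"] >= 0).all()

    def test_parc_consistent_with_region(self, small_panel):
        sub = small_panel.drop_duplicates("subject_id")
        lab = m.classify_region(sub["parc_value"].to_numpy())
        assert (lab == sub["region"].to_numpy()).all()

    def test_ground_truth_manifest(self, small_panel, small_config):
        truth = small_panel.attrs["ground_truth"]
        assert truth["config"]["seed"] == small_config.seed
        assert truth["config"]["kappa"] == small_config.kappa
        assert isinstance(truth["n_pi_clipped"], int)

    def test_write_cohort_files(self, small_panel, tmp_path):
        csv_path, json_path = m.write_cohort(small_panel, str(tmp_path / "c"))
        back = pd.read_csv(csv_path)
        assert len(back) == len(small_panel)
        with open(json_path) as fh:
            truth = json.load(fh)
        assert "config" in truth

    def test_death_hazard_truncates(self):
        cfg = m.default_params()
        cfg.n_subjects = 200
        cfg.seed = 5
        cfg.death_hazard = 0.02
        panel = m.generate_cohort(cfg)
        lengths = panel.groupby("subject_id")["time"].agg(["size", "max"])
        assert (lengths["size"] == lengths["max"] + 1).all()  # no gaps
        assert lengths["size"].min() < 49 <= lengths["size"].max() + 1


@pytest.fixture(scope="module")
def cell_panel():
    cfg = m.default_params()
    cfg.n_subjects = 4000
    cfg.seed = 77
    cfg.covariates = _constant_covariates()
    cfg.vulnerable_fraction = 0.0   # single region cell
    return cfg, m.generate_cohort(cfg)


class TestGenerativeMoments:
    """Empirical moments against the analytic two-part mixture."""

    def test_positive_share_matches_mixed_logistic(self, cell_panel):
        cfg, panel = cell_panel
        params = cfg.params()
        x = {c: 0.0 for c in cfg.columns}
        x.update({"intercept": 1.0, "age": 60.0, "cci": 1.0})
        z, w = hermegauss(41)
        w = w / np.sqrt(2 * np.pi)
        for t in (0, 24, 48):
            x_t = dict(x, time=float(t),
                       diagnosis=float(t >= 24),
                       **{"diagnosis:after_time": float(max(0, t - 24))})
            eta1 = sum(params.alpha[i] * x_t[c] for i, c in enumerate(cfg.columns))
            analytic = np.sum(w * expit(eta1 + params.sigma_a * z))
            emp = (panel.loc[panel["time"] == t, "cost"] > 0).mean()
            se = np.sqrt(analytic * (1 - analytic) / cfg.n_subjects)
            assert abs(emp - analytic) < 4 * se

    def test_mean_cost_matches_lognormal_mixing_identity(self, cell_panel):
        cfg, panel = cell_panel
        params = cfg.params()
        t = 24
        rows = panel[panel["time"] == t]
        x = {c: 0.0 for c in cfg.columns}
        x.update({"intercept": 1.0, "age": 60.0, "cci": 1.0,
                  "time": float(t), "diagnosis": 1.0})
        eta2 = sum(params.beta[i] * x[c] for i, c in enumerate(cfg.columns))
        analytic = np.exp(eta2 + params.sigma_d**2 / 2) / cfg.currency_rate
        emp = rows["cost"].mean()
        se = rows["cost"].std() / np.sqrt(len(rows))
        assert abs(emp - analytic) < 4 * se

    def test_no_random_effects_gives_independent_two_part(self):
        cfg = m.default_params()
        cfg.n_subjects = 3000
        cfg.seed = 11
        cfg.covariates = _constant_covariates()
        cfg.vulnerable_fraction = 0.0
        cfg.sigma_a = cfg.sigma_d = 0.0
        cfg.rho = 0.0
        panel = m.generate_cohort(cfg)
        params = cfg.params()
        t = 10
        rows = panel[panel["time"] == t]
        eta1 = (params.alpha[0] + params.alpha[3] * t
                + params.alpha[8] * 60.0 + params.alpha[10] * 1.0)
        eta2 = (params.beta[0] + params.beta[3] * t
                + params.beta[8] * 60.0 + params.beta[10] * 1.0)
        pi = expit(eta1)
        emp_pos = (rows["cost"] > 0).mean()
        assert abs(emp_pos - pi) < 4 * np.sqrt(pi * (1 - pi) / len(rows))
        pos = rows.loc[rows["cost"] > 0, "cost"]
        mu = np.exp(eta2) / pi / cfg.currency_rate
        assert abs(pos.mean() - mu) < 4 * pos.std() / np.sqrt(len(pos))

    def test_zero_share_near_study_level(self):
        # full covariate mix at reduced size; the full-size calibration
        # check lives in the acceptance suite
        cfg = m.default_params()
        cfg.n_subjects = 2000
        cfg.seed = 3
        panel = m.generate_cohort(cfg)
        assert abs(m.zero_fraction(panel) - 0.29) < 0.02


def test_currency_rate_matches_study_conversion():
    assert KRW_PER_USD == pytest.approx(1313.17, abs=0.01)
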