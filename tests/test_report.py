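import hashlib

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from fabrykit.cli import main as cli_main
from fabrykit.config import AppConfig, load_config, write_default_config
from fabrykit.errors import ConfigurationError, DataError
from fabrykit.report import (
    annotate_cohort,
    carrier_proportion,
    cohort_counts_table,
    run_full_analysis,
)
from fabrykit.simulate import SimConfig, generate_cohort


@pytest.mark.parametrize(
    "carriers,wildtype,digits,expected",
    [
        (1587, 210_097, 4, 0.0075),
        (854, 214_197, 5, 0.00397),
        (0, 100, 4, 0.0),
        (1, 3, 2, 0.25),
    ],
)
def test_carrier_proportion_printed_precision(carriers, wildtype, digits, expected):
    assert carrier_proportion(carriers, wildtype, digits) == expected


def test_carrier_proportion_half_even_rounding():
    # 1/8 = 0.125 -> 0.12 under banker's rounding at two digits
    assert carrier_proportion(1, 7, 2) == 0.12
    assert carrier_proportion(3, 5, 1) == 0.4  # 0.375 -> 0.4 (round up: 7 is odd digit)


def test_carrier_proportion_errors():
    with pytest.raises(DataError):
        carrier_proportion(0, 0)
    with pytest.raises(DataError):
        carrier_proportion(-1, 10)


def test_counts_table_all_wildtype():
    cohort = pd.DataFrame({"sex": ["male", "female"] * 10, "ac_G": 0})
    table = cohort_counts_table(cohort, ["G"])
    row = table.iloc[0]
    assert row["carriers_male"] == 0 and row["prop_male"] == 0.0
    assert row["wildtype_female"] == 10


def test_counts_table_conservation(dense_cohort, dense_config):
    table = cohort_counts_table(dense_cohort.table, dense_config.groups)
    for _, row in table.iterrows():
        assert row["carriers_male"] + row["wildtype_male"] == dense_config.n_males
        assert (row["carriers_female"] + row["wildtype_female"]
                + row["homozygous_female"]) == dense_config.n_females


def test_counts_table_binomial_tolerance(dense_cohort, dense_config):
    table = cohort_counts_table(dense_cohort.table, dense_config.groups).set_index("group")
    n = dense_config.n_males
    for group, freq in dense_config.carrier_freq_by_group.items():
        observed = table.loc[group, "carriers_male"] / n
        tol = 4 * np.sqrt(freq * (1 - freq) / n)
        assert abs(observed - freq) < tol


def test_annotation_columns_and_missing_renal(annotated):
    for col in ("fdf_pain", "fdf_renal", "fdf_cardiac", "fdf_cerebrovascular",
                "fdf_total", "fdf_high", "hypertension", "diabetes"):
        assert col in annotated.columns
    missing_renal = annotated["uacr"].isna() | annotated["egfr"].isna()
    assert annotated.loc[missing_renal, "fdf_total"].isna().all()
    scored = annotated["fdf_total"].notna()
    assert (annotated.loc[scored, "fdf_high"]
            == (annotated.loc[scored, "fdf_total"] > 4)).all()


def _small_run(tmp_path, seed=1):
    config = SimConfig(
        n_males=4000, n_females=4000, seed=seed,
        carrier_freq_by_group={"ALL_P": 0.02, "ALL_C": 0.03},
    )
    return run_full_analysis(sim_config=config, out_dir=tmp_path,
                             trait_labs=("egfr", "uacr", "cholesterol"))


def test_full_analysis_smoke_and_determinism(tmp_path):
    bundle = _small_run(tmp_path / "run1")
    assert not bundle.counts.empty
    assert not bundle.adjusted.empty
    assert not bundle.traits.empty
    assert set(bundle.paths) == {
        "cohort_counts.tsv", "fdf_distribution.tsv", "associations_adjusted.tsv",
        "associations_stratified.tsv", "trait_models.tsv", "cv_model.txt",
    }
    assert "auc" in bundle.roc
    _small_run(tmp_path / "run2")
    for name in bundle.paths:
        h1 = hashlib.sha256((tmp_path / "run1" / name).read_bytes()).hexdigest()
        h2 = hashlib.sha256((tmp_path / "run2" / name).read_bytes()).hexdigest()
        assert h1 == h2  # same seed and config -> byte-identical report


def test_bh_applied_across_full_result_set(tmp_path):
    bundle = _small_run(tmp_path)
    pooled = pd.concat([bundle.adjusted, bundle.traits[bundle.adjusted.columns]])
    ok = pooled["p_adjusted"].notna()
    assert (pooled.loc[ok, "p_adjusted"] >= pooled.loc[ok, "p_raw"] - 1e-12).all()


def test_config_roundtrip(tmp_path):
    path = tmp_path / "config.yaml"
    write_default_config(path)
    app = load_config(path)
    default = AppConfig()
    assert app.simulation.carrier_freq_by_group == default.simulation.carrier_freq_by_group
    assert app.scoring.egfr_bands == default.scoring.egfr_bands
    assert app.registry.riskfactor_codes == default.registry.riskfactor_codes


def test_config_rejects_unknown_fields(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("simulation:\n  frobnicate: 3\n")
    with pytest.raises(ConfigurationError):
        load_config(path)
    path.write_text("mystery_section: {}\n")
    with pytest.raises(ConfigurationError):
        load_config(path)


def test_cli_simulate_and_score(tmp_path):
    runner = CliRunner()
    config_path = tmp_path / "config.yaml"
    config_path.write_text(
        "simulation:\n"
        "  n_males: 1500\n"
        "  n_females: 1500\n"
        "  carrier_freq_by_group: {ALL_P: 0.02, ALL_C: 0.03}\n"
        "  seed: 3\n"
    )
    out_dir = tmp_path / "out"
    base = ["--config", str(config_path), "--out-dir", str(out_dir)]
    result = runner.invoke(cli_main, base + ["simulate"])
    assert result.exit_code == 0, result.output
    cohort_path = out_dir / "cohort.tsv"
    assert cohort_path.exists()
    result = runner.invoke(cli_main, base + ["score", str(cohort_path)])
    assert result.exit_code == 0, result.output
    scored = pd.read_csv(out_dir / "cohort_scored.tsv", sep="\t")
    assert "fdf_total" in scored.columns
    result = runner.invoke(cli_main, base + ["cvrisk", str(cohort_path)])
    assert result.exit_code == 0, result.output
    assert (out_dir / "cv_model.txt").exists()


def test_cli_init_config(tmp_path):
    runner = CliRunner()
    target = tmp_path / "cfg.yaml"
    result = runner.invoke(
        cli_main,
        ["--out-dir", str(tmp_path / "od"), "init-config", "--out", str(target)],
    )
    assert result.exit_code == 0
    assert load_config(target).scoring.domain_max == 4
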