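"""Cohort table ingestion and sample-specific model instantiation."""

import numpy as np
import pandas as pd
import pytest

from tmesim.cohort import (MUTATION_PREVALENCE, read_cohort,
                           instantiate_sample, sample_mutation_bits)
from tmesim.demo import demo_parameter_space
from tmesim.tissue import generate_tissue


@pytest.fixture()
def cohort_files(tmp_path):
    pd.DataFrame({
        "barcode": ["S1", "S2", "S3"],
        "PCC": [0.5, 0.3, 0.6],
        "PSC": [0.3, 0.5, 0.2],
        "other": [0.2, 0.2, 0.2],        # unmodeled mass, discarded
    }).to_csv(tmp_path / "fractions.csv", index=False)
    pd.DataFrame({
        "barcode": ["S1", "S2", "S3"],
        "KRAS": [1, 1, 0], "TP53": [1, 0, 1],
        "CDKN2A": [0, 0, 1], "SMAD4": [0, 1, 0],
    }).to_csv(tmp_path / "mutations.csv", index=False)
    genes = [f"g{i}" for i in range(6)]
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.random((6, 3)), columns=["S1", "S2", "S3"])
    expr.insert(0, "gene", genes)
    expr.to_csv(tmp_path / "expression.csv", index=False)
    return tmp_path


def test_read_cohort_roundtrip(cohort_files):
    records = read_cohort(cohort_files / "fractions.csv",
                          cohort_files / "mutations.csv",
                          cohort_files / "expression.csv",
                          cell_types=["PCC", "PSC"])
    assert len(records) == 3
    by = {r.barcode: r for r in records}
    # fractions renormalized over modeled types
    assert sum(by["S1"].fractions.values()) == pytest.approx(1.0)
    assert by["S1"].fractions["PCC"] == pytest.approx(0.5 / 0.8)
    assert by["S3"].mutations == {"KRAS": 0, "TP53": 1, "CDKN2A": 1, "SMAD4": 0}
    assert len(by["S2"].expression) == 6


def test_missing_barcode_dropped_with_warning(cohort_files, caplog):
    mu = pd.read_csv(cohort_files / "mutations.csv")
    mu.iloc[:2].to_csv(cohort_files / "mutations.csv", index=False)
    with caplog.at_level("WARNING"):
        records = read_cohort(cohort_files / "fractions.csv",
                              cohort_files / "mutations.csv",
                              cohort_files / "expression.csv",
                              cell_types=["PCC", "PSC"])
    assert {r.barcode for r in records} == {"S1", "S2"}
    assert "dropped" in caplog.text


def test_shuffled_rows_yield_identical_records(cohort_files):
    ref = {r.barcode: r for r in read_cohort(
        cohort_files / "fractions.csv", cohort_files / "mutations.csv",
        cohort_files / "expression.csv", cell_types=["PCC", "PSC"])}
    fr = pd.read_csv(cohort_files / "fractions.csv").iloc[::-1]
    fr.to_csv(cohort_files / "fractions.csv", index=False)
    shuffled = {r.barcode: r for r in read_cohort(
        cohort_files / "fractions.csv", cohort_files / "mutations.csv",
        cohort_files / "expression.csv", cell_types=["PCC", "PSC"])}
    for bc in ref:
        assert ref[bc].fractions == shuffled[bc].fractions
        assert ref[bc].mutations == shuffled[bc].mutations


def test_missing_column_named(cohort_files):
    mu = pd.read_csv(cohort_files / "mutations.csv").drop(columns=["SMAD4"])
    mu.to_csv(cohort_files / "mutations.csv", index=False)
    with pytest.raises(ValueError, match="SMAD4"):
        read_cohort(cohort_files / "fractions.csv",
                    cohort_files / "mutations.csv",
                    cohort_files / "expression.csv")


def test_negative_fraction_rejected(cohort_files):
    fr = pd.read_csv(cohort_files / "fractions.csv")
    fr.loc[0, "PCC"] = -0.1
    fr.to_csv(cohort_files / "fractions.csv", index=False)
    with pytest.raises(ValueError, match="negative"):
        read_cohort(cohort_files / "fractions.csv",
                    cohort_files / "mutations.csv",
                    cohort_files / "expression.csv",
                    cell_types=["PCC", "PSC"])


def test_long_format_expression(cohort_files):
    wide = pd.read_csv(cohort_files / "expression.csv")
    long = wide.melt(id_vars="gene", var_name="barcode", value_name="value")
    long.to_csv(cohort_files / "expression.csv", index=False)
    records = read_cohort(cohort_files / "fractions.csv",
                          cohort_files / "mutations.csv",
                          cohort_files / "expression.csv",
                          cell_types=["PCC", "PSC"])
    assert len(records) == 3 and len(records[0].expression) == 6


def test_instantiate_sample_sets_composition_and_mutations(cohort_files, demo):
    records = {r.barcode: r for r in read_cohort(
        cohort_files / "fractions.csv", cohort_files / "mutations.csv",
        cohort_files / "expression.csv", cell_types=["PCC", "PSC"])}
    space = demo_parameter_space(include_mutations=True).drop("r_PSC")
    model, sp = instantiate_sample(records["S3"], demo, space)
    # S3 has no KRAS/SMAD4 mutation: alphas forced to 0, params dropped
    alphas = {m.gene: m.alpha for m in model.mutations}
    assert alphas["KRAS"] == 0.0 and alphas["SMAD4"] == 0.0
    names = sp.names
    assert "alpha:KRAS" not in names and "alpha:SMAD4" not in names
    assert "alpha:TP53" in names and "alpha:CDKN2A" in names
    assert model.tissue.r_C == pytest.approx(0.75)
    # base model untouched
    assert demo.tissue.r_C == 0.6


def test_instantiated_tissue_matches_record_fractions(cohort_files, demo):
    records = {r.barcode: r for r in read_cohort(
        cohort_files / "fractions.csv", cohort_files / "mutations.csv",
        cohort_files / "expression.csv", cell_types=["PCC", "PSC"])}
    model = instantiate_sample(records["S2"], demo)
    counts = {"PCC": 0, "PSC": 0}
    for seed in range(30):
        c = generate_tissue(model.tissue, seed=seed).type_counts()
        for t in counts:
            counts[t] += c.get(t, 0)
    total = sum(counts.values())
    frac_pcc = counts["PCC"] / total
    se = np.sqrt(0.375 * 0.625 / total)
    assert abs(frac_pcc - 0.3 / 0.8) < 4 * se


def test_mutation_bit_prevalence_law_of_large_numbers(rng):
    bits = pd.DataFrame([sample_mutation_bits(MUTATION_PREVALENCE, rng)
                         for _ in range(2000)])
    for gene, p in MUTATION_PREVALENCE.items():
        se = np.sqrt(p * (1 - p) / 2000)
        assert abs(bits[gene].mean() - p) < 4 * se
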