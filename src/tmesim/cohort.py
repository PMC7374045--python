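"""Cohort tables -> sample-specific models.

Reads the three per-sample tables produced upstream of the simulator —
cell-type fractions (deconvolution output), binary mutation presence for
KRAS/TP53/CDKN2A/SMAD4, and deconvolved cancer-cell gene expression — joins
them on sample barcode, and instantiates a sample-specific model: the tissue
composition is set from the fractions (renormalized over the modeled cell
types, with the ductal/cancer estimate as the cancer fraction), and for each
gene whose mutation bit is 0 the mutated fraction alpha_g is fixed at 0 and
removed from the calibration space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import TMEModel
from .params import ParameterSpace

__all__ = ["SampleRecord", "read_cohort", "read_table", "instantiate_sample",
           "MUTATION_GENES", "MUTATION_PREVALENCE"]

logger = logging.getLogger(__name__)

MUTATION_GENES = ["KRAS", "TP53", "CDKN2A", "SMAD4"]
#: cohort prevalence of each mutation among TCGA PDAC samples
MUTATION_PREVALENCE = {"KRAS": 0.93, "TP53": 0.73, "CDKN2A": 0.30, "SMAD4": 0.32}


@dataclass
class SampleRecord:
    barcode: str
    fractions: dict[str, float]        # renormalized over modeled cell types
    mutations: dict[str, int]          # gene -> 0/1
    expression: pd.Series              # gene -> deconvolved cancer expression

    def __post_init__(self):
        total = sum(self.fractions.values())
        if total <= 0:
            raise ValueError(f"{self.barcode}: nonpositive total cell fraction")
        if abs(total - 1.0) > 1e-9:
            self.fractions = {k: v / total for k, v in self.fractions.items()}
        for g, bit in self.mutations.items():
            if bit not in (0, 1):
                raise ValueError(f"{self.barcode}: mutation bit for {g} must be 0/1")


def read_table(path) -> pd.DataFrame:
    """Delimited table, CSV or TSV auto-detected by extension."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def _require(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing column(s) {missing}")


def read_cohort(fractions_file, mutations_file, expression_file,
                cell_types=None, mutation_genes=None) -> list[SampleRecord]:
    """Inner-join the three tables on barcode and validate each sample.

    The expression table may be wide (genes x samples, first column the gene
    name) or long (columns barcode, gene, value).  Samples missing from any
    table are dropped with a logged warning.
    """
    mutation_genes = list(mutation_genes or MUTATION_GENES)
    fr = read_table(fractions_file)
    mu = read_table(mutations_file)
    _require(fr, ["barcode"], "fractions")
    _require(mu, ["barcode"] + mutation_genes, "mutations")
    if cell_types is None:
        cell_types = [c for c in fr.columns if c != "barcode"]
    _require(fr, cell_types, "fractions")
    if (fr[cell_types].to_numpy(float) < 0).any():
        raise ValueError("negative cell fraction in fractions table")

    ex = read_table(expression_file)
    if {"barcode", "gene", "value"} <= set(ex.columns):          # long format
        expr = ex.pivot(index="gene", columns="barcode", values="value")
    else:                                                        # wide: genes x samples
        expr = ex.set_index(ex.columns[0])
    expr.columns = expr.columns.astype(str)

    fr = fr.set_index(fr["barcode"].astype(str))
    mu = mu.set_index(mu["barcode"].astype(str))
    barcodes = fr.index.intersection(mu.index).intersection(expr.columns)
    dropped = (set(fr.index) | set(mu.index) | set(expr.columns)) - set(barcodes)
    if dropped:
        logger.warning("dropped %d barcode(s) absent from some table: %s",
                       len(dropped), sorted(dropped)[:10])

    records = []
    for bc in barcodes:
        records.append(SampleRecord(
            barcode=bc,
            fractions={ct: float(fr.loc[bc, ct]) for ct in cell_types},
            mutations={g: int(mu.loc[bc, g]) for g in mutation_genes},
            expression=expr[bc].astype(float),
        ))
    return records


def sample_mutation_bits(probabilities: dict[str, float],
                         rng: np.random.Generator) -> dict[str, int]:
    """Bernoulli instantiation of binary mutation presence from per-gene
    probabilities (helper for synthetic cohorts; real cohorts arrive already
    instantiated)."""
    return {g: int(rng.random() < p) for g, p in probabilities.items()}


def instantiate_sample(record: SampleRecord, base_model: TMEModel,
                       space: ParameterSpace | None = None):
    """Derive a sample-specific model (and calibration space) from a record.

    Pure derivation: the base model is never mutated.  Sets the cancer
    fraction and stromal composition from the record's fractions; for each
    mutation gene with bit 0 the alpha is fixed at 0 and the corresponding
    ``alpha:<gene>`` parameter is dropped from the space.
    Returns ``model`` or ``(model, space)`` if a space was supplied.
    """
    for ct in base_model.networks:
        if ct not in record.fractions:
            raise ValueError(f"sample {record.barcode} lacks a fraction for "
                             f"modeled cell type {ct!r}")
    cancer = base_model.cancer_type
    modeled = {ct: record.fractions[ct] for ct in base_model.networks}
    total = sum(modeled.values())
    r_C = modeled[cancer] / total
    stromal = {ct: v / total for ct, v in modeled.items() if ct != cancer}
    denom = sum(stromal.values())
    stromal_fractions = ({ct: v / denom for ct, v in stromal.items()}
                         if denom > 0 else {})
    tissue = base_model.tissue.replace(r_C=r_C, cancer_type=cancer,
                                       stromal_fractions=stromal_fractions)

    mutations = []
    absent = []
    for m in base_model.mutations:
        bit = record.mutations.get(m.gene)
        if bit == 0:
            mutations.append(replace(m, alpha=0.0))
            absent.append(m.gene)
        else:
            mutations.append(m)

    model = TMEModel(networks=base_model.networks,
                     cytokines=list(base_model.cytokines.values()),
                     secretion=base_model.secretion,
                     receptors=base_model.receptors,
                     tissue=tissue, mutations=mutations, q=base_model.q,
                     h=base_model.h, cancer_type=cancer,
                     name=f"{base_model.name}:{record.barcode}")
    if space is None:
        return model
    space = space.drop(*[f"alpha:{g}" for g in absent])
    return model, space
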