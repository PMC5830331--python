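import numpy as np
import pandas as pd
import pytest

from bemut import simulate
from bemut.arms import load_arm_table
from bemut.refsigs import load_reference_signatures


@pytest.fixture(scope="session")
def arm_table():
    return load_arm_table()


@pytest.fixture(scope="session")
def reference():
    return load_reference_signatures()


@pytest.fixture(scope="session")
def gene_model(arm_table):
    return simulate.synthetic_gene_model(arm_table=arm_table)


@pytest.fixture(scope="session")
def pathway_db(gene_model):
    return simulate.synthetic_pathways(gene_model)


@pytest.fixture(scope="session")
def small_cohort(reference, gene_model, pathway_db, arm_table):
    """One default-configuration cohort shared across read-only tests."""
    truth = simulate.default_truth(seed=11)
    catalog, meta, segments, truth_log = simulate.generate_cohort(
        truth, pathway_db, reference, gene_model, arm_table
    )
    return {
        "truth": truth,
        "catalog": catalog,
        "meta": meta,
        "segments": segments,
        "truth_log": truth_log,
    }


@pytest.fixture()
def tiny_catalog():
    """Hand-built three-patient catalog with known channel content."""
    rows = [
        ("P1", "1", 1000, "C", "T", "SNV", "ACG", 0.40, "G1", "exon-non-synonymous"),
        ("P1", "1", 2000, "G", "T", "SNV", "AGA", 0.10, "G1", "intron-coding-gene"),
        ("P2", "2", 500, "A", "G", "SNV", "TAC", 0.31, "", "intergenic-near-capture"),
        ("P2", "2", 900, "AT", "A", "DEL", "", 0.25, "G2", "3'utr-exon"),
        ("P3", "3", 123, "T", "C", "SNV", "CTT", 0.50, "G2,G3", "coding-splicing"),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "chrom", "pos", "ref", "alt",
            "mut_type", "context3", "vaf", "genes", "category",
        ],
    )


@pytest.fixture()
def tiny_meta():
    return pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3"],
            "nsaid_user": [True, False, True],
            "ever_smoker": [False, True, False],
            "tp53_mutant": [False, False, True],
            "target_mb": [100.0, 100.0, 50.0],
        }
    )
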